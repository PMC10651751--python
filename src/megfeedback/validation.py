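"""Calibration and recovery experiments for the whole pipeline.

These functions run the package's own methods on synthetic studies whose
ground truth is known — exchangeable null data for family-wise error
calibration, planted amplitude and narrow-band oscillatory effects for
recovery — and report empirical rates.  They are the quantitative basis for
trusting the cluster inference: a well-calibrated test rejects on null data
at its nominal level, and a useful one recovers effects of realistic size.
"""

from __future__ import annotations

import numpy as np

from ._utils import substream
from .cluster import ClusterConfig, critical_t, permutation_test
from .lattices import space_time_lattice
from .mesh import make_synthetic_mesh
from .roi import compare_learners, representative_stc
from .synth import EffectSpec, EpochWindow, generate_source_epochs
from .task import TaskConfig, generate_task_session
from .tfr import TFRConfig, morlet_tfr, spectrotemporal_cluster_test, \
    tfr_baseline_zscore

__all__ = [
    "contingency_percentage", "scpt_false_positive_rate",
    "amplitude_recovery", "oscillation_recovery", "learner_contrast_power",
]


def contingency_percentage(seed: int, n_draws: int = 100_000) -> float:
    """Percent of dominant ('sun') outcomes for one sun-dominant stimulus.

    Simulates ``n_draws`` task trials per stimulus under the default task
    configuration (90/10 contingency) and reports the empirical percentage of
    'sun' outcomes for a sun-dominant stimulus.
    """
    cfg = TaskConfig(n_blocks=1, trials_per_block=4 * n_draws)
    session = generate_task_session(cfg, seed=seed)
    sun_dom = session.loc[session["dominant_outcome"] == "sun", "stimulus"].iloc[0]
    sub = session[session["stimulus"] == sun_dom]
    return 100.0 * float((sub["outcome"] == "sun").mean())


def scpt_false_positive_rate(
    seed: int,
    n_datasets: int = 500,
    n_control: int = 20,
    n_trauma: int = 55,
    n_vertices: int = 200,
    n_times: int = 40,
    n_permutations: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Family-wise false-positive rate of the SCPT under exchangeable null.

    Every dataset is white Gaussian per-subject source maps for two groups of
    the study's sizes on a shared synthetic mesh; a study counts as a false
    positive when any cluster's permutation p-value is at or below ``alpha``.
    The cluster-forming threshold is the two-sided critical t at ``alpha``
    for the two-sample design (1.99 for 20 + 55 subjects).
    """
    rng = substream(seed, "scpt-null")
    mesh = make_synthetic_mesh(n_vertices, 8, seed=int(rng.integers(2**31)))
    lattice = space_time_lattice(mesh, n_times)
    df = n_control + n_trauma - 2
    thr = round(critical_t(alpha, df, 2), 2)
    hits = 0
    for _ in range(n_datasets):
        a = rng.standard_normal((n_control, lattice.n_elements))
        b = rng.standard_normal((n_trauma, lattice.n_elements))
        cfg = ClusterConfig(t_threshold=thr, n_permutations=n_permutations,
                            significance_alpha=alpha,
                            seed=int(rng.integers(2**31)))
        res = permutation_test(a, b, lattice, cfg)
        hits += res.min_p() <= alpha
    rate = hits / n_datasets
    return {"rate": rate, "n_datasets": n_datasets, "t_threshold": thr,
            "bound": alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_datasets)}


def amplitude_recovery(
    seed: int,
    n_sims: int = 50,
    amplitude_delta: float = 1.5,
    time_window_s: tuple = (0.2, 0.4),
    n_per_group: int = 15,
    n_epochs: int = 30,
    n_vertices: int = 100,
    n_parcels: int = 5,
    sfreq: float = 50.0,
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Detection and localisation of a planted amplitude effect.

    One group carries an ``amplitude_delta`` (baseline-SD units) shift in one
    parcel within ``time_window_s``.  A simulation is *detected* when the
    SCPT yields a cluster with p <= alpha, and *identified* when the parcel
    holding most of the top cluster's vertices is the planted parcel.
    """
    rng = substream(seed, "amp-recovery")
    mesh = make_synthetic_mesh(n_vertices, n_parcels,
                               seed=int(rng.integers(2**31)),
                               medial_wall_fraction=0.0)
    target = max(mesh.parcels, key=lambda k: len(mesh.parcels[k]))
    window = EpochWindow(sfreq=sfreq)
    n_times = window.times().size
    lattice = space_time_lattice(mesh, n_times)
    effect = EffectSpec(parcels=(target,), time_window_s=time_window_s,
                        amplitude_delta=amplitude_delta)
    detected = identified = 0
    for _ in range(n_sims):
        maps_a, maps_b = [], []
        for _ in range(n_per_group):
            maps_a.append(generate_source_epochs(
                mesh, n_epochs, None, seed=int(rng.integers(2**31)),
                window=window).data.mean(0))
            maps_b.append(generate_source_epochs(
                mesh, n_epochs, effect, seed=int(rng.integers(2**31)),
                window=window).data.mean(0))
        cfg = ClusterConfig(cluster_alpha=0.05, n_permutations=n_permutations,
                            significance_alpha=alpha,
                            seed=int(rng.integers(2**31)))
        res = permutation_test(
            np.stack(maps_a).reshape(n_per_group, -1),
            np.stack(maps_b).reshape(n_per_group, -1), lattice, cfg)
        sig = res.significant(alpha)
        if not sig:
            continue
        detected += 1
        top = max(sig, key=lambda c: abs(c.mass))
        verts = top.element_indices // n_times
        labels, counts = np.unique(
            [mesh.parcel_label[int(v)] for v in np.unique(verts)],
            return_counts=True)
        if labels[np.argmax(counts)] == target:
            identified += 1
    return {"detection_rate": detected / n_sims,
            "identification_rate": identified / n_sims,
            "planted_parcel": target, "n_sims": n_sims}


def oscillation_recovery(
    seed: int,
    n_sims: int = 50,
    osc_freq_hz: float = 6.0,
    osc_amplitude: float = 1.5,
    time_window_s: tuple = (0.2, 0.5),
    n_per_group: int = 15,
    n_epochs: int = 40,
    sfreq: float = 200.0,
    n_permutations: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Recovery of a planted narrow-band power effect in the TFR pipeline.

    One group's ROI time course carries a windowed ``osc_freq_hz`` sinusoid.
    Per subject, the representative time course is Morlet-transformed and
    baseline z-scored; the groups are compared with the spectro-temporal
    cluster test.  A simulation counts as recovered when a significant
    cluster's frequency extent covers the planted frequency.
    """
    rng = substream(seed, "osc-recovery")
    mesh = make_synthetic_mesh(1, 1, seed=0)
    window = EpochWindow(sfreq=sfreq)
    tcfg = TFRConfig()
    effect = EffectSpec(parcels=("parcel_0",), time_window_s=time_window_s,
                        amplitude_delta=0.0, osc_freq_hz=osc_freq_hz,
                        osc_amplitude=osc_amplitude)
    covered = detected = 0
    import warnings
    for _ in range(n_sims):
        planes = {"a": [], "b": []}
        for grp, eff in (("a", None), ("b", effect)):
            for _ in range(n_per_group):
                ep = generate_source_epochs(
                    mesh, n_epochs, eff, seed=int(rng.integers(2**31)),
                    window=window)
                rstc = representative_stc(ep, [0])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    raw = morlet_tfr(rstc, ep.times_s, sfreq, tcfg)
                planes[grp].append(tfr_baseline_zscore(raw).power)
        cfg = ClusterConfig(t_threshold=2.0, n_permutations=n_permutations,
                            significance_alpha=alpha,
                            seed=int(rng.integers(2**31)))
        res, lattice = spectrotemporal_cluster_test(
            np.stack(planes["a"]), np.stack(planes["b"]), cfg)
        sig = res.significant(alpha)
        if not sig:
            continue
        detected += 1
        for c in sig:
            f_idx = np.unravel_index(c.element_indices, lattice.shape)[0]
            fmin, fmax = tcfg.freqs_hz[f_idx.min()], tcfg.freqs_hz[f_idx.max()]
            if fmin <= osc_freq_hz <= fmax:
                covered += 1
                break
    return {"detection_rate": detected / n_sims,
            "frequency_coverage_rate": covered / n_sims, "n_sims": n_sims}


def learner_contrast_power(
    seed: int,
    n_sims: int = 200,
    gap_sd: float = 1.5,
    n_learners: int = 36,
    n_nonlearners: int = 19,
    alpha: float = 0.05,
) -> dict:
    """Power of the learner vs non-learner contrast at a planted TOI gap.

    Learner and non-learner per-subject summaries are unit-variance normals
    whose means differ by ``gap_sd`` pooled SDs; reports the fraction of
    simulations with p < alpha and the (constant) reported df.
    """
    rng = substream(seed, "learner-power")
    flags = np.array([True] * n_learners + [False] * n_nonlearners)
    hits = 0
    df = None
    for _ in range(n_sims):
        values = rng.standard_normal(flags.size)
        values[~flags] += gap_sd
        res = compare_learners(values, flags)
        df = res["df"]
        hits += res["p"] < alpha
    return {"power": hits / n_sims, "df": df, "n_sims": n_sims}
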