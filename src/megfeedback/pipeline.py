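"""End-to-end study orchestration.

``simulate_study`` builds a complete synthetic study — mesh, behavioral
sessions, source-space epochs for positive- and negative-feedback events,
with configurable planted group effects.  ``run_pipeline`` takes a study
through behavioral statistics, epoch preparation, spatio-temporal cluster
inference, ROI extraction, temporal and spectro-temporal cluster tests and
learner contrasts, writing a JSON summary report plus stage outputs.

All randomness flows from one root seed through named substreams, so
rerunning a stage never changes another stage's draws and identical configs
give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import prep, roi, tfr
from ._utils import substream
from .cluster import ClusterConfig, critical_t, permutation_test
from .lattices import space_time_lattice
from .mesh import Mesh, make_synthetic_mesh
from .synth import EffectSpec, EpochWindow, SourceEpochs, generate_source_epochs
from .task import RTModel, TaskConfig, generate_task_session, simulate_agent_responses

log = logging.getLogger("megfeedback")

__all__ = ["PipelineConfig", "Study", "simulate_study", "simulate",
           "load_study", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Study and analysis parameters with study-like defaults.

    Group sizes default to 20 control vs 55 trauma subjects.  The
    positive-feedback space-time test uses a cluster-forming alpha of 0.05;
    the negative-feedback test, which rests on far fewer trials, uses 0.001;
    both judge cluster significance at 0.05.  The spectro-temporal test uses
    an explicit threshold of 2.0.
    """

    seed: int = 0
    # --- synthetic study ---------------------------------------------------
    n_control: int = 20
    n_trauma: int = 55
    n_vertices: int = 200
    n_parcels: int = 8
    medial_wall_fraction: float = 0.1
    sfreq_hz: float = 100.0
    epoch_fraction: float = 0.15   # feedback trials carried into MEG epochs
    learner_fraction: float = 0.65
    learner_acc_range: tuple = (0.72, 0.95)
    nonlearner_acc_range: tuple = (0.45, 0.62)
    neg_acc_range: tuple = (0.75, 0.95)  # nearly everyone learns negative cards
    task: TaskConfig = field(default_factory=TaskConfig)
    effects: list = field(default_factory=lambda: [
        {"event": "positive", "parcels": ["parcel_0"], "group": "trauma",
         "time_window_s": (0.2, 0.4), "amplitude_delta": 1.5,
         "osc_freq_hz": 6.0, "osc_amplitude": 1.5},
        {"event": "negative", "parcels": ["parcel_1"], "group": "trauma",
         "time_window_s": (0.3, 0.5), "amplitude_delta": 1.5},
    ])
    learner_delta_gap: float = 0.75  # extra amplitude for non-learners (SD)
    noise_sd: float = 1.0
    ar_coef: float = 0.0
    # --- analysis ----------------------------------------------------------
    events: tuple = ("positive", "negative")
    baseline_window_s: tuple = (-0.250, 0.0)
    reject_threshold: float = 6.0
    scpt_cluster_alpha: dict = field(default_factory=lambda: {
        "positive": 0.05, "negative": 0.001})
    n_permutations: int = 10_000
    significance_alpha: float = 0.05
    temporal_cluster_alpha: float = 0.05
    tf_t_threshold: float = 2.0
    roi_min_vertices: int = 16
    roi_min_area_cm2: float = 2.29
    roi_min_duration_ms: float = 20.0
    learner_threshold: float = 0.65
    min_nonlearners_for_chisq: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "task" in raw:
            raw["task"] = TaskConfig(**raw["task"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class Study:
    """In-memory synthetic study: mesh, behavior and per-event epochs."""

    mesh: Mesh
    sessions: list                 # per-subject completed trial DataFrames
    groups: list                   # per-subject group label
    subject_ids: list
    epochs: dict                   # event -> {subject_id: SourceEpochs}
    learner_truth: dict            # subject_id -> planted learner status


def simulate_study(cfg: PipelineConfig) -> Study:
    """Generate a full study in memory under the config's root seed."""
    mesh = make_synthetic_mesh(
        cfg.n_vertices, cfg.n_parcels, seed=int(substream(cfg.seed, "mesh").integers(2**31)),
        medial_wall_fraction=cfg.medial_wall_fraction)
    rng = substream(cfg.seed, "study")
    window = EpochWindow(sfreq=cfg.sfreq_hz)

    subject_ids, groups, sessions = [], [], []
    learner_truth = {}
    epochs = {ev: {} for ev in cfg.events}

    n_total = cfg.n_control + cfg.n_trauma
    for i in range(n_total):
        group = "control" if i < cfg.n_control else "trauma"
        sid = f"{group[:3]}{i:03d}"
        is_learner = rng.random() < cfg.learner_fraction
        lo, hi = cfg.learner_acc_range if is_learner else cfg.nonlearner_acc_range
        pos_acc = rng.uniform(lo, hi)
        neg_acc = rng.uniform(*cfg.neg_acc_range)
        session = generate_task_session(cfg.task, seed=int(rng.integers(2**31)), subject_id=sid)
        session = simulate_agent_responses(
            session, {"positive": pos_acc, "negative": neg_acc},
            seed=int(rng.integers(2**31)), rt_model=RTModel())
        subject_ids.append(sid)
        groups.append(group)
        sessions.append(session)
        learner_truth[sid] = bool(is_learner)

        for ev in cfg.events:
            n_fb = int((session["feedback_shown"] == ev).sum())
            n_ep = max(3, int(round(n_fb * cfg.epoch_fraction)))
            effect = _subject_effect(cfg, ev, group, is_learner)
            epochs[ev][sid] = generate_source_epochs(
                mesh, n_ep, effect, seed=int(rng.integers(2**31)),
                window=window, noise_sd=cfg.noise_sd, ar_coef=cfg.ar_coef,
                subject_id=sid, group=group, event=ev)
    return Study(mesh, sessions, groups, subject_ids, epochs, learner_truth)


def _subject_effect(cfg: PipelineConfig, event: str, group: str,
                    is_learner: bool) -> EffectSpec | None:
    entry = next((e for e in cfg.effects if e["event"] == event), None)
    if entry is None or group != entry.get("group", "trauma"):
        return None
    delta = float(entry.get("amplitude_delta", 0.0))
    if not is_learner:
        delta += cfg.learner_delta_gap
    return EffectSpec(
        parcels=tuple(entry["parcels"]),
        time_window_s=tuple(entry.get("time_window_s", (0.2, 0.4))),
        amplitude_delta=delta,
        osc_freq_hz=entry.get("osc_freq_hz"),
        osc_amplitude=float(entry.get("osc_amplitude", 1.0)),
    )


# ---------------------------------------------------------------------------
# disk layout

def simulate(cfg: PipelineConfig, outdir, overwrite: bool = False) -> Path:
    """Write a synthetic study to ``outdir``.

    Layout: ``mesh.json``, one ``<subject>.csv`` behavioral log and one
    ``<subject>.h5`` epoch file per subject (each event in its own HDF5
    group), plus a ``manifest.json`` echoing the config.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")
    (outdir / "behavior").mkdir(parents=True, exist_ok=True)
    (outdir / "epochs").mkdir(exist_ok=True)

    study = simulate_study(cfg)
    study.mesh.to_json(outdir / "mesh.json")
    import h5py
    for sid, grp, session in zip(study.subject_ids, study.groups, study.sessions):
        session.to_csv(outdir / "behavior" / f"{sid}.csv", index=False)
        with h5py.File(outdir / "epochs" / f"{sid}.h5", "w") as h:
            h.attrs["subject"] = sid
            h.attrs["group"] = grp
            for ev in cfg.events:
                study.epochs[ev][sid].to_hdf5(h.create_group(ev))
    manifest = {
        "config": _jsonable(dataclasses.asdict(cfg)),
        "config_hash": cfg.config_hash(),
        "n_subjects": len(study.subject_ids),
        "groups": {"control": cfg.n_control, "trauma": cfg.n_trauma},
        "subjects": study.subject_ids,
        "learner_truth": study.learner_truth,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_study(indir) -> Study:
    """Load a study previously written by :func:`simulate`."""
    import h5py
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    mesh = Mesh.from_json(indir / "mesh.json")
    subject_ids = manifest["subjects"]
    sessions, groups = [], []
    events = list(manifest["config"]["events"])
    epochs = {ev: {} for ev in events}
    for sid in subject_ids:
        df = pd.read_csv(indir / "behavior" / f"{sid}.csv")
        sessions.append(df)
        with h5py.File(indir / "epochs" / f"{sid}.h5", "r") as h:
            groups.append(str(h.attrs["group"]))
            for ev in events:
                epochs[ev][sid] = SourceEpochs.from_hdf5(h[ev])
    return Study(mesh, sessions, groups, subject_ids, epochs,
                 {k: bool(v) for k, v in manifest["learner_truth"].items()})


# ---------------------------------------------------------------------------
# the pipeline proper

class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(study: Study, cfg: PipelineConfig, outdir) -> dict:
    """Run behavior -> prep -> SCPT -> ROI -> time course -> TFR -> report.

    Returns the summary report (also written to ``outdir/report.json``).
    Stage outputs are written as they complete, so partial results survive a
    failure; the raised :class:`StageError` names the failing stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": cfg.config_hash(), "stages": {}}

    stage = "behavior"
    try:
        report["stages"]["behavior"] = _stage_behavior(study, cfg, outdir)
        stage = "prep"
        prepped = _stage_prep(study, cfg, outdir)
        report["stages"]["prep"] = prepped["report"]
        stage = "scpt"
        scpt = _stage_scpt(study, cfg, prepped)
        report["stages"]["scpt"] = scpt["report"]
        stage = "roi"
        rois = _stage_rois(study, cfg, prepped, scpt)
        report["stages"]["roi"] = rois["report"]
        stage = "timecourse"
        tcs = _stage_timecourse(study, cfg, prepped, rois, report["stages"]["behavior"])
        report["stages"]["timecourse"] = tcs["report"]
        stage = "tfr"
        report["stages"]["tfr"] = _stage_tfr(
            study, cfg, tcs, rois, report["stages"]["behavior"])
    except Exception as err:
        (outdir / "report.partial.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True))
        raise StageError(f"stage '{stage}' failed: {err}") from err

    (outdir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


def _stage_behavior(study: Study, cfg: PipelineConfig, outdir: Path) -> dict:
    lcfg = bh.LearnerConfig(threshold=cfg.learner_threshold)
    table = bh.behavioral_table(study.sessions, study.groups)
    table["subject_id"] = study.subject_ids
    table.to_csv(outdir / "behavioral_table.csv", index=False)
    manova = bh.manova_group_effect(table)
    first_block = min(cfg.task.trials_per_block,
                      int(min(len(s) for s in study.sessions)))
    manova_first = bh.manova_group_effect(
        bh.behavioral_table(study.sessions, study.groups, first_n=first_block))

    out = {"manova": manova, "manova_first_block": manova_first,
           "learners": {}, "chi_square": {}}
    for card, col in (("positive", "pos_accuracy"), ("negative", "neg_accuracy")):
        flags = table[col].map(lambda a: bh.classify_learner(a, lcfg))
        out["learners"][card] = {
            "by_subject": dict(zip(table["subject_id"], map(bool, flags))),
            "n_learners": int(flags.sum()),
            "n_nonlearners": int((~flags).sum()),
        }
        if (~flags).sum() < cfg.min_nonlearners_for_chisq:
            out["chi_square"][card] = {
                "excluded": True,
                "reason": f"fewer than {cfg.min_nonlearners_for_chisq} non-learners"}
            continue
        counts = [
            [int(flags[table["group"] == g].sum()),
             int((~flags[table["group"] == g]).sum())]
            for g in ("control", "trauma")
        ]
        res = bh.chi_square_learners(counts)
        res["excluded"] = False
        out["chi_square"][card] = res
    return out


def _stage_prep(study: Study, cfg: PipelineConfig, outdir: Path) -> dict:
    ecfg = prep.EpochConfig(baseline_window_s=cfg.baseline_window_s,
                            amplitude_reject_threshold=cfg.reject_threshold)
    rng = substream(cfg.seed, "prep")
    result = {"report": {}, "subject_maps": {}, "epochs": {}}
    for ev in cfg.events:
        counts, cleaned = [], {}
        n_rejected = {}
        for sid in study.subject_ids:
            rej = prep.reject_high_amplitude(study.epochs[ev][sid],
                                             ecfg.amplitude_reject_threshold)
            z = prep.baseline_zscore(rej["epochs"], ecfg)
            cleaned[sid] = z
            n_rejected[sid] = rej["n_rejected"]
            counts.append((sid, z.n_epochs))
        count_df = pd.DataFrame({
            "subject_id": [c[0] for c in counts],
            "group": study.groups,
            "n_trials": [c[1] for c in counts],
        })
        match = prep.match_trial_density(
            count_df, prep.MatchConfig(n_bins=cfg.n_control,
                                       seed=int(rng.integers(2**31))))
        maps = {}
        for sid in study.subject_ids:
            sub = prep.apply_matching(cleaned[sid], match["kept_indices"][sid])
            cleaned[sid] = sub
            maps[sid] = sub.data.mean(axis=0)  # (V, T) evoked map
        result["subject_maps"][ev] = maps
        result["epochs"][ev] = cleaned
        result["report"][ev] = {
            "n_rejected": n_rejected,
            "matched_counts": {s: int(t) for s, t in match["targets"].items()},
            "bins": match["bins"],
        }
        (outdir / f"matching_{ev}.json").write_text(
            json.dumps(_jsonable(result["report"][ev]), indent=2))
    return result


def _split_groups(study: Study, maps: dict):
    a = np.stack([maps[s] for s, g in zip(study.subject_ids, study.groups)
                  if g == "control"])
    b = np.stack([maps[s] for s, g in zip(study.subject_ids, study.groups)
                  if g == "trauma"])
    return a, b


def _stage_scpt(study: Study, cfg: PipelineConfig, prepped: dict) -> dict:
    rng = substream(cfg.seed, "scpt")
    out = {"report": {}, "results": {}, "lattices": {}}
    for ev in cfg.events:
        a, b = _split_groups(study, prepped["subject_maps"][ev])
        n_times = a.shape[-1]
        lattice = space_time_lattice(study.mesh, n_times)
        df = a.shape[0] + b.shape[0] - 2
        alpha = cfg.scpt_cluster_alpha[ev]
        ccfg = ClusterConfig(
            stat="two_sample_t", cluster_alpha=alpha,
            t_threshold=round(critical_t(alpha, df, 2), 2),
            n_permutations=cfg.n_permutations,
            significance_alpha=cfg.significance_alpha,
            seed=int(rng.integers(2**31)))
        res = permutation_test(a.reshape(a.shape[0], -1),
                               b.reshape(b.shape[0], -1), lattice, ccfg)
        out["results"][ev] = res
        out["lattices"][ev] = lattice
        out["report"][ev] = {
            "t_threshold": res.t_threshold,
            "n_clusters": len(res.clusters),
            "n_significant": len(res.significant()),
            "min_p": res.min_p(),
        }
    return out


def _stage_rois(study: Study, cfg: PipelineConfig, prepped: dict, scpt: dict) -> dict:
    fcfg = roi.ROIFilterConfig(
        min_vertices=cfg.roi_min_vertices, min_area_cm2=cfg.roi_min_area_cm2,
        min_duration_ms=cfg.roi_min_duration_ms)
    out = {"report": {}, "rois": {}}
    for ev in cfg.events:
        res = scpt["results"][ev]
        n_times = scpt["lattices"][ev].shape[1]
        sig = res.significant()
        surviving = roi.filter_clusters(sig, study.mesh, n_times,
                                        cfg.sfreq_hz, fcfg)
        rois = []
        for k, c in enumerate(surviving):
            rois.extend(roi.clusters_to_rois(c, study.mesh, n_times, fcfg,
                                             source_cluster=k))
        out["rois"][ev] = rois
        out["report"][ev] = {
            "n_significant_clusters": len(sig),
            "n_surviving_clusters": len(surviving),
            "rois": [r.to_dict() for r in rois],
        }
    return out


def _learner_flags(study: Study, behavior_report: dict, subjects, card="positive"):
    by_subject = behavior_report["learners"][card]["by_subject"]
    return np.array([by_subject[s] for s in subjects])


def _stage_timecourse(study: Study, cfg: PipelineConfig, prepped: dict,
                      rois: dict, behavior_report: dict) -> dict:
    rng = substream(cfg.seed, "timecourse")
    out = {"report": {}, "rstcs": {}}
    for ev in cfg.events:
        ev_out = []
        out["rstcs"][ev] = {}
        for r in rois["rois"][ev]:
            rstc = {
                sid: roi.representative_stc(
                    prepped["epochs"][ev][sid], r.member_vertices,
                    cfg.baseline_window_s)
                for sid in study.subject_ids
            }
            out["rstcs"][ev][r.parcel_label] = rstc
            a = np.stack([rstc[s] for s, g in zip(study.subject_ids, study.groups)
                          if g == "control"])
            b = np.stack([rstc[s] for s, g in zip(study.subject_ids, study.groups)
                          if g == "trauma"])
            ccfg = ClusterConfig(
                stat="two_sample_t", cluster_alpha=cfg.temporal_cluster_alpha,
                n_permutations=cfg.n_permutations,
                significance_alpha=cfg.significance_alpha,
                seed=int(rng.integers(2**31)))
            res = roi.temporal_cluster_test(a, b, ccfg)
            times = next(iter(prepped["epochs"][ev].values())).times_s
            tois = []
            for c in res.significant():
                t_idx = np.sort(c.element_indices)
                onset, offset = times[t_idx[0]], times[t_idx[-1]]
                toi = {
                    "onset_ms": float(onset * 1000), "offset_ms": float(offset * 1000),
                    "midpoint_ms": float((onset + offset) / 2 * 1000),
                    "p_value": c.p_value, "sign": c.sign,
                }
                # learner contrast on TOI means, per group
                dt = times[1] - times[0]
                interval = (onset, offset + dt)
                toi["learner_contrast"] = {}
                for grp in ("control", "trauma"):
                    sel = [s for s, g in zip(study.subject_ids, study.groups) if g == grp]
                    vals = [roi.toi_summary(rstc[s], times, interval) for s in sel]
                    flags = _learner_flags(study, behavior_report, sel)
                    if flags.sum() >= 2 and (~flags).sum() >= 2:
                        toi["learner_contrast"][grp] = roi.compare_learners(vals, flags)
                    else:
                        toi["learner_contrast"][grp] = {"excluded": True}
                tois.append(toi)
            ev_out.append({
                "roi": r.parcel_label,
                "n_significant_temporal_clusters": len(res.significant()),
                "tois": tois,
            })
        out["report"][ev] = ev_out
    return out


def _stage_tfr(study: Study, cfg: PipelineConfig, tcs: dict, rois: dict,
               behavior_report: dict) -> dict:
    rng = substream(cfg.seed, "tfr")
    tcfg = tfr.TFRConfig(baseline_window_s=cfg.baseline_window_s)
    report = {}
    for ev in cfg.events:
        ev_out = []
        for r in rois["rois"][ev]:
            rstc = tcs["rstcs"][ev][r.parcel_label]
            times_s = EpochWindow(sfreq=cfg.sfreq_hz).times()
            planes = {}
            for sid in study.subject_ids:
                raw = tfr.morlet_tfr(rstc[sid], times_s, cfg.sfreq_hz, tcfg)
                planes[sid] = tfr.tfr_baseline_zscore(
                    raw, cfg.baseline_window_s).power
            a = np.stack([planes[s] for s, g in zip(study.subject_ids, study.groups)
                          if g == "control"])
            b = np.stack([planes[s] for s, g in zip(study.subject_ids, study.groups)
                          if g == "trauma"])
            ccfg = ClusterConfig(
                stat="two_sample_t", t_threshold=cfg.tf_t_threshold,
                n_permutations=cfg.n_permutations,
                significance_alpha=cfg.significance_alpha,
                seed=int(rng.integers(2**31)))
            res, lattice = tfr.spectrotemporal_cluster_test(a, b, ccfg)
            clusters = []
            for c in res.significant():
                f_idx, t_idx = np.unravel_index(c.element_indices, lattice.shape)
                entry = {
                    "p_value": c.p_value, "sign": c.sign,
                    "freq_band_hz": [float(tcfg.freqs_hz[f_idx.min()]),
                                     float(tcfg.freqs_hz[f_idx.max()])],
                    "time_span_ms": [float(times_s[t_idx.min()] * 1000),
                                     float(times_s[t_idx.max()] * 1000)],
                }
                entry["learner_contrast"] = {}
                for grp in ("control", "trauma"):
                    sel = [s for s, g in zip(study.subject_ids, study.groups) if g == grp]
                    vals = [tfr.tfoi_power(planes[s], c.element_indices) for s in sel]
                    flags = _learner_flags(study, behavior_report, sel)
                    if flags.sum() >= 2 and (~flags).sum() >= 2:
                        entry["learner_contrast"][grp] = roi.compare_learners(vals, flags)
                    else:
                        entry["learner_contrast"][grp] = {"excluded": True}
                clusters.append(entry)
            ev_out.append({"roi": r.parcel_label,
                           "n_significant_tf_clusters": len(res.significant()),
                           "clusters": clusters})
        report[ev] = ev_out
    return report
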