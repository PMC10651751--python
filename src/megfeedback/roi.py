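"""From significant space-time clusters to ROIs, time courses and contrasts.

A surviving cluster is projected onto the mesh parcellation to produce
regions of interest; per subject a representative source time course (rSTC)
averages the cluster's significant vertices; temporal cluster tests localise
group differences in time; time-interval summaries (TOIs) feed learner vs
non-learner contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cluster import Cluster, ClusterConfig, permutation_test
from .lattices import chain_lattice
from .mesh import Mesh
from .prep import DegenerateBaselineError
from .synth import SourceEpochs

__all__ = [
    "ROIFilterConfig", "ROIResult",
    "filter_clusters", "clusters_to_rois", "representative_stc",
    "temporal_cluster_test", "toi_summary", "compare_learners",
    "cluster_vertices_times",
]


@dataclass
class ROIFilterConfig:
    """Cluster survival rules.

    A cluster survives if, after removing medial-wall vertices, it spans at
    least ``min_vertices`` distinct vertices (default 16, i.e. clusters of 15
    or fewer are excluded), at least ``min_area_cm2`` of cortex, and at least
    ``min_duration_ms`` between its first and last time sample (default 20 ms,
    i.e. shorter-lived clusters are discarded).
    """

    min_vertices: int = 16
    min_area_cm2: float = 2.29
    min_duration_ms: float = 20.0
    exclude_medial_wall: bool = True

    def __post_init__(self):
        if self.min_vertices < 0 or self.min_area_cm2 < 0 or self.min_duration_ms < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class ROIResult:
    """One parcel's share of a significant cluster."""

    parcel_label: str
    member_vertices: np.ndarray
    coverage_percent: float
    centroid: np.ndarray
    source_cluster: int
    cluster_p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "parcel_label": self.parcel_label,
            "member_vertices": self.member_vertices.tolist(),
            "coverage_percent": float(self.coverage_percent),
            "centroid": [float(x) for x in self.centroid],
            "source_cluster": int(self.source_cluster),
            "cluster_p_value": None if self.cluster_p_value is None
            else float(self.cluster_p_value),
        }


def cluster_vertices_times(cluster: Cluster, n_times: int):
    """Split a space-time cluster's element ids into (vertex, time) indices."""
    v = cluster.element_indices // n_times
    t = cluster.element_indices % n_times
    return v, t


def filter_clusters(
    clusters, mesh: Mesh, n_times: int, sfreq_hz: float,
    cfg: ROIFilterConfig | None = None,
) -> list:
    """Apply spatial-extent, duration and medial-wall rules to clusters.

    Duration is the elapsed time between a cluster's first and last sample,
    ``(t_last - t_first) / sfreq``.  Medial-wall elements are removed before
    any counting; a cluster emptied by that removal is dropped.  Filtering is
    idempotent and order-independent.
    """
    cfg = cfg or ROIFilterConfig()
    out = []
    for c in clusters:
        v, t = cluster_vertices_times(c, n_times)
        if cfg.exclude_medial_wall:
            keep = ~mesh.medial_wall[v]
            if not keep.any():
                continue
            v, t = v[keep], t[keep]
        verts = np.unique(v)
        if verts.size < cfg.min_vertices:
            continue
        if mesh.vertex_area_cm2[verts].sum() < cfg.min_area_cm2:
            continue
        duration_ms = (t.max() - t.min()) / sfreq_hz * 1000.0
        if duration_ms < cfg.min_duration_ms:
            continue
        out.append(c)
    return out


def clusters_to_rois(
    cluster: Cluster, mesh: Mesh, n_times: int,
    cfg: ROIFilterConfig | None = None, source_cluster: int = 0,
) -> list:
    """Project one surviving cluster onto the parcellation.

    Each parcel the cluster touches yields one ROI whose members are the
    cluster's vertices inside that parcel; fragments smaller than the
    vertex/area minima are dropped, mirroring the elimination of small
    regions.  Coverage is the percentage of the parcel's (non-medial)
    vertices inside the cluster.
    """
    cfg = cfg or ROIFilterConfig()
    v, _ = cluster_vertices_times(cluster, n_times)
    if cfg.exclude_medial_wall:
        v = v[~mesh.medial_wall[v]]
    verts = np.unique(v)
    rois = []
    for label, parcel in mesh.parcels.items():
        if cfg.exclude_medial_wall:
            parcel = parcel[~mesh.medial_wall[parcel]]
        if parcel.size == 0:
            continue
        members = np.intersect1d(verts, parcel)
        if members.size == 0:
            continue
        if members.size < cfg.min_vertices:
            continue
        if mesh.vertex_area_cm2[members].sum() < cfg.min_area_cm2:
            continue
        rois.append(ROIResult(
            parcel_label=label,
            member_vertices=members,
            coverage_percent=100.0 * members.size / parcel.size,
            centroid=mesh.coords[members].mean(axis=0),
            source_cluster=source_cluster,
            cluster_p_value=cluster.p_value,
        ))
    rois.sort(key=lambda r: -r.coverage_percent)
    return rois


def representative_stc(
    epochs: SourceEpochs, roi_vertices, baseline_window=(-0.250, 0.0)
) -> np.ndarray:
    """Representative source time course of one subject for one ROI.

    Averages over epochs first, then over the ROI's significant vertices,
    then z-scores against the baseline interval (sample SD).  Raises
    :class:`DegenerateBaselineError` if the averaged trace has zero baseline
    SD (e.g. exact cancellation between vertices).
    """
    verts = np.asarray(roi_vertices, dtype=int)
    if verts.size == 0:
        raise ValueError("ROI has no member vertices")
    if verts.max() >= epochs.n_vertices:
        raise ValueError("ROI vertex outside epochs array")
    trace = epochs.data[:, verts, :].mean(axis=0).mean(axis=0)
    times = epochs.times_s
    mask = (times >= baseline_window[0] - 1e-12) & (times <= baseline_window[1] + 1e-12)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain >= 2 samples")
    mu = trace[mask].mean()
    sd = trace[mask].std(ddof=1)
    if sd <= 1e-12:
        raise DegenerateBaselineError("zero baseline SD in rSTC")
    return (trace - mu) / sd


def temporal_cluster_test(rstc_a: np.ndarray, rstc_b: np.ndarray, cfg: ClusterConfig):
    """Cluster permutation test on per-subject time courses (chain lattice)."""
    rstc_a = np.atleast_2d(rstc_a)
    rstc_b = np.atleast_2d(rstc_b)
    if rstc_a.shape[1] != rstc_b.shape[1]:
        raise ValueError("time axes differ between groups")
    lattice = chain_lattice(rstc_a.shape[1])
    return permutation_test(rstc_a, rstc_b, lattice, cfg)


def toi_summary(rstc: np.ndarray, times_s: np.ndarray, interval_s) -> float:
    """Mean amplitude over a half-open time interval [onset, offset)."""
    onset, offset = interval_s
    times_s = np.asarray(times_s)
    dt = times_s[1] - times_s[0] if times_s.size > 1 else 0.0
    if onset < times_s[0] - 1e-12 or offset > times_s[-1] + dt + 1e-12:
        raise ValueError("interval outside epoch")
    mask = (times_s >= onset - 1e-12) & (times_s < offset - 1e-12)
    if not mask.any():
        raise ValueError("interval contains no samples")
    return float(np.asarray(rstc)[..., mask].mean())


def compare_learners(values, learner_flags) -> dict:
    """Pooled two-sample t between learner and non-learner subjects.

    ``values``: per-subject scalars (e.g. TOI means); ``learner_flags``:
    matching booleans.  Student (pooled-variance) t with df = n - 2, so a 55-
    subject group split 36/19 reports df = 53.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(learner_flags, dtype=bool)
    if values.shape != flags.shape:
        raise ValueError("values and flags must align")
    x, y = values[flags], values[~flags]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each subgroup needs >= 2 subjects")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return {
        "t": float(t),
        "df": int(len(values) - 2),
        "p": float(p),
        "mean_learners": float(x.mean()),
        "mean_nonlearners": float(y.mean()),
        "n_learners": int(len(x)),
        "n_nonlearners": int(len(y)),
    }
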