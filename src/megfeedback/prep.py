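"""Epoch preparation: baseline z-scoring, amplitude rejection, density matching.

Baseline z-scoring removes per-vertex offset and scale using the pre-feedback
interval; amplitude rejection drops epochs whose peak absolute value exceeds a
threshold; trial-density matching equalises per-subject epoch counts between
two unbalanced groups by binning subjects on trial count and truncating every
bin member to the bin minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import SourceEpochs

__all__ = [
    "EpochConfig", "MatchConfig", "DegenerateBaselineError",
    "baseline_zscore", "reject_high_amplitude", "match_trial_density",
    "apply_matching",
]


class DegenerateBaselineError(ValueError):
    """Raised when a vertex has (near-)zero baseline standard deviation."""


@dataclass
class EpochConfig:
    """Baseline window (closed interval, seconds) and rejection threshold.

    The rejection threshold is in the data's own units: picotesla at the
    sensor stage the convention comes from, unit-free for source estimates.
    """

    baseline_window_s: tuple = (-0.250, 0.0)
    amplitude_reject_threshold: float = 5.0

    def __post_init__(self):
        if self.baseline_window_s[1] <= self.baseline_window_s[0]:
            raise ValueError("baseline window must have positive length")
        if self.amplitude_reject_threshold <= 0:
            raise ValueError("rejection threshold must be positive")


@dataclass
class MatchConfig:
    """Density-matching parameters: number of bins and assignment rule."""

    n_bins: int = 20
    bin_rule: str = "rank"  # or "random"
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.bin_rule not in ("rank", "random"):
            raise ValueError("bin_rule must be 'rank' or 'random'")


def _baseline_mask(times: np.ndarray, window) -> np.ndarray:
    mask = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    return mask


def baseline_zscore(
    epochs: SourceEpochs, cfg: EpochConfig | None = None, mode: str = "pooled"
) -> SourceEpochs:
    """Z-score every vertex's signal against its baseline interval.

    ``mode='pooled'`` (default) estimates the per-vertex baseline mean and
    sample SD (ddof=1) across the baseline samples of *all* epochs, which
    stabilises the SD estimate; ``mode='per_epoch'`` normalises each epoch by
    its own baseline.  A vertex whose baseline SD is (near-)zero raises
    :class:`DegenerateBaselineError` naming the vertex.
    """
    cfg = cfg or EpochConfig()
    mask = _baseline_mask(epochs.times_s, cfg.baseline_window_s)
    x = epochs.data
    if mode == "pooled":
        base = x[:, :, mask]  # (epochs, vertices, samples)
        flat = np.moveaxis(base, 1, 0).reshape(x.shape[1], -1)
        mu = flat.mean(axis=1)
        sd = flat.std(axis=1, ddof=1)
        _check_sd(sd)
        z = (x - mu[None, :, None]) / sd[None, :, None]
    elif mode == "per_epoch":
        base = x[:, :, mask]
        mu = base.mean(axis=2)
        sd = base.std(axis=2, ddof=1)
        _check_sd(sd.min(axis=0))
        z = (x - mu[:, :, None]) / sd[:, :, None]
    else:
        raise ValueError("mode must be 'pooled' or 'per_epoch'")
    return SourceEpochs(epochs.subject_id, epochs.group, epochs.event,
                        z, epochs.times_s, epochs.sfreq_hz)


def _check_sd(sd: np.ndarray, tol: float = 1e-12) -> None:
    bad = np.flatnonzero(np.asarray(sd) <= tol)
    if bad.size:
        raise DegenerateBaselineError(
            f"zero baseline SD at vertex {int(bad[0])}"
            + (f" (+{bad.size - 1} more)" if bad.size > 1 else "")
        )


def reject_high_amplitude(epochs: SourceEpochs, threshold: float) -> dict:
    """Drop epochs whose peak |amplitude| exceeds ``threshold``.

    Returns ``{"epochs": kept, "n_rejected": int, "rejected_indices": array}``.
    Raises if every epoch is rejected — the subject is unusable.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    bad = np.flatnonzero(peak > threshold)
    if bad.size == epochs.n_epochs:
        raise ValueError(
            f"all {epochs.n_epochs} epochs exceed {threshold}; "
            f"subject {epochs.subject_id} unusable"
        )
    keep = np.setdiff1d(np.arange(epochs.n_epochs), bad)
    kept = SourceEpochs(epochs.subject_id, epochs.group, epochs.event,
                        epochs.data[keep], epochs.times_s, epochs.sfreq_hz)
    return {"epochs": kept, "n_rejected": int(bad.size), "rejected_indices": bad}


def match_trial_density(counts: pd.DataFrame, cfg: MatchConfig | None = None) -> dict:
    """Equalise per-subject epoch counts between two groups, bin by bin.

    ``counts`` needs columns ``subject_id``, ``group`` (exactly two labels;
    the smaller group defines the bins) and ``n_trials``.  Both groups are
    sorted by trial count; the larger group is partitioned into ``n_bins``
    contiguous rank blocks of 2–3 subjects, each paired with the rank-matched
    member of the smaller group.  Every bin member's target count is the bin
    minimum, and the retained epochs are a seeded uniform subsample.

    Returns ``{"bins": [...], "targets": {subject: int},
    "kept_indices": {subject: array}}``.
    """
    cfg = cfg or MatchConfig()
    req = {"subject_id", "group", "n_trials"}
    if not req.issubset(counts.columns):
        raise ValueError(f"counts must have columns {sorted(req)}")
    if (counts["n_trials"] < 1).any():
        raise ValueError("every subject needs at least one trial")
    labels = counts["group"].unique()
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    sizes = counts["group"].value_counts()
    small_lab = sizes.idxmin()
    large_lab = [g for g in labels if g != small_lab][0]
    small = counts[counts["group"] == small_lab]
    large = counts[counts["group"] == large_lab]
    if len(small) != cfg.n_bins:
        raise ValueError(
            f"smaller group size ({len(small)}) must equal n_bins ({cfg.n_bins})"
        )
    if not 2 * cfg.n_bins <= len(large) <= 3 * cfg.n_bins:
        raise ValueError("larger group must supply 2-3 subjects per bin")

    rng = np.random.default_rng(cfg.seed)
    if cfg.bin_rule == "rank":
        small_sorted = small.sort_values("n_trials", kind="mergesort")
        large_sorted = large.sort_values("n_trials", kind="mergesort")
    else:
        small_sorted = small.iloc[rng.permutation(len(small))]
        large_sorted = large.iloc[rng.permutation(len(large))]
    blocks = np.array_split(np.arange(len(large_sorted)), cfg.n_bins)

    bins, targets, kept = [], {}, {}
    for b, (small_row, block) in enumerate(
        zip(small_sorted.itertuples(index=False), blocks)
    ):
        members = [(small_row.subject_id, int(small_row.n_trials))]
        members += [
            (r.subject_id, int(r.n_trials))
            for r in large_sorted.iloc[block].itertuples(index=False)
        ]
        tgt = min(c for _, c in members)
        bins.append({"bin": b, "members": [m for m, _ in members], "target": tgt})
        for subj, c in members:
            targets[subj] = tgt
            kept[subj] = np.sort(rng.choice(c, size=tgt, replace=False))
    return {"bins": bins, "targets": targets, "kept_indices": kept}


def apply_matching(epochs: SourceEpochs, kept_indices: np.ndarray) -> SourceEpochs:
    """Subset a subject's epochs to the matched index set."""
    idx = np.asarray(kept_indices, dtype=int)
    if idx.size and idx.max() >= epochs.n_epochs:
        raise ValueError("kept index outside epoch range")
    return SourceEpochs(epochs.subject_id, epochs.group, epochs.event,
                        epochs.data[idx], epochs.times_s, epochs.sfreq_hz)
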