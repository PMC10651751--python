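"""Synthetic source-space epochs with optional planted group effects.

Stands in for noise-normalised inverse solutions (e.g. dSPM): per subject, an
``epochs x vertices x time`` array around feedback onset.  Baseline activity
is white Gaussian noise (optionally AR(1)-correlated in time, in arbitrary
units scaled by the baseline SD).  An :class:`EffectSpec` plants an amplitude
shift — and optionally a windowed narrow-band oscillation — into named parcels
within a time window, giving full control over where and when a group
difference exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .mesh import Mesh

__all__ = ["EpochWindow", "EffectSpec", "SourceEpochs", "generate_source_epochs"]


@dataclass
class EpochWindow:
    """Epoch time axis: tmin/tmax in seconds around feedback onset."""

    tmin: float = -0.250
    tmax: float = 0.600
    sfreq: float = 200.0

    def __post_init__(self):
        if self.tmax <= self.tmin:
            raise ValueError("tmax must exceed tmin")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.sfreq)) + 1
        return self.tmin + np.arange(n) / self.sfreq


@dataclass
class EffectSpec:
    """Planted group effect.

    amplitude_delta is an additive mean shift in baseline-SD units applied to
    every vertex of ``parcels`` within ``time_window_s``.  If ``osc_freq_hz``
    is set, a Hann-windowed sinusoid of amplitude ``osc_amplitude`` (same
    units) at that frequency is added over the window as well.
    """

    parcels: tuple
    time_window_s: tuple = (0.2, 0.4)
    amplitude_delta: float = 0.0
    osc_freq_hz: float | None = None
    osc_amplitude: float = 1.0

    def __post_init__(self):
        if isinstance(self.parcels, str):
            self.parcels = (self.parcels,)
        self.parcels = tuple(self.parcels)
        if self.osc_freq_hz is not None and not 1.0 <= self.osc_freq_hz:
            raise ValueError("osc_freq_hz must be >= 1 Hz")


@dataclass
class SourceEpochs:
    """Per-subject source-space epochs around one feedback event type."""

    subject_id: str
    group: str
    event: str
    data: np.ndarray          # (n_epochs, n_vertices, n_times)
    times_s: np.ndarray
    sfreq_hz: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, vertices, times)")
        if self.data.shape[2] != self.times_s.size:
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    # -- I/O ----------------------------------------------------------------
    def to_hdf5(self, path_or_group) -> None:
        """Write ``/data`` and ``/times`` datasets plus identifying attrs."""
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        h = h5py.File(path_or_group, "w") if own else path_or_group
        try:
            h.create_dataset("data", data=self.data.astype(np.float32))
            h.create_dataset("times", data=self.times_s)
            h.attrs["subject"] = self.subject_id
            h.attrs["group"] = self.group
            h.attrs["event"] = self.event
            h.attrs["sfreq"] = self.sfreq_hz
        finally:
            if own:
                h.close()

    @classmethod
    def from_hdf5(cls, path_or_group) -> "SourceEpochs":
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        h = h5py.File(path_or_group, "r") if own else path_or_group
        try:
            return cls(
                subject_id=str(h.attrs["subject"]),
                group=str(h.attrs["group"]),
                event=str(h.attrs["event"]),
                data=np.asarray(h["data"], dtype=np.float64),
                times_s=np.asarray(h["times"], dtype=np.float64),
                sfreq_hz=float(h.attrs["sfreq"]),
            )
        finally:
            if own:
                h.close()


def generate_source_epochs(
    mesh: Mesh,
    n_epochs: int,
    effect: EffectSpec | None,
    seed: int,
    *,
    window: EpochWindow | None = None,
    noise_sd: float = 1.0,
    ar_coef: float = 0.0,
    subject_id: str = "S000",
    group: str = "control",
    event: str = "positive",
) -> SourceEpochs:
    """Draw noise epochs and plant the requested effect.

    Noise is white Gaussian with SD ``noise_sd`` per sample; ``ar_coef`` adds
    AR(1) temporal autocorrelation (variance renormalised so the marginal SD
    stays ``noise_sd``).  The baseline interval is untouched by any effect, so
    it remains zero-mean by construction.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    window = window or EpochWindow()
    times = window.times()
    rng = np.random.default_rng(seed)

    shape = (n_epochs, mesh.n_vertices, times.size)
    data = rng.standard_normal(shape) * noise_sd
    if ar_coef:
        if not -1 < ar_coef < 1:
            raise ValueError("ar_coef must be in (-1, 1)")
        innov_sd = np.sqrt(1.0 - ar_coef**2)
        out = np.empty_like(data)
        out[..., 0] = data[..., 0]
        for t in range(1, times.size):
            out[..., t] = ar_coef * out[..., t - 1] + innov_sd * data[..., t]
        data = out

    if effect is not None:
        t0, t1 = effect.time_window_s
        if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9 or t1 <= t0:
            raise ValueError("effect time window outside epoch")
        parcels = mesh.parcels
        verts = []
        for p in effect.parcels:
            if p not in parcels:
                raise ValueError(f"parcel {p!r} not in mesh")
            verts.append(parcels[p])
        verts = np.concatenate(verts)
        tmask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
        bump = np.full(tmask.sum(), float(effect.amplitude_delta) * noise_sd)
        if effect.osc_freq_hz is not None:
            tt = times[tmask] - t0
            hann = 0.5 - 0.5 * np.cos(2 * np.pi * tt / (t1 - t0))
            bump = bump + (effect.osc_amplitude * noise_sd * hann
                           * np.sin(2 * np.pi * effect.osc_freq_hz * tt))
        data[np.ix_(np.arange(n_epochs), verts, np.flatnonzero(tmask))] += bump

    return SourceEpochs(subject_id, group, event, data, times, window.sfreq)
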