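"""Morlet time-frequency analysis and spectro-temporal cluster testing.

Power is computed by convolving the signal with complex Morlet wavelets —
Gaussian-windowed complex exponentials with a per-frequency number of cycles
f/3 (a deliberately short wavelet that favours temporal over spectral
resolution; below 2 cycles a warning is emitted).  Epochs are reflect-padded
by half the widest wavelet's support so that the 4 Hz wavelet fits the short
feedback epoch, and power is baseline z-scored per frequency row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .cluster import ClusterConfig, permutation_test
from .lattices import grid_lattice
from .prep import DegenerateBaselineError

__all__ = [
    "TFRConfig", "TFRArray", "morlet_tfr", "tfr_baseline_zscore",
    "spectrotemporal_cluster_test", "tfoi_power", "plot_tfr",
]

#: Gaussian support half-width of the wavelet, in standard deviations.
_SUPPORT_SD = 5.0


@dataclass
class TFRConfig:
    """Morlet decomposition parameters.

    Default frequency axis 4..45 Hz at 1 Hz resolution, number of cycles
    f / cycles_divisor (divisor 3).  ``edge_policy='reflect'`` pads the
    signal by half the widest wavelet support before convolving and crops
    afterwards; ``'none'`` convolves the raw signal and leaves edge effects
    in place.
    """

    freqs_hz: np.ndarray = field(
        default_factory=lambda: np.arange(4.0, 46.0, 1.0))
    cycles_divisor: float = 3.0
    baseline_window_s: tuple = (-0.250, 0.0)
    edge_policy: str = "reflect"

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if np.any(self.freqs_hz <= 0):
            raise ValueError("frequencies must be positive")
        if self.edge_policy not in ("reflect", "none"):
            raise ValueError("edge_policy must be 'reflect' or 'none'")

    def n_cycles(self) -> np.ndarray:
        return self.freqs_hz / self.cycles_divisor


@dataclass
class TFRArray:
    """Time-frequency power for one subject/ROI: (n_freqs, n_times)."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    z_scored: bool = False

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.shape != (len(self.freqs_hz), len(self.times_s)):
            raise ValueError("power must be (n_freqs, n_times)")
        if not self.z_scored and np.any(self.power < 0):
            raise ValueError("raw power must be non-negative")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            h.create_dataset("power", data=self.power)
            h.create_dataset("freqs", data=self.freqs_hz)
            h.create_dataset("times", data=self.times_s)
            h.attrs["z_scored"] = self.z_scored

    @classmethod
    def from_hdf5(cls, path) -> "TFRArray":
        import h5py

        with h5py.File(path, "r") as h:
            return cls(np.asarray(h["power"]), np.asarray(h["freqs"]),
                       np.asarray(h["times"]), bool(h.attrs["z_scored"]))


def _morlet_wavelet(freq: float, n_cycles: float, sfreq: float) -> np.ndarray:
    """Unit-L2-norm complex Morlet wavelet sampled over ±5 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(_SUPPORT_SD * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.linalg.norm(w)


def morlet_tfr(
    signal: np.ndarray, times_s: np.ndarray, sfreq: float,
    cfg: TFRConfig | None = None,
) -> TFRArray:
    """Complex Morlet wavelet power of a 1-D time course.

    Power is the squared magnitude of the wavelet coefficients, so it scales
    quadratically with signal amplitude.  Raises if a wavelet's support
    exceeds the (padded) signal, naming the offending frequency.
    """
    cfg = cfg or TFRConfig()
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D; loop subjects/ROIs externally")
    if x.size != len(times_s):
        raise ValueError("signal and time axis lengths differ")
    nyquist = sfreq / 2.0
    if np.any(cfg.freqs_hz >= nyquist):
        raise ValueError("frequency axis exceeds the Nyquist frequency")
    cycles = cfg.n_cycles()
    if np.any(cycles < 2.0):
        warnings.warn(
            "wavelets below 2 cycles have very coarse spectral resolution",
            RuntimeWarning, stacklevel=2)

    wavelets = [_morlet_wavelet(f, c, sfreq) for f, c in zip(cfg.freqs_hz, cycles)]
    max_half = max((len(w) - 1) // 2 for w in wavelets)
    if cfg.edge_policy == "reflect":
        pad = max_half
        xp = np.concatenate([x[1:pad + 1][::-1], x, x[-pad - 1:-1][::-1]]) \
            if pad < x.size else None
        if xp is None:
            raise ValueError(
                f"signal too short to reflect-pad for "
                f"{cfg.freqs_hz[int(np.argmax([len(w) for w in wavelets]))]:g} Hz wavelet")
    else:
        xp, pad = x, 0

    power = np.empty((len(wavelets), x.size))
    for i, w in enumerate(wavelets):
        if len(w) > xp.size:
            raise ValueError(
                f"wavelet support at {cfg.freqs_hz[i]:g} Hz exceeds the signal")
        coef = fftconvolve(xp, np.conj(w[::-1]), mode="same")
        if pad:
            coef = coef[pad:pad + x.size]
        power[i] = np.abs(coef) ** 2
    return TFRArray(power, cfg.freqs_hz.copy(), np.asarray(times_s, float))


def tfr_baseline_zscore(
    tfr: TFRArray, baseline_window_s=(-0.250, 0.0), mode: str = "per_frequency"
) -> TFRArray:
    """Z-score power against the pre-feedback baseline.

    ``per_frequency`` (default) normalises each frequency row by its own
    baseline mean and sample SD; ``global`` uses one mean/SD over the whole
    baseline plane.  Z-scored power is invariant to rescaling the input.
    """
    mask = (tfr.times_s >= baseline_window_s[0] - 1e-12) & \
           (tfr.times_s <= baseline_window_s[1] + 1e-12)
    if mask.sum() < 2:
        raise ValueError("baseline window needs >= 2 TFR samples")
    base = tfr.power[:, mask]
    if mode == "per_frequency":
        mu = base.mean(axis=1, keepdims=True)
        sd = base.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd <= 1e-30):
            bad = int(np.flatnonzero(sd.ravel() <= 1e-30)[0])
            raise DegenerateBaselineError(
                f"zero baseline SD at {tfr.freqs_hz[bad]:g} Hz")
    elif mode == "global":
        mu = base.mean()
        sd = base.std(ddof=1)
        if sd <= 1e-30:
            raise DegenerateBaselineError("zero baseline SD in TFR plane")
    else:
        raise ValueError("mode must be 'per_frequency' or 'global'")
    return TFRArray((tfr.power - mu) / sd, tfr.freqs_hz, tfr.times_s,
                    z_scored=True)


def spectrotemporal_cluster_test(tfrs_a, tfrs_b, cfg: ClusterConfig):
    """Cluster permutation test on stacked (n_freqs, n_times) power planes.

    ``tfrs_a``/``tfrs_b``: arrays (n_subjects, n_freqs, n_times) or lists of
    :class:`TFRArray`.  Clusters grow over the 4-connected time-frequency
    grid; the returned clusters' element indices unravel to (freq, time).
    """
    a = _stack(tfrs_a)
    b = _stack(tfrs_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("TFR grids differ between groups")
    lattice = grid_lattice(a.shape[1], a.shape[2])
    return permutation_test(a.reshape(a.shape[0], -1),
                            b.reshape(b.shape[0], -1), lattice, cfg), lattice


def _stack(tfrs) -> np.ndarray:
    if isinstance(tfrs, np.ndarray):
        return np.asarray(tfrs, dtype=np.float64)
    return np.stack([t.power for t in tfrs]).astype(np.float64)


def tfoi_power(tfr, cluster_elements) -> float:
    """Mean (z-scored) power over a significant time-frequency element set."""
    elements = np.asarray(cluster_elements, dtype=int)
    if elements.size == 0:
        raise ValueError("empty time-frequency cluster")
    plane = tfr.power if isinstance(tfr, TFRArray) else np.asarray(tfr)
    return float(plane.ravel()[elements].mean())


def plot_tfr(tfr: TFRArray, path=None, cluster_elements=None, title=""):
    """Render a time-frequency map, optionally outlining a cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(tfr.times_s, tfr.freqs_hz, tfr.power,
                         shading="nearest", cmap="RdBu_r")
    fig.colorbar(mesh, ax=ax, label="power (z)" if tfr.z_scored else "power")
    if cluster_elements is not None and len(cluster_elements):
        m = np.zeros(tfr.power.shape, dtype=float)
        m.ravel()[np.asarray(cluster_elements, dtype=int)] = 1.0
        ax.contour(tfr.times_s, tfr.freqs_hz, m, levels=[0.5], colors="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
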