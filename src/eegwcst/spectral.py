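"""Spectral features: PSD, alpha-peak-anchored bands, band power, coherence.

Spectra are estimated per 5-s epoch with a Hann taper and averaged over the
accepted epochs (0.2 Hz resolution); the taper normalization preserves
Parseval, so the PSD integral over [0, Nyquist] equals the signal variance.
Magnitude-squared coherence between channels i and j is

    msc(w) = |C_ij(w)|^2 / (C_ii(w) * C_jj(w)),

with C the epoch-averaged (cross-)spectra; pool coherence averages the
msc over the band bins and then over the 9 cross-pool channel pairs.

Frequency bands are individualized: the alpha peak frequency (APF) is the
argmax of the pool-averaged PSD on the 8-13 Hz grid, the alpha band is
APF +/- 2 Hz and the theta band APF-7 to APF-3 Hz.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .recording import EpochSet, POOLS

__all__ = [
    "SpectrumSet",
    "ApfEstimate",
    "BandScheme",
    "SpectralError",
    "estimate_spectra",
    "detect_apf",
    "band_limits",
    "band_power",
    "pool_coherence",
    "baseline_correct",
    "apf_asymmetry",
]

APF_WINDOW = (8.0, 13.0)


class SpectralError(RuntimeError):
    pass


@dataclasses.dataclass
class SpectrumSet:
    """Epoch-averaged auto- and cross-spectra on a common frequency grid."""

    freqs: np.ndarray  # Hz, resolution 1/epoch_length
    psd: np.ndarray  # (n_channels, n_freqs), power density
    cross: np.ndarray  # (n_channels, n_channels, n_freqs), complex
    channels: tuple
    n_epochs_used: int
    fs: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def channel_psd(self, label: str) -> np.ndarray:
        return self.psd[self.channels.index(label)]


@dataclasses.dataclass(frozen=True)
class ApfEstimate:
    """Alpha peak frequency with a confidence flag for flat spectra."""

    frequency: float  # Hz
    low_confidence: bool = False


@dataclasses.dataclass(frozen=True)
class BandScheme:
    """Per-pool individualized band limits anchored at the alpha peak."""

    apf: dict  # pool -> ApfEstimate
    alpha: dict  # pool -> (lo, hi) Hz
    theta: dict  # pool -> (lo, hi) Hz

    def band(self, pool: str, name: str):
        return getattr(self, name)[pool]


def estimate_spectra(eps: EpochSet, channels=None) -> SpectrumSet:
    """Hann-tapered per-epoch (cross-)periodograms averaged over accepted
    epochs.

    Requires at least two accepted epochs (coherence from one epoch is
    identically 1 and therefore meaningless).
    """
    if channels is None:
        channels = eps.channels
    idx = [eps.channels.index(c) for c in channels]
    data = eps.accepted_data()[:, idx, :]
    n_ep = data.shape[0]
    if n_ep < 2:
        raise SpectralError(
            f"need >= 2 accepted epochs to estimate spectra, got {n_ep}"
        )
    n_times = data.shape[2]
    window = np.hanning(n_times)
    scale = 2.0 / (eps.fs * (window**2).sum())
    fft = np.fft.rfft(data * window, axis=2)  # (ep, ch, f)
    freqs = np.fft.rfftfreq(n_times, 1.0 / eps.fs)

    cross = np.einsum("eif,ejf->ijf", fft, fft.conj()) * (scale / n_ep)
    # DC and Nyquist bins are not doubled by the one-sided convention
    cross[..., 0] *= 0.5
    if n_times % 2 == 0:
        cross[..., -1] *= 0.5
    psd = np.real(np.einsum("iif->if", cross)).copy()
    psd[psd < 0] = 0.0
    return SpectrumSet(
        freqs=freqs,
        psd=psd,
        cross=cross,
        channels=tuple(channels),
        n_epochs_used=n_ep,
        fs=eps.fs,
    )


def _band_mask(freqs, band):
    lo, hi = band
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise SpectralError(f"band {band} outside the frequency grid")
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def detect_apf(
    spec: SpectrumSet,
    pool_channels,
    window=APF_WINDOW,
    prominence: float = 0.05,
) -> ApfEstimate:
    """Alpha peak frequency: argmax of the pool-averaged PSD on the 8-13 Hz
    grid (edges inclusive, ties broken toward the lower frequency).

    The estimate is flagged low-confidence when the peak rises less than
    ``prominence`` above the window median (e.g. on a monotone 1/f
    spectrum, where the argmax is just the window edge).
    """
    idx = [spec.channels.index(c) for c in pool_channels]
    pool_psd = spec.psd[idx].mean(axis=0)
    mask = _band_mask(spec.freqs, window)
    grid = spec.freqs[mask]
    values = pool_psd[mask]
    k = int(np.argmax(values))  # first maximum = lowest frequency on ties
    peak = values[k]
    median = np.median(values)
    low_conf = bool(peak < (1.0 + prominence) * median) or k in (0, len(grid) - 1)
    return ApfEstimate(frequency=float(grid[k]), low_confidence=low_conf)


def band_limits(apf: float):
    """Individualized band limits: alpha = APF +/- 2 Hz, theta = APF-7 to
    APF-3 Hz.  APF must lie in the 8-13 Hz search window."""
    if not APF_WINDOW[0] <= apf <= APF_WINDOW[1]:
        raise ValueError(f"alpha peak {apf} Hz outside {APF_WINDOW}")
    return {
        "alpha": (apf - 2.0, apf + 2.0),
        "theta": (apf - 7.0, apf - 3.0),
    }


def band_scheme_for(spec: SpectrumSet) -> BandScheme:
    """Detect the APF of every pool and derive its band limits."""
    apf, alpha, theta = {}, {}, {}
    for pool, members in POOLS.items():
        present = [c for c in members if c in spec.channels]
        if len(present) != len(members):
            continue
        est = detect_apf(spec, present)
        lims = band_limits(est.frequency)
        apf[pool] = est
        alpha[pool] = lims["alpha"]
        theta[pool] = lims["theta"]
    return BandScheme(apf=apf, alpha=alpha, theta=theta)


def band_power(spec: SpectrumSet, pool_channels, band) -> float:
    """Pool band power: mean over the pool's channels of the PSD integrated
    over the band bins (both edges inclusive on the discrete grid)."""
    mask = _band_mask(spec.freqs, band)
    idx = [spec.channels.index(c) for c in pool_channels]
    return float(spec.psd[idx][:, mask].sum(axis=1).mean() * spec.df)


def pool_coherence(
    spec: SpectrumSet, pool_a, pool_b, band, mode: str = "msc"
) -> float:
    """Band-averaged coherence between two electrode pools.

    For each of the 9 cross-pool channel pairs the magnitude-squared
    coherence is formed from the epoch-averaged spectra, averaged over the
    band bins, then over the pairs.  ``mode="magnitude"`` returns the
    square root (magnitude coherence) at each bin instead.
    """
    if tuple(pool_a) == tuple(pool_b):
        raise ValueError("pool coherence requires two distinct pools")
    if spec.n_epochs_used < 2:
        raise SpectralError("coherence needs >= 2 averaged epochs")
    if mode not in ("msc", "magnitude"):
        raise ValueError(f"unknown coherence mode {mode!r}")
    mask = _band_mask(spec.freqs, band)
    ia = [spec.channels.index(c) for c in pool_a]
    ib = [spec.channels.index(c) for c in pool_b]
    vals = []
    for i in ia:
        for j in ib:
            denom = spec.psd[i][mask] * spec.psd[j][mask]
            if np.any(denom <= 0):
                raise SpectralError(
                    f"zero auto-spectrum in band for pair "
                    f"({spec.channels[i]}, {spec.channels[j]})"
                )
            msc = np.abs(spec.cross[i, j][mask]) ** 2 / denom
            if mode == "magnitude":
                msc = np.sqrt(msc)
            vals.append(msc.mean())
    return float(np.mean(vals))


def baseline_correct(task_value, baseline_value, mode: str = "subtract"):
    """Contrast a task-period feature against the resting baseline.

    ``subtract`` returns task - baseline; ``log_ratio`` (power only)
    returns 10*log10(task/baseline) in dB.
    """
    if mode == "subtract":
        return task_value - baseline_value
    if mode == "log_ratio":
        if task_value <= 0 or baseline_value <= 0:
            raise ValueError("log-ratio correction requires positive values")
        return 10.0 * np.log10(task_value / baseline_value)
    raise ValueError(f"unknown baseline correction mode {mode!r}")


def apf_asymmetry(left: ApfEstimate, right: ApfEstimate) -> ApfEstimate:
    """Lateral asymmetry of the alpha peak: left minus right (signed Hz).

    The result carries a low-confidence flag if either input does.
    """
    return ApfEstimate(
        frequency=left.frequency - right.frequency,
        low_confidence=left.low_confidence or right.low_confidence,
    )
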