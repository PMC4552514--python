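"""Raw recordings to clean, Laplacian-referenced, epoched data.

Fixed stage order: zero-phase Butterworth band-pass and mains notch,
ICA-based ocular correction, spherical-spline surface Laplacian (current
source density), segmentation into contiguous 5-s epochs, and amplitude /
peak-to-peak artifact rejection at 500 and 800 uV/m^2.

Filters are 4th-order Butterworth applied forward-backward, which doubles
the magnitude roll-off to 48 dB/oct and cancels the phase response.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal

from .recording import ANALYSIS_CHANNELS, EpochSet, Recording

__all__ = [
    "PreprocessError",
    "OcularReport",
    "bandpass_filter",
    "notch_filter",
    "remove_ocular",
    "apply_csd",
    "segment",
    "reject_epochs",
    "preprocess_recording",
]

AMPLITUDE_THRESHOLD = 500.0  # uV/m^2, max |sample|
PEAK_TO_PEAK_THRESHOLD = 800.0  # uV/m^2, max - min per channel


class PreprocessError(RuntimeError):
    pass


def _require_stage(rec: Recording, expected, op: str) -> None:
    if isinstance(expected, str):
        expected = (expected,)
    if rec.stage not in expected:
        raise PreprocessError(
            f"{op} expects stage {' or '.join(expected)}, got {rec.stage!r}"
        )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass_filter(
    rec: Recording, highpass: float = 0.3, lowpass: float = 100.0
) -> Recording:
    """Zero-phase Butterworth band-pass (0.3-100 Hz, 48 dB/oct overall).

    A 4th-order section per edge, applied forward-backward.  Requires
    fs >= 256 Hz so the 100 Hz edge stays clear of Nyquist.
    """
    _require_stage(rec, "raw", "bandpass_filter")
    if rec.fs < 256.0:
        raise PreprocessError(
            f"sampling rate {rec.fs} Hz too low for a {lowpass} Hz low-pass"
        )
    sos_hp = signal.butter(4, highpass, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(4, lowpass, btype="lowpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
    data = signal.sosfiltfilt(sos_lp, data, axis=1)
    return rec.copy(data=data, stage="filtered")


def notch_filter(rec: Recording, mains: float = 50.0, width: float = 2.0) -> Recording:
    """Zero-phase Butterworth band-stop around the mains frequency.

    The band-stop transmission zero sits exactly on ``mains``; the 2 Hz
    stop band leaves 45 and 55 Hz essentially untouched.
    """
    if mains >= rec.fs / 2:
        raise PreprocessError("mains frequency must be below Nyquist")
    sos = signal.butter(
        2,
        [mains - width / 2, mains + width / 2],
        btype="bandstop",
        fs=rec.fs,
        output="sos",
    )
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy(data=data)


# ---------------------------------------------------------------------------
# Ocular correction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OcularReport:
    """Which independent components were flagged as ocular, and why."""

    n_components: int
    flagged: list
    proxy_correlation: np.ndarray  # |corr| with the frontal proxy signal
    frontal_dominance: np.ndarray  # mean |frontal load| / mean |parietal load|
    low_freq_fraction: np.ndarray  # component variance below 5 Hz
    proxy_channels: tuple
    converged: bool = True
    n_iter: int = 0


def _anterior_order(rec: Recording):
    """Channel indices sorted front (max y) to back."""
    y = np.array([rec.positions[c][1] for c in rec.channels])
    return np.argsort(y)[::-1], y


def remove_ocular(
    rec: Recording,
    seed: int = 0,
    n_components: int | None = None,
    corr_threshold: float = 0.7,
    dominance_threshold: float = 2.0,
    lf_threshold: float = 0.55,
    lf_cutoff: float = 5.0,
    enabled: bool = True,
):
    """Remove ocular (blink) components by seeded fast fixed-point ICA.

    A component is flagged as ocular when (a) the absolute correlation of
    its time course with the frontal proxy (mean of the two most frontal
    channels) exceeds ``corr_threshold``, (b) its scalp loading is
    frontal-dominant, and (c) most of its variance lies below ``lf_cutoff``
    (blinks are slow transients).  Flagged components are zeroed and the
    data reconstructed.  Returns ``(recording, OcularReport)``.

    The decomposition is fit on data decimated to about 64 Hz (blinks live
    far below that) and applied to the full-rate data.  An iteration-limit
    stop is recorded in the report (on blink-free, near-Gaussian data the
    fixed point has no stable contrast optimum and the flagging criteria
    are what protect the data); a non-finite decomposition raises.

    With ``enabled=False`` the decomposition is skipped entirely and the
    data pass through unchanged (for recordings known to be blink-free).
    """
    _require_stage(rec, "filtered", "remove_ocular")
    if rec.n_channels < 8:
        raise PreprocessError("ocular correction needs at least 8 channels")
    order, y = _anterior_order(rec)
    proxy_idx = order[:2]
    proxy_channels = tuple(rec.channels[i] for i in proxy_idx)
    if not enabled:
        report = OcularReport(
            n_components=0,
            flagged=[],
            proxy_correlation=np.empty(0),
            frontal_dominance=np.empty(0),
            low_freq_fraction=np.empty(0),
            proxy_channels=proxy_channels,
        )
        return rec.copy(stage="ocular_corrected"), report

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    x = rec.data
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    k = min(n_components or rec.n_channels, rec.n_channels)
    decim = max(1, int(rec.fs // 64))

    ica = FastICA(
        n_components=k, random_state=seed, max_iter=300, tol=5e-4,
        whiten="unit-variance",
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ica.fit(xc[:, ::decim].T)
    converged = not any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )
    if not (
        np.all(np.isfinite(ica.components_))
        and np.all(np.isfinite(ica.mixing_))
    ):
        raise PreprocessError(
            f"ICA produced a non-finite decomposition "
            f"(k={k}, decim={decim}, n_iter={ica.n_iter_})"
        )
    sources = ica.components_ @ xc  # (k, n_samp) at full rate
    mixing = ica.mixing_  # (n_ch, k): xc ~= mixing @ sources

    # frontal proxy and flagging criteria
    proxy = xc[proxy_idx].mean(axis=0)
    corr = np.array(
        [abs(np.corrcoef(srcrow, proxy)[0, 1]) for srcrow in sources]
    )
    thirds = max(1, rec.n_channels // 3)
    frontal_set = order[:thirds]
    parietal_set = order[-thirds:]
    load = np.abs(mixing)
    dominance = load[frontal_set].mean(axis=0) / np.maximum(
        load[parietal_set].mean(axis=0), 1e-12
    )
    freqs = np.fft.rfftfreq(sources.shape[1], 1.0 / rec.fs)
    spec = np.abs(np.fft.rfft(sources, axis=1)) ** 2
    lf = spec[:, freqs < lf_cutoff].sum(axis=1) / np.maximum(
        spec.sum(axis=1), 1e-30
    )

    flagged = [
        int(i)
        for i in range(k)
        if corr[i] > corr_threshold
        and dominance[i] > dominance_threshold
        and lf[i] > lf_threshold
    ]
    report = OcularReport(
        n_components=k,
        flagged=flagged,
        proxy_correlation=corr,
        frontal_dominance=dominance,
        low_freq_fraction=lf,
        proxy_channels=proxy_channels,
        converged=converged,
        n_iter=int(ica.n_iter_),
    )
    if not flagged:
        return rec.copy(stage="ocular_corrected"), report
    cleaned = rec.data - mixing[:, flagged] @ sources[flagged]
    return rec.copy(data=cleaned, stage="ocular_corrected"), report


# ---------------------------------------------------------------------------
# Surface Laplacian (current source density)
# ---------------------------------------------------------------------------

def apply_csd(
    rec: Recording,
    stiffness: int = 4,
    lambda2: float = 1e-5,
    n_legendre_terms: int = 50,
) -> Recording:
    """Spherical-spline surface Laplacian; output units uV/m^2.

    Electrode positions are projected onto the unit sphere; the Laplacian
    is computed at that radius, which puts clean EEG in the tens of
    uV/m^2 and focal high-amplitude artifacts in the thousands - the scale
    at which the standard 500/800 uV/m^2 rejection thresholds operate.
    """
    _require_stage(rec, "ocular_corrected", "apply_csd")
    missing = [c for c in rec.channels if c not in rec.positions]
    if missing:
        raise PreprocessError(f"positions missing for {missing}")

    from mne.preprocessing import compute_current_source_density

    raw = rec.to_mne_raw()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = compute_current_source_density(
            raw,
            sphere=(0.0, 0.0, 0.0, 1.0),
            lambda2=lambda2,
            stiffness=stiffness,
            n_legendre_terms=n_legendre_terms,
            copy=True,
            verbose="ERROR",
        )
    return rec.copy(data=out.get_data() * 1e6, stage="csd", units="uV/m^2")


# ---------------------------------------------------------------------------
# Epoching and rejection
# ---------------------------------------------------------------------------

def segment(
    rec: Recording,
    epoch_length: float = 5.0,
    start: float = 0.0,
    stop: float | None = None,
) -> EpochSet:
    """Cut the recording into contiguous, non-overlapping epochs.

    A trailing partial epoch is discarded.  ``start``/``stop`` (seconds)
    restrict the span; bounds outside the recording raise.
    """
    if stop is None:
        stop = rec.duration
    if start < 0 or stop > rec.duration + 1e-9 or stop <= start:
        raise ValueError(
            f"span [{start}, {stop}] outside recording of {rec.duration} s"
        )
    i0 = int(round(start * rec.fs))
    i1 = int(round(stop * rec.fs))
    ep_samp = int(round(epoch_length * rec.fs))
    n_epochs = (i1 - i0) // ep_samp
    if n_epochs < 1:
        raise ValueError(
            f"span of {stop - start:.3f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    data = rec.data[:, i0:i0 + n_epochs * ep_samp]
    epochs = data.reshape(rec.n_channels, n_epochs, ep_samp).swapaxes(0, 1)
    return EpochSet(
        epochs=epochs.copy(),
        fs=rec.fs,
        channels=rec.channels,
        epoch_length=epoch_length,
        accepted=np.ones(n_epochs, dtype=bool),
        rejection_reason=["none"] * n_epochs,
        stage=rec.stage,
        units=rec.units,
    )


def reject_epochs(
    eps: EpochSet,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    ptp_threshold: float = PEAK_TO_PEAK_THRESHOLD,
    channels=None,
) -> EpochSet:
    """Flag epochs whose Laplacian amplitude exceeds the rejection limits.

    An epoch is rejected when any channel's max |sample| exceeds
    ``amplitude_threshold`` or any channel's max-min range exceeds
    ``ptp_threshold`` (amplitude takes precedence as the recorded reason).
    Thresholds apply per channel over the analysis channels by default.
    """
    if eps.stage != "csd":
        raise PreprocessError("rejection thresholds are defined on Laplacian data")
    if channels is None:
        channels = [c for c in ANALYSIS_CHANNELS if c in eps.channels]
    idx = [eps.channels.index(c) for c in channels]
    sub = eps.epochs[:, idx, :]
    max_abs = np.abs(sub).max(axis=(1, 2))
    ptp = (sub.max(axis=2) - sub.min(axis=2)).max(axis=1)

    accepted = np.ones(eps.n_epochs, dtype=bool)
    reasons = []
    for e in range(eps.n_epochs):
        if max_abs[e] > amplitude_threshold:
            accepted[e] = False
            reasons.append("amplitude")
        elif ptp[e] > ptp_threshold:
            accepted[e] = False
            reasons.append("peak_to_peak")
        else:
            reasons.append("none")
    return EpochSet(
        epochs=eps.epochs,
        fs=eps.fs,
        channels=eps.channels,
        epoch_length=eps.epoch_length,
        accepted=accepted,
        rejection_reason=reasons,
        stage=eps.stage,
        units=eps.units,
    )


def preprocess_recording(
    rec: Recording,
    seed: int = 0,
    epoch_length: float = 5.0,
    ocular: bool = True,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    ptp_threshold: float = PEAK_TO_PEAK_THRESHOLD,
    mains: float = 50.0,
):
    """Run the full fixed-order pipeline on one raw recording.

    filter -> notch -> ocular correction -> surface Laplacian -> 5-s
    epochs -> amplitude/peak-to-peak rejection.  Returns
    ``(EpochSet, OcularReport)``.
    """
    rec = bandpass_filter(rec)
    rec = notch_filter(rec, mains=mains)
    rec, report = remove_ocular(rec, seed=seed, enabled=ocular)
    rec = apply_csd(rec)
    eps = segment(rec, epoch_length=epoch_length)
    eps = reject_epochs(
        eps,
        amplitude_threshold=amplitude_threshold,
        ptp_threshold=ptp_threshold,
    )
    return eps, report
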