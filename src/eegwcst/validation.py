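"""End-to-end validation harnesses with known ground truth.

Each function runs a self-contained experiment against the package's own
oracles (closed forms, planted generator truth, independent re-derivations)
and returns plain numbers.  The problem sizes are scaled so the whole
battery runs on one CPU in minutes; the methods note documents the sizes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import (
    bandpass_filter,
    notch_filter,
    preprocess_recording,
    remove_ocular,
    segment,
)
from .recording import EpochSet, POOLS, default_positions
from .spectral import band_power, estimate_spectra, pool_coherence
from .stats import partial_correlation, run_design
from .synthdata import (
    CohortConfig,
    draw_subject_truths,
    iter_cohort,
    plant_artifacts,
    synthesize_coherent_pair,
    synthesize_eeg,
)
from .pipeline import RunConfig, run_all

#: Reduced montage used by the validation experiments (all pooled channels
#: plus frontal/midline/occipital coverage for the Laplacian and ICA).
VALIDATION_CHANNELS = (
    "Fp1", "Fp2", "F3", "Fz", "F4",
    "FC5", "FC1", "FC2", "FC6", "Cz",
    "CP5", "CP1", "CP2", "CP6",
    "P3", "Pz", "P4", "O1", "O2",
)


def _epochs_from_array(data, fs, epoch_length=5.0, channels=("A", "B")):
    n_ch = data.shape[0]
    ep = int(round(epoch_length * fs))
    n_ep = data.shape[1] // ep
    epochs = data[:, : n_ep * ep].reshape(n_ch, n_ep, ep).swapaxes(0, 1)
    return EpochSet(
        epochs=epochs,
        fs=fs,
        channels=channels,
        epoch_length=epoch_length,
        accepted=np.ones(n_ep, dtype=bool),
        rejection_reason=["none"] * n_ep,
    )


def coherence_oracle(
    seed: int, gammas=(0.25, 0.5, 1.0, 2.0, 4.0), n_epochs: int = 500
):
    """Pipeline msc on shared-source pairs vs the closed form (g/(1+g))^2.

    Returns ``{gamma: (estimate, analytic)}``.
    """
    out = {}
    for k, gamma in enumerate(gammas):
        data, fs = synthesize_coherent_pair(
            gamma, n_epochs=n_epochs, seed=seed + k
        )
        eps = _epochs_from_array(data, fs)
        spec = estimate_spectra(eps)
        est = pool_coherence(spec, ("A",), ("B",), (8.0, 12.0))
        out[gamma] = (est, (gamma / (1.0 + gamma)) ** 2)
    return out


def independent_noise_coherence(seed: int, n_epochs: int = 200) -> float:
    """msc of two independent white-noise channels (bias ~ 1/n_epochs)."""
    rng = np.random.default_rng(seed)
    fs = 256.0
    data = rng.standard_normal((2, int(n_epochs * 5 * fs)))
    spec = estimate_spectra(_epochs_from_array(data, fs))
    return pool_coherence(spec, ("A",), ("B",), (8.0, 12.0))


def parseval_integral(seed: int, n_epochs: int = 60) -> float:
    """Integral of the PSD of unit-variance white noise over [0, Nyquist]."""
    rng = np.random.default_rng(seed)
    fs = 256.0
    data = rng.standard_normal((1, int(n_epochs * 5 * fs)))
    spec = estimate_spectra(_epochs_from_array(data, fs, channels=("A",)))
    return float(spec.psd[0].sum() * spec.df)


def apf_recovery(seed: int, n_epochs: int = 150):
    """Recover planted on-grid alpha peaks through synthesis + estimation.

    The planted peaks sit on the 0.2 Hz analysis grid and the inter-pool
    coherence is set to its minimum so the alpha bump rises well clear of
    the 1/f background (peak SNR far above 2).  Returns the maximum
    |estimated - planted| in Hz across subjects and pools.
    """
    config = CohortConfig(
        n_subjects=6,
        seed=seed,
        fs=256.0,
        task_duration=n_epochs * 5.0,
        channels=VALIDATION_CHANNELS,
        n_blink_epochs=0,
        n_amplitude_epochs=0,
        coherence_base=0.012,
        coherence_age_slope=0.0,
        coherence_skill_effect=0.0,
        coherence_noise_sd=0.0,
        coherence_bounds=(0.01, 0.02),
    )
    truths = draw_subject_truths(config)
    planted = np.round(np.linspace(8.6, 12.2, len(truths)) / 0.2) * 0.2
    positions = default_positions(config.channels)
    errs = []
    from .spectral import band_scheme_for

    for truth, apf in zip(truths, planted):
        truth.apf_left = float(apf)
        truth.apf_right = float(apf)
        rec = synthesize_eeg(
            truth, config.task_duration, config.fs, config.channels,
            positions, seed=seed + int(apf * 10), config=config,
        )
        eps = segment(rec, epoch_length=5.0)
        spec = estimate_spectra(
            eps, [c for p in POOLS.values() for c in p]
        )
        scheme = band_scheme_for(spec)
        for pool in POOLS:
            errs.append(abs(scheme.apf[pool].frequency - apf))
    return float(max(errs))


def artifact_recovery(seed: int, n_subjects: int = 3):
    """Full pipeline on a cohort with planted artifacts.

    Returns ``(false_positives, false_negatives)`` of epoch rejection
    against the planted amplitude-artifact ledger (blinks are removed by
    the ocular stage and must not trigger rejection).
    """
    config = CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        fs=256.0,
        task_duration=60.0,
        channels=VALIDATION_CHANNELS,
        n_blink_epochs=2,
        n_amplitude_epochs=2,
    )
    fp = fn = 0
    for i, subject in enumerate(iter_cohort(config)):
        eps, _ = preprocess_recording(
            subject.recording_task, seed=seed + i, ocular=True
        )
        rejected = {e for e in range(eps.n_epochs) if not eps.accepted[e]}
        planted = {
            e for e, kind in subject.truth.artifact_ledger
            if kind == "amplitude"
        }
        fp += len(rejected - planted)
        fn += len(planted - rejected)
    return fp, fn


@dataclasses.dataclass
class BlinkCorrectionResult:
    frontal_variance_reduction: float  # fraction removed in blink epochs
    parietal_alpha_change: float  # relative change of PL/PR alpha power
    n_flagged: int


def blink_correction(seed: int) -> BlinkCorrectionResult:
    """Plant blinks, run ocular correction, measure what it removed.

    Frontal variance is compared before/after in the ledgered blink
    epochs; parietal alpha band power (8-12 Hz, pre-Laplacian) must pass
    through nearly unchanged.
    """
    config = CohortConfig(
        n_subjects=3,
        seed=seed,
        fs=256.0,
        task_duration=60.0,
        channels=VALIDATION_CHANNELS,
        n_blink_epochs=0,
        n_amplitude_epochs=0,
    )
    truth = draw_subject_truths(config)[0]
    positions = default_positions(config.channels)
    rec = synthesize_eeg(
        truth, config.task_duration, config.fs, config.channels, positions,
        seed=seed, config=config,
    )
    blink_epochs = (2, 5, 8)
    dirty, _ = plant_artifacts(
        rec, blink_epochs=blink_epochs, seed=seed,
        blink_amplitude=config.blink_amplitude,
    )
    filtered = notch_filter(bandpass_filter(dirty))
    clean, report = remove_ocular(filtered, seed=seed)

    frontal = [clean.index(c) for c in ("Fp1", "Fp2", "F3", "F4")]
    parietal_pools = [list(POOLS["PL"]), list(POOLS["PR"])]
    ep = int(5 * config.fs)

    reductions = []
    for e in blink_epochs:
        sl = slice(e * ep, (e + 1) * ep)
        before = filtered.data[frontal, sl].var(axis=1)
        after = clean.data[frontal, sl].var(axis=1)
        reductions.append(1.0 - after.sum() / before.sum())

    def parietal_alpha(recording):
        eps = segment(recording, epoch_length=5.0)
        spec = estimate_spectra(eps, [c for p in parietal_pools for c in p])
        return np.mean(
            [band_power(spec, pool, (8.0, 12.0)) for pool in parietal_pools]
        )

    p_before = parietal_alpha(filtered)
    p_after = parietal_alpha(clean)
    return BlinkCorrectionResult(
        frontal_variance_reduction=float(min(reductions)),
        parietal_alpha_change=float(abs(p_after - p_before) / p_before),
        n_flagged=len(report.flagged),
    )


def partial_correlation_oracle(seed: int, n_instances: int = 100) -> float:
    """Max |formula - residual-regression| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(10, 200))
        base = rng.standard_normal((3, n))
        mix = rng.standard_normal((3, 3))
        x, y, z = mix @ base
        r = partial_correlation(x, y, z).estimates["r"]
        # independent oracle: correlation of the OLS residuals
        zc = np.column_stack([np.ones(n), z])
        rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
        ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
        r_resid = np.corrcoef(rx, ry)[0, 1]
        worst = max(worst, abs(r - r_resid))
    return float(worst)


def partial_correlation_type1(
    seed: int, n_sims: int = 2000, n: int = 60, alpha: float = 0.05
) -> float:
    """Empirical type-I error of the partial-correlation t-test under
    independence (x, y, z iid normal)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        x, y, z = rng.standard_normal((3, n))
        if partial_correlation(x, y, z).p_values["r"] < alpha:
            hits += 1
    return hits / n_sims


def recovery_run_config(seed: int, n_subjects: int = 60) -> RunConfig:
    """Scaled pipeline configuration for the parameter-recovery study:
    256 Hz, 300-s tasks (60 epochs), artifact-free, ocular stage skipped."""
    return RunConfig(
        mode="synthetic",
        seed=seed,
        cohort=CohortConfig(
            n_subjects=n_subjects,
            seed=seed,
            fs=256.0,
            task_duration=300.0,
            channels=VALIDATION_CHANNELS,
            n_blink_epochs=0,
            n_amplitude_epochs=0,
        ),
        ocular_correction=False,
        run_stats=False,
    )


RECOVERY_FEATURES = (
    "power_FL_alpha_task", "power_FR_alpha_task",
    "power_PL_alpha_task", "power_PR_alpha_task",
    "apf_FL", "coh_FL_PR_alpha_task", "coh_FL_PR_theta_task",
)


def age_structure_recovery(seed: int, n_seeds: int = 20, n_subjects: int = 60):
    """Sign recovery of the planted age and performance effects through the
    full pipeline, over ``n_seeds`` independent cohorts.

    Returns a dict with the fraction of runs recovering (a) the negative
    age slope of task alpha power in all four pools, (b) the negative age
    slope of the left-frontal alpha peak, and (c) the positive FL-PR
    coherence/performance partial correlation in the elders-only subgroup
    (plus its median p-value).
    """
    alpha_ok = apf_ok = elders_ok = 0
    elders_p = []
    for k in range(n_seeds):
        run_seed = seed + 17 * k
        result = run_all(recovery_run_config(run_seed, n_subjects))
        stats = run_design(
            result.features,
            feature_columns=list(RECOVERY_FEATURES),
            subgroups=True,
        )
        betas = stats[(stats.design == "regression") & (stats.term == "age")]
        alpha_cols = [f"power_{p}_alpha_task" for p in POOLS]
        signs = [
            float(betas[betas.feature == c].estimate.iloc[0]) < 0
            for c in alpha_cols
        ]
        alpha_ok += all(signs)
        apf_beta = float(
            betas[betas.feature == "apf_FL"].estimate.iloc[0]
        )
        apf_ok += apf_beta < 0
        elders = stats[
            (stats.subgroup == "elders")
            & (stats.feature == "coh_FL_PR_alpha_task")
        ]
        r = float(elders.estimate.iloc[0])
        p = float(elders.p.iloc[0])
        elders_ok += r > 0
        elders_p.append(p)
    return {
        "alpha_power_negative_age_slope": alpha_ok / n_seeds,
        "apf_left_negative_age_slope": apf_ok / n_seeds,
        "elders_flpr_positive": elders_ok / n_seeds,
        "elders_flpr_median_p": float(np.median(elders_p)),
        "n_seeds": n_seeds,
    }
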