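"""Synthetic cohorts with known ground truth: EEG, WCST behavior, metadata.

The generator emulates the statistical structure of an aging/EEG study:
three age groups (young ~20-34, mid ~51-64, elder ~67-82), cognitive
performance anticorrelated with age (target Pearson r = -0.621), alpha and
theta band power declining with age, a left-hemisphere alpha-peak-frequency
slowdown with age, a performance-only coherence effect on the FL-PR
coupling, plus blink and high-amplitude artifacts with a ledger for
verification.

EEG synthesis is exact in the frequency domain: every component is realized
with deterministic spectral magnitudes and random phases, so the analytic
power spectra and cross-spectra of the generated signals equal the planted
targets and pipeline estimates converge to them as the epoch count grows.
Channels are built from

* a 1/f-shaped background that is channel-independent inside the 1-18 Hz
  analysis range (a spatially correlated background would impose a hard
  floor on cross-pool coherence) and carried by spatially smooth fields
  outside it (smoothness keeps the broadband surface-Laplacian amplitude
  of clean data far below the artifact-rejection thresholds);
* one alpha and one theta oscillator per electrode pool (Gaussian spectral
  bumps anchored at the subject's alpha peak frequency) with a compact
  scalp map centred on the pool;
* one band-limited shared source per pool coupling and band whose gains
  are solved against the full analytic cross-spectral model (background
  correlation, scalp-map leakage and every other source included) so the
  band-averaged magnitude-squared coherence equals the subject's target.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.optimize import brentq

from .recording import (
    DEFAULT_CHANNELS,
    POOL_COUPLINGS,
    POOLS,
    Recording,
    default_positions,
)
from .wcst import RULES, RUN_LENGTH, TrialLog, TrialRecord

__all__ = [
    "CohortConfig",
    "SubjectTruth",
    "CohortSubject",
    "ConfigurationError",
    "draw_subject_truths",
    "synthesize_eeg",
    "synthesize_coherent_pair",
    "plant_artifacts",
    "simulate_wcst_agent",
    "agent_rates_from_skill",
    "generate_cohort",
    "iter_cohort",
]

BANDS = ("theta", "alpha")


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the emulated study: 62 subjects in three age groups
    (19/28/15), age-performance correlation -0.621, 1024 Hz sampling,
    300 s task recordings and 30 s baselines, 5-s epochs.
    """

    n_subjects: int = 62
    seed: int = 0
    age_groups: tuple = ((20, 34), (51, 64), (67, 82))
    age_group_names: tuple = ("young", "mid", "elder")
    age_proportions: tuple = (19 / 62, 28 / 62, 15 / 62)
    skill_age_correlation: float = -0.621

    fs: float = 1024.0
    task_duration: float = 300.0
    baseline_duration: float = 30.0
    epoch_length: float = 5.0
    channels: tuple = DEFAULT_CHANNELS

    # Background spectrum: S(f) = bg_level / max(f, 0.5)^slope + white_floor
    spectral_slope: float = 1.0
    bg_level: float = 3.0  # uV^2 (1/f numerator)
    white_floor: float = 0.05  # uV^2/Hz
    bg_smooth_fraction: float = 0.85  # share of background power in smooth fields
    n_smooth_fields: int = 16
    smooth_field_width: float = 0.09  # m, spatial Gaussian width
    # Inside this band the background is channel-independent: a spatially
    # correlated (volume-conduction-like) background would impose a hard
    # floor on cross-pool coherence and make low planted targets
    # unrealizable.  Outside it, smooth fields keep the broadband surface
    # Laplacian of clean data small.
    smooth_exclude_band: tuple = (1.0, 18.0)
    pool_map_width: float = 0.03  # m, oscillator/shared-source scalp maps (narrow:
    # wider maps leak across regions and inflate cross-pool coherence)

    # Band-power targets (pool-averaged, uV^2) as linear functions of age
    alpha_power_base: float = 20.0  # at the reference age
    alpha_power_age_slope: float = 0.15  # uV^2 lost per year
    theta_power_base: float = 14.0
    theta_power_age_slope: float = 0.08
    power_noise_sd: float = 1.0
    power_floor: float = 6.0
    reference_age: float = 50.0
    baseline_alpha_factor: float = 1.3  # resting alpha exceeds task alpha
    baseline_theta_factor: float = 0.8  # task theta exceeds resting theta

    # Alpha peak frequency (Hz): left hemisphere declines with age
    apf_left_base: float = 10.4
    apf_age_slope: float = 0.025  # Hz lost per year, left hemisphere
    apf_right_base: float = 10.2
    apf_noise_sd: float = 0.25
    apf_bounds: tuple = (8.3, 12.5)
    alpha_bump_sigma: float = 0.5  # Hz
    theta_bump_sigma: float = 0.7  # Hz

    # Coherence targets (band-averaged msc) per coupling.  Modest values:
    # each pool carries three couplings plus its oscillator and the 1/f
    # background inside one band-power budget, which bounds the jointly
    # realizable coherence.
    coherence_base: float = 0.03
    coherence_age_slope: float = 0.0005  # per year, age-coupled pairs
    coherence_skill_effect: float = 0.02  # per skill SD, FL-PR only
    coherence_noise_sd: float = 0.006
    coherence_bounds: tuple = (0.01, 0.075)
    baseline_coherence_factor: float = 1.15

    # Artifacts (per task recording)
    n_blink_epochs: int = 2
    n_amplitude_epochs: int = 2
    blink_amplitude: float = 350.0  # uV at the most frontal site
    artifact_amplitude: float = 400.0  # uV, focal half-sine transient

    # WCST agent links (latent skill -> behavior)
    learn_intercept: float = 0.8
    learn_slope: float = 1.6
    persev_intercept: float = -1.8
    persev_slope: float = 1.6
    distraction_intercept: float = -2.6
    distraction_slope: float = 1.2

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        if not (-1.0 < self.skill_age_correlation <= 0.0):
            raise ConfigurationError("skill_age_correlation must be in (-1, 0]")
        if self.task_duration <= 0 or self.baseline_duration <= 0:
            raise ConfigurationError("durations must be positive")
        if self.baseline_duration < 30.0 - 1e-9:
            raise ConfigurationError("baseline recording must be >= 30 s")
        for lo, hi in self.age_groups:
            if lo >= hi:
                raise ConfigurationError(f"invalid age range ({lo}, {hi})")
        if len(self.age_groups) != len(self.age_proportions):
            raise ConfigurationError("age group/proportion length mismatch")
        if abs(sum(self.age_proportions) - 1.0) > 1e-6:
            raise ConfigurationError("age proportions must sum to 1")
        missing = [p for pool in POOLS.values() for p in pool
                   if p not in self.channels]
        if missing:
            raise ConfigurationError(f"montage lacks pooled channels {missing}")


@dataclasses.dataclass
class SubjectTruth:
    """Planted ground truth for one synthetic subject."""

    subject_id: str
    age: float
    sex: str
    age_group: str
    latent_skill: float
    apf_left: float
    apf_right: float
    band_power_targets: dict  # (pool, band, span) -> uV^2
    coherence_targets: dict  # (coupling, band, span) -> msc in [0, 1]
    artifact_ledger: list = dataclasses.field(default_factory=list)

    def apf(self, pool: str) -> float:
        return self.apf_left if pool.endswith("L") else self.apf_right

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["band_power_targets"] = {
            "|".join(k): v for k, v in self.band_power_targets.items()
        }
        payload["coherence_targets"] = {
            "|".join(("-".join(k[0]),) + k[1:]): v
            for k, v in self.coherence_targets.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclasses.dataclass
class CohortSubject:
    truth: SubjectTruth
    recording_task: Recording
    recording_baseline: Recording
    trial_log: TrialLog


# ---------------------------------------------------------------------------
# Subject-level truth
# ---------------------------------------------------------------------------

def _truth_bands(truth: SubjectTruth):
    """Band limits per pool and the per-coupling band (mean of pool APFs)."""
    pool_bands = {}
    for pool in POOLS:
        apf = truth.apf(pool)
        pool_bands[pool] = {
            "alpha": (apf - 2.0, apf + 2.0),
            "theta": (apf - 7.0, apf - 3.0),
        }
    coupling_bands = {}
    for a, b in POOL_COUPLINGS:
        apf = 0.5 * (truth.apf(a) + truth.apf(b))
        coupling_bands[(a, b)] = {
            "alpha": (apf - 2.0, apf + 2.0),
            "theta": (apf - 7.0, apf - 3.0),
        }
    return pool_bands, coupling_bands


def draw_subject_truths(config: CohortConfig, rng=None) -> list:
    """Draw per-subject ground truth (metadata, spectra and behavior targets)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.n_subjects
    # deterministic group sizes closest to the target proportions
    sizes = [int(round(p * n)) for p in config.age_proportions]
    while sum(sizes) > n:
        sizes[int(np.argmax(sizes))] -= 1
    while sum(sizes) < n:
        sizes[int(np.argmin(sizes))] += 1
    ages, groups = [], []
    for (lo, hi), name, m in zip(
        config.age_groups, config.age_group_names, sizes
    ):
        ages.extend(rng.integers(lo, hi + 1, size=m).astype(float))
        groups.extend([name] * m)
    ages = np.asarray(ages)

    age_sd = ages.std(ddof=1)
    if age_sd > 0:
        z_age = (ages - ages.mean()) / age_sd
    else:
        z_age = np.zeros_like(ages)  # degenerate: correlation undefined
    rho = -config.skill_age_correlation  # positive magnitude
    skill = rho * (-z_age) + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    truths = []
    for i in range(n):
        dage = ages[i] - config.reference_age
        apf_left = float(
            np.clip(
                config.apf_left_base
                - config.apf_age_slope * dage
                + rng.normal(0, config.apf_noise_sd),
                *config.apf_bounds,
            )
        )
        apf_right = float(
            np.clip(
                config.apf_right_base + rng.normal(0, config.apf_noise_sd),
                *config.apf_bounds,
            )
        )

        power = {}
        for pool in POOLS:
            for band, base, slope in (
                ("alpha", config.alpha_power_base, config.alpha_power_age_slope),
                ("theta", config.theta_power_base, config.theta_power_age_slope),
            ):
                task = max(
                    base - slope * dage + rng.normal(0, config.power_noise_sd),
                    config.power_floor,
                )
                factor = (
                    config.baseline_alpha_factor
                    if band == "alpha"
                    else config.baseline_theta_factor
                )
                power[(pool, band, "task")] = task
                power[(pool, band, "baseline")] = max(
                    task * factor, config.power_floor
                )

        coherence = {}
        for coupling in POOL_COUPLINGS:
            for band in BANDS:
                c = config.coherence_base - config.coherence_age_slope * dage
                if coupling == ("FL", "PR"):
                    # performance-only effect, age plays no role here
                    c = config.coherence_base + (
                        config.coherence_skill_effect * skill[i]
                    )
                c += rng.normal(0, config.coherence_noise_sd)
                c = float(np.clip(c, *config.coherence_bounds))
                coherence[(coupling, band, "task")] = c
                coherence[(coupling, band, "baseline")] = float(
                    np.clip(
                        c * config.baseline_coherence_factor,
                        *config.coherence_bounds,
                    )
                )

        truths.append(
            SubjectTruth(
                subject_id=f"S{i:03d}",
                age=float(ages[i]),
                sex="F" if rng.random() < 0.5 else "M",
                age_group=groups[i],
                latent_skill=float(skill[i]),
                apf_left=apf_left,
                apf_right=apf_right,
                band_power_targets=power,
                coherence_targets=coherence,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# Spectral plan: analytic PSDs and calibrated source gains
# ---------------------------------------------------------------------------

def _gauss_bump(f, center, sigma):
    """Unit-integral Gaussian spectral bump (1/Hz)."""
    return np.exp(-0.5 * ((f - center) / sigma) ** 2) / (
        sigma * np.sqrt(2 * np.pi)
    )


def _bg_psd(f, config: CohortConfig):
    return config.bg_level / np.maximum(f, 0.5) ** config.spectral_slope + (
        config.white_floor
    )


def _bg_split(f, config: CohortConfig):
    """Background PSD split into channel-independent and spatially smooth
    shares; inside ``smooth_exclude_band`` everything is independent."""
    bg = _bg_psd(f, config)
    lo, hi = config.smooth_exclude_band
    inside = (f >= lo) & (f <= hi)
    ind_share = np.where(inside, 1.0, 1.0 - config.bg_smooth_fraction)
    return bg * ind_share, bg * (1.0 - ind_share)


def _pool_maps(channels, positions, width):
    """Smooth scalp map per pool: Gaussian around the pool centroid,
    rescaled so the RMS over the pool's own channels is 1."""
    pos = np.array([positions[c] for c in channels])
    maps = {}
    for pool, members in POOLS.items():
        centroid = np.mean([positions[m] for m in members], axis=0)
        d2 = np.sum((pos - centroid) ** 2, axis=1)
        m = np.exp(-d2 / (2 * width**2))
        idx = [channels.index(c) for c in members]
        maps[pool] = m / np.sqrt(np.mean(m[idx] ** 2))
    return maps


@dataclasses.dataclass
class _SpectralPlan:
    """Calibrated per-span synthesis recipe for one subject.

    ``cross`` holds the full analytic cross-spectral cube of the pooled
    channels (pair x pair x frequency) implied by the calibrated
    components; its diagonal is the per-channel PSD.
    """

    freqs: np.ndarray  # calibration grid (epoch resolution)
    osc_power: dict  # (pool, band) -> oscillator power (uV^2, pool RMS)
    shared_power: dict  # (coupling, band) -> per-pool source power (uV^2)
    pool_bands: dict
    coupling_bands: dict
    cross: np.ndarray  # (12, 12, n_freqs) analytic cross-spectra
    pooled_channels: tuple

    def _pool_idx(self, pool):
        return [self.pooled_channels.index(c) for c in POOLS[pool]]

    def analytic_band_power(self, pool: str, band: str) -> float:
        """Pool-mean band power implied by the calibrated components."""
        bins = _band_bins(self.freqs, self.pool_bands[pool][band])
        df = self.freqs[1] - self.freqs[0]
        idx = self._pool_idx(pool)
        diag = self.cross[idx, idx, :]
        return float(diag[:, bins].sum(axis=1).mean() * df)

    def analytic_msc(self, coupling, band: str) -> float:
        """Band-averaged msc implied by the calibrated components."""
        a, b = coupling
        bins = _band_bins(self.freqs, self.coupling_bands[coupling][band])
        ia, ib = self._pool_idx(a), self._pool_idx(b)
        n = len(self.pooled_channels)
        diag = self.cross[np.arange(n), np.arange(n), :][:, bins]
        c = self.cross[np.ix_(ia, ib)][:, :, bins]
        denom = diag[ia][:, None, :] * diag[ib][None, :, :]
        return float((c**2 / np.maximum(denom, 1e-300)).mean())


def _band_bins(freqs, band):
    lo, hi = band
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def _source_support(freqs, band, margin=0.0):
    lo, hi = band
    return (freqs >= lo + margin - 1e-9) & (freqs <= hi - margin + 1e-9)


def _shared_gvec(maps, coupling, g2):
    """Per-channel gain vector of a shared source (the synthesis uses the
    same expression, so calibration and realization agree exactly)."""
    a, b = coupling
    return np.sqrt(g2[0]) * maps[a] + np.sqrt(g2[1]) * maps[b]


def _source_level(freqs, band_lims, margin=0.0):
    """Unit-power flat PSD on the source support inside a band.

    The source spans the whole band: leaving background-only margin bins
    inside the band would let the spatially correlated background dominate
    those bins and bias the band-averaged coherence upward.  The level
    uses the continuous band width so that calibration and synthesis
    grids see the same in-band PSD height.
    """
    support = _source_support(freqs, band_lims, margin)
    width = (band_lims[1] - margin) - (band_lims[0] + margin)
    level = np.zeros_like(freqs)
    if width > 0:
        level[support] = 1.0 / width
    return level


def _smooth_mixing(channels, positions, config: CohortConfig):
    """Fixed spatial mixing of the smooth background fields.

    Field centres are a deterministic subset of the electrode sites, so
    the spatial covariance of the background is identical for every
    subject; columns are normalized so each channel's background PSD is
    exactly the smooth share of the background spectrum.  Returns a
    ``(n_fields, n_channels)`` matrix.
    """
    pos = np.array([positions[c] for c in channels])
    centers = pos[
        np.linspace(0, len(channels) - 1, config.n_smooth_fields).astype(int)
    ]
    mix = np.exp(
        -np.sum((pos[None, :, :] - centers[:, None, :]) ** 2, axis=2)
        / (2 * config.smooth_field_width**2)
    )
    norms = np.sqrt((mix**2).sum(axis=0))
    return mix / np.maximum(norms, 1e-12)


def build_spectral_plan(
    truth: SubjectTruth, config: CohortConfig, channels, positions, span: str
) -> _SpectralPlan:
    """Solve oscillator powers and shared-source gains for one subject/span.

    The calibration tracks the full analytic cross-spectral cube of the
    pooled channels - background spatial correlation, oscillator scalp-map
    leakage and every shared source all contribute to the cross-spectra
    exactly as the synthesis realizes them.  It iterates between (a)
    setting each pool's oscillator power so that the pool-averaged band
    power equals the planted target and (b) root-finding each coupling's
    shared-source gain so the analytic band-averaged msc equals the
    planted coherence target.
    """
    channels = list(channels)
    pooled = tuple(c for pool in POOLS.values() for c in pool)
    pidx = [channels.index(c) for c in pooled]
    maps_full = _pool_maps(channels, positions, config.pool_map_width)
    maps = {pool: maps_full[pool][pidx] for pool in POOLS}
    mix = _smooth_mixing(channels, positions, config)[:, pidx]
    n = len(pooled)
    df = 1.0 / config.epoch_length
    freqs = np.arange(0.0, 40.0 + df / 2, df)  # analysis range is < 20 Hz
    pool_bands, coupling_bands = _truth_bands(truth)
    pool_idx = {p: [pooled.index(c) for c in POOLS[p]] for p in POOLS}
    diag_idx = np.arange(n)

    target_power = {
        (pool, band): truth.band_power_targets[(pool, band, span)]
        for pool in POOLS
        for band in BANDS
    }
    target_coh = {
        (coupling, band): truth.coherence_targets[(coupling, band, span)]
        for coupling in POOL_COUPLINGS
        for band in BANDS
    }

    # analytic cross-spectral cube, seeded with the fixed background:
    # smooth fields give off-diagonal structure, the independent share is
    # diagonal only
    bg_ind, bg_sm = _bg_split(freqs, config)
    cross = (mix.T @ mix)[:, :, None] * bg_sm
    cross[diag_idx, diag_idx, :] += bg_ind

    # each component contributes outer(alpha, alpha) x its spectral row;
    # rows are fixed, only the amplitude vectors change during calibration
    rows, alphas = {}, {}
    for pool in POOLS:
        apf = truth.apf(pool)
        for band, center, sigma in (
            ("alpha", apf, config.alpha_bump_sigma),
            ("theta", apf - 5.0, config.theta_bump_sigma),
        ):
            rows[("osc", pool, band)] = _gauss_bump(freqs, center, sigma)
            alphas[("osc", pool, band)] = np.zeros(n)
    for coupling in POOL_COUPLINGS:
        for band in BANDS:
            rows[("shared", coupling, band)] = _source_level(
                freqs, coupling_bands[coupling][band]
            )
            alphas[("shared", coupling, band)] = np.zeros(n)

    def _set(key, alpha):
        nonlocal cross
        old = alphas[key]
        cross += (np.outer(alpha, alpha) - np.outer(old, old))[:, :, None] * (
            rows[key]
        )
        alphas[key] = alpha

    def _diag():
        return cross[diag_idx, diag_idx, :]

    def _band_msc(coupling, band):
        a, b = coupling
        bins = _band_bins(freqs, coupling_bands[coupling][band])
        ia, ib = pool_idx[a], pool_idx[b]
        d = _diag()[:, bins]
        c = cross[np.ix_(ia, ib)][:, :, bins]
        denom = d[ia][:, None, :] * d[ib][None, :, :]
        return float((c**2 / np.maximum(denom, 1e-300)).mean())

    osc_power = {(pool, band): 0.0 for pool in POOLS for band in BANDS}
    shared_gain2 = {
        (coupling, band): np.zeros(2)
        for coupling in POOL_COUPLINGS
        for band in BANDS
    }

    relax = 0.6  # damped Gauss-Seidel; the plain iteration oscillates
    for iteration in range(40):
        # (a) oscillator powers: match pool-mean band power targets
        for pool in POOLS:
            for band in BANDS:
                key = ("osc", pool, band)
                _set(key, np.zeros(n))
                bins = _band_bins(freqs, pool_bands[pool][band])
                have = _diag()[pool_idx[pool]][:, bins].sum(axis=1).mean() * df
                need = target_power[(pool, band)] - have
                # pool-mean band power added per unit oscillator power
                unit = np.mean(
                    maps[pool][pool_idx[pool]] ** 2
                ) * rows[key][bins].sum() * df
                osc_power[(pool, band)] = max(need, 0.0) / unit
                _set(key, maps[pool] * np.sqrt(osc_power[(pool, band)]))

        # (b) shared-source gains: match band-averaged msc targets
        for coupling in POOL_COUPLINGS:
            a, b = coupling
            for band in BANDS:
                key = ("shared", coupling, band)
                band_lims = coupling_bands[coupling][band]
                ta = target_power[(a, band)]
                tb = target_power[(b, band)]
                target = target_coh[(coupling, band)]

                # cross-spectra of everything else at the band bins; the
                # objective adds the trial source on top
                _set(key, np.zeros(n))
                bins = _band_bins(freqs, band_lims)
                level_b = _source_level(freqs, band_lims)[bins]
                ia, ib = pool_idx[a], pool_idx[b]
                c_base = cross[np.ix_(ia, ib)][:, :, bins]
                d = _diag()[:, bins]
                pa_base, pb_base = d[ia], d[ib]
                ma, mb = maps[a], maps[b]

                def f(u, c_base=c_base, pa_base=pa_base, pb_base=pb_base,
                      level_b=level_b, ia=ia, ib=ib, ma=ma, mb=mb,
                      ta=ta, tb=tb, target=target):
                    gvec = np.sqrt(u * ta) * ma + np.sqrt(u * tb) * mb
                    ga, gb = gvec[ia], gvec[ib]
                    c = c_base + ga[:, None, None] * gb[None, :, None] * (
                        level_b
                    )
                    da = pa_base + (ga**2)[:, None] * level_b
                    db = pb_base + (gb**2)[:, None] * level_b
                    denom = da[:, None, :] * db[None, :, :]
                    return float(
                        (c**2 / np.maximum(denom, 1e-300)).mean()
                    ) - target

                if f(0.0) > 0:
                    raise ConfigurationError(
                        f"{coupling}/{band}/{span}: coherence target "
                        f"{target:.3f} lies below the floor induced by the "
                        "background spatial correlation and scalp-map "
                        "leakage; raise the target or decorrelate the "
                        "background"
                    )
                u_hi = 0.55
                if f(u_hi) < 0:
                    raise ConfigurationError(
                        f"{coupling}/{band}/{span}: coherence target "
                        f"{target:.3f} not realizable within the band power "
                        "budget"
                    )
                u = brentq(f, 0.0, u_hi, xtol=1e-4)
                g2 = (
                    relax * np.array([u * ta, u * tb])
                    + (1 - relax) * shared_gain2[(coupling, band)]
                )
                shared_gain2[(coupling, band)] = g2
                _set(key, _shared_gvec(maps, coupling, g2))

        # convergence check on the coupled system
        errs = [
            abs(_band_msc(coupling, band) - target_coh[(coupling, band)])
            for coupling in POOL_COUPLINGS
            for band in BANDS
        ]
        perrs = []
        for pool in POOLS:
            for band in BANDS:
                bins = _band_bins(freqs, pool_bands[pool][band])
                have = _diag()[pool_idx[pool]][:, bins].sum(axis=1).mean() * df
                perrs.append(
                    abs(have - target_power[(pool, band)])
                    / target_power[(pool, band)]
                )
        if max(errs) < 5e-4 and max(perrs) < 1e-3 and iteration >= 1:
            break
    else:
        raise ConfigurationError(
            f"{span}: band power and coherence targets jointly infeasible "
            f"(msc residual {max(errs):.2e}, power residual {max(perrs):.2e}); "
            "lower the coherence targets or raise the band power targets"
        )

    # a vanishing oscillator would leave no alpha peak to detect
    for pool in POOLS:
        if osc_power[(pool, "alpha")] <= 0:
            raise ConfigurationError(
                f"{pool}/alpha/{span}: no spectral room for the alpha "
                "oscillator; the planted peak would be undetectable"
            )

    return _SpectralPlan(
        freqs=freqs,
        osc_power=osc_power,
        shared_power=shared_gain2,
        pool_bands=pool_bands,
        coupling_bands=coupling_bands,
        cross=cross,
        pooled_channels=pooled,
    )


# ---------------------------------------------------------------------------
# Time-domain synthesis
# ---------------------------------------------------------------------------

def _realize(rng, magnitude):
    """Random-phase realization of rFFT coefficients with fixed magnitudes."""
    phases = np.exp(2j * np.pi * rng.random(magnitude.shape))
    coeff = magnitude * phases
    coeff[..., 0] = 0.0
    coeff[..., -1] = 0.0
    return coeff


def _coeff_magnitude(psd, n, fs):
    """|X_k| such that irfft yields a signal whose one-sided PSD is ``psd``."""
    return n * np.sqrt(np.maximum(psd, 0.0) * (fs / n) / 2.0)


def synthesize_eeg(
    truth: SubjectTruth,
    duration: float,
    fs: float,
    channels=DEFAULT_CHANNELS,
    positions=None,
    seed: int = 0,
    config: CohortConfig | None = None,
    span: str = "task",
) -> Recording:
    """Synthesize one multichannel recording realizing the subject's truth.

    Raises :class:`ConfigurationError` when the duration is shorter than one
    epoch or the montage lacks the pooled channels.
    """
    if config is None:
        config = CohortConfig()
    if duration < config.epoch_length:
        raise ConfigurationError(
            f"duration {duration} s shorter than one {config.epoch_length} s "
            "epoch"
        )
    channels = tuple(channels)
    if positions is None:
        positions = default_positions(channels)
    missing = [c for pool in POOLS.values() for c in pool if c not in channels]
    if missing:
        raise ConfigurationError(f"montage lacks pooled channels {missing}")

    plan = build_spectral_plan(truth, config, channels, positions, span)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    n_ch = len(channels)
    pos = np.array([positions[c] for c in channels])
    maps = _pool_maps(list(channels), positions, config.pool_map_width)

    coeffs = np.zeros((n_ch, len(f)), dtype=complex)

    # background: smooth spatial fields (fixed mixing, random phases)
    # plus a channel-independent share that carries the analysis bands
    bg_ind, bg_sm = _bg_split(f, config)
    mix = _smooth_mixing(channels, positions, config)
    smooth_mag = _coeff_magnitude(bg_sm, n, fs)
    for m in range(config.n_smooth_fields):
        coeffs += np.outer(mix[m], _realize(rng, smooth_mag))
    sensor_mag = _coeff_magnitude(bg_ind, n, fs)
    for ch in range(n_ch):
        coeffs[ch] += _realize(rng, sensor_mag)

    # pool oscillators
    for pool in POOLS:
        apf = truth.apf(pool)
        for band, center, sigma in (
            ("alpha", apf, config.alpha_bump_sigma),
            ("theta", apf - 5.0, config.theta_bump_sigma),
        ):
            p = plan.osc_power[(pool, band)]
            mag = _coeff_magnitude(p * _gauss_bump(f, center, sigma), n, fs)
            coeffs += np.outer(maps[pool], _realize(rng, mag))

    # shared sources per coupling and band
    for (coupling, band), g2 in plan.shared_power.items():
        level = _source_level(f, plan.coupling_bands[coupling][band])
        if not level.any():
            continue
        src = _realize(rng, _coeff_magnitude(level, n, fs))
        coeffs += np.outer(_shared_gvec(maps, coupling, g2), src)

    data = np.fft.irfft(coeffs, n=n, axis=1)
    return Recording(
        data=data, fs=fs, channels=channels, positions=positions, stage="raw"
    )


def synthesize_coherent_pair(
    gamma: float,
    n_epochs: int,
    fs: float = 256.0,
    epoch_length: float = 5.0,
    seed: int = 0,
    source_band=(6.0, 14.0),
):
    """Two-channel harness with a closed-form coherence oracle.

    Both channels are unit-level white noise plus a shared band-limited
    source whose in-band PSD is ``gamma`` times the noise PSD, so the
    magnitude-squared coherence inside ``source_band`` is analytically
    ``(gamma / (1 + gamma))**2``.  Returns ``(data, fs)`` with data shaped
    ``(2, n_samples)``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(n_epochs * epoch_length * fs))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    noise_level = 2.0 / fs  # one-sided PSD of unit-variance white noise
    support = (f >= source_band[0]) & (f <= source_band[1])
    psd = np.zeros_like(f)
    psd[support] = gamma * noise_level
    src = np.fft.irfft(_realize(rng, _coeff_magnitude(psd, n, fs)), n=n)
    x = rng.standard_normal(n) + src
    y = rng.standard_normal(n) + src
    return np.vstack([x, y]), fs


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def _blink_weights(channels, positions):
    """Frontal-dominant spatial pattern: 1 at the front, 0.1 at the back."""
    y = np.array([positions[c][1] for c in channels])
    w = (y - y.min()) / max(y.max() - y.min(), 1e-12)
    return 0.1 + 0.9 * w**2


def plant_artifacts(
    rec: Recording,
    blink_epochs=(),
    amplitude_epochs=(),
    seed: int = 0,
    epoch_length: float = 5.0,
    blink_amplitude: float = 350.0,
    artifact_amplitude: float = 400.0,
):
    """Insert stereotyped artifacts into listed epochs; returns a new
    recording and the ledger ``[(epoch_index, kind), ...]``.

    Blinks are 300-ms raised-cosine transients with a frontal-dominant
    spatial pattern (two per epoch).  Amplitude artifacts are focal 0.5-s
    half-sine transients on a single pooled channel, sized to exceed the
    post-Laplacian 500 uV/m^2 rejection threshold in exactly the listed
    epochs.  Overlapping epoch lists raise ``ValueError``.
    """
    blink_epochs = sorted(int(e) for e in blink_epochs)
    amplitude_epochs = sorted(int(e) for e in amplitude_epochs)
    overlap = set(blink_epochs) & set(amplitude_epochs)
    if overlap:
        raise ValueError(f"overlapping artifact epochs: {sorted(overlap)}")
    n_epochs = int(rec.n_samples / (epoch_length * rec.fs))
    for e in blink_epochs + amplitude_epochs:
        if not 0 <= e < n_epochs:
            raise ValueError(f"epoch index {e} outside recording ({n_epochs})")
    if not blink_epochs and not amplitude_epochs:
        return rec.copy(), []

    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    ep_samp = int(round(epoch_length * rec.fs))
    blink_len = int(round(0.3 * rec.fs))
    blink_shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(blink_len) / blink_len))
    weights = _blink_weights(rec.channels, rec.positions)

    # transients stay clear of epoch edges: the 0.3 Hz zero-phase high-pass
    # has second-scale tails that would otherwise leak into neighbours
    margin = int(round(1.0 * rec.fs))

    ledger = []
    for e in blink_epochs:
        for _ in range(2):
            lo = e * ep_samp + margin
            hi = (e + 1) * ep_samp - margin - blink_len
            t0 = rng.integers(lo, max(hi, lo + 1))
            data[:, t0:t0 + blink_len] += np.outer(
                weights * blink_amplitude, blink_shape
            )
        ledger.append((e, "blink"))

    art_len = int(round(0.5 * rec.fs))
    # biphasic (zero-mean) pulse: negligible sub-0.3 Hz content
    art_shape = np.sin(2 * np.pi * np.arange(art_len) / art_len)
    pooled = [c for pool in POOLS.values() for c in pool if c in rec.channels]
    for k, e in enumerate(amplitude_epochs):
        ch = rec.index(pooled[k % len(pooled)])
        lo = e * ep_samp + margin
        hi = (e + 1) * ep_samp - margin - art_len
        t0 = rng.integers(lo, max(hi, lo + 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[ch, t0:t0 + art_len] += sign * artifact_amplitude * art_shape
        ledger.append((e, "amplitude"))

    out = rec.copy(data=data)
    return out, sorted(ledger)


# ---------------------------------------------------------------------------
# WCST agent
# ---------------------------------------------------------------------------

def _sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def agent_rates_from_skill(skill: float, config: CohortConfig | None = None):
    """Map latent skill to agent parameters by logistic links.

    Returns ``(learn_prob, perseveration_rate, distraction_rate)``.
    """
    if config is None:
        config = CohortConfig()
    learn = _sigmoid(config.learn_intercept + config.learn_slope * skill)
    persev = _sigmoid(config.persev_intercept - config.persev_slope * skill)
    distraction = _sigmoid(
        config.distraction_intercept - config.distraction_slope * skill
    )
    return float(learn), float(persev), float(distraction)


def simulate_wcst_agent(
    skill: float,
    perseveration_rate: float,
    distraction_rate: float,
    seed: int = 0,
    subject_id: str = "",
    learn_prob: float | None = None,
) -> TrialLog:
    """Simulate one subject performing the card-sorting task.

    ``skill`` sets the probability of inferring the active rule per trial
    (through a logistic link; ``numpy.inf`` gives an oracle that always
    knows the rule).  ``perseveration_rate`` is the probability of
    repeating the pre-shift rule while searching; ``distraction_rate`` the
    probability of an off-rule lapse after the rule has been acquired.
    """
    for name, rate in (
        ("perseveration_rate", perseveration_rate),
        ("distraction_rate", distraction_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if learn_prob is None:
        learn_prob = float(_sigmoid(0.8 + 1.6 * skill)) if np.isfinite(
            skill
        ) else 1.0
    rng = np.random.default_rng(seed)

    rule_idx = 0
    prev_rule = None
    acquired = False
    run = 0
    completed = 0
    records = []

    for trial in range(1, 129):
        rule = RULES[rule_idx]
        card = {cat: int(rng.integers(1, 5)) for cat in RULES}
        correct_deck = card[rule]

        if acquired:
            if rng.random() < distraction_rate:
                others = [d for d in range(1, 5) if d != correct_deck]
                choice = int(others[rng.integers(0, 3)])
            else:
                choice = correct_deck
        else:
            if prev_rule is not None and rng.random() < perseveration_rate:
                choice = card[prev_rule]
            elif rng.random() < learn_prob:
                choice = correct_deck
            else:
                choice = int(rng.integers(1, 5))

        matched = frozenset(cat for cat in RULES if card[cat] == choice)
        correct = rule in matched
        records.append(
            TrialRecord(
                trial=trial,
                rule=rule,
                choice=choice,
                matched=matched,
                correct=correct,
            )
        )

        if correct:
            acquired = True
            run += 1
            if run == RUN_LENGTH:
                completed += 1
                if completed == 9:
                    break
                prev_rule = rule
                rule_idx = (rule_idx + 1) % 3
                acquired = False
                run = 0
        else:
            run = 0

    return TrialLog(records=records, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def iter_cohort(config: CohortConfig):
    """Yield :class:`CohortSubject` one at a time (memory-friendly)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths = draw_subject_truths(config, rng)
    positions = default_positions(config.channels)
    n_task_epochs = int(config.task_duration / config.epoch_length)
    seeds = np.random.SeedSequence(config.seed).spawn(len(truths))

    for truth, seed_seq in zip(truths, seeds):
        sub_rng = np.random.default_rng(seed_seq)
        s_task, s_base, s_art, s_beh = sub_rng.integers(0, 2**31 - 1, 4)
        rec_task = synthesize_eeg(
            truth, config.task_duration, config.fs, config.channels,
            positions, seed=int(s_task), config=config, span="task",
        )
        rec_base = synthesize_eeg(
            truth, config.baseline_duration, config.fs, config.channels,
            positions, seed=int(s_base), config=config, span="baseline",
        )
        n_art = config.n_blink_epochs + config.n_amplitude_epochs
        if n_art > 0 and n_art <= n_task_epochs:
            chosen = sub_rng.choice(n_task_epochs, size=n_art, replace=False)
            blink = chosen[: config.n_blink_epochs]
            ampl = chosen[config.n_blink_epochs:]
            rec_task, ledger = plant_artifacts(
                rec_task,
                blink_epochs=blink,
                amplitude_epochs=ampl,
                seed=int(s_art),
                epoch_length=config.epoch_length,
                blink_amplitude=config.blink_amplitude,
                artifact_amplitude=config.artifact_amplitude,
            )
            truth.artifact_ledger = ledger
        learn, persev, distraction = agent_rates_from_skill(
            truth.latent_skill, config
        )
        log = simulate_wcst_agent(
            truth.latent_skill,
            persev,
            distraction,
            seed=int(s_beh),
            subject_id=truth.subject_id,
            learn_prob=learn,
        )
        yield CohortSubject(
            truth=truth,
            recording_task=rec_task,
            recording_baseline=rec_base,
            trial_log=log,
        )


def generate_cohort(config: CohortConfig) -> list:
    """Generate the full cohort as a list (see :func:`iter_cohort`)."""
    return list(iter_cohort(config))
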