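"""Synthetic cohort generator: determinism, planted structure, oracles."""

import dataclasses

import numpy as np
import pytest

from eegwcst.recording import POOL_COUPLINGS, POOLS
from eegwcst.spectral import estimate_spectra, pool_coherence
from eegwcst.synthdata import (
    CohortConfig,
    ConfigurationError,
    build_spectral_plan,
    draw_subject_truths,
    iter_cohort,
    plant_artifacts,
    synthesize_coherent_pair,
    synthesize_eeg,
)
from eegwcst.preprocess import segment
from eegwcst.validation import _epochs_from_array


class TestCohortStructure:
    def test_age_skill_correlation_matches_target(self):
        config = CohortConfig(n_subjects=60, seed=7)
        truths = draw_subject_truths(config)
        ages = np.array([t.age for t in truths])
        skill = np.array([t.latent_skill for t in truths])
        r = np.corrcoef(ages, skill)[0, 1]
        assert -0.72 <= r <= -0.52  # within 0.1 of the -0.62 target

    def test_constant_ages_leave_correlation_undefined(self):
        config = CohortConfig(
            n_subjects=3,
            age_groups=((30, 31),),
            age_group_names=("only",),
            age_proportions=(1.0,),
        )
        rng = np.random.default_rng(0)
        truths = draw_subject_truths(config, rng)
        ages = np.array([t.age for t in truths])
        if ages.std() == 0:  # all equal: r is reported as missing
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(ages, [t.latent_skill for t in truths])[0, 1]
            assert np.isnan(r)

    def test_truth_invariants(self):
        truths = draw_subject_truths(CohortConfig(n_subjects=30, seed=3))
        for t in truths:
            assert 8.0 <= t.apf_left <= 13.0
            assert 8.0 <= t.apf_right <= 13.0
            for v in t.coherence_targets.values():
                assert 0.0 <= v <= 1.0
            for v in t.band_power_targets.values():
                assert v > 0

    def test_invalid_configs_raise(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_subjects=2).validate()
        with pytest.raises(ConfigurationError):
            CohortConfig(age_groups=((40, 30), (51, 64), (67, 82))).validate()
        with pytest.raises(ConfigurationError):
            CohortConfig(task_duration=-5.0).validate()
        with pytest.raises(ConfigurationError):
            CohortConfig(skill_age_correlation=0.4).validate()

    def test_generation_is_deterministic(self, channels):
        config = CohortConfig(
            n_subjects=3, seed=9, fs=256.0, task_duration=30.0,
            channels=channels, n_blink_epochs=1, n_amplitude_epochs=1,
        )
        a = list(iter_cohort(config))
        b = list(iter_cohort(config))
        for sa, sb in zip(a, b):
            assert np.array_equal(
                sa.recording_task.data, sb.recording_task.data
            )
            assert sa.trial_log.records == sb.trial_log.records
            assert sa.truth.artifact_ledger == sb.truth.artifact_ledger


class TestSpectralPlanting:
    def test_analytic_coherence_and_power_match_targets(
        self, clean_config, positions
    ):
        """The calibrated plan realizes every coherence and band-power
        target analytically (full cross-spectral accounting)."""
        truth = draw_subject_truths(clean_config)[0]
        plan = build_spectral_plan(
            truth, clean_config, clean_config.channels, positions, "task"
        )
        for coupling in POOL_COUPLINGS:
            for band in ("theta", "alpha"):
                got = plan.analytic_msc(coupling, band)
                want = truth.coherence_targets[(coupling, band, "task")]
                assert got == pytest.approx(want, abs=1e-3)
        for pool in POOLS:
            for band in ("theta", "alpha"):
                got = plan.analytic_band_power(pool, band)
                want = truth.band_power_targets[(pool, band, "task")]
                assert got == pytest.approx(want, rel=2e-3)

    def test_band_power_calibration_within_ten_percent(
        self, clean_config, positions
    ):
        """Pool band power measured on clean synthetic data hits the
        planted targets within 10% at 60 epochs."""
        truth = draw_subject_truths(clean_config)[0]
        rec = synthesize_eeg(
            truth, 300.0, clean_config.fs, clean_config.channels,
            positions, seed=5, config=clean_config,
        )
        eps = segment(rec)
        spec = estimate_spectra(eps, [c for p in POOLS.values() for c in p])
        from eegwcst.spectral import band_power

        for pool in POOLS:
            apf = truth.apf(pool)
            for band, lims in (
                ("alpha", (apf - 2, apf + 2)),
                ("theta", (apf - 7, apf - 3)),
            ):
                est = band_power(spec, POOLS[pool], lims)
                want = truth.band_power_targets[(pool, band, "task")]
                assert est == pytest.approx(want, rel=0.10)

    def test_planted_alpha_peak_location(self, positions, clean_config):
        truth = draw_subject_truths(clean_config)[0]
        truth.apf_left = truth.apf_right = 9.4
        rec = synthesize_eeg(
            truth, 300.0, 256.0, clean_config.channels, positions,
            seed=2, config=clean_config,
        )
        spec = estimate_spectra(
            segment(rec), [c for p in POOLS.values() for c in p]
        )
        win = (spec.freqs >= 8) & (spec.freqs <= 13)
        for pool in POOLS:
            idx = [spec.channels.index(c) for c in POOLS[pool]]
            pool_psd = spec.psd[idx].mean(axis=0)
            peak = spec.freqs[win][np.argmax(pool_psd[win])]
            assert abs(peak - 9.4) <= 0.2

    def test_cohort_coherence_estimate_tracks_target(
        self, clean_config, positions
    ):
        """Pipeline msc on long clean recordings approaches the planted
        band-averaged coherence target."""
        truth = draw_subject_truths(clean_config)[0]
        rec = synthesize_eeg(
            truth, 600.0, 256.0, clean_config.channels, positions,
            seed=8, config=clean_config,
        )
        spec = estimate_spectra(
            segment(rec), [c for p in POOLS.values() for c in p]
        )
        apf = 0.5 * (truth.apf_left + truth.apf_right)
        est = pool_coherence(
            spec, POOLS["FL"], POOLS["PR"], (apf - 2, apf + 2)
        )
        want = truth.coherence_targets[(("FL", "PR"), "alpha", "task")]
        assert est == pytest.approx(want, abs=0.03)

    def test_duration_shorter_than_one_epoch_raises(
        self, clean_config, positions
    ):
        truth = draw_subject_truths(clean_config)[0]
        with pytest.raises(ConfigurationError, match="epoch"):
            synthesize_eeg(
                truth, 3.0, 256.0, clean_config.channels, positions,
                seed=0, config=clean_config,
            )


class TestCoherentPair:
    def test_independent_channels_have_near_zero_coherence(self):
        data, fs = synthesize_coherent_pair(0.0, n_epochs=200, seed=4)
        spec = estimate_spectra(_epochs_from_array(data, fs))
        assert pool_coherence(spec, ("A",), ("B",), (8, 12)) <= 0.05

    def test_unit_snr_gives_quarter_coherence(self):
        data, fs = synthesize_coherent_pair(1.0, n_epochs=200, seed=4)
        spec = estimate_spectra(_epochs_from_array(data, fs))
        est = pool_coherence(spec, ("A",), ("B",), (8, 12))
        assert est == pytest.approx(0.25, abs=0.03)


@pytest.fixture(scope="module")
def base_recording(clean_config, positions):
    truth = draw_subject_truths(clean_config)[0]
    return synthesize_eeg(
        truth, 60.0, 256.0, clean_config.channels, positions,
        seed=3, config=clean_config,
    )


class TestArtifacts:

    def test_empty_lists_leave_recording_unchanged(self, base_recording):
        out, ledger = plant_artifacts(base_recording)
        assert ledger == []
        assert np.array_equal(out.data, base_recording.data)

    def test_overlapping_epochs_raise(self, base_recording):
        with pytest.raises(ValueError, match="overlap"):
            plant_artifacts(
                base_recording, blink_epochs=[2], amplitude_epochs=[2]
            )

    def test_out_of_range_epoch_raises(self, base_recording):
        with pytest.raises(ValueError, match="outside"):
            plant_artifacts(base_recording, blink_epochs=[40])

    def test_blink_raises_frontal_low_band_variance_only(
        self, base_recording
    ):
        out, _ = plant_artifacts(base_recording, blink_epochs=[3], seed=1)
        fs = base_recording.fs
        ep = int(5 * fs)
        sl = slice(3 * ep, 4 * ep)

        def band_var(rec, chans, lo, hi):
            idx = [rec.index(c) for c in chans]
            seg = rec.data[idx, sl]
            spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2
            freqs = np.fft.rfftfreq(seg.shape[1], 1 / fs)
            return spec[:, (freqs >= lo) & (freqs < hi)].sum()

        frontal = ("Fp1", "Fp2", "F3", "F4")
        parietal = POOLS["PL"] + POOLS["PR"]
        # blinks are slow frontal transients: frontal low-band variance
        # jumps while the parietal alpha band stays untouched
        assert band_var(out, frontal, 0, 5) > 5 * band_var(
            base_recording, frontal, 0, 5
        )
        assert band_var(out, parietal, 8, 12) == pytest.approx(
            band_var(base_recording, parietal, 8, 12), rel=0.05
        )

    def test_ledger_lists_planted_epochs(self, base_recording):
        out, ledger = plant_artifacts(
            base_recording, blink_epochs=[1, 4], amplitude_epochs=[7],
            seed=2,
        )
        assert ledger == [(1, "blink"), (4, "blink"), (7, "amplitude")]


class TestConfigFeasibility:
    def test_unrealizable_coherence_target_raises(
        self, clean_config, positions
    ):
        config = dataclasses.replace(
            clean_config,
            coherence_base=0.5,
            coherence_bounds=(0.4, 0.9),
        )
        truth = draw_subject_truths(config)[0]
        with pytest.raises(ConfigurationError):
            build_spectral_plan(
                truth, config, config.channels, positions, "task"
            )
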