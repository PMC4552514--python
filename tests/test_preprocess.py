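"""Filtering, ocular correction, surface Laplacian, epoching, rejection."""

import numpy as np
import pytest

from eegwcst.preprocess import (
    PreprocessError,
    apply_csd,
    bandpass_filter,
    notch_filter,
    reject_epochs,
    remove_ocular,
    segment,
)
from eegwcst.recording import EpochSet, Recording
from eegwcst.synthdata import plant_artifacts


FS = 1024.0


def _sine_recording(freq, channels, positions, fs=FS, duration=20.0,
                    amplitude=1.0, stage="raw"):
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t),
                   (len(channels), 1))
    return Recording(data=data, fs=fs, channels=channels,
                     positions=positions, stage=stage)


def _mid_amplitude(rec):
    """Peak amplitude in the middle half (away from filter edge effects)."""
    n = rec.n_samples
    return np.abs(rec.data[0, n // 4: 3 * n // 4]).max()


class TestBandpass:
    def test_slow_drift_attenuated_40_db(self, channels, positions):
        rec = _sine_recording(0.05, channels, positions, duration=80.0)
        out = bandpass_filter(rec)
        assert _mid_amplitude(out) < 10 ** (-40 / 20)

    def test_passband_identity_at_10_hz(self, channels, positions):
        # long recording so the 0.3 Hz high-pass startup transient has
        # fully decayed inside the measured middle half
        rec = _sine_recording(10.0, channels, positions, duration=60.0)
        out = bandpass_filter(rec)
        assert _mid_amplitude(out) == pytest.approx(1.0, rel=0.01)
        # zero phase: cross-correlation peak at zero lag
        mid = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        assert np.corrcoef(rec.data[0, mid], out.data[0, mid])[0, 1] > 0.9999

    def test_impulse_response_has_no_group_delay(self, channels, positions):
        data = np.zeros((len(channels), int(4 * FS)))
        data[:, int(2 * FS)] = 1.0
        rec = Recording(data=data, fs=FS, channels=channels,
                        positions=positions)
        out = bandpass_filter(rec)
        assert np.argmax(np.abs(out.data[0])) == int(2 * FS)

    def test_low_sampling_rate_rejected(self, channels, positions):
        rec = _sine_recording(10.0, channels, positions, fs=128.0)
        with pytest.raises(PreprocessError, match="sampling rate"):
            bandpass_filter(rec)

    def test_linearity(self, channels, positions, rng):
        a = rng.standard_normal((len(channels), int(10 * FS)))
        b = rng.standard_normal((len(channels), int(10 * FS)))
        mk = lambda d: Recording(data=d, fs=FS, channels=channels,
                                 positions=positions)
        fa = bandpass_filter(mk(a)).data
        fb = bandpass_filter(mk(b)).data
        fab = bandpass_filter(mk(a + b)).data
        assert np.allclose(fab, fa + fb, rtol=1e-8, atol=1e-8)


class TestNotch:
    def test_mains_component_removed(self, channels, positions):
        rec = _sine_recording(50.0, channels, positions, stage="raw")
        out = notch_filter(rec)
        assert _mid_amplitude(out) <= 0.03

    def test_neighbouring_frequencies_preserved(self, channels, positions):
        for freq in (45.0, 55.0):
            rec = _sine_recording(freq, channels, positions)
            out = notch_filter(rec)
            assert _mid_amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_out_of_notch_identity_at_10_hz(self, channels, positions):
        rec = _sine_recording(10.0, channels, positions)
        out = notch_filter(rec)
        assert _mid_amplitude(out) == pytest.approx(1.0, rel=0.01)

    def test_dc_unchanged(self, channels, positions):
        data = np.full((len(channels), int(10 * FS)), 3.0)
        rec = Recording(data=data, fs=FS, channels=channels,
                        positions=positions)
        out = notch_filter(rec)
        assert np.allclose(out.data, 3.0, atol=1e-6)


class TestOcular:
    def test_planted_blinks_removed_and_alpha_preserved(self):
        from eegwcst.validation import blink_correction

        result = blink_correction(seed=3)
        assert result.n_flagged >= 1
        assert result.frontal_variance_reduction >= 0.90
        assert result.parietal_alpha_change <= 0.10

    def test_no_blinks_means_no_flagged_components(
        self, clean_subject
    ):
        _, rec = clean_subject
        filtered = notch_filter(bandpass_filter(rec))
        out, report = remove_ocular(filtered, seed=0)
        assert report.flagged == []
        assert np.array_equal(out.data, filtered.data)
        assert out.stage == "ocular_corrected"

    def test_requires_filtered_stage(self, clean_subject):
        _, rec = clean_subject
        with pytest.raises(PreprocessError, match="stage"):
            remove_ocular(rec, seed=0)


class TestCSD:
    def _as_corrected(self, data, channels, positions, fs=256.0):
        return Recording(data=data, fs=fs, channels=channels,
                         positions=positions, stage="ocular_corrected")

    def test_spatially_uniform_input_maps_to_zero(self, channels, positions):
        rng = np.random.default_rng(0)
        common = rng.standard_normal(512)
        data = np.tile(common, (len(channels), 1))
        out = apply_csd(self._as_corrected(data, channels, positions))
        assert np.abs(out.data).max() < 1e-6 * np.abs(common).max()

    def test_linearity(self, channels, positions):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((len(channels), 512))
        one = apply_csd(self._as_corrected(data, channels, positions))
        two = apply_csd(self._as_corrected(2 * data, channels, positions))
        assert np.allclose(two.data, 2 * one.data, rtol=1e-10, atol=1e-10)

    def test_focal_source_maximal_at_source_with_inverted_ring(
        self, channels, positions
    ):
        data = np.zeros((len(channels), 64))
        i = channels.index("Cz")
        data[i] = 10.0
        out = apply_csd(self._as_corrected(data, channels, positions))
        snapshot = out.data[:, 32]
        assert np.argmax(np.abs(snapshot)) == i
        neighbours = [channels.index(c)
                      for c in ("FC1", "FC2", "CP1", "CP2")]
        # qualitative surround inversion: the neighbouring ring carries
        # net opposite sign to the source
        assert np.sign(np.mean(snapshot[neighbours])) == -np.sign(snapshot[i])

    def test_units_and_stage(self, channels, positions):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((len(channels), 256))
        out = apply_csd(self._as_corrected(data, channels, positions))
        assert out.stage == "csd"
        assert out.units == "uV/m^2"


class TestSegment:
    def test_thirty_second_baseline_gives_six_epochs(
        self, channels, positions
    ):
        rng = np.random.default_rng(0)
        rec = Recording(
            data=rng.standard_normal((len(channels), int(30 * 1024))),
            fs=1024.0, channels=channels, positions=positions,
        )
        eps = segment(rec)
        assert eps.n_epochs == 6
        assert eps.epochs.shape[2] == 5120

    def test_trailing_partial_epoch_discarded(self, channels, positions):
        rec = Recording(
            data=np.zeros((len(channels), int(12 * 256))), fs=256.0,
            channels=channels, positions=positions,
        )
        assert segment(rec).n_epochs == 2

    def test_too_short_recording_raises(self, channels, positions):
        rec = Recording(
            data=np.zeros((len(channels), int(4 * 256))), fs=256.0,
            channels=channels, positions=positions,
        )
        with pytest.raises(ValueError, match="shorter"):
            segment(rec)

    def test_span_outside_recording_raises(self, channels, positions):
        rec = Recording(
            data=np.zeros((len(channels), int(10 * 256))), fs=256.0,
            channels=channels, positions=positions,
        )
        with pytest.raises(ValueError, match="outside"):
            segment(rec, start=0.0, stop=20.0)


def _epochset(arrays, channels, fs=256.0):
    epochs = np.stack(arrays)
    return EpochSet(
        epochs=epochs, fs=fs, channels=channels, epoch_length=5.0,
        accepted=np.ones(len(arrays), dtype=bool),
        rejection_reason=["none"] * len(arrays),
        stage="csd", units="uV/m^2",
    )


class TestRejection:
    @pytest.fixture()
    def epochs(self, channels):
        n_t = int(5 * 256)
        quiet = np.zeros((len(channels), n_t))
        spike = quiet.copy()
        spike[channels.index("F3"), 100] = 600.0  # amplitude breach
        swing = quiet.copy()
        i = channels.index("P4")
        swing[i, 200] = 420.0
        swing[i, 300] = -450.0  # range 870, |max| below 500
        return _epochset([quiet, spike, swing], channels)

    def test_default_thresholds_and_reasons(self, epochs):
        out = reject_epochs(epochs)
        assert list(out.accepted) == [True, False, False]
        assert out.rejection_reason == ["none", "amplitude", "peak_to_peak"]

    def test_all_zero_epoch_accepted(self, epochs):
        out = reject_epochs(epochs)
        assert out.accepted[0]

    def test_rejection_monotone_in_thresholds(self, epochs):
        base = reject_epochs(epochs)
        looser = reject_epochs(
            epochs, amplitude_threshold=700.0, ptp_threshold=1000.0
        )
        # raising thresholds never rejects more epochs
        assert (~base.accepted).sum() >= (~looser.accepted).sum()
        assert all(
            base.accepted[e] <= looser.accepted[e]
            for e in range(epochs.n_epochs)
        )

    def test_non_analysis_channels_ignored(self, channels):
        n_t = int(5 * 256)
        data = np.zeros((len(channels), n_t))
        data[channels.index("Fp1"), 50] = 900.0  # Fp1 is not pooled
        out = reject_epochs(_epochset([data], channels))
        assert out.accepted[0]


class TestPipelineOrder:
    def test_clean_recording_keeps_all_epochs(self, clean_subject):
        from eegwcst.preprocess import preprocess_recording

        _, rec = clean_subject
        eps, report = preprocess_recording(rec, seed=0, ocular=True)
        assert eps.n_epochs == 12
        assert eps.accepted.all()

    def test_planted_amplitude_ledger_recovered(self, clean_subject):
        from eegwcst.preprocess import preprocess_recording

        _, rec = clean_subject
        dirty, ledger = plant_artifacts(
            rec, amplitude_epochs=[2, 9], seed=5
        )
        eps, _ = preprocess_recording(dirty, seed=0, ocular=True)
        rejected = {e for e in range(eps.n_epochs) if not eps.accepted[e]}
        assert rejected == {2, 9}

    def test_stage_order_enforced(self, clean_subject):
        _, rec = clean_subject
        with pytest.raises(PreprocessError, match="stage"):
            apply_csd(rec)  # raw recording cannot jump to the Laplacian
        with pytest.raises(PreprocessError):
            bandpass_filter(bandpass_filter(rec))
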