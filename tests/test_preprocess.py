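"""Cleaning chain and preictal/interictal labeling rules."""

import numpy as np
import pytest
from scipy import signal as sig

from preictal import (
    EpochLabel,
    PreprocessConfig,
    Recording,
    bandpass,
    label_and_epoch,
    notch,
    remove_baseline,
)
from preictal.io_eeg import Annotation
from preictal.preprocess import ConfigError

from conftest import make_recording, seizure


def tone(freq, fs=256.0, duration=4.0, amp=10.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def as_rec(x, fs=256.0):
    return Recording(np.atleast_2d(x), fs, ["EEG0"])


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBaseline:
    def test_mean_subtraction(self):
        rec = as_rec(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(remove_baseline(rec).data[0], [-1, 0, 1])

    def test_idempotent_on_zero_mean(self):
        rec = as_rec(np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(remove_baseline(rec).data, rec.data)

    def test_constant_channel_goes_to_zero(self):
        rec = as_rec(np.array([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(remove_baseline(rec).data, 0.0)


class TestBandpass:
    def setup_method(self):
        self.cfg = PreprocessConfig()

    def _predicted_gain(self, freq, fs=256.0):
        # analytic magnitude of the designed filter, squared because the
        # zero-phase application runs it forward and backward
        sos = sig.butter(self.cfg.butter_order,
                         [self.cfg.bandpass_low, self.cfg.bandpass_high],
                         btype="bandpass", fs=fs, output="sos")
        _, h = sig.sosfreqz(sos, worN=[freq], fs=fs)
        return float(np.abs(h[0]) ** 2)

    def test_stopband_tone_attenuated(self):
        x = tone(100.0, duration=8.0)
        out = bandpass(as_rec(x), self.cfg).data[0]
        assert self._predicted_gain(100.0) < 0.05
        interior = slice(256, -256)  # steady state, past edge transients
        assert rms(out[interior]) < 0.05 * rms(x[interior])

    def test_passband_tone_preserved(self):
        x = tone(10.0)
        out = bandpass(as_rec(x), self.cfg).data[0]
        assert abs(self._predicted_gain(10.0) - 1.0) < 0.01
        interior = slice(256, -256)  # skip filter edge transients
        assert abs(rms(out[interior]) / rms(x[interior]) - 1.0) < 0.05

    def test_zero_in_zero_out(self):
        out = bandpass(as_rec(np.zeros(1024)), self.cfg).data
        np.testing.assert_allclose(out, 0.0)

    def test_linearity(self, rng):
        x, y = rng.standard_normal(1024), rng.standard_normal(1024)
        a, b = 2.5, -1.25
        lhs = bandpass(as_rec(a * x + b * y), self.cfg).data
        rhs = (a * bandpass(as_rec(x), self.cfg).data
               + b * bandpass(as_rec(y), self.cfg).data)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_cutoff_at_nyquist_rejected(self):
        cfg = PreprocessConfig(bandpass_high=130.0)
        with pytest.raises(ConfigError):
            bandpass(as_rec(np.zeros(100)), cfg)


class TestNotch:
    def test_mains_tone_suppressed(self):
        x = tone(50.0)
        out = notch(as_rec(x), 50.0).data[0]
        assert rms(out) <= 0.10 * rms(x)

    def test_neighbor_tone_untouched(self):
        x = tone(10.0)
        out = notch(as_rec(x), 50.0).data[0]
        interior = slice(256, -256)
        assert abs(rms(out[interior]) / rms(x[interior]) - 1.0) < 0.01

    def test_none_is_identity(self):
        rec = as_rec(tone(50.0))
        assert notch(rec, None) is rec

    def test_notch_at_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            notch(as_rec(np.zeros(100)), 128.0)


class TestLabelAndEpoch:
    def test_preictal_window_before_onset(self):
        rec = make_recording(n_channels=1, fs=32.0, duration_s=600.0,
                             annotations=[seizure(500.0)])
        cfg = PreprocessConfig(preictal_minutes=5.0, epoch_seconds=5.0)
        eps = label_and_epoch(rec, cfg)
        pre = [e for e in eps if e.label == EpochLabel.PREICTAL]
        inter = [e for e in eps if e.label == EpochLabel.INTERICTAL]
        assert len(pre) == 60
        assert min(e.t_start for e in pre) == 200.0
        assert max(e.t_start for e in pre) == 495.0
        assert inter == []  # 4-h gap rule cannot be met in 600 s

    def test_no_annotations_all_unlabeled(self):
        rec = make_recording(n_channels=1, fs=32.0, duration_s=60.0)
        eps = label_and_epoch(rec, PreprocessConfig())
        assert len(eps) == 12
        assert all(e.label == EpochLabel.UNLABELED for e in eps)

    def test_close_seizure_skipped_as_target(self):
        # second onset 20 min after the first: below the 30-min rule, so
        # it contributes no preictal epochs
        rec = make_recording(n_channels=1, fs=32.0, duration_s=3000.0,
                             annotations=[seizure(1500.0), seizure(2700.0)])
        cfg = PreprocessConfig(preictal_minutes=5.0)
        eps = label_and_epoch(rec, cfg)
        groups = {e.group for e in eps if e.label == EpochLabel.PREICTAL}
        assert groups == {0}

    def test_interictal_requires_distance_from_onset_and_offset(self):
        rec = make_recording(
            n_channels=1, fs=32.0, duration_s=2000.0,
            annotations=[Annotation(900.0, 60.0, "seizure")],
        )
        cfg = PreprocessConfig(preictal_minutes=1.0,
                               interictal_gap_hours=0.1)  # 360 s
        eps = label_and_epoch(rec, cfg)
        inter_t = [e.t_start for e in eps if e.label == EpochLabel.INTERICTAL]
        assert inter_t
        assert all(t + 5.0 <= 900.0 - 360.0 or t >= 960.0 + 360.0
                   for t in inter_t)

    def test_artifact_overlap_dropped(self):
        rec = make_recording(
            n_channels=1, fs=32.0, duration_s=60.0,
            annotations=[Annotation(12.0, 6.0, "artifact_exclude")],
        )
        eps = label_and_epoch(rec, PreprocessConfig())
        starts = [e.t_start for e in eps]
        assert 10.0 not in starts and 15.0 not in starts
        assert len(eps) == 10  # 12 grid epochs minus the 2 overlapping

    def test_epoching_partitions_the_signal(self):
        rec = make_recording(n_channels=2, fs=32.0, duration_s=33.0)
        eps = label_and_epoch(rec, PreprocessConfig())
        rebuilt = np.concatenate([e.data for e in eps], axis=1)
        np.testing.assert_array_equal(rebuilt, rec.data[:, : rebuilt.shape[1]])
        assert rebuilt.shape[1] == 6 * 160  # trailing 3 s dropped

    def test_epoch_longer_than_recording(self):
        rec = make_recording(n_channels=1, fs=32.0, duration_s=3.0)
        with pytest.raises(ValueError, match="longer than recording"):
            label_and_epoch(rec, PreprocessConfig(epoch_seconds=5.0))

    def test_labels_are_disjoint(self):
        rec = make_recording(
            n_channels=1, fs=32.0, duration_s=2000.0,
            annotations=[seizure(1800.0)],
        )
        cfg = PreprocessConfig(preictal_minutes=5.0,
                               interictal_gap_hours=0.1)
        eps = label_and_epoch(rec, cfg)
        pre = {e.t_start for e in eps if e.label == EpochLabel.PREICTAL}
        inter = {e.t_start for e in eps if e.label == EpochLabel.INTERICTAL}
        assert pre and inter and not (pre & inter)
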