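import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from jtpeak.ecg_io import INDEPENDENT_LEADS, EcgRecord
from jtpeak.errors import InsufficientBeatsError, NoBeatsError
from jtpeak.preprocess import (
    BeatTriggers,
    build_median_beat,
    detect_qrs_triggers,
    remove_baseline,
)
from jtpeak import synthetic as syn

FS = 500.0


def _record_from(signal):
    return EcgRecord(np.tile(signal, (8, 1)), FS, INDEPENDENT_LEADS)


def _triggers_every_second(n_samples, first_ms=400.0):
    idx = np.arange(first_ms / 1000.0 * FS, n_samples - 100, FS, dtype=int)
    return BeatTriggers(idx, FS)


def _beat_template():
    """One 500 Hz beat: stylized QRS + Gaussian T, R apex at sample 150."""
    t = np.arange(0, 1000, 2.0)  # ms
    comps = [(a, 300.0 + c, w) for a, c, w in syn.DEFAULT_QRS]
    comps.append((400.0, 570.0, 30.0))
    out = np.zeros_like(t)
    for a, c, w in comps:
        out += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def _beat_train(n_beats=10, rr_ms=1000.0):
    beat = _beat_template()
    sig = np.zeros(int(10 * FS))
    starts = []
    for k in range(n_beats):
        s = int((100 + k * rr_ms) / 1000.0 * FS)
        if s + len(beat) > len(sig):
            break
        sig[s : s + len(beat)] += beat
        starts.append(s + 150)  # R apex sample
    return sig, np.array(starts)


class TestRemoveBaseline:
    def test_sinusoidal_wander_suppressed_within_knot_span(self):
        n = int(10 * FS)
        t = np.arange(n) / FS
        wander = 200.0 * np.sin(2 * np.pi * 0.3 * t)
        record = _record_from(wander)
        # 100 bpm trigger train -> one isoelectric knot every 600 ms
        idx = np.arange(0.4 * FS, n - 100, 0.6 * FS, dtype=int)
        clean = remove_baseline(record, BeatTriggers(idx, FS))
        knots = idx - int(0.08 * FS)
        span = clean.samples[0][knots[1] : knots[-2]]  # well-supported span
        assert np.ptp(span) < 10.0

    def test_zero_signal_unchanged(self):
        n = int(10 * FS)
        record = _record_from(np.zeros(n))
        clean = remove_baseline(record, _triggers_every_second(n))
        np.testing.assert_allclose(clean.samples, 0.0, atol=1e-9)

    def test_constant_offset_removed(self):
        n = int(10 * FS)
        record = _record_from(np.full(n, 100.0))
        clean = remove_baseline(record, _triggers_every_second(n))
        np.testing.assert_allclose(clean.samples, 0.0, atol=1e-6)

    def test_too_few_beats_rejected(self):
        n = int(10 * FS)
        record = _record_from(np.zeros(n))
        with pytest.raises(InsufficientBeatsError):
            remove_baseline(record, BeatTriggers([1000, 2000], FS))


class TestDetectQrsTriggers:
    def test_clean_train_detected_near_r_apices(self):
        sig, apices = _beat_train()
        triggers = detect_qrs_triggers(_record_from(sig))
        assert len(triggers) == len(apices)
        err_ms = np.abs(triggers.trigger_samples - apices) * 1000.0 / FS
        assert err_ms.max() <= 10.0

    def test_noise_does_not_change_detection_count(self, rng):
        sig, apices = _beat_train()
        noisy = sig + rng.normal(0, 20.0, size=sig.shape)
        triggers = detect_qrs_triggers(_record_from(noisy))
        assert len(triggers) == len(apices)

    def test_flat_record_raises(self):
        with pytest.raises(NoBeatsError):
            detect_qrs_triggers(_record_from(np.zeros(int(10 * FS))))


class TestBuildMedianBeat:
    def test_identical_beats_reproduce_the_beat(self):
        sig, apices = _beat_train()
        record = _record_from(sig)
        triggers = BeatTriggers(apices, FS)
        median = build_median_beat(record, triggers)
        assert median.fs == 1000.0 and median.median_rr_ms == 1000.0
        # compare against the upsampled single-beat window
        pre, post = 150, int(0.7 * FS)
        window = sig[apices[3] - pre : apices[3] + post]
        t_src = np.arange(len(window)) * 2.0
        expect = CubicSpline(t_src, window)(np.arange(median.n_ms, dtype=float))
        assert np.max(np.abs(median.samples[0] - expect)) < 1.0

    def test_artifact_burst_in_one_beat_is_rejected_by_the_median(self):
        sig, apices = _beat_train()
        record_clean = _record_from(sig)
        dirty = sig.copy()
        dirty[apices[4] + 50 : apices[4] + 80] += 500.0
        record_dirty = _record_from(dirty)
        triggers = BeatTriggers(apices, FS)
        clean = build_median_beat(record_clean, triggers)
        robust = build_median_beat(record_dirty, triggers)
        assert np.max(np.abs(clean.samples - robust.samples)) < 1.0

    def test_median_invariant_under_beat_permutation(self):
        beat = _beat_template()
        sig_a = np.zeros(int(10 * FS))
        sig_b = np.zeros(int(10 * FS))
        scales = [0.9, 1.0, 1.1, 1.05, 0.95]
        for k, scale in enumerate(scales):
            s = int((100 + k * 1000) / 1000.0 * FS)
            sig_a[s : s + len(beat)] += scale * beat
            sig_b[s : s + len(beat)] += scales[::-1][k] * beat
        apices = np.array([int((100 + k * 1000) / 1000.0 * FS) + 150 for k in range(5)])
        triggers = BeatTriggers(apices, FS)
        med_a = build_median_beat(_record_from(sig_a), triggers)
        med_b = build_median_beat(_record_from(sig_b), triggers)
        np.testing.assert_allclose(med_a.samples, med_b.samples, atol=1e-9)

    def test_upsampling_preserves_local_maximum_position(self):
        sig, apices = _beat_train()
        median = build_median_beat(_record_from(sig), BeatTriggers(apices, FS))
        t_apex = np.argmax(median.samples[0][400:700]) + 400
        assert abs(t_apex - 570.0) <= 1.0  # T apex at 570 ms in beat coordinates

    def test_too_few_usable_beats_rejected(self):
        sig, apices = _beat_train(n_beats=3)
        # push two windows out of bounds
        triggers = BeatTriggers([5, apices[0], len(sig) - 10], FS)
        with pytest.raises(InsufficientBeatsError):
            build_median_beat(_record_from(sig), triggers)
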