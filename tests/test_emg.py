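"""EMG conditioning, normalization, onset detection, and exclusion gates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypojump import emg
from hypojump.emg import ExclusionRule

FS = 2000.0


def step_burst(aerial_ms=460.0, onset_ms=100.0, amp=0.3, baseline=0.0, fs=FS):
    """Aerial rectified trace: baseline, then a step of ``amp`` starting
    ``onset_ms`` before the final (touchdown) sample."""
    n = int(aerial_ms / 1000.0 * fs) + 1
    x = np.full(n, baseline)
    x[n - 1 - int(onset_ms / 1000.0 * fs) :] = amp
    return x


def chord_oracle(seg, fs):
    """Brute-force elbow: test every sample for the maximum downward
    deviation of the cumulative integral from the endpoint chord."""
    c = np.concatenate([[0.0], np.cumsum((seg[1:] + seg[:-1]) / 2.0 / fs)])
    best, best_i = np.inf, 0
    for i in range(c.size):
        chord = c[0] + (c[-1] - c[0]) * i / (c.size - 1)
        dev = c[i] - chord
        if dev <= best:
            best, best_i = dev, i
    return best_i


class TestPreprocess:
    def test_dc_rejected(self):
        out = emg.preprocess(np.full(4000, 0.5), FS)
        assert np.max(out[500:-500]) < 1e-3

    def test_sine_rectified_mean(self):
        t = np.arange(8000) / FS
        out = emg.preprocess(np.sin(2 * np.pi * 100 * t), FS)
        assert np.mean(out[1000:-1000]) == pytest.approx(2 / np.pi, rel=0.02)

    def test_rectification_symmetry(self):
        x = np.random.default_rng(3).standard_normal(4000)
        assert np.allclose(emg.preprocess(x, FS), emg.preprocess(-x, FS))

    def test_low_fs_clamps_corner(self):
        with pytest.warns(UserWarning, match="clamped"):
            emg.preprocess(np.random.default_rng(0).standard_normal(1000), 800.0)


class TestNormalizationPeak:
    def test_constant(self):
        assert emg.normalization_peak(np.full(2000, 0.4), 1000.0) == pytest.approx(0.4)

    def test_impulse_window_arithmetic(self):
        x = np.zeros(1000)
        x[500] = 2.0
        assert emg.normalization_peak(x, 1000.0) == pytest.approx(2.0 / 100)

    def test_max_over_trials(self):
        trials = [np.full(2000, v) for v in (0.1, 0.5, 0.3)]
        assert emg.normalization_peak(trials, 1000.0) == pytest.approx(0.5)

    def test_silent_reference_raises(self):
        with pytest.raises(emg.SilentReferenceError):
            emg.normalization_peak(np.zeros(2000), 1000.0)


class TestDetectOnset:
    def run(self, seg):
        x = np.concatenate([np.zeros(100), seg])
        return emg.detect_onset(x, FS, (100, x.size - 1))

    def test_all_zero_excluded_sub1(self):
        res = self.run(np.zeros(1000))
        assert res.exclusion_rule is ExclusionRule.SUB_1_PERCENT
        assert not res.included

    def test_step_burst_100ms_included(self):
        res = self.run(step_burst(onset_ms=100.0))
        assert res.included
        assert res.onset_ms_before_landing == pytest.approx(100.0, abs=5.0)

    def test_step_burst_200ms_too_early(self):
        res = self.run(step_burst(onset_ms=200.0))
        assert res.exclusion_rule is ExclusionRule.TOO_EARLY

    def test_early_bump_no_late_max(self):
        """Activity confined to early flight: latest 1 Hz local max falls
        more than 150 ms before touchdown."""
        n = int(0.46 * FS) + 1
        t = np.arange(n) / FS
        bump = 0.4 * np.exp(-(((t - 0.10) / 0.03) ** 2))
        res = self.run(bump)
        assert res.exclusion_rule is ExclusionRule.NO_LATE_MAX

    def test_tiny_burst_sub1(self):
        res = self.run(step_burst(onset_ms=100.0, amp=0.005))
        assert res.exclusion_rule is ExclusionRule.SUB_1_PERCENT

    def test_matches_brute_force_chord_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(300, 1200))
            seg = rng.uniform(0, 1, n) * np.linspace(0, 1, n) ** rng.uniform(0.5, 3)
            x = np.concatenate([np.zeros(10), seg])
            res = emg.detect_onset(x, FS, (10, x.size - 1))
            expect = chord_oracle(seg, FS)
            if res.onset_ms_before_landing is not None:
                got = (
                    seg.size - 1 - round(res.onset_ms_before_landing / 1000.0 * FS)
                )
                assert got == expect

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            emg.detect_onset(np.zeros(100), FS, (50, 40))

    def test_recovers_injected_onsets(self, participant, norm_peaks, zero_noise_config):
        from hypojump import pipeline, synth

        errs = []
        for s in range(10):
            tr, gt = synth.generate_trial(participant, "PRE", 900 + s, zero_noise_config)
            an = pipeline.analyze_trial(tr, norm_peaks, gt.target_height)
            for m, res in an.preactivation.items():
                assert res.included
                errs.append(res.onset_ms_before_landing - gt.true_onset_ms[m])
        assert np.max(np.abs(errs)) <= 10.0


class TestMetrics:
    def test_rectangle(self):
        x = np.full(201, 0.2)
        mag, iemg = emg.preactivation_metrics(x, FS, 0, 200)
        assert mag == pytest.approx(0.2)
        assert iemg == pytest.approx(0.02)

    def test_ramp(self):
        x = np.linspace(0, 0.4, 201)
        mag, iemg = emg.preactivation_metrics(x, FS, 0, 200)
        assert mag == pytest.approx(0.2)
        assert iemg == pytest.approx(0.02)

    def test_onset_after_touchdown_raises(self):
        with pytest.raises(ValueError):
            emg.preactivation_metrics(np.zeros(100), FS, 50, 50)


class TestTricepsSuraePreactivity:
    def test_mean(self):
        v, reason = emg.triceps_surae_preactivity({"MG": 0.03, "LG": 0.02, "SOL": 0.01})
        assert v == pytest.approx(0.02)
        assert reason is None

    def test_idempotent(self):
        v, _ = emg.triceps_surae_preactivity({"MG": 0.7, "LG": 0.7, "SOL": 0.7})
        assert v == pytest.approx(0.7)

    def test_missing_propagates(self):
        v, reason = emg.triceps_surae_preactivity({"MG": 0.03, "LG": None, "SOL": 0.01})
        assert v is None
        assert "LG" in reason

    def test_partial_fallback(self):
        v, _ = emg.triceps_surae_preactivity(
            {"MG": 0.03, "LG": None, "SOL": 0.01}, allow_partial=True
        )
        assert v == pytest.approx(0.02)


class TestScaleEquivariance:
    @given(k=st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_gain_invariance(self, k):
        """Scaling a raw channel and its normalization trials together
        leaves normalized traces and onsets unchanged."""
        rng = np.random.default_rng(11)
        ref = np.abs(rng.standard_normal(3000))
        raw = rng.standard_normal(3000)
        raw[2400:] *= 8.0

        def chain(scale):
            peak = emg.normalization_peak(np.abs(scale * ref), FS)
            rect = emg.preprocess(scale * raw, FS) / peak
            res = emg.detect_onset(rect, FS, (2000, 2999))
            return rect, res

        r1, o1 = chain(1.0)
        rk, ok = chain(k)
        assert np.allclose(r1, rk, atol=1e-12)
        assert o1.onset_ms_before_landing == ok.onset_ms_before_landing
        assert o1.exclusion_rule == ok.exclusion_rule


class TestIncludedInvariants:
    def test_fuzz_included_results_valid(self, rng):
        """Included results always satisfy the onset/magnitude bounds."""
        for _ in range(200):
            n = int(rng.integers(200, 1500))
            x = np.abs(rng.standard_normal(n)) * rng.uniform(0, 0.5)
            res = emg.detect_onset(x, FS, (0, n - 1))
            if res.included:
                assert 0.0 <= res.onset_ms_before_landing <= 150.0
                assert res.magnitude >= 0.01
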