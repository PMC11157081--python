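"""Phase segmentation, impulses, jump metrics, and ballistic timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypojump import kinetics as kin
from hypojump.config import CohortConfig
from hypojump import synth

BW = 700.0
FS = 1000.0


def brute_force_phases(grf, bw):
    """Sample-by-sample scan of the stated crossing rules (test oracle)."""
    below = grf < 25.0
    runs = []
    i = 0
    while i < grf.size:
        if below[i]:
            j = i
            while j < grf.size and below[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    peak = int(np.argmax(grf[:start]))
    lift = None
    for i in range(peak - 1, -1, -1):
        if grf[i] <= bw < grf[i + 1]:
            while i > 0 and grf[i - 1] == bw:
                i -= 1
            lift = i
            break
    lpeak = stop + int(np.argmax(grf[stop:]))
    lend = None
    for i in range(lpeak, grf.size - 1):
        if grf[i] >= bw > grf[i + 1]:
            while i > lpeak and grf[i - 1] == bw:
                i -= 1
            lend = i
            break
    return lift, start, stop, lend


def trapezoid_trial():
    """BW for 1 s, ramp to 2 BW, drop to 0 for 0.3 s, landing spike, settle."""
    seg = [
        np.full(1000, BW),
        np.linspace(BW, 2 * BW, 200),
        np.linspace(2 * BW, 30.0, 50),
        np.zeros(300),
        np.linspace(1800.0, BW / 2, 150),
        np.full(400, BW),
    ]
    return np.concatenate(seg)


class TestSegmentPhases:
    def test_no_jump_raises(self):
        with pytest.raises(kin.NoAerialPhaseError):
            kin.segment_phases(np.full(2000, BW), BW, FS)

    def test_matches_brute_force_scan(self):
        grf = trapezoid_trial()
        ph = kin.segment_phases(grf, BW, FS)
        lift, lo, td, lend = brute_force_phases(grf, BW)
        assert (ph.lift_start, ph.liftoff, ph.touchdown, ph.land_end) == (lift, lo, td, lend)

    def test_random_profiles_match_oracle(self, rng):
        for _ in range(100):
            bw = rng.uniform(500, 900)
            push = rng.uniform(1.5, 2.5) * bw
            n_air = rng.integers(200, 500)
            grf = np.concatenate(
                [
                    np.full(rng.integers(300, 800), bw),
                    np.linspace(bw, push, rng.integers(100, 300)),
                    np.linspace(push, 20.0, rng.integers(30, 80)),
                    rng.uniform(0, 20, n_air),
                    np.linspace(rng.uniform(2, 4) * bw, bw * 0.4, rng.integers(80, 200)),
                    np.full(300, bw),
                ]
            )
            ph = kin.segment_phases(grf, bw, FS)
            assert (ph.lift_start, ph.liftoff, ph.touchdown, ph.land_end) == brute_force_phases(
                grf, bw
            )
            assert 0 <= ph.lift_start < ph.liftoff < ph.touchdown <= ph.land_end < grf.size

    def test_flight_duration_matches_truth(self, zero_noise_trial):
        tr, gt = zero_noise_trial
        ph = kin.segment_phases(tr.grf_z, tr.body_weight, tr.fs_grf)
        measured = (ph.touchdown - ph.liftoff) / tr.fs_grf
        assert abs(measured - gt.flight_duration) <= 1.0 / tr.fs_grf


class TestImpulses:
    def test_rectangle(self):
        grf = np.full(1501, BW)
        ph = kin.JumpPhases(0, 500, 1000, 1500, FS)
        lift, land = kin.compute_impulses(grf, ph, FS)
        assert lift == pytest.approx(BW * 0.5)
        assert land == pytest.approx(BW * 0.5)

    def test_triangle(self):
        tri = np.interp(np.arange(201), [0, 100, 200], [0, 1000, 0])
        grf = np.concatenate([tri, np.zeros(300), tri])
        ph = kin.JumpPhases(0, 200, 501, 701, FS)
        lift, land = kin.compute_impulses(grf, ph, FS)
        assert lift == pytest.approx(100.0)
        assert land == pytest.approx(100.0)

    def test_matches_riemann_oracle(self, rng):
        """Independent trapezoidal Riemann sum, accumulated sample by sample."""
        for _ in range(100):
            n = int(rng.integers(50, 400))
            grf = rng.uniform(0, 2000, n)
            ph = kin.JumpPhases(0, n // 3, 2 * n // 3, n - 1, FS)
            lift, land = kin.compute_impulses(grf, ph, FS)
            oracle = 0.0
            for i in range(ph.lift_start, ph.liftoff):
                oracle += (grf[i] + grf[i + 1]) / 2.0 / FS
            assert lift == pytest.approx(oracle, rel=1e-9)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            kin.compute_impulses(np.zeros(10), kin.JumpPhases(0, 0, 5, 9, FS), FS)


class TestJumpMetrics:
    def test_arithmetic(self):
        marker = np.full(400, 1.60)
        marker[150:250] = np.linspace(1.6, 1.9, 100)
        ph = kin.JumpPhases(50, 100, 300, 350, 200.0)
        h, e = kin.jump_metrics(marker, 200.0, ph, 1.60, 0.25)
        assert h == pytest.approx(0.30)
        assert e == pytest.approx(0.05)

    def test_degenerate_height_not_positive(self):
        marker = np.full(400, 1.60)
        ph = kin.JumpPhases(50, 100, 300, 350, 200.0)
        h, _ = kin.jump_metrics(marker, 200.0, ph, 1.60, 0.25)
        assert h <= 0

    def test_zero_noise_height_within_1mm(self, zero_noise_trial, participant):
        tr, gt = zero_noise_trial
        ph = kin.segment_phases(tr.grf_z, tr.body_weight, tr.fs_grf)
        h, _ = kin.jump_metrics(
            tr.marker_z, tr.fs_marker, ph, participant.standing_height, gt.target_height
        )
        assert h == pytest.approx(gt.true_jump_height, abs=1e-3)

    def test_flight_time_height_consistency(self, zero_noise_trial, participant):
        """g * t_f^2 / 8 from the detected flight agrees with marker height."""
        tr, gt = zero_noise_trial
        ph = kin.segment_phases(tr.grf_z, tr.body_weight, tr.fs_grf)
        tf = (ph.touchdown - ph.liftoff) / tr.fs_grf
        h_flight = gt.true_effective_g * tf**2 / 8.0
        h_marker, _ = kin.jump_metrics(
            tr.marker_z, tr.fs_marker, ph, participant.standing_height, gt.target_height
        )
        assert h_flight == pytest.approx(h_marker, rel=0.01)


class TestAerialAcceleration:
    def _parabola_trial(self, g):
        fs = 200.0
        t = np.arange(300) / fs
        marker = 1.6 + 2.0 * (t - 0.5) - 0.5 * g * (t - 0.5) ** 2
        ph = kin.JumpPhases(10, 50, 250, 280, fs)
        return marker, fs, ph

    @pytest.mark.parametrize("g", [9.81, 4.905])
    def test_exact_parabola(self, g):
        marker, fs, ph = self._parabola_trial(g)
        assert kin.aerial_acceleration(marker, fs, ph) == pytest.approx(-g, abs=1e-9)

    def test_hypogravity_trial(self, participant, zero_noise_config):
        cfg = CohortConfig(
            **{**zero_noise_config.to_dict(), "effective_g": {"PRE": 0.508 * 9.81,
               "ADAPT": 0.51 * 9.81, "POST": 9.81}}
        )
        tr, gt = synth.generate_trial(participant, "PRE", 7, cfg)
        ph = kin.segment_phases(tr.grf_z, tr.body_weight, tr.fs_grf)
        assert kin.aerial_acceleration(tr.marker_z, tr.fs_marker, ph) == pytest.approx(
            -4.983, abs=1e-3
        )

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            kin.aerial_acceleration(np.zeros(100), 200.0, kin.JumpPhases(0, 10, 13, 20, 200.0))


class TestBallisticTiming:
    def test_fall_times_and_delay(self):
        assert round(kin.fall_time(0.273, 9.81) * 1000) == 236
        assert round(kin.fall_time(0.273, 0.508 * 9.81) * 1000) == 331
        assert round(kin.delay_prediction(0.273, 9.81, 0.508 * 9.81) * 1000) == 95
        assert kin.fall_time(0.0, 9.81) == 0.0
        assert kin.delay_prediction(0.273, 9.81, 9.81) == 0.0
        # g/4 doubles the fall time, so the delay equals the 1 g fall time
        assert kin.delay_prediction(0.273, 9.81, 9.81 / 4) == pytest.approx(
            kin.fall_time(0.273, 9.81)
        )

    def test_mitigation_percent(self):
        assert kin.delay_mitigation_percent(0.095, 0.026) == pytest.approx(72.63, abs=0.01)
        assert kin.delay_mitigation_percent(0.1, 0.1) == 0.0
        assert kin.delay_mitigation_percent(0.1, 0.0) == 100.0
        with pytest.raises(ValueError):
            kin.delay_mitigation_percent(0.0, 0.0)

    @given(
        h1=st.floats(0.01, 2.0),
        h2=st.floats(0.01, 2.0),
        g1=st.floats(0.5, 20.0),
        g2=st.floats(0.5, 20.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_fall_time_monotone(self, h1, h2, g1, g2):
        if h1 < h2:
            assert kin.fall_time(h1, g1) <= kin.fall_time(h2, g1)
        if g1 < g2:
            assert kin.fall_time(h1, g1) >= kin.fall_time(h1, g2)
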