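"""Kinematics: headings, wall incidence, polarization, pair geometry, bursts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schoolnet.errors import TooShortError, UndefinedHeadingError
from schoolnet.kinematics import (BurstSegmentation, burst_influence_overlap,
                                  compute_kinematics, detect_bursts,
                                  pair_geometry, pair_geometry_series,
                                  polarization)
from schoolnet.trajdata import FishTrack, RingGeometry, TrajectorySet

GEOM = RingGeometry()
DT = 0.02


def track_from_positions(pos, fish_id=1):
    pos = np.asarray(pos, dtype=float)
    times = np.arange(len(pos)) * DT
    return FishTrack(fish_id, times, pos)


def circle_set(radius=300.0, omega=0.5, n=200, anticlockwise=True):
    t = np.arange(n) * DT
    s = 1.0 if anticlockwise else -1.0
    psi = s * omega * t
    pos = np.stack([radius * np.cos(psi), radius * np.sin(psi)], 1)
    return TrajectorySet([track_from_positions(pos)], GEOM, DT)


class TestHeadings:
    def test_tangential_motion_has_quarter_turn_incidence(self):
        kin = compute_kinematics(circle_set())
        # anticlockwise along the wall: theta_w ~ +pi/2
        mid = kin.theta_w[0, 5:-5]
        np.testing.assert_allclose(mid, np.pi / 2, atol=1e-3)
        kin2 = compute_kinematics(circle_set(anticlockwise=False))
        np.testing.assert_allclose(kin2.theta_w[0, 5:-5], -np.pi / 2, atol=1e-3)

    def test_radial_motion_incidence(self):
        # moving straight outward along +x from (260,0): phi = psi = 0
        x = 260 + 100 * np.arange(50) * DT
        ts = TrajectorySet([track_from_positions(np.stack([x, np.zeros(50)], 1))],
                           GEOM, DT)
        kin = compute_kinematics(ts)
        np.testing.assert_allclose(kin.theta_w[0, 1:-1], 0.0, atol=1e-9)
        # moving toward the center: phi = pi, psi = 0 -> |theta_w| = pi
        ts2 = TrajectorySet([track_from_positions(np.stack([x[::-1], np.zeros(50)], 1))],
                            GEOM, DT)
        kin2 = compute_kinematics(ts2)
        np.testing.assert_allclose(np.abs(kin2.theta_w[0, 1:-1]), np.pi, atol=1e-9)

    def test_speed_floor_carries_heading_forward(self):
        x = np.concatenate([260 + 50 * np.arange(20) * DT,
                            np.full(10, 260 + 50 * 19 * DT),
                            260 + 50 * 19 * DT + 50 * np.arange(10) * DT])
        ts = TrajectorySet([track_from_positions(np.stack([x, np.zeros(40)], 1))],
                           GEOM, DT)
        kin = compute_kinematics(ts, speed_floor=1.0)
        # during the stall the last defined heading (along +x) is carried
        assert np.allclose(kin.phi[0, 22:28], 0.0)

    def test_never_moving_track_rejected(self):
        pos = np.full((30, 2), (300.0, 0.0))
        ts = TrajectorySet([track_from_positions(pos)], GEOM, DT)
        with pytest.raises(UndefinedHeadingError):
            compute_kinematics(ts)


class TestPolarization:
    def test_reference_values(self):
        e = np.tile([1.0, 0.0], (5, 1))
        assert polarization(e) == pytest.approx(1.0)
        assert polarization(np.array([[1, 0], [-1, 0.]])) == pytest.approx(0.0)
        assert polarization(np.array([[1, 0], [0, 1.]])) == pytest.approx(np.sqrt(2) / 2)

    def test_undefined_heading_propagates(self):
        e = np.array([[[1.0, 0.0]], [[np.nan, np.nan]]])
        assert np.isnan(polarization(e)[0])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=8),
           st.floats(-np.pi, np.pi))
    def test_bounds_and_rotation_invariance(self, angles, rot):
        e = np.stack([np.cos(angles), np.sin(angles)], 1)
        p = polarization(e)
        assert -1e-12 <= p <= 1 + 1e-12
        e_rot = np.stack([np.cos(np.array(angles) + rot),
                          np.sin(np.array(angles) + rot)], 1)
        assert polarization(e_rot) == pytest.approx(p, abs=1e-12)

    def test_unity_iff_identical(self):
        e = np.stack([np.cos([0.3, 0.3, 0.31]), np.sin([0.3, 0.3, 0.31])], 1)
        assert polarization(e) < 1.0


def two_fish_set(p1, p2, v1, v2, n=9):
    """Straight-line motion so central differences give exact velocities."""
    t = np.arange(n)[:, None] * DT
    a = np.asarray(p1) + t * np.asarray(v1)
    b = np.asarray(p2) + t * np.asarray(v2)
    return TrajectorySet([track_from_positions(a, 1), track_from_positions(b, 2)],
                         GEOM, DT)


class TestPairGeometry:
    def test_neighbor_dead_ahead(self):
        ts = two_fish_set((260, 0), (320, 0), (100, 0), (100, 0))
        kin = compute_kinematics(ts)
        g = pair_geometry(kin, 1, 2, 4)
        assert g.theta_ij == pytest.approx(0.0, abs=1e-12)
        assert g.d_ij == pytest.approx(60.0)
        assert g.phi_ij == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_construction(self):
        ts = two_fish_set((300, 0), (300, 100), (100, 0), (100, 0))
        kin = compute_kinematics(ts)
        g = pair_geometry(kin, 1, 2, 4)
        assert g.d_ij == pytest.approx(100.0)
        assert g.theta_ij == pytest.approx(np.pi / 2)

    def test_asymmetry_of_viewing_angle(self):
        ts = two_fish_set((300, 0), (300, 100), (100, 0), (0, 100))
        kin = compute_kinematics(ts)
        assert pair_geometry(kin, 1, 2, 4).theta_ij != pytest.approx(
            pair_geometry(kin, 2, 1, 4).theta_ij)

    def test_mirror_reflection_negates_angles(self):
        ts = two_fish_set((300, 50), (260, 120), (80, 60), (90, -10))
        kin = compute_kinematics(ts)
        g = pair_geometry(kin, 1, 2, 4)
        # reflect the whole scene across the x axis
        mirrored = TrajectorySet(
            [FishTrack(tr.fish_id, tr.times.copy(), tr.positions * [1.0, -1.0])
             for tr in ts.tracks], GEOM, DT)
        gm = pair_geometry(compute_kinematics(mirrored), 1, 2, 4)
        assert gm.theta_ij == pytest.approx(-g.theta_ij)
        assert gm.phi_ij == pytest.approx(-g.phi_ij)
        assert gm.d_ij == pytest.approx(g.d_ij)

    def test_series_matches_scalar(self):
        ts = two_fish_set((300, 0), (320, 40), (100, 10), (90, 0))
        kin = compute_kinematics(ts)
        series = pair_geometry_series(kin, 1, 2)
        g = pair_geometry(kin, 1, 2, 3)
        assert series["d_ij"][3] == pytest.approx(g.d_ij)
        assert series["theta_ij"][3] == pytest.approx(g.theta_ij)


class TestBursts:
    def test_constant_speed_no_bursts(self):
        seg = detect_bursts(np.full(100, 120.0), DT)
        assert seg.intervals == []
        assert not seg.bursting.any()

    def test_sawtooth_one_burst_per_ramp(self):
        # linear rise 50->200 mm/s over 0.2 s (acceleration 750 mm/s^2 > 300),
        # then fall back; brute-force expectation: one burst per rising ramp
        ramp = np.concatenate([np.linspace(50, 200, 10), np.linspace(200, 50, 10)])
        speed = np.tile(ramp, 5)
        seg = detect_bursts(speed, DT, accel_threshold=300.0)
        assert len(seg.intervals) == 5
        for (a, b), k in zip(seg.intervals, range(5)):
            assert a >= 20 * k and b <= 20 * k + 12

    def test_empty_series_too_short(self):
        with pytest.raises(TooShortError):
            detect_bursts(np.array([]), DT)


class TestBurstOverlap:
    def make_records(self, frames, focal, neighbor, tau_frames):
        return pd.DataFrame({"frame": frames, "focal": focal,
                             "neighbor": neighbor, "tau_frames": tau_frames})

    def test_always_bursting_influencer_statistic_is_one(self):
        bursts = {1: BurstSegmentation([(0, 99)], np.ones(100, bool)),
                  2: BurstSegmentation([], np.zeros(100, bool))}
        rec = self.make_records([50, 60], [2, 2], [1, 1], [10, 10])
        out = burst_influence_overlap(bursts, rec, DT)
        assert out.statistic[1] == pytest.approx(1.0)

    def test_no_records_undefined(self):
        bursts = {1: BurstSegmentation([(0, 9)], np.r_[np.ones(10, bool),
                                                       np.zeros(90, bool)])}
        out = burst_influence_overlap(bursts, self.make_records([], [], [], []), DT)
        assert np.isnan(out.statistic[1])

    def test_lookback_before_start_skipped(self):
        bursts = {1: BurstSegmentation([], np.zeros(50, bool))}
        rec = self.make_records([5], [1], [1], [10])
        out = burst_influence_overlap(bursts, rec, DT)
        assert out.skipped == 1

    def test_independent_bursts_near_unity(self):
        # influence times drawn independently of burst intervals: statistic
        # should be ~1 (permutation oracle at generous Monte Carlo tolerance)
        rng = np.random.default_rng(0)
        bursting = rng.random(4000) < 0.3
        bursts = {1: BurstSegmentation([], bursting)}
        frames = rng.integers(100, 4000, size=1500)
        rec = self.make_records(frames, [2] * 1500, [1] * 1500, [10] * 1500)
        out = burst_influence_overlap(bursts, rec, DT)
        assert out.statistic[1] == pytest.approx(1.0, abs=0.12)
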