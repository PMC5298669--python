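"""Kalman filtering, assignment algorithms, heading gate, track_step."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flytrax.tracking import (
    Assignment,
    TrackConfig,
    build_cost_matrix,
    closest_neighbor_assign,
    heading_check,
    hungarian_assign,
    kf_predict,
    kf_update,
    new_tracker,
    track_step,
)


def unit(a):
    return np.array([np.cos(a), np.sin(a)])


def brute_force_min_cost(costs):
    n = costs.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(n)):
        best = min(best, sum(costs[i, perm[i]] for i in range(n)))
    return best


def greedy_trace(costs):
    """Literal re-trace of the closest-neighbor procedure, list-based."""
    rows = list(range(costs.shape[0]))
    cols = list(range(costs.shape[1]))
    pairs = []
    while rows and cols:
        best = None
        for r in rows:
            for c in cols:
                if best is None or costs[r, c] < costs[best[0], best[1]]:
                    best = (r, c)
        pairs.append(best)
        rows.remove(best[0])
        cols.remove(best[1])
    return pairs


class TestKalman:
    def test_prediction_moves_by_velocity(self):
        t = new_tracker(1, (0.0, 0.0))
        t.state[2:] = [1.0, 2.0]
        p = kf_predict(t, dt=1.0)
        assert np.allclose(p.position, [1.0, 2.0])
        assert np.allclose(p.velocity, [1.0, 2.0])

    def test_zero_velocity_stays_put(self):
        t = new_tracker(1, (5.0, 7.0))
        assert np.allclose(kf_predict(t).position, [5.0, 7.0])

    def test_n_step_closed_form(self):
        t = new_tracker(1, (2.0, -1.0))
        t.state[2:] = [0.5, 1.5]
        for _ in range(12):
            t = kf_predict(t, dt=1.0)
        assert np.allclose(t.position, [2.0 + 12 * 0.5, -1.0 + 12 * 1.5])

    def test_zero_innovation_keeps_position_shrinks_covariance(self):
        t = new_tracker(1, (3.0, 4.0))
        p = kf_predict(t)
        u = kf_update(p, p.position)
        assert np.allclose(u.position, p.position)
        block = p.covariance[:2, :2] - u.covariance[:2, :2]
        assert np.all(np.linalg.eigvalsh(block) >= -1e-9)

    def test_small_r_pulls_to_measurement(self):
        t = new_tracker(1, (0.0, 0.0))
        p = kf_predict(t)
        u = kf_update(p, (10.0, -5.0), r_sd=1e-6)
        assert np.allclose(u.position, [10.0, -5.0], atol=1e-3)

    def test_covariance_stays_symmetric_psd(self):
        t = new_tracker(1, (0.0, 0.0))
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = kf_predict(t)
            t = kf_update(t, rng.normal(size=2) * 3)
        assert np.allclose(t.covariance, t.covariance.T)
        assert np.all(np.linalg.eigvalsh(t.covariance) >= -1e-9)

    def test_filter_beats_raw_measurement_noise(self):
        rng = np.random.default_rng(42)
        v = np.array([3.0, 2.0])
        sigma_m = 2.0
        t = new_tracker(1, (0.0, 0.0))
        errs, verrs = [], []
        pos = np.zeros(2)
        # constant-velocity truth: the matching process model has (near)
        # zero acceleration noise
        for k in range(1, 120):
            pos = pos + v
            z = pos + rng.normal(0, sigma_m, 2)
            t = kf_predict(t, 1.0, q_accel_sd=0.05)
            t = kf_update(t, z, r_sd=sigma_m)
            if k > 20:
                errs.append(np.linalg.norm(t.position - pos))
            if k > 30:
                verrs.append(np.linalg.norm(t.velocity - v))
        assert np.sqrt(np.mean(np.square(errs))) < sigma_m
        assert np.sqrt(np.mean(np.square(verrs))) / np.linalg.norm(v) < 0.10


class TestAssignment:
    def test_identity_costs_give_diagonal(self):
        c = np.ones((3, 3)) - np.eye(3)
        a = hungarian_assign(c)
        assert a.pairs == [(0, 0), (1, 1), (2, 2)]
        assert a.total_cost == 0.0

    def test_two_by_two(self):
        a = hungarian_assign(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert a.pairs == [(0, 0), (1, 1)]
        assert a.total_cost == 2.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_hungarian_matches_brute_force(self, seed, n):
        costs = np.random.default_rng(seed).uniform(0, 100, size=(n, n))
        a = hungarian_assign(costs)
        assert a.total_cost == pytest.approx(brute_force_min_cost(costs))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_greedy_matches_literal_trace_and_bounds_hungarian(self, seed, n):
        costs = np.random.default_rng(seed).uniform(0, 100, size=(n, n))
        g = closest_neighbor_assign(costs)
        assert g.pairs == sorted(greedy_trace(costs))
        assert hungarian_assign(costs).total_cost <= g.total_cost + 1e-9

    def test_greedy_vs_hungarian_divergent_example(self):
        costs = np.array([[1.0, 2.0], [1.5, 10.0]])
        g = closest_neighbor_assign(costs)
        h = hungarian_assign(costs)
        assert g.pairs == [(0, 0), (1, 1)] and g.total_cost == 11.0
        assert h.pairs == [(0, 1), (1, 0)] and h.total_cost == 3.5

    def test_single_row_takes_minimum(self):
        g = closest_neighbor_assign(np.array([[4.0, 1.0, 7.0]]))
        assert g.pairs == [(0, 1)]

    def test_dummy_padding_reports_unmatched(self):
        cm = build_cost_matrix(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0], [80.0, 0.0]]),
                               dummy_cost=10.0)
        a = hungarian_assign(cm)
        assert a.pairs == [(0, 0)]
        assert a.unmatched_jobs == [1]  # beyond dummy cost: left unmatched


class TestHeadingCheck:
    def test_identical_headings_accepted(self):
        a = Assignment(pairs=[(0, 0)], unmatched_workers=[], unmatched_jobs=[], total_cost=0)
        acc, rej = heading_check(a, [unit(0.3)], [unit(0.3).copy()], tolerance=0.0)
        assert acc == [(0, 0)] and rej == []

    def test_antiparallel_rejected(self):
        a = Assignment(pairs=[(0, 0)], unmatched_workers=[], unmatched_jobs=[], total_cost=0)
        acc, rej = heading_check(a, [unit(0.0)], [unit(np.pi)], tolerance=np.pi / 2)
        assert acc == [] and rej == [(0, 0)]

    def test_missing_heading_accepted(self):
        a = Assignment(pairs=[(0, 0), (1, 1)], unmatched_workers=[], unmatched_jobs=[],
                       total_cost=0)
        acc, rej = heading_check(a, [None, unit(0)], [unit(1.0), None], tolerance=0.1)
        assert acc == [(0, 0), (1, 1)]


def five_fly_step(use_heading_check):
    """Crossing-prediction scenario: three obvious pairs plus two flies that
    stepped backward, so distance-only matching exchanges them."""
    cfg = TrackConfig(gate=50.0, use_heading_check=use_heading_check)
    specs = [
        (1, (10.0, 10.0), (2.0, 0.0), 0.0),
        (2, (60.0, 10.0), (0.0, 2.0), np.pi / 2),
        (3, (110.0, 10.0), (-2.0, 0.0), np.pi),
        (4, (40.0, 60.0), (10.0, 0.0), 0.0),
        (5, (54.0, 60.0), (-10.0, 0.0), np.pi),
    ]
    trackers = []
    for tid, p, v, h in specs:
        t = new_tracker(tid, p, unit(h))
        t.state[2:] = v
        trackers.append(t)
    dets = [
        (np.array([12.0, 10.0]), unit(0.0)),
        (np.array([60.0, 12.0]), unit(np.pi / 2)),
        (np.array([108.0, 10.0]), unit(np.pi)),
        (np.array([37.0, 60.0]), unit(0.0)),
        (np.array([57.0, 60.0]), unit(np.pi)),
    ]
    out = track_step(trackers, dets, cfg)
    return {t.id: t.position for t in out}


class TestTrackStep:
    def test_single_tracker_trivial_match(self):
        t = new_tracker(1, (10.0, 10.0), unit(0.0))
        out = track_step([t], [(np.array([10.0, 10.0]), unit(0.0))], TrackConfig())
        assert len(out) == 1 and out[0].id == 1 and out[0].matched

    def test_five_fly_heading_confirmation(self):
        pos = five_fly_step(use_heading_check=True)
        assert abs(pos[4][0] - 37.0) < 2.0  # tracker 4 -> detection d
        assert abs(pos[5][0] - 57.0) < 2.0  # tracker 5 -> detection e

    def test_five_fly_hungarian_only_swaps(self):
        pos = five_fly_step(use_heading_check=False)
        assert abs(pos[4][0] - 57.0) < 2.0  # swapped
        assert abs(pos[5][0] - 37.0) < 2.0

    def test_empty_detections_all_coast(self):
        t = new_tracker(1, (5.0, 5.0))
        out = track_step([t], [], TrackConfig())
        assert len(out) == 1 and out[0].missed == 1 and not out[0].matched

    def test_unmatched_detection_spawns_zero_velocity_tracker(self):
        out = track_step([], [(np.array([3.0, 4.0]), None)], TrackConfig())
        assert len(out) == 1
        assert np.allclose(out[0].velocity, 0.0)

    def test_retirement_after_max_missed(self):
        cfg = replace(TrackConfig(), max_missed=2)
        trackers = [new_tracker(1, (5.0, 5.0))]
        for _ in range(3):
            trackers = track_step(trackers, [], cfg)
        assert trackers == []

    def test_identity_conservation_one_detection_per_id(self):
        rng = np.random.default_rng(1)
        trackers = []
        for f in range(30):
            dets = [(rng.uniform(0, 200, 2), None) for _ in range(6)]
            trackers = track_step(trackers, dets, TrackConfig())
            ids = [t.id for t in trackers]
            assert len(ids) == len(set(ids))

    def test_backward_motion_scenario_full_vs_ablated(self):
        """Two flies approach head-on, stop, and retreat; the heading gate
        keeps identities while distance-only matching swaps them."""

        def run(use_heading_check):
            cfg = TrackConfig(gate=60.0, use_heading_check=use_heading_check)
            xa = list(range(0, 66, 6)) + list(range(54, -6, -6))
            xb = [126 - x for x in xa]
            trackers = []
            for f in range(len(xa)):
                dets = [
                    (np.array([float(xa[f]), 50.0]), unit(0.0)),
                    (np.array([float(xb[f]), 50.0]), unit(np.pi)),
                ]
                trackers = track_step(trackers, dets, cfg)
            final = {t.id: t.position[0] for t in trackers}
            return final

        full = run(True)
        assert full[1] == pytest.approx(0.0, abs=3.0)
        assert full[2] == pytest.approx(126.0, abs=3.0)
        ablated = run(False)
        assert ablated[1] > 60.0 or ablated[2] < 60.0  # swapped
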