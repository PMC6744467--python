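import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trailtrack.core_io import Detection
from trailtrack.tracker import (
    TrackParams,
    build_trajectories,
    extract_cues,
    pairwise_cost,
    select_training_frames,
    solve_frame_assignment,
)

from conftest import brute_force_assignment, make_frameset, straight_line_detections

P = TrackParams()


def det(x, y, frame=0, appearance=None):
    return Detection(frame=frame, x_px=x, y_px=y, appearance=appearance)


class TestPairwiseCost:
    def test_identity_is_zero(self):
        a = det(10, 20, appearance=(1.0, 2.0))
        b = det(10, 20, frame=1, appearance=(1.0, 2.0))
        assert pairwise_cost(a, b, P) == 0.0

    def test_gate_distance_normalizes_to_one(self):
        a = det(0, 0)
        b = det(P.gate_px, 0, frame=1)
        assert pairwise_cost(a, b, P) == pytest.approx(1.0)

    def test_beyond_gate_infeasible(self):
        assert pairwise_cost(det(0, 0), det(P.gate_px + 1, 0, frame=1), P) == math.inf

    def test_appearance_length_mismatch(self):
        with pytest.raises(ValueError, match="appearance"):
            pairwise_cost(det(0, 0, appearance=(1,)), det(0, 0, appearance=(1, 2)), P)

    def test_one_sided_appearance_rejected(self):
        with pytest.raises(ValueError):
            pairwise_cost(det(0, 0, appearance=(1,)), det(0, 0), P)

    def test_appearance_term_added(self):
        a = det(0, 0, appearance=(0.0,))
        b = det(0, 0, frame=1, appearance=(1.0,))
        # range scaling of a single pair defaults to raw differences
        assert pairwise_cost(a, b, P) == pytest.approx(P.w_app * 1.0)


class TestSolveFrameAssignment:
    def test_forced_match(self):
        res = solve_frame_assignment([det(0, 0)], [det(9, 0, frame=1)], P)
        assert len(res.matches) == 1
        assert res.matches[0][:2] == (0, 0)
        assert res.total_cost == pytest.approx(9 / P.gate_px)

    def test_empty_suppliers_all_births(self):
        receivers = [det(x, 0, frame=1) for x in (10, 20, 30)]
        res = solve_frame_assignment([], receivers, P)
        assert res.matches == []
        assert res.births == [0, 1, 2]
        assert res.total_cost == pytest.approx(3 * P.birth_death_cost)

    def test_far_apart_pair_prefers_birth_death(self):
        res = solve_frame_assignment([det(0, 0)], [det(500, 0, frame=1)], P)
        assert res.matches == []
        assert res.births == [0] and res.deaths == [0]

    def test_conservation(self):
        rng = np.random.default_rng(0)
        k = [det(x, y) for x, y in rng.uniform(0, 100, size=(4, 2))]
        k1 = [det(x, y, frame=1) for x, y in rng.uniform(0, 100, size=(6, 2))]
        res = solve_frame_assignment(k, k1, P)
        assert len(res.matches) + len(res.deaths) == 4
        assert len(res.matches) + len(res.births) == 6
        used_i = [m[0] for m in res.matches] + res.deaths
        used_j = [m[1] for m in res.matches] + res.births
        assert sorted(used_i) == list(range(4))
        assert sorted(used_j) == list(range(6))

    def test_3x3_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = [det(x, y) for x, y in rng.uniform(0, 60, size=(3, 2))]
            k1 = [det(x, y, frame=1) for x, y in rng.uniform(0, 60, size=(3, 2))]
            res = solve_frame_assignment(k, k1, P)
            cost = np.array([[pairwise_cost(a, b, P) for b in k1] for a in k])
            assert res.total_cost == pytest.approx(
                brute_force_assignment(cost, P.birth_death_cost)
            )

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(0, 5),
        m=st.integers(0, 5),
        seed=st.integers(0, 10_000),
        bd=st.floats(0.2, 3.0),
    )
    def test_optimality_property(self, n, m, seed, bd):
        rng = np.random.default_rng(seed)
        p = TrackParams(birth_death_cost=bd)
        k = [det(x, y) for x, y in rng.uniform(0, 120, size=(n, 2))]
        k1 = [det(x, y, frame=1) for x, y in rng.uniform(0, 120, size=(m, 2))]
        res = solve_frame_assignment(k, k1, p)
        if n and m:
            cost = np.array([[pairwise_cost(a, b, p) for b in k1] for a in k])
        else:
            cost = np.full((n, m), np.inf)
        expected = brute_force_assignment(cost, bd)
        assert res.total_cost == pytest.approx(expected)
        assert len(res.matches) + len(res.deaths) == n
        assert len(res.matches) + len(res.births) == m

    def test_margins_nonnegative_and_meaningful(self):
        k = [det(0, 0), det(40, 0)]
        k1 = [det(5, 0, frame=1), det(45, 0, frame=1)]
        res = solve_frame_assignment(k, k1, P, compute_margins=True)
        assert all(v >= 0 for v in res.margins.values())
        # well-separated pairs: forbidding a match forces a worse solution
        assert all(v > 0.1 for v in res.margins.values())


class TestBuildTrajectories:
    def test_three_separated_ants_recovered(self):
        rows = []
        for i, y in enumerate((10, 60, 110)):
            rows += straight_line_detections(30, x0=0, y0=y, vx=8, vy=0)
        fs = make_frameset(rows, width=600, height=120)
        trajs = build_trajectories(fs, P)
        assert len(trajs) == 3
        for t, y in zip(trajs, (10, 60, 110)):
            assert t.n_samples == 30
            np.testing.assert_allclose(t.y_px, y)
            np.testing.assert_allclose(np.diff(t.x_px), 8)
            assert not t.interpolated.any()

    def test_gap_bridging(self):
        rows = []
        for y in (10, 60, 110):
            for f, x, yy in straight_line_detections(30, x0=0, y0=y, vx=8, vy=0):
                if f in (14, 15):  # two consecutive missed frames
                    continue
                rows.append((f, x, yy))
        fs = make_frameset(rows, width=600, height=120)
        trajs = build_trajectories(fs, TrackParams(max_gap_frames=5))
        assert len(trajs) == 3
        for t in trajs:
            assert t.n_samples == 30  # gaps filled
            assert set(np.nonzero(t.interpolated)[0]) == {14, 15}
            np.testing.assert_allclose(np.diff(t.x_px), 8)  # linear interpolation

    def test_isolated_false_positives_pruned(self):
        rng = np.random.default_rng(3)
        rows = [
            (int(f), float(x), float(y))
            for f, x, y in zip(
                rng.choice(200, size=40, replace=False),
                rng.uniform(0, 600, 40),
                rng.uniform(0, 120, 40),
            )
        ]
        fs = make_frameset(rows, width=600, height=120)
        assert build_trajectories(fs, TrackParams(min_track_frames=13)) == []

    def test_min_track_frames_monotone(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(6):
            n = int(rng.integers(5, 40))
            rows += straight_line_detections(n, x0=0, y0=10 + 18 * i, vx=8, vy=0,
                                             start_frame=int(rng.integers(0, 20)))
        fs = make_frameset(rows, width=600, height=120)
        counts = [
            len(build_trajectories(fs, TrackParams(min_track_frames=k)))
            for k in (2, 5, 13, 20, 40)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_input_order_symmetry(self):
        rows = []
        for y in (10, 60, 110):
            rows += straight_line_detections(30, x0=0, y0=y, vx=8, vy=0)
        fs1 = make_frameset(rows, width=600, height=120)
        fs2 = make_frameset(rows[::-1], width=600, height=120)
        t1 = build_trajectories(fs1, P)
        t2 = build_trajectories(fs2, P)
        key = lambda t: (t.frames[0], t.x_px[0], t.y_px[0])
        s1 = sorted(((tuple(t.frames), tuple(t.x_px), tuple(t.y_px)) for t in t1))
        s2 = sorted(((tuple(t.frames), tuple(t.x_px), tuple(t.y_px)) for t in t2))
        assert s1 == s2

    def test_empty_frameset(self):
        fs = make_frameset([], width=600, height=120)
        assert build_trajectories(fs, P) == []


class TestExtractCues:
    def test_interior_termination_cue(self, cfg):
        # one full crossing plus one track that dies mid-view
        rows = straight_line_detections(76, x0=0, y0=20, vx=8, vy=0)
        rows += straight_line_detections(20, x0=0, y0=100, vx=8, vy=0)
        fs = make_frameset(rows, width=600, height=120)
        trajs = build_trajectories(fs, P)
        cues = extract_cues(fs, trajs, cfg, P)
        interior = [c for c in cues if c.cue_type == "interior_termination"]
        assert len(interior) >= 1
        assert any(abs(c.x_px - 8 * 19) < 1 and c.frame == 19 for c in interior)

    def test_crossing_yields_ambiguity_cue(self, cfg):
        # symmetric X-crossing: swap and identity matchings cost the same at
        # the crossing frame, so the match margin collapses
        rows = straight_line_detections(31, x0=0, y0=0, vx=8, vy=4)
        rows += straight_line_detections(31, x0=0, y0=120, vx=8, vy=-4)
        fs = make_frameset(rows, width=600, height=120)
        trajs = build_trajectories(fs, P)
        cues = extract_cues(fs, trajs, cfg, P)
        amb = [c for c in cues if c.cue_type == "ambiguity"]
        assert len(amb) >= 1
        assert any(abs(c.frame - 15) <= 2 for c in amb)

    def test_homogeneous_scene_no_speed_cues(self, cfg):
        rows = []
        for y in (20, 60, 100):
            rows += straight_line_detections(76, x0=0, y0=y, vx=8, vy=0)
        fs = make_frameset(rows, width=600, height=120)
        trajs = build_trajectories(fs, P)
        cues = extract_cues(fs, trajs, cfg, P)
        assert [c for c in cues if c.cue_type == "speed"] == []


class TestSelectTrainingFrames:
    def _fs(self):
        return make_frameset(straight_line_detections(50, 0, 60, 8, 0), 600, 120)

    def test_random_reproducible(self):
        fs = self._fs()
        a = select_training_frames(fs, [], 10, mode="random", seed=42)
        b = select_training_frames(fs, [], 10, mode="random", seed=42)
        assert a == b
        assert len(set(a)) == 10

    def test_hard_mode_ranks_cue_frames_first(self, cfg):
        from trailtrack.tracker import CueRecord

        fs = self._fs()
        cues = [CueRecord("speed", 10, 0, 0, 1.0)] * 3 + [CueRecord("speed", 11, 0, 0, 1.0)] * 2
        got = select_training_frames(fs, cues, 2, mode="hard")
        assert got == [10, 11]

    def test_hard_ties_broken_by_earliest(self):
        fs = self._fs()
        got = select_training_frames(fs, [], 3, mode="hard")
        assert got == [0, 1, 2]

    def test_n_zero(self):
        assert select_training_frames(self._fs(), [], 0, mode="random", seed=1) == []

    def test_n_too_large(self):
        with pytest.raises(ValueError):
            select_training_frames(self._fs(), [], 1000, mode="random", seed=1)
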