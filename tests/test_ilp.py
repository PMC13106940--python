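"""ILP tracker: hypothesis enumeration, cost forms, optimality, lineage.

The central check is oracle equivalence: on every instance small enough to
enumerate (up to 3 frames x 3 cells), the solver's objective must equal the
minimum over *all* feasible event selections, computed by exhaustive
recursion that never touches the solver or the hypothesis graph.
"""

import itertools
import math

import numpy as np
import pytest

from cytolink.calibration import lineage_summary
from cytolink.ctc_io import extract_detections
from cytolink.ilp import (
    CostWeights,
    check_flow_conservation,
    enumerate_hypotheses,
    event_cost,
    reconstruct_lineage,
    solve,
    track,
)

from conftest import make_detection


# ---------------------------------------------------------------------------
# independent brute-force oracle


def _pair_min_cost(A, B, w):
    """Minimum cost of covering frame pair (A -> B) by disjoint events.

    Every a in A must be consumed exactly once (disappear / transition /
    mitosis parent / fusion co-parent), every b in B at most once; leftover
    b's appear.  Pure recursion, independent of the hypothesis graph.
    """

    def near(x, y):
        return x.distance_to(y) <= w.dmax

    best = math.inf

    def rec(i, used_a, used_b, acc):
        nonlocal best
        if acc >= best:
            return
        if i == len(A):
            leftover = sum(w.wa for j in range(len(B)) if j not in used_b)
            best = min(best, acc + leftover)
            return
        if i in used_a:
            rec(i + 1, used_a, used_b, acc)
            return
        a = A[i]
        rec(i + 1, used_a | {i}, used_b, acc + w.wd)  # disappearance
        for j, b in enumerate(B):
            if j in used_b or not near(a, b):
                continue
            rec(
                i + 1,
                used_a | {i},
                used_b | {j},
                acc + event_cost("transition", (a, b), w),
            )
        for j, k in itertools.combinations(range(len(B)), 2):
            if j in used_b or k in used_b:
                continue
            if not (near(a, B[j]) and near(a, B[k])):
                continue
            rec(
                i + 1,
                used_a | {i},
                used_b | {j, k},
                acc + event_cost("mitosis", (a, B[j], B[k]), w),
            )
        for i2 in range(i + 1, len(A)):
            if i2 in used_a:
                continue
            for j, b in enumerate(B):
                if j in used_b or not (near(a, b) and near(A[i2], b)):
                    continue
                rec(
                    i + 1,
                    used_a | {i, i2},
                    used_b | {j},
                    acc + event_cost("fusion", (a, A[i2], b), w),
                )

    rec(0, frozenset(), frozenset(), 0.0)
    return best


def oracle_min_cost(detections, w):
    """Global optimum by summing independent frame-pair optima (appearance
    in the first frame and disappearance in the last cost nothing)."""
    return sum(
        _pair_min_cost(detections[t], detections[t + 1], w)
        for t in range(len(detections) - 1)
    )


def random_instance(rng, n_frames, max_cells):
    frames = []
    for t in range(n_frames):
        n = int(rng.integers(0, max_cells + 1))
        frames.append(
            [
                make_detection(
                    frame=t,
                    label=i + 1,
                    centroid=tuple(rng.uniform(0, 60, 2)),
                    area=float(rng.uniform(40, 160)),
                )
                for i in range(n)
            ]
        )
    return frames


# ---------------------------------------------------------------------------
# enumeration


class TestEnumerateHypotheses:
    def test_single_pair_candidate_count(self):
        dets = [
            [make_detection(0, 1, (10, 10))],
            [make_detection(1, 1, (10, 13))],
        ]
        g = enumerate_hypotheses(dets, CostWeights(dmax=50))
        kinds = [c.kind for c in g.candidates]
        assert kinds.count("transition") == 1
        assert kinds.count("appearance") == 2
        assert kinds.count("disappearance") == 2
        assert kinds.count("mitosis") == kinds.count("fusion") == 0

    def test_parent_with_two_nearby_daughters(self):
        dets = [
            [make_detection(0, 1, (50, 50), area=100)],
            [
                make_detection(1, 1, (47, 50), area=50),
                make_detection(1, 2, (53, 50), area=50),
            ],
        ]
        g = enumerate_hypotheses(dets, CostWeights(dmax=50))
        kinds = [c.kind for c in g.candidates]
        assert kinds.count("transition") == 2
        assert kinds.count("mitosis") == 1
        assert kinds.count("fusion") == 0

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 2), (3, 2), (2, 3), (4, 4)])
    def test_dense_pair_combinatorics(self, n, m):
        """All cells mutually within dmax: n*m transitions, n*C(m,2)
        mitoses, C(n,2)*m fusions."""
        dets = [
            [make_detection(0, i + 1, (10 + i, 10)) for i in range(n)],
            [make_detection(1, j + 1, (12 + j, 11)) for j in range(m)],
        ]
        g = enumerate_hypotheses(dets, CostWeights(dmax=50))
        kinds = [c.kind for c in g.candidates]
        assert kinds.count("transition") == n * m
        assert kinds.count("mitosis") == n * math.comb(m, 2)
        assert kinds.count("fusion") == math.comb(n, 2) * m

    def test_every_node_has_slacks(self):
        rng = np.random.default_rng(0)
        dets = random_instance(rng, 3, 3)
        g = enumerate_hypotheses(dets, CostWeights())
        for v in range(g.n_nodes):
            assert any(
                g.candidates[i].kind == "appearance" for i in g.incoming[v]
            )
            assert any(
                g.candidates[i].kind == "disappearance" for i in g.outgoing[v]
            )


class TestEventCost:
    w = CostWeights(wt=1.0, wm=5.0, wf=20.0, wa=20.0, wd=20.0, dmax=50.0)

    def test_stationary_transition_costs_zero(self):
        a = make_detection(0, 1, (10, 10), area=100)
        b = make_detection(1, 1, (10, 10), area=100)
        assert event_cost("transition", (a, b), self.w) == 0.0

    def test_transition_at_dmax_with_equal_areas_costs_wt(self):
        a = make_detection(0, 1, (0, 0), area=100)
        b = make_detection(1, 1, (0, 50), area=100)
        assert event_cost("transition", (a, b), self.w) == pytest.approx(1.0)

    def test_perfect_split_costs_wm(self):
        p = make_detection(0, 1, (10, 10), area=100)
        d1 = make_detection(1, 1, (8, 10), area=50)
        d2 = make_detection(1, 2, (12, 10), area=50)
        assert event_cost("mitosis", (p, d1, d2), self.w) == pytest.approx(5.0)

    def test_perfect_merge_costs_wf(self):
        p1 = make_detection(0, 1, (8, 10), area=50)
        p2 = make_detection(0, 2, (12, 10), area=50)
        c = make_detection(1, 1, (10, 10), area=100)
        assert event_cost("fusion", (p1, p2, c), self.w) == pytest.approx(20.0)

    def test_area_change_and_midpoint_offset_penalized(self):
        p = make_detection(0, 1, (10, 10), area=100)
        d1 = make_detection(1, 1, (8, 10), area=80)
        d2 = make_detection(1, 2, (14, 10), area=40)
        # midpoint (11, 10) offset 1 px; area ratio 1.2
        expected = 5.0 + 1.0 / 50.0 + 0.2
        assert event_cost("mitosis", (p, d1, d2), self.w) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# solving


class TestSolve:
    def test_single_transition_beats_slacks(self):
        dets = [
            [make_detection(0, 1, (10, 10))],
            [make_detection(1, 1, (10, 13))],
        ]
        g = enumerate_hypotheses(dets, CostWeights())
        sol = solve(g)
        assert check_flow_conservation(g, sol)
        assert {g.candidates[i].kind for i in sol.selected} == {
            "transition",
            "appearance",  # frame-0 appearance, cost 0
            "disappearance",  # last-frame disappearance, cost 0
        }
        assert sol.objective_value == pytest.approx(3 / 50)

    def test_split_selects_mitosis_over_appearance(self):
        dets = [
            [make_detection(0, 1, (50, 50), area=100)],
            [
                make_detection(1, 1, (47, 50), area=50),
                make_detection(1, 2, (53, 50), area=50),
            ],
        ]
        g = enumerate_hypotheses(dets, CostWeights(wt=1, wm=5, wa=20, wd=20))
        sol = solve(g)
        kinds = [g.candidates[i].kind for i in sol.selected]
        assert kinds.count("mitosis") == 1
        # brute force confirms optimality
        assert sol.objective_value == pytest.approx(
            oracle_min_cost(dets, g.weights)
        )

    def test_empty_second_frame_forces_disappearances(self):
        dets = [
            [make_detection(0, 1, (10, 10)), make_detection(0, 2, (30, 30))],
            [],
        ]
        g = enumerate_hypotheses(dets, CostWeights())
        sol = solve(g)
        kinds = [g.candidates[i].kind for i in sol.selected]
        assert kinds.count("disappearance") == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_instance(rng, int(rng.integers(1, 4)), 3)
        w = CostWeights(wt=1, wm=3, wf=6, wa=8, wd=8, dmax=45)
        g = enumerate_hypotheses(dets, w)
        sol = solve(g)
        assert check_flow_conservation(g, sol)
        assert sol.objective_value == pytest.approx(
            oracle_min_cost(dets, w), abs=1e-6
        )

    def test_mitosis_count_non_increasing_in_wm(self):
        rng = np.random.default_rng(5)
        dets = [
            [make_detection(0, i + 1, tuple(rng.uniform(0, 80, 2)), area=100) for i in range(3)],
            [make_detection(1, i + 1, tuple(rng.uniform(0, 80, 2)), area=55) for i in range(5)],
        ]
        counts = []
        for wm in (0.1, 1.0, 3.0, 10.0, 40.0):
            w = CostWeights(wm=wm, wf=50, wa=6, wd=6, dmax=120)
            g = enumerate_hypotheses(dets, w)
            sol = solve(g)
            counts.append(
                sum(1 for i in sol.selected if g.candidates[i].kind == "mitosis")
            )
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # the sweep actually spans regimes

    def test_objective_non_increasing_as_dmax_grows(self):
        rng = np.random.default_rng(3)
        dets = random_instance(rng, 3, 3)
        objs = []
        for dmax in (10.0, 25.0, 50.0, 100.0):
            w = CostWeights(dmax=dmax)
            objs.append(solve(enumerate_hypotheses(dets, w)).objective_value)
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))


# ---------------------------------------------------------------------------
# reconstruction


class TestReconstructLineage:
    def test_pure_transitions_give_full_length_tracks(self):
        dets = [
            [
                make_detection(t, 1, (10, 10 + 2 * t)),
                make_detection(t, 2, (60, 60 + 2 * t)),
            ]
            for t in range(5)
        ]
        lineage = track(dets, CostWeights())
        assert len(lineage.tracks) == 2
        assert all(t.length == 5 for t in lineage.tracks.values())

    def test_mitosis_reconstruction_links_parent(self):
        dets = [
            [make_detection(0, 1, (50, 50), area=100)],
            [
                make_detection(1, 1, (47, 50), area=50),
                make_detection(1, 2, (53, 50), area=50),
            ],
        ]
        lineage = track(dets, CostWeights())
        assert len(lineage.tracks) == 3
        assert lineage.n_mitosis == 1
        assert lineage.children_of(1) == [2, 3]

    def test_fusion_reconstruction_links_both_parents(self):
        dets = [
            [
                make_detection(0, 1, (47, 50), area=50),
                make_detection(0, 2, (53, 50), area=50),
            ],
            [make_detection(1, 1, (50, 50), area=100)],
        ]
        lineage = track(dets, CostWeights(wf=5))
        assert len(lineage.tracks) == 3
        merged = lineage.fusion_products()
        assert len(merged) == 1
        assert lineage.tracks[merged[0]].parents == (1, 2)

    def test_end_to_end_recovery_on_clean_synthetic(self, small_synth):
        """On clean synthetic masks the reconstructed lineage must equal the
        generator schedule exactly."""
        from cytolink.ilp import SYNTHETIC_PRESET

        gt = lineage_summary(small_synth.gt_lineage)
        got = lineage_summary(track(small_synth.stack, SYNTHETIC_PRESET))
        assert got.total_tracks == gt.total_tracks
        assert got.mitosis_events == gt.mitosis_events
        assert got.fusion_events == gt.fusion_events
        assert got.mean_track_length == pytest.approx(gt.mean_track_length)

    def test_deterministic_across_runs(self, small_synth):
        dets = extract_detections(small_synth.stack)
        w = CostWeights()
        a = track(dets, w)
        b = track(dets, w)
        key = lambda lin: [
            (t.track_id, t.frame_begin, t.frame_end, t.parents)
            for t in lin.tracks.values()
        ]
        assert key(a) == key(b)
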