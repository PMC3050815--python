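"""Stereo correspondence by min-cut: graph construction and optimality."""

from itertools import product

import numpy as np
import pytest

from shimmer3d.matching import (
    CorrespondenceProblem,
    SlotCandidate,
    assignment_energy,
    build_match_graph,
    candidate_costs,
    default_neighbour_graph,
    patch_ncc,
    solve_from_costs,
    solve_matching,
)
from shimmer3d.segmentation import Detection


def det(u, v):
    return Detection((u, v), 0.0, 1.0, 1.0)


def enumerate_minimum(problem, costs, neighbours):
    """Independent oracle: exhaustive search over all slot labellings."""
    ps = sorted(costs)
    best = (np.inf, None)
    for labels in product(range(problem.n_slots + 1), repeat=len(ps)):
        lab = dict(zip(ps, labels))
        e = assignment_energy(problem, costs, lab, neighbours)
        if e < best[0] - 1e-12:
            best = (e, lab)
    return best


def random_problem(rng, n_left=6, n_slots=3, lam=0.3):
    left = [det(rng.uniform(0, 200), rng.uniform(0, 200)) for _ in range(n_left)]
    right = []  # costs injected directly
    nb = default_neighbour_graph(left)
    problem = CorrespondenceProblem(
        left,
        right,
        n_slots=n_slots,
        lam=lam,
        occlusion_cost=float(rng.uniform(0.3, 0.9)),
        neighbour_graph=nb,
    )
    costs = {}
    n_right = 0
    for p in range(n_left):
        slots = []
        for j in range(n_slots):
            if rng.random() < 0.7:
                # right candidates may be shared between chains
                share = n_right > 0 and rng.random() < 0.2
                idx = int(rng.integers(0, n_right)) if share else n_right
                if not share:
                    n_right += 1
                slots.append(SlotCandidate(idx, float(rng.uniform(0, 1.2)), float(j)))
            else:
                slots.append(None)
        costs[p] = slots
    return problem, costs, nb


class TestCandidateCosts:
    def test_identical_patches_cost_zero(self, rng):
        img = (rng.random((80, 120)) * 255).astype(float)
        left = [det(40, 40)]
        right = [det(40, 40)]
        problem = CorrespondenceProblem(left, right, disparity_range=(-50, 50))
        costs = candidate_costs(problem, img, img)
        cands = [c for c in costs[0] if c is not None]
        assert len(cands) == 1
        assert cands[0].cost == pytest.approx(0.0, abs=1e-12)

    def test_row_tolerance_excludes_candidates(self, rng):
        img = rng.random((80, 120))
        problem = CorrespondenceProblem(
            [det(40, 40)], [det(38, 45)], row_tol=2.0, disparity_range=(-50, 50)
        )
        costs = candidate_costs(problem, img, img)
        assert all(c is None for c in costs[0])

    def test_costs_equal_direct_ncc(self, rng):
        img_l = rng.random((100, 140)) * 255
        img_r = rng.random((100, 140)) * 255
        left = [det(30 + 15 * i, 50) for i in range(5)]
        right = [det(28 + 15 * i, 50) for i in range(5)]
        problem = CorrespondenceProblem(left, right, disparity_range=(-40, 40))
        costs = candidate_costs(problem, img_l, img_r)
        for p, slots in costs.items():
            for cand in slots:
                if cand is None:
                    continue
                ul, vl = left[p].thorax
                ur, vr = right[cand.right_index].thorax
                pl = img_l[int(vl) - 10 : int(vl) + 10, int(ul) - 10 : int(ul) + 10]
                pr = img_r[int(vr) - 10 : int(vr) + 10, int(ur) - 10 : int(ur) + 10]
                assert cand.cost == pytest.approx(1.0 - patch_ncc(pl, pr), abs=1e-12)


class TestMatchGraph:
    def test_single_chain_selects_candidate_iff_cheaper_than_occlusion(self):
        for cost, expect_match in ((0.2, True), (0.9, False)):
            problem = CorrespondenceProblem(
                [det(0, 0)], [det(0, 0)], n_slots=3, occlusion_cost=0.6, neighbour_graph=[]
            )
            costs = {0: [SlotCandidate(0, cost, 0.0), None, None]}
            sol = solve_from_costs(problem, costs)
            assert (len(sol.pairs) == 1) == expect_match
            e_min, _ = enumerate_minimum(problem, costs, [])
            assert sol.cut_energy == pytest.approx(e_min, abs=1e-9)

    def test_zero_lambda_gives_zero_n_links(self):
        problem = CorrespondenceProblem(
            [det(0, 0), det(10, 0)], [], lam=0.0, neighbour_graph=[(0, 1)]
        )
        costs = {0: [None] * 3, 1: [None] * 3}
        mg = build_match_graph(problem, costs)
        n_links = [
            d["capacity"]
            for a, b, d in mg.graph.edges(data=True)
            if isinstance(a, tuple) and isinstance(b, tuple) and a[0] != b[0]
        ]
        assert n_links == []

    def test_smoothness_breaks_tie_towards_equal_slots(self):
        """Two neighbouring chains with equal-cost candidates one slot apart:
        the n-links make the common-slot assignment strictly cheaper."""
        problem = CorrespondenceProblem(
            [det(0, 0), det(10, 0)],
            [],
            n_slots=2,
            lam=0.3,
            occlusion_cost=0.9,
            neighbour_graph=[(0, 1)],
        )
        costs = {
            0: [SlotCandidate(0, 0.4, 0.0), None],
            1: [SlotCandidate(1, 0.4, 0.0), SlotCandidate(2, 0.4, 1.0)],
        }
        sol = solve_from_costs(problem, costs)
        assert sol.labels == {0: 1, 1: 1}
        e_min, lab = enumerate_minimum(problem, costs, [(0, 1)])
        assert sol.cut_energy == pytest.approx(e_min, abs=1e-9)

    def test_min_cut_equals_exhaustive_enumeration(self, rng):
        """The cut value and labelling attain the exhaustive minimum on 50
        random problems (<= 8 chains, M = 3)."""
        for k in range(50):
            n_left = int(rng.integers(2, 9))
            problem, costs, nb = random_problem(rng, n_left=n_left)
            sol = solve_from_costs(problem, costs)
            e_min, _ = enumerate_minimum(problem, costs, nb)
            assert sol.cut_energy == pytest.approx(e_min, abs=1e-9), f"instance {k}"
            e_raw = assignment_energy(problem, costs, sol.raw_labels, nb)
            assert e_raw == pytest.approx(sol.cut_energy, abs=1e-9)

    def test_energy_not_worse_than_greedy(self, rng):
        for _ in range(20):
            problem, costs, nb = random_problem(rng, n_left=7)
            sol = solve_from_costs(problem, costs)
            greedy = {}
            for p, slots in costs.items():
                options = [(problem.occlusion_cost, 0)] + [
                    (c.cost, j + 1) for j, c in enumerate(slots) if c is not None
                ]
                greedy[p] = min(options)[1]
            e_greedy = assignment_energy(problem, costs, greedy, nb)
            assert sol.cut_energy <= e_greedy + 1e-9

    def test_all_occluded_without_right_detections(self):
        left = [det(10 * i, 0) for i in range(5)]
        problem = CorrespondenceProblem(left, [], occlusion_cost=0.6, neighbour_graph=[])
        costs = {p: [None] * 3 for p in range(5)}
        sol = solve_from_costs(problem, costs)
        assert sol.pairs == []
        assert sol.unmatched_left == list(range(5))
        assert sol.cut_energy == pytest.approx(5 * 0.6, abs=1e-9)

    def test_infinite_smoothness_locks_one_slot_on_rigid_scene(self, rng):
        """With lambda -> inf and uniform true disparity, every matched pair
        occupies the same disparity slot."""
        n = 6
        problem = CorrespondenceProblem(
            [det(30 * i, 0) for i in range(n)],
            [],
            n_slots=3,
            lam=1e6,
            occlusion_cost=5.0,  # force matches
            neighbour_graph=[(i, i + 1) for i in range(n - 1)],
        )
        costs = {}
        for p in range(n):
            slots = [SlotCandidate(p * 3 + j, float(rng.uniform(0.1, 0.9)), float(j)) for j in range(3)]
            costs[p] = slots
        sol = solve_from_costs(problem, costs)
        labels = set(sol.labels.values())
        assert len(labels) == 1


class TestOneToOne:
    def test_output_one_to_one_and_row_consistent(self, rng):
        """Across 100 random synthetic problems, no right detection is used
        twice and all pairs obey the row tolerance."""
        for _ in range(100):
            n_l, n_r = int(rng.integers(1, 10)), int(rng.integers(0, 10))
            left = [det(rng.uniform(0, 300), rng.uniform(0, 100)) for _ in range(n_l)]
            right = [det(rng.uniform(0, 300), rng.uniform(0, 100)) for _ in range(n_r)]
            img = rng.random((120, 340)) * 255
            problem = CorrespondenceProblem(left, right, disparity_range=(-80, 80))
            sol = solve_matching(problem, img, img)
            rights = [i for _, i in sol.pairs]
            lefts = [p for p, _ in sol.pairs]
            assert len(set(rights)) == len(rights)
            assert len(set(lefts)) == len(lefts)
            for p, i in sol.pairs:
                assert abs(left[p].thorax[1] - right[i].thorax[1]) <= problem.row_tol
                assert (
                    problem.disparity_range[0]
                    <= left[p].thorax[0] - right[i].thorax[0]
                    <= problem.disparity_range[1]
                )
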