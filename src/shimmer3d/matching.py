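"""One-to-one stereo correspondence of detections by discrete energy minimization.

Because the rectified views show rows of near-identical bees, greedy
best-correlation matching is ambiguous.  Matching is therefore posed as a
labelling problem: each left-image detection p chooses one of M disparity
slots (an interval of the admissible disparity range holding at most one
right-image candidate) or the occlusion label, minimising

    E(d) = E_data(d) + lambda * E_smooth(d)

where the data term is 1 - NCC of the 20x20 thorax patches (or a constant
occlusion penalty Ct0) and the smoothness term penalises neighbouring left
detections that choose different slots, Cn = lambda * |slot difference|.

The energy is minimised exactly by a minimum s-t cut on a layered graph: one
chain of M slot nodes per left detection from source to sink, infinite
reverse arcs so each chain is cut exactly once, and per-level links of
capacity lambda between neighbouring chains realising the linear smoothness
cost.  Cutting a chain's t-link selects the slot above the cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay

from .segmentation import Detection


@dataclass
class CorrespondenceProblem:
    """Inputs of one frame-pair matching problem."""

    left: list[Detection]
    right: list[Detection]
    row_tol: float = 2.0
    disparity_range: tuple[float, float] = (-134.0, 134.0)
    n_slots: int = 3
    lam: float = 0.3
    occlusion_cost: float = 0.6
    patch_px: int = 20
    neighbour_graph: list[tuple[int, int]] | None = None  # indices into left

    def __post_init__(self) -> None:
        if self.n_slots < 1:
            raise ValueError("n_slots must be >= 1")
        if self.disparity_range[0] >= self.disparity_range[1]:
            raise ValueError("disparity range must be an increasing interval")


@dataclass
class SlotCandidate:
    right_index: int
    cost: float
    disparity: float


@dataclass
class MatchGraph:
    graph: nx.DiGraph
    n_slots: int
    chains: list[int]  # left indices with a chain in the graph


@dataclass
class CorrespondenceSet:
    """One-to-one left-right pairing for one frame."""

    pairs: list[tuple[int, int]]  # (left index, right index)
    disparities: dict[tuple[int, int], float]
    costs: dict[tuple[int, int], float]
    unmatched_left: list[int]
    unmatched_right: list[int]
    labels: dict[int, int]  # left index -> slot label (0 = occluded)
    raw_labels: dict[int, int]  # labels read off the cut, before one-to-one
    cut_energy: float  # min-cut value = optimal labelling energy
    energy: float  # energy of the returned (one-to-one) assignment


def patch_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """NCC of two equal-size patches; 0 if either has zero variance."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _extract_patch(img: np.ndarray, uv: tuple[float, float], size: int) -> np.ndarray | None:
    u, v = int(round(uv[0])), int(round(uv[1]))
    half = size // 2
    v0, u0 = v - half, u - half
    if v0 < 0 or u0 < 0 or v0 + size > img.shape[0] or u0 + size > img.shape[1]:
        return None
    return img[v0 : v0 + size, u0 : u0 + size]


def default_neighbour_graph(left: list[Detection], prune_factor: float = 3.0) -> list[tuple[int, int]]:
    """Delaunay triangulation of the left thoraces, pruned at
    ``prune_factor`` times the median edge length."""
    if len(left) < 3:
        return [(i, j) for i, j in combinations(range(len(left)), 2)]
    pts = np.array([d.thorax for d in left])
    try:
        tri = Delaunay(pts)
    except Exception:
        return []
    edges = set()
    for simplex in tri.simplices:
        for i, j in combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    edges = sorted(edges)
    lengths = np.array([np.linalg.norm(pts[i] - pts[j]) for i, j in edges])
    if len(lengths) == 0:
        return []
    cut = prune_factor * np.median(lengths)
    return [e for e, L in zip(edges, lengths) if L <= cut]


def candidate_costs(
    problem: CorrespondenceProblem, img_l: np.ndarray, img_r: np.ndarray
) -> dict[int, list[SlotCandidate | None]]:
    """Per left detection, the best right candidate of each disparity slot.

    A right detection i is a candidate of left detection p when their rows
    agree within ``row_tol`` and the disparity u_p - u_i lies in the
    admissible range.  Its data cost is 1 - NCC of the two thorax patches.
    Candidates are binned into the M equal-width disparity slots; each slot
    keeps its lowest-cost candidate.
    """
    d_min, d_max = problem.disparity_range
    M = problem.n_slots
    width = (d_max - d_min) / M
    out: dict[int, list[SlotCandidate | None]] = {}
    for p, dl in enumerate(problem.left):
        slots: list[SlotCandidate | None] = [None] * M
        patch_l = _extract_patch(img_l, dl.thorax, problem.patch_px)
        for i, dr in enumerate(problem.right):
            if abs(dl.thorax[1] - dr.thorax[1]) > problem.row_tol:
                continue
            disp = dl.thorax[0] - dr.thorax[0]
            if not d_min <= disp <= d_max:
                continue
            patch_r = _extract_patch(img_r, dr.thorax, problem.patch_px)
            if patch_l is None or patch_r is None:
                cost = 1.0  # border patch: neutral similarity
            else:
                cost = 1.0 - patch_ncc(patch_l, patch_r)
            slot = min(int((disp - d_min) / width), M - 1)
            cur = slots[slot]
            if cur is None or cost < cur.cost:
                slots[slot] = SlotCandidate(i, cost, disp)
        out[p] = slots
    return out


def _theta(problem: CorrespondenceProblem, slots, label: int) -> float:
    """Cost of assigning one chain the given label (0 = occluded)."""
    if label == 0:
        return problem.occlusion_cost
    cand = slots[label - 1]
    return problem.occlusion_cost if cand is None else cand.cost


def assignment_energy(
    problem: CorrespondenceProblem,
    costs: dict[int, list[SlotCandidate | None]],
    labels: dict[int, int],
    neighbours: list[tuple[int, int]],
) -> float:
    """E_data + lambda * E_smooth of a labelling (slot labels, 0 = occluded)."""
    e = sum(_theta(problem, costs[p], labels[p]) for p in costs)
    e += problem.lam * sum(abs(labels[p] - labels[q]) for p, q in neighbours)
    return float(e)


def build_match_graph(
    problem: CorrespondenceProblem,
    costs: dict[int, list[SlotCandidate | None]],
    neighbours: list[tuple[int, int]] | None = None,
) -> MatchGraph:
    """Layered min-cut graph encoding the labelling energy.

    Chain for left detection p: source -> w_{p,1} -> ... -> w_{p,M} -> sink.
    The arc entering w_{p,1} carries the occlusion penalty Ct0(p); the arc
    leaving w_{p,j} carries Ct(p, j) (the slot-j candidate's data cost, or
    Ct0 for an empty slot).  Infinite reverse arcs keep the source side of
    any finite cut a prefix of each chain, so cut position == label.
    Neighbouring chains are tied level-by-level with capacity-lambda arcs in
    both directions, charging lambda per level of slot disagreement.
    """
    if neighbours is None:
        neighbours = problem.neighbour_graph
        if neighbours is None:
            neighbours = default_neighbour_graph(problem.left)
    M = problem.n_slots
    G = nx.DiGraph()
    chains = sorted(costs)
    for p in chains:
        slots = costs[p]
        nodes = ["s"] + [(p, j) for j in range(1, M + 1)] + ["t"]
        for j in range(M + 1):
            G.add_edge(nodes[j], nodes[j + 1], capacity=_theta(problem, slots, j))
            if 1 <= j:  # infinite reverse arc within the chain
                G.add_edge(nodes[j + 1], nodes[j], capacity=math.inf)
    if problem.lam > 0:
        for p, q in neighbours:
            for j in range(1, M + 1):
                G.add_edge((p, j), (q, j), capacity=problem.lam)
                G.add_edge((q, j), (p, j), capacity=problem.lam)
    return MatchGraph(G, M, chains)


def solve_matching(
    problem: CorrespondenceProblem,
    img_l: np.ndarray,
    img_r: np.ndarray,
) -> CorrespondenceSet:
    """Match left and right detections of one rectified frame pair.

    Runs candidate search, builds the layered graph, takes its minimum cut,
    reads slot labels off the cut, and enforces one-to-one use of right
    detections (conflicts keep the lower data cost; losers become occluded).
    """
    costs = candidate_costs(problem, img_l, img_r)
    return solve_from_costs(problem, costs)


def solve_from_costs(
    problem: CorrespondenceProblem,
    costs: dict[int, list[SlotCandidate | None]],
) -> CorrespondenceSet:
    """Minimum-cut labelling and one-to-one resolution of a cost table."""
    neighbours = problem.neighbour_graph
    if neighbours is None:
        neighbours = default_neighbour_graph(problem.left)
    labels: dict[int, int] = {}
    if costs:
        mg = build_match_graph(problem, costs, neighbours)
        cut_value, (src_side, _) = nx.minimum_cut(mg.graph, "s", "t")
        src_side = set(src_side)
        for p in mg.chains:
            label = 0
            for j in range(1, problem.n_slots + 1):
                if (p, j) in src_side:
                    label = j
            labels[p] = label
        cut_energy = float(cut_value)
    else:
        cut_energy = 0.0

    # realize labels as pairs; resolve right-candidate conflicts by data cost
    chosen: dict[int, tuple[int, float, float]] = {}  # p -> (right, cost, disp)
    for p, label in labels.items():
        if label == 0:
            continue
        cand = costs[p][label - 1]
        if cand is None:
            continue
        chosen[p] = (cand.right_index, cand.cost, cand.disparity)
    by_right: dict[int, list[int]] = {}
    for p, (i, cost, _) in chosen.items():
        by_right.setdefault(i, []).append(p)
    final_labels = dict(labels)
    for i, ps in by_right.items():
        if len(ps) > 1:
            ps.sort(key=lambda p: (chosen[p][1], p))
            for loser in ps[1:]:
                del chosen[loser]
                final_labels[loser] = 0

    pairs = sorted((p, chosen[p][0]) for p in chosen)
    disparities = {(p, i): chosen[p][2] for p, i in pairs}
    pair_costs = {(p, i): chosen[p][1] for p, i in pairs}
    matched_r = {i for _, i in pairs}
    unmatched_left = sorted(set(range(len(problem.left))) - set(chosen))
    unmatched_right = sorted(set(range(len(problem.right))) - matched_r)
    energy = assignment_energy(problem, costs, final_labels, neighbours) if costs else 0.0
    return CorrespondenceSet(
        pairs=pairs,
        disparities=disparities,
        costs=pair_costs,
        unmatched_left=unmatched_left,
        unmatched_right=unmatched_right,
        labels=final_labels,
        raw_labels=labels,
        cut_energy=cut_energy,
        energy=energy,
    )
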