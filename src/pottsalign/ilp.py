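"""Integer-linear-programming alignment of two Potts models.

An alignment of models A (length L_A) and B (length L_B) is a strictly
increasing set of matched position pairs — an *increasing path* through the
L_A×L_B grid of candidate match nodes i.k.  Binary node variables x_ik select
matches; binary edge variables y_ikjl (for i<j, k<l) activate the coupling
similarity term of every matched pair of pairs; the objective

    max  Σ s_v(i,k)·x_ik + α_w·Σ s_w(i,j,k,l)·y_ikjl − gap costs

is solved exactly (or to a certified relative gap ε) by branch-and-bound
(HiGHS via scipy).  Constraints tie y to x through antichain ("mutually
contradicting") node sets per row and column, force y on when both endpoints
of a negative-score edge are matched, and keep the selected nodes on an
increasing path.  Affine gap costs are charged on consecutive-match arcs of
a unit source→sink flow over the selected nodes.

The module also carries two independent oracles used to verify the solver:
exhaustive enumeration (``brute_force_align``) and the affine-gap dynamic
program over match predecessors (``dp_align_independent``), exact when
couplings are ignored.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .alphabet import background_frequencies
from .inference import background_field_v0
from .model import PottsModel
from .scoring import AlignConfig, ScoreTables, build_score_tables

_SCORE_TOL = 1e-9


@dataclass
class AlignmentGraph:
    """The L_A×L_B grid graph of candidate matches.

    Nodes are (i, k); directed edges ((i, k), (j, l)) exist for i<j, k<l.
    ``row_set``/``col_set`` return the antichain node sets used by the ILP
    head/tail constraints: e.g. the heads in row j reachable from (i, k)
    mutually contradict because no two nodes of one row lie on a common
    increasing path.
    """

    L_A: int
    L_B: int

    def __post_init__(self) -> None:
        if self.L_A < 1 or self.L_B < 1:
            raise ValueError("grid dimensions must be ≥ 1")

    @property
    def n_nodes(self) -> int:
        return self.L_A * self.L_B

    @property
    def n_edges(self) -> int:
        return (self.L_A * (self.L_A - 1) // 2) * (self.L_B * (self.L_B - 1) // 2)

    def edges(self):
        """Edges as (i, j, k, l): tail node (i, k), head node (j, l)."""
        for i, j in itertools.combinations(range(self.L_A), 2):
            for k, l in itertools.combinations(range(self.L_B), 2):
                yield (i, j, k, l)

    def row_set(self, i: int, k: int, j: int) -> list[tuple[int, int]]:
        """Antichain in row j of edge endpoints sharing node (i, k)."""
        if j > i:
            return [(j, l) for l in range(k + 1, self.L_B)]
        if j < i:
            return [(j, l) for l in range(0, k)]
        raise ValueError("j must differ from i")

    def col_set(self, i: int, k: int, l: int) -> list[tuple[int, int]]:
        """Antichain in column l of edge endpoints sharing node (i, k)."""
        if l > k:
            return [(j, l) for j in range(i + 1, self.L_A)]
        if l < k:
            return [(j, l) for j in range(0, i)]
        raise ValueError("l must differ from k")


def build_alignment_graph(L_A: int, L_B: int) -> AlignmentGraph:
    return AlignmentGraph(L_A=L_A, L_B=L_B)


@dataclass
class Alignment:
    """Strictly increasing matched pairs (0-based) with score bookkeeping."""

    pairs: list[tuple[int, int]]
    score: float
    gap_cost_paid: float = 0.0

    def __post_init__(self) -> None:
        for (i, k), (j, l) in zip(self.pairs, self.pairs[1:]):
            if not (i < j and k < l):
                raise ValueError("alignment pairs must be strictly increasing")

    @property
    def n_aligned(self) -> int:
        return len(self.pairs)


@dataclass
class SolverResult:
    """Solver outcome with the optimality-gap certificate."""

    alignment: Alignment
    upper_bound: float
    lower_bound: float
    relative_gap: float
    status: str                      # optimal | epsilon_optimal | timeout | infeasible
    tables: ScoreTables | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# gap model

def arc_gap_cost(i: int, k: int, j: int, l: int, gap_open: float,
                 gap_extend: float) -> float:
    """Cost of the gap segments between consecutive matches (i,k) and (j,l).

    Skipping positions on either side opens one segment (gap_open) plus
    gap_extend per skipped position; with the trained gap_extend = 0 this is
    gap_open per gap segment.
    """
    cost = 0.0
    if j > i + 1:
        cost += gap_open + gap_extend * (j - i - 1)
    if l > k + 1:
        cost += gap_open + gap_extend * (l - k - 1)
    return cost


def _lead_gap_cost(i: int, k: int, config: AlignConfig) -> float:
    if config.free_end_gaps:
        return 0.0
    cost = 0.0
    if i > 0:
        cost += config.gap_open + config.gap_extend * i
    if k > 0:
        cost += config.gap_open + config.gap_extend * k
    return cost


def _tail_gap_cost(i: int, k: int, L_A: int, L_B: int, config: AlignConfig) -> float:
    if config.free_end_gaps:
        return 0.0
    cost = 0.0
    if i < L_A - 1:
        cost += config.gap_open + config.gap_extend * (L_A - 1 - i)
    if k < L_B - 1:
        cost += config.gap_open + config.gap_extend * (L_B - 1 - k)
    return cost


def _empty_gap_cost(L_A: int, L_B: int, config: AlignConfig) -> float:
    if config.free_end_gaps:
        return 0.0
    return 2 * config.gap_open + config.gap_extend * (L_A + L_B)


def total_gap_cost(pairs: list[tuple[int, int]], L_A: int, L_B: int,
                   config: AlignConfig) -> float:
    """Affine gap cost of an alignment under the arc decomposition."""
    if not pairs:
        return _empty_gap_cost(L_A, L_B, config)
    cost = _lead_gap_cost(*pairs[0], config)
    for (i, k), (j, l) in zip(pairs, pairs[1:]):
        cost += arc_gap_cost(i, k, j, l, config.gap_open, config.gap_extend)
    cost += _tail_gap_cost(*pairs[-1], L_A, L_B, config)
    return cost


def score_alignment(pairs: list[tuple[int, int]], tables: ScoreTables,
                    config: AlignConfig) -> float:
    """Re-evaluate the full objective (fields + α_w·couplings − gaps) of a pair list."""
    sv = sum(tables.sv[i, k] for i, k in pairs)
    sw = 0.0
    for (i, k), (j, l) in itertools.combinations(pairs, 2):
        sw += tables.sw.get((i, j, k, l), 0.0)
    return float(sv + config.alpha_w * sw
                 - total_gap_cost(pairs, tables.L_A, tables.L_B, config))


# ---------------------------------------------------------------------------
# oracles

def brute_force_align(tables: ScoreTables, config: AlignConfig) -> Alignment:
    """Exhaustive enumeration of every increasing pair set (L_A, L_B ≤ 8).

    Ties are broken by fewest pairs, then lexicographically smallest pair
    list — the canonical tie rule for reproducibility.
    """
    L_A, L_B = tables.L_A, tables.L_B
    if L_A > 8 or L_B > 8:
        raise ValueError("brute force restricted to L_A, L_B ≤ 8")
    best_pairs: list[tuple[int, int]] = []
    best_score = score_alignment([], tables, config)
    n_max = min(L_A, L_B)
    for n in range(1, n_max + 1):
        for rows in itertools.combinations(range(L_A), n):
            for cols in itertools.combinations(range(L_B), n):
                pairs = list(zip(rows, cols))
                s = score_alignment(pairs, tables, config)
                if s > best_score + _SCORE_TOL:
                    best_score, best_pairs = s, pairs
                elif abs(s - best_score) <= _SCORE_TOL:
                    if (len(pairs), pairs) < (len(best_pairs), best_pairs) \
                            and best_pairs:
                        best_pairs = pairs
    return Alignment(pairs=best_pairs, score=best_score,
                     gap_cost_paid=total_gap_cost(best_pairs, L_A, L_B, config))


def dp_align_independent(sv: np.ndarray, gap_open: float = 13.0,
                         gap_extend: float = 0.0,
                         free_end_gaps: bool = True) -> Alignment:
    """Optimal affine-gap alignment of a positional score matrix.

    Exact dynamic program over match predecessors: E(i,k) is the best score
    of an alignment whose last match is (i,k), recursed over every earlier
    match (i',k') with the arc gap cost between them.  This is term-for-term
    the gap model the ILP charges, so with α_w = 0 the two scores coincide.
    Quadratic in the number of grid cells — an oracle, not a production
    aligner.
    """
    sv = np.asarray(sv, dtype=float)
    L_A, L_B = sv.shape
    cfg = AlignConfig(gap_open=gap_open, gap_extend=gap_extend,
                      offset_gamma=0.0, free_end_gaps=free_end_gaps)
    E = np.full((L_A, L_B), -np.inf)
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    for i in range(L_A):
        for k in range(L_B):
            best, arg = -_lead_gap_cost(i, k, cfg), None
            for ip in range(i):
                for kp in range(k):
                    cand = E[ip, kp] - arc_gap_cost(ip, kp, i, k,
                                                    gap_open, gap_extend)
                    if cand > best + _SCORE_TOL:
                        best, arg = cand, (ip, kp)
            E[i, k] = best + sv[i, k]
            back[(i, k)] = arg
    best_score = -_empty_gap_cost(L_A, L_B, cfg)
    best_end: tuple[int, int] | None = None
    for i in range(L_A):
        for k in range(L_B):
            cand = E[i, k] - _tail_gap_cost(i, k, L_A, L_B, cfg)
            if cand > best_score + _SCORE_TOL:
                best_score, best_end = cand, (i, k)
    pairs: list[tuple[int, int]] = []
    node = best_end
    while node is not None:
        pairs.append(node)
        node = back[node]
    pairs.reverse()
    return Alignment(pairs=pairs, score=float(best_score),
                     gap_cost_paid=total_gap_cost(pairs, L_A, L_B, cfg))


# ---------------------------------------------------------------------------
# ILP construction and solve

class _ILPInstance:
    """Variable layout and constraint matrix for one alignment problem."""

    def __init__(self, graph: AlignmentGraph, tables: ScoreTables,
                 config: AlignConfig):
        if (graph.L_A, graph.L_B) != (tables.L_A, tables.L_B):
            raise ValueError("score tables do not match the alignment graph")
        self.graph, self.tables, self.config = graph, tables, config
        L_A, L_B = graph.L_A, graph.L_B

        def node_id(i, k):
            return i * L_B + k

        self.node_id = node_id
        n_x = L_A * L_B
        # y variables only for edges carrying a (weighted) coupling score
        self.y_edges = [e for e in sorted(tables.sw)
                        if config.alpha_w * tables.sw[e] != 0.0]
        y_index = {e: n_x + t for t, e in enumerate(self.y_edges)}
        n_y = len(self.y_edges)

        # consecutive-match arcs for the affine gap flow
        arcs: list[tuple[int | None, int | None, float]] = []  # (tail, head, cost)
        for i in range(L_A):
            for k in range(L_B):
                nid = node_id(i, k)
                arcs.append((None, nid, _lead_gap_cost(i, k, config)))
                arcs.append((nid, None, _tail_gap_cost(i, k, L_A, L_B, config)))
        for (i, j, k, l) in graph.edges():
            arcs.append((node_id(i, k), node_id(j, l),
                         arc_gap_cost(i, k, j, l, config.gap_open,
                                      config.gap_extend)))
        arcs.append((None, None, _empty_gap_cost(L_A, L_B, config)))
        self.arcs = arcs
        n_z = len(arcs)
        self.n_x, self.n_y, self.n_z = n_x, n_y, n_z
        n_var = n_x + n_y + n_z

        # objective (maximization; milp minimizes -c)
        c = np.zeros(n_var)
        for i in range(L_A):
            for k in range(L_B):
                c[node_id(i, k)] = tables.sv[i, k]
        for e in self.y_edges:
            c[y_index[e]] = config.alpha_w * tables.sw[e]
        for t, (_, _, cost) in enumerate(arcs):
            c[n_x + n_y + t] = -cost
        self.c_max = c

        rows, cols, vals, lo, hi = [], [], [], [], []
        r = 0

        def add(coefs: list[tuple[int, float]], lb: float, ub: float):
            nonlocal r
            for cc, vv in coefs:
                rows.append(r)
                cols.append(cc)
                vals.append(vv)
            lo.append(lb)
            hi.append(ub)
            r += 1

        # (24)-(27): antichain constraints tying edges to their shared node
        tails_row: dict[tuple[int, int, int], list] = {}
        tails_col: dict[tuple[int, int, int], list] = {}
        heads_row: dict[tuple[int, int, int], list] = {}
        heads_col: dict[tuple[int, int, int], list] = {}
        for e in self.y_edges:
            i, j, k, l = e
            tails_row.setdefault((i, k, j), []).append(y_index[e])
            tails_col.setdefault((i, k, l), []).append(y_index[e])
            heads_row.setdefault((j, l, i), []).append(y_index[e])
            heads_col.setdefault((j, l, k), []).append(y_index[e])
        for group in (tails_row, tails_col, heads_row, heads_col):
            for (i, k, _), members in group.items():
                add([(m, 1.0) for m in members] + [(node_id(i, k), -1.0)],
                    -np.inf, 0.0)

        # (28): negative-score edges must activate when both endpoints do
        for e in self.y_edges:
            if config.alpha_w * tables.sw[e] < 0:
                i, j, k, l = e
                add([(node_id(i, k), 1.0), (node_id(j, l), 1.0),
                     (y_index[e], -1.0)], -np.inf, 1.0)

        # (29): increasing-path constraint
        for i in range(L_A):
            for k in range(L_B):
                coefs = [(node_id(i, l), 1.0) for l in range(k + 1)]
                coefs += [(node_id(j, k), 1.0) for j in range(i)]
                add(coefs, -np.inf, 1.0)

        # gap flow: unit source flow, conservation at every node
        in_arcs: dict[int, list[int]] = {n: [] for n in range(n_x)}
        out_arcs: dict[int, list[int]] = {n: [] for n in range(n_x)}
        source_out = []
        for t, (tail, head, _) in enumerate(arcs):
            zid = n_x + n_y + t
            if tail is None:
                source_out.append(zid)
            else:
                out_arcs[tail].append(zid)
            if head is not None:
                in_arcs[head].append(zid)
        add([(z, 1.0) for z in source_out], 1.0, 1.0)
        for n in range(n_x):
            add([(z, 1.0) for z in in_arcs[n]] + [(n, -1.0)], 0.0, 0.0)
            add([(z, 1.0) for z in out_arcs[n]] + [(n, -1.0)], 0.0, 0.0)

        self.A = csr_matrix((vals, (rows, cols)), shape=(r, n_var))
        self.lb = np.array(lo)
        self.ub = np.array(hi)
        self.n_var = n_var

    def solve(self, mip_rel_gap: float, time_limit: float):
        res = milp(
            c=-self.c_max,
            constraints=LinearConstraint(self.A, self.lb, self.ub),
            integrality=np.ones(self.n_var),
            bounds=Bounds(0, 1),
            options={"mip_rel_gap": mip_rel_gap, "time_limit": time_limit,
                     "presolve": True})
        return res

    def extract_pairs(self, x: np.ndarray) -> list[tuple[int, int]]:
        L_B = self.graph.L_B
        sel = [divmod(n, L_B) for n in range(self.n_x) if x[n] > 0.5]
        return sorted((int(i), int(k)) for i, k in sel)


def build_ilp(graph: AlignmentGraph, tables: ScoreTables,
              config: AlignConfig) -> _ILPInstance:
    """Assemble the ILP for one model pair (opaque instance handle)."""
    return _ILPInstance(graph, tables, config)


def solve_from_tables(tables: ScoreTables, config: AlignConfig | None = None
                      ) -> SolverResult:
    """Solve the alignment ILP for prebuilt score tables, to within ε."""
    config = config or AlignConfig()
    graph = build_alignment_graph(tables.L_A, tables.L_B)
    inst = build_ilp(graph, tables, config)
    denom = tables.self_score_A + tables.self_score_B

    deadline = time.monotonic() + config.time_limit_seconds
    # phase 1: let the solver stop early; accept if the ε certificate holds
    rel = config.epsilon if config.epsilon > 1e-9 else 0.0
    res = inst.solve(mip_rel_gap=rel,
                     time_limit=max(deadline - time.monotonic(), 1.0))
    result = _wrap_result(inst, res, denom, config)
    if result.status in ("optimal", "epsilon_optimal"):
        return result
    # phase 2: tighten to proven optimality within the remaining budget
    res = inst.solve(mip_rel_gap=0.0,
                     time_limit=max(deadline - time.monotonic(), 1.0))
    return _wrap_result(inst, res, denom, config)


def _wrap_result(inst: _ILPInstance, res, denom: float,
                 config: AlignConfig) -> SolverResult:
    if res.x is None:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    pairs = inst.extract_pairs(res.x)
    lb = float(-res.fun)
    ub = float(-res.mip_dual_bound) if res.mip_dual_bound is not None else lb
    ub = max(ub, lb)
    gap_abs = ub - lb
    if denom > 1e-12:
        relative_gap = 2.0 * gap_abs / denom
    else:
        relative_gap = 0.0 if gap_abs <= 1e-9 else float("inf")
    scale = max(1.0, abs(lb), abs(ub))
    if gap_abs <= 1e-7 * scale and res.status == 0:
        status = "optimal"
    elif relative_gap <= config.epsilon:
        status = "epsilon_optimal"
    else:
        status = "timeout"
    alignment = Alignment(
        pairs=pairs, score=lb,
        gap_cost_paid=total_gap_cost(pairs, inst.graph.L_A, inst.graph.L_B,
                                     config))
    return SolverResult(alignment=alignment, upper_bound=ub, lower_bound=lb,
                        relative_gap=relative_gap, status=status,
                        tables=inst.tables)


def solve_alignment(A: PottsModel, B: PottsModel,
                    config: AlignConfig | None = None,
                    v0: np.ndarray | None = None) -> SolverResult:
    """Align two Potts models (ε-certified optimum).

    ``v0`` is the background field subtracted before field comparison;
    by default it is derived from the standard amino-acid background for the
    models' alphabet (zero for uniform synthetic alphabets).
    """
    config = config or AlignConfig()
    if A.q != B.q or A.alphabet != B.alphabet:
        raise ValueError("models must share q and alphabet order")
    if v0 is None:
        v0 = background_field_v0(background_frequencies(A.alphabet))
    tables = build_score_tables(A, B, v0, config)
    return solve_from_tables(tables, config)


def independent_site_config(config: AlignConfig | None = None) -> AlignConfig:
    """The same hyperparameters with the coupling term switched off."""
    config = config or AlignConfig()
    return AlignConfig(alpha_w=0.0, gap_open=config.gap_open,
                       gap_extend=config.gap_extend,
                       offset_gamma=config.offset_gamma,
                       epsilon=config.epsilon,
                       w_norm_threshold=config.w_norm_threshold,
                       time_limit_seconds=config.time_limit_seconds,
                       free_end_gaps=config.free_end_gaps)
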