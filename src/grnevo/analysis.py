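"""Comparative statistics over GRN ensembles.

Implements the quantities used to contrast evolved genotypes with the
multicanonical reference ensemble at matched fitness:

* mutational robustness r -- the mean fitness after each of the K single-edge
  deletions -- and the essential-edge count (deletions dropping fitness below
  a threshold, 0.8 by default);
* bistability via hysteresis: warm-started up/down sweeps of the input I with
  a strict (dI = 0.001, x_th = 1e-6) or loose (dI = 0.01, x_th = 0.5)
  detection criterion, plus toggle / one-way / unswitchable subtyping from
  the saddle-node jumps inside the swept range;
* effective nodes (nodes with a directed path to the output), simple-path
  counts from input to output, and a signed motif census (auto- and mutual
  regulation, coherent feed-forward loops, positive feedback loops);
* sub-bin reweighting that matches the within-bin fitness distribution of
  evolved samples to the reference before comparing a statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from grnevo import _kernels
from grnevo.model import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    RegulatoryNetwork,
)
from grnevo.mucamc import FitnessBinning

__all__ = [
    "RobustnessResult",
    "BistabilityCriterion",
    "BistabilityReport",
    "MotifCounts",
    "STRICT",
    "LOOSE",
    "robustness",
    "essential_edge_count",
    "hysteresis_sweep",
    "classify_switch",
    "effective_node_count",
    "count_paths",
    "count_motifs",
    "reweight_histogram",
    "bistable_fraction",
]

ESSENTIAL_THRESHOLD = 0.8
PATH_CAP = 1_000_000
JUMP_THRESHOLD = 0.1


@dataclass
class RobustnessResult:
    """Per-edge deletion fitnesses f'_i and their mean r.

    r lies in [0, 1]; an edge is essential when its f' falls below the
    threshold, and ``essential_count`` is the number of such edges.
    """

    r: float
    per_edge_fitness: np.ndarray
    essential_count: int
    threshold: float = ESSENTIAL_THRESHOLD


@dataclass(frozen=True)
class BistabilityCriterion:
    """Hysteresis detection parameters: input increment and output gap."""

    delta_I: float = 0.001
    x_th: float = 1e-6

    def __post_init__(self) -> None:
        steps = round(1.0 / self.delta_I)
        if abs(steps * self.delta_I - 1.0) > 1e-9 or steps < 1:
            raise ValueError("delta_I must divide 1 evenly")
        if self.x_th <= 0:
            raise ValueError("x_th must be positive")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, round(1.0 / self.delta_I) + 1)


STRICT = BistabilityCriterion(delta_I=0.001, x_th=1e-6)
LOOSE = BistabilityCriterion(delta_I=0.01, x_th=0.5)


@dataclass
class BistabilityReport:
    """Hysteresis branches and the mono/bistable verdict.

    ``up_branch``/``down_branch`` hold the steady-state output at each grid
    input for the increasing and decreasing sweeps; ``max_gap`` is the
    largest pointwise difference, and the verdict is bistable exactly when it
    exceeds the criterion's output threshold.
    """

    criterion: BistabilityCriterion
    I_grid: np.ndarray
    up_branch: np.ndarray
    down_branch: np.ndarray
    max_gap: float
    verdict: str  # "monostable" | "bistable"
    subtype: str = "none"  # "toggle" | "one_way" | "unswitchable" | "none"
    nonconverged_points: int = 0

    @property
    def bistable(self) -> bool:
        return self.verdict == "bistable"


@dataclass(frozen=True)
class MotifCounts:
    """Signed local pattern census of one genotype.

    Pair patterns count unordered node pairs; the coherent feed-forward count
    is over ordered triples (j -> k -> i plus the direct j -> i with matching
    sign product); positive feedback loops are directed 3-cycles with sign
    product +1 (2-node positive loops appear under the mutual_* counts).
    """

    auto_activation: int = 0
    auto_repression: int = 0
    mutual_activation: int = 0
    mutual_repression: int = 0
    ffl_coherent: int = 0
    fbl_positive: int = 0
    mutual_activation_with_auto: int = 0
    mutual_repression_with_auto: int = 0


def robustness(
    net: RegulatoryNetwork,
    threshold: float = ESSENTIAL_THRESHOLD,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RobustnessResult:
    """Single-edge-deletion robustness r = (1/K) sum_i f'_i.

    Each f'_i is the fitness of the (K-1)-edge network with edge i removed
    and nothing added.
    """
    if net.n_edges < 1:
        raise ValueError("robustness requires at least one edge")
    p = net.params
    k = net.n_edges
    fprime = np.empty(k)
    mask = np.ones(k, dtype=bool)
    for i in range(k):
        mask[i] = False
        fprime[i] = _kernels.fitness_kernel(
            net.src[mask], net.dst[mask], net.sign[mask],
            p.n_nodes, p.beta, p.mu, p.output_index, tol, max_iter,
        )
        mask[i] = True
    return RobustnessResult(
        r=float(fprime.mean()),
        per_edge_fitness=fprime,
        essential_count=int((fprime < threshold).sum()),
        threshold=threshold,
    )


def essential_edge_count(
    net: RegulatoryNetwork,
    threshold: float = ESSENTIAL_THRESHOLD,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> int:
    """Number of edges whose single deletion drops fitness below threshold."""
    return robustness(net, threshold, tol, max_iter).essential_count


def hysteresis_sweep(
    net: RegulatoryNetwork,
    criterion: BistabilityCriterion = STRICT,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    classify: bool = True,
) -> BistabilityReport:
    """Up/down input sweeps with warm starts; bistable iff branches split.

    The up sweep starts from the spontaneous all-0.5 state at I = 0 and
    carries each converged state to the next grid input; the down sweep
    mirrors this from its own cold start at I = 1.  The genotype is bistable
    when the two branches differ by more than ``criterion.x_th`` anywhere on
    the grid.
    """
    p = net.params
    grid = criterion.grid
    up, down, bad = _kernels.hysteresis_kernel(
        net.src, net.dst, net.sign, p.n_nodes, p.beta, p.mu,
        p.output_index, grid, tol, max_iter,
    )
    gap = float(np.max(np.abs(up - down)))
    report = BistabilityReport(
        criterion=criterion,
        I_grid=grid,
        up_branch=up,
        down_branch=down,
        max_gap=gap,
        verdict="bistable" if gap > criterion.x_th else "monostable",
        nonconverged_points=int(bad),
    )
    if classify and report.bistable:
        report.subtype = classify_switch(report)
    return report


def classify_switch(
    report: BistabilityReport, jump_threshold: float = JUMP_THRESHOLD
) -> str:
    """Subtype a bistable genotype from its saddle-node jumps.

    A sweep "jumps" when the output changes by more than ``jump_threshold``
    between adjacent grid inputs strictly inside (0, 1).  Both sweeps jumping
    means both bifurcations lie in range (toggle); one jump is a one-way
    switch; no jump with split branches means both bifurcations sit outside
    the swept range (unswitchable).
    """
    if not report.bistable:
        raise ValueError("classify_switch requires a bistable report")
    up_jump = bool(np.any(np.abs(np.diff(report.up_branch)) > jump_threshold))
    down_jump = bool(np.any(np.abs(np.diff(report.down_branch)) > jump_threshold))
    if up_jump and down_jump:
        return "toggle"
    if up_jump or down_jump:
        return "one_way"
    return "unswitchable"


def _reverse_adjacency(net: RegulatoryNetwork) -> list[list[int]]:
    radj: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for s, d in zip(net.src.tolist(), net.dst.tolist()):
        radj[d].append(s)
    return radj


def effective_node_count(net: RegulatoryNetwork) -> int:
    """Nodes with at least one directed path to the output node.

    The output node itself counts (path of length zero), so a fully
    connected genotype scores N.
    """
    radj = _reverse_adjacency(net)
    out = net.params.output_index
    seen = {out}
    stack = [out]
    while stack:
        u = stack.pop()
        for v in radj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen)


def count_paths(
    net: RegulatoryNetwork, cap: int = PATH_CAP
) -> tuple[int, bool]:
    """Simple directed paths from the input node to the output node.

    Exhaustive DFS with a visited set (no node repeated).  Returns
    ``(count, saturated)``; counting stops once ``cap`` paths are found.
    Only nodes that can still reach the output are descended into, which
    prunes the search without changing the count.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    out = net.params.output_index
    start = net.params.input_index
    adj: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for s, d in zip(net.src.tolist(), net.dst.tolist()):
        adj[s].append(d)
    # restrict to nodes with a path to the output
    radj = _reverse_adjacency(net)
    useful = {out}
    stack = [out]
    while stack:
        u = stack.pop()
        for v in radj[u]:
            if v not in useful:
                useful.add(v)
                stack.append(v)
    if start not in useful:
        return 0, False

    count = 0
    visited = [False] * net.n_nodes
    path_stack = [(start, iter(adj[start]))]
    visited[start] = True
    while path_stack:
        node, it = path_stack[-1]
        advanced = False
        for nxt in it:
            if nxt == out:
                count += 1
                if count >= cap:
                    return count, True
            elif nxt in useful and not visited[nxt]:
                visited[nxt] = True
                path_stack.append((nxt, iter(adj[nxt])))
                advanced = True
                break
        if not advanced:
            path_stack.pop()
            visited[node] = False
    return count, False


def count_motifs(net: RegulatoryNetwork) -> MotifCounts:
    """Exhaustive signed census of the local patterns of one genotype."""
    sign_of: dict[tuple[int, int], int] = {}
    for s, d, g in zip(net.src.tolist(), net.dst.tolist(), net.sign.tolist()):
        sign_of[(s, d)] = g

    auto_act = sum(1 for (s, d), g in sign_of.items() if s == d and g > 0)
    auto_rep = sum(1 for (s, d), g in sign_of.items() if s == d and g < 0)

    mut_act = mut_rep = mut_act_auto = mut_rep_auto = 0
    pairs = {
        (min(s, d), max(s, d))
        for (s, d) in sign_of
        if s != d and (d, s) in sign_of
    }
    for i, j in pairs:
        gij, gji = sign_of[(i, j)], sign_of[(j, i)]
        both_auto_act = (
            sign_of.get((i, i), 0) > 0 and sign_of.get((j, j), 0) > 0
        )
        if gij > 0 and gji > 0:
            mut_act += 1
            mut_act_auto += both_auto_act
        elif gij < 0 and gji < 0:
            mut_rep += 1
            mut_rep_auto += both_auto_act

    ffl = 0
    fbl = 0
    # ordered triples over distinct nodes via edge composition
    out_edges: dict[int, list[tuple[int, int]]] = {}
    for (s, d), g in sign_of.items():
        if s != d:
            out_edges.setdefault(s, []).append((d, g))
    for (j, k), g_jk in sign_of.items():
        if j == k:
            continue
        for i, g_ki in out_edges.get(k, ()):
            if i == j or i == k:
                continue
            g_ji = sign_of.get((j, i))
            # coherent FFL: direct j->i sign equals the j->k->i product
            if g_ji is not None and g_ji == g_jk * g_ki:
                ffl += 1
            # positive 3-cycle j->k->i->j, counted once per cycle (anchor at
            # the smallest node)
            g_ij = sign_of.get((i, j))
            if (
                g_ij is not None
                and j < k
                and j < i
                and g_jk * g_ki * g_ij > 0
            ):
                fbl += 1
    return MotifCounts(
        auto_activation=auto_act,
        auto_repression=auto_rep,
        mutual_activation=mut_act,
        mutual_repression=mut_rep,
        ffl_coherent=ffl,
        fbl_positive=fbl,
        mutual_activation_with_auto=mut_act_auto,
        mutual_repression_with_auto=mut_rep_auto,
    )


@dataclass
class ReweightedHistogram:
    """A statistic distribution reweighted to the reference f-distribution."""

    statistic_values: np.ndarray
    weights: np.ndarray  # per-sample, normalized to sum 1
    sub_bin_weights: np.ndarray
    coverage_gap: bool  # reference has mass where the compared set has none

    def histogram(self, bins) -> tuple[np.ndarray, np.ndarray]:
        h, edges = np.histogram(
            self.statistic_values, bins=bins, weights=self.weights
        )
        return h, edges


def reweight_histogram(
    es_samples: tuple[np.ndarray, np.ndarray],
    ref_samples: np.ndarray,
    target_bin: tuple[float, float],
    n_sub: int = 10,
) -> ReweightedHistogram:
    """Match the within-bin fitness distribution of ES samples to a reference.

    ``es_samples`` is ``(f, statistic)`` for the evolved set restricted to
    ``target_bin``; ``ref_samples`` is the reference set's fitness values in
    the same bin.  The bin is split into ``n_sub`` sub-bins and each ES
    sample in sub-bin s receives weight proportional to
    (reference count in s) / (ES count in s); sub-bins with ES samples but no
    reference mass get weight 0, and reference mass where the ES has no
    samples is flagged as a coverage gap.
    """
    f_es, stat = (np.asarray(a, dtype=float) for a in es_samples)
    f_ref = np.asarray(ref_samples, dtype=float)
    lo, hi = target_bin
    if not (lo < hi):
        raise ValueError("empty target bin")
    in_es = (f_es >= lo) & (f_es <= hi)
    in_ref = (f_ref >= lo) & (f_ref <= hi)
    if not in_es.any() or not in_ref.any():
        raise ValueError("both sample sets must be nonempty within target_bin")
    f_es, stat, f_ref = f_es[in_es], stat[in_es], f_ref[in_ref]

    edges = np.linspace(lo, hi, n_sub + 1)
    sub_es = np.clip(np.searchsorted(edges, f_es, side="right") - 1, 0, n_sub - 1)
    c_es = np.bincount(sub_es, minlength=n_sub).astype(float)
    sub_ref = np.clip(np.searchsorted(edges, f_ref, side="right") - 1, 0, n_sub - 1)
    c_ref = np.bincount(sub_ref, minlength=n_sub).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        sub_w = np.where(c_es > 0, c_ref / c_es, 0.0)
    coverage_gap = bool(np.any((c_ref > 0) & (c_es == 0)))
    w = sub_w[sub_es]
    total = w.sum()
    if total <= 0:
        raise ValueError("no overlap between ES and reference sub-bins")
    return ReweightedHistogram(
        statistic_values=stat,
        weights=w / total,
        sub_bin_weights=sub_w,
        coverage_gap=coverage_gap,
    )


def bistable_fraction(
    samples: list[tuple[RegulatoryNetwork, float]],
    binning: FitnessBinning,
    criterion: BistabilityCriterion = STRICT,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> pd.DataFrame:
    """Fraction of bistable genotypes P2(f) per fitness bin.

    ``samples`` is a list of (network, fitness) pairs.  Returns one row per
    bin that contains samples, with the binomial standard error; empty bins
    are absent rather than reported as zero.
    """
    per_bin: dict[int, list[bool]] = {}
    for net, f in samples:
        rep = hysteresis_sweep(
            net, criterion, tol=tol, max_iter=max_iter, classify=False
        )
        per_bin.setdefault(binning.bin_of(f), []).append(rep.bistable)
    rows = []
    edges = binning.edges
    for b in sorted(per_bin):
        flags = per_bin[b]
        n = len(flags)
        p = sum(flags) / n
        rows.append(
            {
                "bin": b,
                "f_lo": edges[b],
                "f_hi": edges[b + 1],
                "n": n,
                "p2": p,
                "se": math.sqrt(p * (1 - p) / n),
            }
        )
    return pd.DataFrame(
        rows, columns=["bin", "f_lo", "f_hi", "n", "p2", "se"]
    )
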