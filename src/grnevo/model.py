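"""Genotype representation, dynamics, fitness, and the elementary rewiring move.

A gene regulatory network (GRN) genotype is a signed directed graph on N
genes: an edge ``j -> i`` with sign +1 (activation) or -1 (repression).  At
most one edge connects any ordered pair; self-loops are allowed.  Expression
levels x_i in [0, 1] follow the synchronous discrete-time dynamics

    x_i(t+1) = R( I * delta_{i,0} + sum_j J_ij x_j(t) ),

with the sigmoidal response R(x) = 1 / (1 + exp(-beta (x - mu))).  Gene 0 is
the input gene and receives the external signal I in [0, 1]; one designated
gene is the output.  Fitness is the responsiveness of the output to switching
the input off/on,

    f = | x_out(I=0) - x_out(I=1) |,

where x_out(I) is the steady-state (or cycle-averaged) output level reached
from the spontaneous state x_i = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from grnevo import _kernels

__all__ = [
    "ModelParams",
    "RegulatoryNetwork",
    "SteadyState",
    "response",
    "step",
    "steady_output",
    "fitness",
    "random_network",
    "rewire_move",
]

DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 10_000


@dataclass(frozen=True)
class ModelParams:
    """Model-level constants shared by every genotype of an ensemble.

    Parameters
    ----------
    n_nodes
        Number of genes N (default 32).
    n_edges
        Number of regulatory edges K (default 80).
    beta
        Steepness of the sigmoidal response (default 2).  With beta=2, mu=0
        a single auto-activating gene is monostable; beta=6, mu=0.5 is the
        classic bistable single-gene example.
    mu
        Response threshold (default 0), giving spontaneous expression
        R(0) = 0.5.
    input_index
        Index of the input gene; fixed to 0 by convention.
    output_index
        Index of the output gene; defaults to N - 1.
    """

    n_nodes: int = 32
    n_edges: int = 80
    beta: float = 2.0
    mu: float = 0.0
    input_index: int = 0
    output_index: int = -1

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (1 <= self.n_edges <= self.n_nodes**2):
            raise ValueError("n_edges must be in [1, n_nodes^2]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.input_index != 0:
            raise ValueError("the input gene is gene 0 by convention")
        if self.output_index == -1:
            object.__setattr__(self, "output_index", self.n_nodes - 1)
        if not (0 <= self.output_index < self.n_nodes):
            raise ValueError("output_index out of range")
        if self.output_index == self.input_index:
            raise ValueError("input and output genes must differ")


@dataclass
class RegulatoryNetwork:
    """A GRN genotype: params plus K signed edges.

    Edges are stored as three equal-length arrays ``src``, ``dst``, ``sign``
    (``sign[e]`` in {-1, +1}); edge e regulates gene ``dst[e]`` from gene
    ``src[e]``.  Ordered pairs are unique.
    """

    params: ModelParams
    src: np.ndarray
    dst: np.ndarray
    sign: np.ndarray

    def __post_init__(self) -> None:
        self.src = np.ascontiguousarray(self.src, dtype=np.int64)
        self.dst = np.ascontiguousarray(self.dst, dtype=np.int64)
        self.sign = np.ascontiguousarray(self.sign, dtype=np.int64)
        k = self.params.n_edges
        if not (self.src.shape == self.dst.shape == self.sign.shape == (k,)):
            raise ValueError(f"expected exactly {k} edges")
        n = self.params.n_nodes
        if self.src.min(initial=0) < 0 or self.src.max(initial=0) >= n:
            raise ValueError("source node id out of range")
        if self.dst.min(initial=0) < 0 or self.dst.max(initial=0) >= n:
            raise ValueError("target node id out of range")
        if not np.all(np.abs(self.sign) == 1):
            raise ValueError("edge signs must be -1 or +1")
        codes = self.src * n + self.dst
        if len(np.unique(codes)) != k:
            raise ValueError("duplicate ordered (source, target) pair")

    @classmethod
    def _from_arrays_unchecked(
        cls,
        params: ModelParams,
        src: np.ndarray,
        dst: np.ndarray,
        sign: np.ndarray,
    ) -> "RegulatoryNetwork":
        # hot-path constructor for moves that preserve the invariants by
        # construction (rewiring, copying); skips __post_init__ validation
        obj = object.__new__(cls)
        obj.params = params
        obj.src = src
        obj.dst = dst
        obj.sign = sign
        return obj

    @property
    def n_nodes(self) -> int:
        return self.params.n_nodes

    @property
    def n_edges(self) -> int:
        return self.params.n_edges

    def edge_set(self) -> frozenset[tuple[int, int, int]]:
        """The genotype as a hashable set of (source, target, sign) triples."""
        return frozenset(
            zip(self.src.tolist(), self.dst.tolist(), self.sign.tolist())
        )

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            self.params, self.src.copy(), self.dst.copy(), self.sign.copy()
        )

    def without_edge(self, index: int) -> "RegulatoryNetwork":
        """The (K-1)-edge network with edge ``index`` deleted (no replacement)."""
        mask = np.ones(self.n_edges, dtype=bool)
        mask[index] = False
        params = replace(self.params, n_edges=self.n_edges - 1)
        return RegulatoryNetwork(
            params, self.src[mask], self.dst[mask], self.sign[mask]
        )

    def adjacency_matrix(self) -> np.ndarray:
        """Dense signed J with J[i, j] the regulation of gene i by gene j."""
        n = self.n_nodes
        j = np.zeros((n, n))
        j[self.dst, self.src] = self.sign
        return j


@dataclass(frozen=True)
class SteadyState:
    """Outcome of iterating the dynamics at fixed input.

    ``output_level`` is the fixed-point output expression, the cycle average
    if a limit cycle was detected, or the trailing-window average if the
    iteration cap was reached.  ``converged`` and ``cycle_detected`` are never
    both set.
    """

    output_level: float
    converged: bool
    cycle_detected: bool
    iterations_used: int


def response(x, beta: float = 2.0, mu: float = 0.0):
    """Sigmoidal gene response R(x) = 1 / (1 + exp(-beta (x - mu))).

    Strictly increasing, R(mu) = 1/2; with the default threshold mu = 0 the
    spontaneous (zero-input) expression is R(0) = 0.5.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = beta * (np.asarray(x, dtype=float) - mu)
    # exp(-logaddexp(0, -z)) = 1/(1+exp(-z)), stable for large |z|
    return np.exp(-np.logaddexp(0.0, -z))


def step(net: RegulatoryNetwork, state: np.ndarray, I: float) -> np.ndarray:
    """One synchronous update of all genes at input strength ``I``.

    Every gene, the input gene included, applies the response to its summed
    regulation; the input gene additionally receives ``I``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n_nodes,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({net.n_nodes},)"
        )
    total = np.zeros(net.n_nodes)
    np.add.at(total, net.dst, net.sign * state[net.src])
    total[net.params.input_index] += I
    return response(total, net.params.beta, net.params.mu)


def steady_output(
    net: RegulatoryNetwork,
    I: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SteadyState:
    """Iterate from the all-0.5 spontaneous state until a steady state.

    Convergence means max per-node change < ``tol``.  Limit cycles (period up
    to 64) are detected by state recurrence and averaged over one full period;
    if the iteration cap is reached the trailing 1000 output values are
    averaged.  Non-convergence is reported through the flags, never raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    p = net.params
    xbar, status, iters = _kernels.steady_from_half(
        net.src, net.dst, net.sign, p.n_nodes, p.beta, p.mu,
        float(I), p.output_index, tol, max_iter,
    )
    return SteadyState(
        output_level=float(xbar),
        converged=status == _kernels.STATUS_CONVERGED,
        cycle_detected=status == _kernels.STATUS_CYCLE,
        iterations_used=int(iters),
    )


def fitness(
    net: RegulatoryNetwork,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> float:
    """Responsiveness f = |x_out(0) - x_out(1)|, in [0, 1]."""
    p = net.params
    return float(
        _kernels.fitness_kernel(
            net.src, net.dst, net.sign, p.n_nodes, p.beta, p.mu,
            p.output_index, tol, max_iter,
        )
    )


def random_network(
    params: ModelParams, rng: np.random.Generator
) -> RegulatoryNetwork:
    """Draw a uniform random genotype: K ordered pairs without replacement
    from the N^2 possible (self-loops included), each sign +-1 equiprobably."""
    n = params.n_nodes
    codes = rng.choice(n * n, size=params.n_edges, replace=False)
    sign = rng.integers(0, 2, size=params.n_edges) * 2 - 1
    return RegulatoryNetwork(params, codes // n, codes % n, sign)


def rewire_move(
    net: RegulatoryNetwork, rng: np.random.Generator
) -> RegulatoryNetwork:
    """The elementary mutation: delete a random edge, add a random new one.

    A uniformly chosen edge is removed, then an edge is added at an ordered
    pair chosen uniformly among pairs unlinked *after* the deletion (so the
    deleted pair may be redrawn), with a fresh +-1 sign.  K is preserved and
    the input network is left unmodified.
    """
    if net.n_edges >= net.n_nodes**2:
        raise ValueError("saturated network: no unlinked ordered pair exists")
    src, dst, sign = net.src.copy(), net.dst.copy(), net.sign.copy()
    n = net.n_nodes
    kdel, code, newsign = _propose_rewire(src, dst, n, rng)
    src[kdel] = code // n
    dst[kdel] = code % n
    sign[kdel] = newsign
    # the move preserves K and pair uniqueness by construction
    return RegulatoryNetwork._from_arrays_unchecked(net.params, src, dst, sign)


def _propose_rewire(
    src: np.ndarray, dst: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Pick (edge index to delete, new pair code, new sign) for a rewire.

    Uses rejection sampling for the unlinked pair, which is cheap while the
    graph is sparse (the default density is 80/1024).
    """
    kdel = int(rng.integers(src.shape[0]))
    linked = set((src * n + dst).tolist())
    linked.discard(int(src[kdel]) * n + int(dst[kdel]))
    while True:
        code = int(rng.integers(n * n))
        if code not in linked:
            break
    newsign = int(rng.integers(0, 2)) * 2 - 1
    return kdel, code, newsign
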