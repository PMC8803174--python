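"""Flat-histogram Monte Carlo over fitness: Wang-Landau weights, entropic
production sampling, and the genotypic entropy Omega(f).

Uniform sampling of genotypes cannot reach high fitness: at the default size
the fraction of networks with f >= 0.99 is of order 1e-16.  Multicanonical
sampling fixes this by running a Metropolis chain over rewiring moves with a
bin-dependent weight w(f) chosen approximately proportional to 1/Omega(f), so
that every fitness bin is visited about equally often.  Within a bin the
stationary distribution is uniform over genotypes regardless of the weights,
so bin-conditioned statistics are unbiased; the appearance probability
Omega(f) itself is recovered by reweighting the flat visitation with 1/w.

The weights are built with the Wang-Landau method: every visit to a bin adds
a modification increment to that bin's running entropy estimate, and the
increment shrinks each time the visit histogram becomes flat.  Production
("entropic") sampling then runs with the weights frozen, which restores
detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from grnevo import _kernels
from grnevo.model import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    ModelParams,
    RegulatoryNetwork,
    _propose_rewire,
    random_network,
    rewire_move,
)

__all__ = [
    "FitnessBinning",
    "WeightTable",
    "SampleRecord",
    "SampleArchive",
    "EntropyEstimate",
    "WangLandauSchedule",
    "bin_of",
    "metropolis_update",
    "wang_landau",
    "run_sampling",
    "sample_fitness_band",
    "estimate_entropy",
    "genotype_space_size",
]


@dataclass(frozen=True)
class FitnessBinning:
    """Partition of [0, 1] into equal fitness bins.

    Bin i covers [i/n, (i+1)/n) for i < n-1; the last bin is closed,
    [(n-1)/n, 1], so f = 1 falls in bin n-1.
    """

    n_bins: int = 100

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    def bin_of(self, f: float) -> int:
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"fitness {f} outside [0, 1]")
        return min(int(f * self.n_bins), self.n_bins - 1)


def bin_of(f: float, binning: FitnessBinning) -> int:
    """Bin index of fitness ``f`` under the half-open convention."""
    return binning.bin_of(f)


@dataclass
class WeightTable:
    """Per-bin multicanonical log-weights and the visit histogram.

    ``log_weights`` is the negative running entropy estimate, log w(f) =
    -log Omega_hat(f), up to an arbitrary additive constant (only differences
    matter).  Bins never visited keep log-weight 0, which -- since visited
    bins carry negative log-weights after normalization is *not* applied --
    makes proposals into them always accepted, the standard flat-histogram
    drive toward unexplored regions.
    """

    binning: FitnessBinning
    log_weights: np.ndarray
    visit_histogram: np.ndarray
    visited: np.ndarray
    converged: bool = True
    final_ln_factor: float = 0.0
    mcs_used: int = 0
    # genotypes optionally recorded during the late (small modification
    # factor) Wang-Landau stages; near-uniform across visited bins
    samples: list = field(default_factory=list)

    @classmethod
    def flat(cls, binning: FitnessBinning) -> "WeightTable":
        n = binning.n_bins
        return cls(
            binning,
            np.zeros(n),
            np.zeros(n, dtype=np.int64),
            np.zeros(n, dtype=bool),
        )

    def log_entropy(self) -> np.ndarray:
        """-log_weights: the unnormalized log density of states per bin."""
        return -self.log_weights


@dataclass(frozen=True)
class WangLandauSchedule:
    """Wang-Landau control parameters.

    The ln-modification factor starts at ``ln_factor_init``; whenever the
    stage's visit histogram is flat (minimum count over ever-visited bins at
    least ``flatness`` of the mean) the factor is multiplied by ``reduction``
    and the histogram reset; the run stops when the factor drops below
    ``ln_factor_stop`` or the ``max_mcs`` budget is exhausted.
    """

    ln_factor_init: float = 1.0
    flatness: float = 0.8
    reduction: float = 0.5
    ln_factor_stop: float = 1e-6
    check_every: int = 100
    max_mcs: int = 10_000_000

    def __post_init__(self) -> None:
        if not (0 < self.flatness < 1):
            raise ValueError("flatness must be in (0, 1)")
        if not (0 < self.reduction < 1):
            raise ValueError("reduction must be in (0, 1)")
        if self.ln_factor_init <= self.ln_factor_stop:
            raise ValueError("ln_factor_init must exceed ln_factor_stop")


@dataclass(frozen=True)
class SampleRecord:
    mcs: int
    fitness: float
    network: RegulatoryNetwork


@dataclass
class SampleArchive:
    """Genotypes recorded during production sampling, in MCS order."""

    records: list[SampleRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def fitnesses(self) -> np.ndarray:
        return np.array([r.fitness for r in self.records])


@dataclass
class EntropyEstimate:
    """Normalized appearance probability Omega per fitness bin.

    ``omega`` sums to 1 over sampled bins; unsampled bins hold NaN in
    ``log10_omega`` and 0 in ``omega``.
    """

    binning: FitnessBinning
    omega: np.ndarray
    log10_omega: np.ndarray


def _accept(log_w_old: float, log_w_new: float, rng: np.random.Generator) -> bool:
    """Metropolis rule for multicanonical weights, P = min(1, w_new/w_old)."""
    d = log_w_new - log_w_old
    return d >= 0 or rng.random() < math.exp(d)


def metropolis_update(
    net: RegulatoryNetwork,
    f: float,
    weights: WeightTable,
    rng: np.random.Generator,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[RegulatoryNetwork, float, bool]:
    """One multicanonical Metropolis update from ``(net, f)``.

    Proposes a rewiring move and accepts with probability
    min(1, w[bin(f')] / w[bin(f)]).  Returns ``(net', f', accepted)``; on
    rejection the input genotype is returned unchanged.
    """
    from grnevo.model import fitness as _fitness

    binning = weights.binning
    cand = rewire_move(net, rng)
    f_new = _fitness(cand, tol=tol, max_iter=max_iter)
    if _accept(
        weights.log_weights[binning.bin_of(f)],
        weights.log_weights[binning.bin_of(f_new)],
        rng,
    ):
        return cand, f_new, True
    return net, f, False


def _fitness_arrays(
    src: np.ndarray,
    dst: np.ndarray,
    sgn: np.ndarray,
    params: ModelParams,
    tol: float,
    max_iter: int,
) -> float:
    return float(
        _kernels.fitness_kernel(
            src, dst, sgn, params.n_nodes, params.beta, params.mu,
            params.output_index, tol, max_iter,
        )
    )


class _Chain:
    """Mutable Markov-chain state over raw edge arrays (internal fast path)."""

    def __init__(
        self,
        params: ModelParams,
        rng: np.random.Generator,
        tol: float,
        max_iter: int,
        start: RegulatoryNetwork | None = None,
    ):
        net = start if start is not None else random_network(params, rng)
        self.params = params
        self.src = net.src.copy()
        self.dst = net.dst.copy()
        self.sgn = net.sign.copy()
        self.tol = tol
        self.max_iter = max_iter
        self.f = _fitness_arrays(self.src, self.dst, self.sgn, params, tol, max_iter)
        self.rng = rng

    def update(self, log_weights: np.ndarray, binning: FitnessBinning) -> bool:
        """One Metropolis update in place; returns acceptance."""
        n = self.params.n_nodes
        kdel, code, newsign = _propose_rewire(self.src, self.dst, n, self.rng)
        old = (self.src[kdel], self.dst[kdel], self.sgn[kdel])
        self.src[kdel], self.dst[kdel], self.sgn[kdel] = code // n, code % n, newsign
        f_new = _fitness_arrays(
            self.src, self.dst, self.sgn, self.params, self.tol, self.max_iter
        )
        if _accept(
            log_weights[binning.bin_of(self.f)],
            log_weights[binning.bin_of(f_new)],
            self.rng,
        ):
            self.f = f_new
            return True
        self.src[kdel], self.dst[kdel], self.sgn[kdel] = old
        return False

    def network(self) -> RegulatoryNetwork:
        return RegulatoryNetwork(
            self.params, self.src.copy(), self.dst.copy(), self.sgn.copy()
        )


def wang_landau(
    params: ModelParams,
    binning: FitnessBinning | None = None,
    schedule: WangLandauSchedule | None = None,
    rng: np.random.Generator | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: RegulatoryNetwork | None = None,
    record_every: int | None = None,
    record_below: float = 0.1,
) -> WeightTable:
    """Determine multicanonical weights with the Wang-Landau method.

    Runs rewiring-move Metropolis updates, adding the current ln-modification
    factor to the entropy estimate of the occupied bin after every update.
    When the per-stage visit histogram is flat over all ever-visited bins the
    factor is reduced and the histogram reset.  If the MCS budget runs out
    first, the partial table is returned with ``converged=False``.

    The negated, normalized log-weights estimate log Omega(f) over the bins
    the chain managed to visit; bins that are practically unreachable at the
    given budget simply stay unvisited.

    With ``record_every`` set, the genotype is recorded every that many MCS
    once the ln-modification factor has dropped below ``record_below``: the
    flat-histogram drive then spreads these samples near-uniformly over all
    visited fitness bins, giving bin-conditioned reference genotypes from
    the same run.
    """
    binning = binning or FitnessBinning()
    schedule = schedule or WangLandauSchedule()
    rng = rng if rng is not None else np.random.default_rng()

    chain = _Chain(params, rng, tol, max_iter, start=start)
    n = binning.n_bins
    log_w = np.zeros(n)  # -running log Omega_hat; drops by ln_f per visit
    hist = np.zeros(n, dtype=np.int64)
    total_hist = np.zeros(n, dtype=np.int64)
    ln_f = schedule.ln_factor_init
    k = params.n_edges

    samples: list[SampleRecord] = []
    mcs = 0
    while mcs < schedule.max_mcs and ln_f >= schedule.ln_factor_stop:
        for _ in range(k):
            chain.update(log_w, binning)
            b = binning.bin_of(chain.f)
            log_w[b] -= ln_f
            hist[b] += 1
        mcs += 1
        if (
            record_every is not None
            and ln_f < record_below
            and mcs % record_every == 0
        ):
            samples.append(SampleRecord(mcs, chain.f, chain.network()))
        if mcs % schedule.check_every == 0:
            visited = log_w < 0
            counts = hist[visited]
            if counts.size and counts.min() >= schedule.flatness * counts.mean():
                ln_f *= schedule.reduction
                total_hist += hist
                hist[:] = 0

    total_hist += hist
    visited = log_w < 0
    if visited.any():
        log_w = log_w - log_w[visited].max()  # gauge: most favorable bin at 0
        log_w[~visited] = 0.0
    return WeightTable(
        binning=binning,
        log_weights=log_w,
        visit_histogram=total_hist,
        visited=visited,
        converged=ln_f < schedule.ln_factor_stop,
        final_ln_factor=ln_f,
        mcs_used=mcs,
        samples=samples,
    )


def run_sampling(
    params: ModelParams,
    weights: WeightTable,
    n_mcs: int,
    sample_every: int = 20,
    rng: np.random.Generator | None = None,
    burn_in: int = 1000,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: RegulatoryNetwork | None = None,
    seed_label: int | None = None,
) -> SampleArchive:
    """Entropic (fixed-weight) production sampling.

    Performs ``burn_in`` then ``n_mcs`` Monte Carlo steps -- one MCS is K
    Metropolis updates -- and records the genotype every ``sample_every`` MCS.
    With converged weights the chain visits all reachable bins near-uniformly
    and detailed balance holds exactly.
    """
    rng = rng if rng is not None else np.random.default_rng()
    binning = weights.binning
    chain = _Chain(params, rng, tol, max_iter, start=start)
    k = params.n_edges
    lw = weights.log_weights

    for _ in range(burn_in * k):
        chain.update(lw, binning)

    records: list[SampleRecord] = []
    visits = np.zeros(binning.n_bins, dtype=np.int64)
    accepted = 0
    for mcs in range(1, n_mcs + 1):
        for _ in range(k):
            accepted += chain.update(lw, binning)
        visits[binning.bin_of(chain.f)] += 1
        if mcs % sample_every == 0:
            records.append(SampleRecord(mcs, chain.f, chain.network()))
    return SampleArchive(
        records=records,
        metadata={
            "params": params,
            "weights": weights,
            "n_mcs": n_mcs,
            "sample_every": sample_every,
            "burn_in": burn_in,
            "seed": seed_label,
            "acceptance_rate": accepted / max(1, n_mcs * k),
            "visit_histogram": visits,
        },
    )


def sample_fitness_band(
    params: ModelParams,
    f_lo: float,
    f_hi: float = 1.0,
    n_mcs: int = 10_000,
    sample_every: int = 20,
    burn_in: int = 1000,
    rng: np.random.Generator | None = None,
    max_climb_mcs: int = 100_000,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SampleArchive:
    """Sample genotypes uniformly from the fitness band [f_lo, f_hi].

    A special case of multicanonical sampling with a single active bin:
    once the chain is inside the band, moves leaving it are rejected, so the
    stationary distribution is uniform over genotypes with fitness in the
    band -- the conditioned reference ensemble at matched fitness.  The band
    is first reached by a Wang-Landau climb from a random genotype (high
    fitness is exponentially rare under uniform sampling, so an unbiased
    entry point needs the flat-histogram drive).

    Raises ``RuntimeError`` if the climb budget is exhausted before the band
    is reached.
    """
    if not (0.0 <= f_lo < f_hi <= 1.0):
        raise ValueError("need 0 <= f_lo < f_hi <= 1")
    rng = rng if rng is not None else np.random.default_rng()
    chain = _Chain(params, rng, tol, max_iter)

    binning = FitnessBinning()
    log_w = np.zeros(binning.n_bins)
    climbed = 0
    k = params.n_edges
    while not (f_lo <= chain.f <= f_hi):
        chain.update(log_w, binning)
        log_w[binning.bin_of(chain.f)] -= 1.0
        climbed += 1
        if climbed > max_climb_mcs * k:
            raise RuntimeError(
                f"failed to reach fitness band [{f_lo}, {f_hi}] within "
                f"{max_climb_mcs} MCS of Wang-Landau climbing"
            )

    def band_update() -> bool:
        n = params.n_nodes
        kdel, code, newsign = _propose_rewire(chain.src, chain.dst, n, rng)
        old = (chain.src[kdel], chain.dst[kdel], chain.sgn[kdel])
        chain.src[kdel], chain.dst[kdel], chain.sgn[kdel] = (
            code // n, code % n, newsign,
        )
        f_new = _fitness_arrays(
            chain.src, chain.dst, chain.sgn, params, tol, max_iter
        )
        if f_lo <= f_new <= f_hi:
            chain.f = f_new
            return True
        chain.src[kdel], chain.dst[kdel], chain.sgn[kdel] = old
        return False

    for _ in range(burn_in * k):
        band_update()
    records: list[SampleRecord] = []
    accepted = 0
    for mcs in range(1, n_mcs + 1):
        for _ in range(k):
            accepted += band_update()
        if mcs % sample_every == 0:
            records.append(SampleRecord(mcs, chain.f, chain.network()))
    return SampleArchive(
        records=records,
        metadata={
            "params": params,
            "band": (f_lo, f_hi),
            "n_mcs": n_mcs,
            "sample_every": sample_every,
            "burn_in": burn_in,
            "climb_mcs": climbed // k,
            "acceptance_rate": accepted / max(1, n_mcs * k),
        },
    )


def estimate_entropy(
    source: Union[SampleArchive, WeightTable],
    binning: FitnessBinning | None = None,
) -> EntropyEstimate:
    """Genotypic entropy Omega(f) per bin, normalized to sum 1.

    From a :class:`WeightTable`, Omega is the normalized exponential of the
    negated log-weights over visited bins.  From a :class:`SampleArchive`,
    the flat-histogram visitation (the per-MCS bin occupancy recorded in the
    archive metadata, falling back to the stored sample records) is
    reweighted by 1/w(bin) with the weights the archive was produced with,
    which corrects the multicanonical bias.
    """
    if isinstance(source, WeightTable):
        binning = source.binning
        log_unnorm = np.where(source.visited, -source.log_weights, -np.inf)
    else:
        if len(source) == 0:
            raise ValueError("empty archive")
        weights: WeightTable = source.metadata["weights"]
        binning = binning or weights.binning
        if "visit_histogram" in source.metadata:
            counts = np.asarray(source.metadata["visit_histogram"], dtype=float)
        else:
            counts = np.zeros(binning.n_bins)
            for r in source.records:
                counts[binning.bin_of(r.fitness)] += 1
        with np.errstate(divide="ignore"):
            log_unnorm = np.where(
                counts > 0, np.log(counts) - weights.log_weights, -np.inf
            )
    finite = np.isfinite(log_unnorm)
    if not finite.any():
        raise ValueError("no visited bins")
    m = log_unnorm[finite].max()
    norm = m + math.log(np.exp(log_unnorm[finite] - m).sum())
    log_omega = log_unnorm - norm
    omega = np.where(finite, np.exp(log_omega), 0.0)
    log10_omega = np.where(finite, log_omega / math.log(10.0), np.nan)
    return EntropyEstimate(binning=binning, omega=omega, log10_omega=log10_omega)


def genotype_space_size(params: ModelParams) -> float:
    """log10 of the number of distinct genotypes, C(N^2, K) * 2^K."""
    n2, k = params.n_nodes**2, params.n_edges
    ln = math.lgamma(n2 + 1) - math.lgamma(k + 1) - math.lgamma(n2 - k + 1)
    return (ln + k * math.log(2.0)) / math.log(10.0)
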