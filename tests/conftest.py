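"""Shared fixtures.

The expensive session fixtures (toy-space enumeration, Wang-Landau runs,
evolutionary replicates) are computed once and shared across test modules;
their problem sizes are chosen so the whole default run stays at desk scale.
"""

import numpy as np
import pytest

from grnevo import (
    FitnessBinning,
    ModelParams,
    WangLandauSchedule,
    fitness,
    run_sampling,
    wang_landau,
)
from grnevo.fixtures import enumerate_genotype_space

# the enumerable oracle space: C(9,2) * 2^2 = 144 genotypes
TOY = ModelParams(n_nodes=3, n_edges=2)


@pytest.fixture(scope="session")
def toy_space():
    """All 144 genotypes of the N=3, K=2 space with exact fitnesses."""
    nets = list(enumerate_genotype_space(TOY))
    return [(net, fitness(net)) for net in nets]


@pytest.fixture(scope="session")
def toy_exact_omega(toy_space):
    """Exact per-bin appearance probability from exhaustive enumeration."""
    binning = FitnessBinning()
    omega = np.zeros(binning.n_bins)
    for _, f in toy_space:
        omega[binning.bin_of(f)] += 1.0 / len(toy_space)
    return binning, omega


@pytest.fixture(scope="session")
def toy_weight_table():
    """Converged Wang-Landau weights on the toy space.

    A stricter flatness (0.9) than the large-scale default is affordable here
    and pins the per-bin error of the weights themselves to a few percent.
    """
    schedule = WangLandauSchedule(max_mcs=300_000, check_every=50, flatness=0.9)
    return wang_landau(
        TOY, FitnessBinning(), schedule, np.random.default_rng(2024)
    )


@pytest.fixture(scope="session")
def toy_archive(toy_weight_table):
    """Entropic production run on the toy space with converged weights."""
    return run_sampling(
        TOY,
        toy_weight_table,
        n_mcs=150_000,
        sample_every=20,
        rng=np.random.default_rng(77),
        burn_in=500,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# full-scale (N=32, K=80) scaled-run fixtures shared by the acceptance tests
# ---------------------------------------------------------------------------

FULL = ModelParams()

# desk-scale problem sizes: a Wang-Landau budget that spans the whole
# fitness range and nearly exhausts the modification schedule, a
# band-confined reference at the highest fitness, and a modest replicate
# count for evolution
WL_BUDGET_MCS = 25_000
BAND_MCS = 6_000
N_REPLICATES = 16


@pytest.fixture(scope="session")
def scaled_weight_table():
    """Wang-Landau weights for the full model at a desk-scale budget.

    Genotypes are recorded during the late, small-modification-factor stages;
    the flat-histogram drive spreads them near-uniformly over fitness bins,
    so bin-conditioned slices serve as reference samples at matched fitness.
    """
    schedule = WangLandauSchedule(max_mcs=WL_BUDGET_MCS, check_every=200)
    return wang_landau(
        FULL, FitnessBinning(), schedule, np.random.default_rng(314),
        record_every=2,
    )


@pytest.fixture(scope="session")
def highf_reference():
    """Uniform samples of the reference ensemble conditioned on f >= 0.99."""
    from grnevo import sample_fitness_band

    return sample_fitness_band(
        FULL, 0.99, 1.0, n_mcs=BAND_MCS, sample_every=20, burn_in=1000,
        rng=np.random.default_rng(161),
    )


@pytest.fixture(scope="session")
def evo50_lineages():
    """Independent full-protocol Evo50 replicates (population 1000,
    150 generations), reduced in count to desk scale."""
    from grnevo import EvolutionConfig, run_lineage_ensemble

    config = EvolutionConfig(params=FULL, mode="evo50")
    return run_lineage_ensemble(
        config, N_REPLICATES, np.random.SeedSequence(5551)
    )
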