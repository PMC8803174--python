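# Methods

## Model

Genotypes are signed directed graphs on N genes (default 32) with exactly K
edges (default 80), at most one edge per ordered pair, self-loops allowed.
Each edge carries a sign: +1 activation, −1 repression. Expression levels
x_i ∈ [0, 1] evolve by the synchronous map

    x_i(t+1) = R( I δ_{i,0} + Σ_j J_ij x_j(t) ),
    R(x) = 1 / (1 + exp(−β (x − μ))),

computed in a numerically stable log-sum-exp form. Gene 0 is the input and
receives the signal I ∈ [0, 1] in addition to any incoming regulation; the
output gene defaults to N−1 (the model is statistically invariant to this
choice under random topology, and it is configurable). With the default
β = 2, μ = 0 the response is shallow: R(0) = 0.5 and a single
auto-activating gene has one stable fixed point, so bistability can only
arise from the cooperation of several genes. (β = 6, μ = 0.5 is the classic
parameter set at which one auto-activating gene is already bistable; the
handcrafted test fixture uses it.)

Fitness is the input responsiveness of the output gene,
f = |x̄_out(0) − x̄_out(1)| ∈ [0, 1], with x̄_out the steady state reached
from the spontaneous all-0.5 state. Fitness is exactly 0 whenever no
directed path connects input to output.

### Steady-state numerics

Iteration from all-0.5 stops when the maximum per-node change falls below
tol = 1e−9 (well below the 1e−6 output threshold used in strict bistability
detection), capped at 10,000 iterations. The first 256 iterations run
without bookkeeping — almost every network converges there. After that,
limit cycles of period ≤ 64 are detected by comparing the state against a
ring buffer of recent states at the same tolerance; on detection the output
is averaged over one full period. If the cap is reached without detection,
the trailing 1,000 output values are averaged. Non-convergence is reported
through flags, never raised. The update sum is accumulated over the sparse
edge list in a numba kernel (80 of 1024 possible edges at default size),
which makes a fitness evaluation ~20 µs and the full pipeline tractable on
one core.

### Mutation move

One uniformly chosen edge is deleted, then an edge is added at an ordered
pair drawn uniformly among pairs unlinked *after* the deletion — so the
deleted pair may be redrawn — with a fresh equiprobable sign. This keeps K
fixed, keeps the proposal kernel symmetric (verified empirically against
the enumerable toy space), and is shared verbatim between the Monte Carlo
sampler and the evolutionary simulator. The sign of the added edge is
random rather than inherited; symmetry is the only unbiased choice where
the protocol is otherwise unspecified.

## Multicanonical sampler

Fitness is divided into 100 equal bins (half-open, the last bin closed).
Wang-Landau weight determination runs Metropolis updates with acceptance
min(1, w(bin′)/w(bin)); after every update the occupied bin's running
entropy estimate grows by the ln-modification factor (equivalently its
log-weight drops). The factor starts at 1.0, halves whenever the per-stage
visit histogram over all ever-visited bins is flat (minimum ≥ 80% of the
mean), and the run stops below 1e−6 or at the MCS budget, returning a
partial table flagged unconverged in the latter case. Unvisited bins keep
log-weight 0, which makes proposals into them always accepted — the
standard drive toward unexplored fitness regions — and they are excluded
from flatness checks. One Monte Carlo step (MCS) is K elementary updates.
Production ("entropic") sampling freezes the weights, restoring exact
detailed balance, and records the genotype every 20 MCS after a 1,000-MCS
burn-in. Tests on the enumerable N=3, K=2 space (144 genotypes) use a
stricter 90% flatness, affordable there, which pins the weight-table error
to a few percent.

The genotypic entropy Ω(f) — the appearance probability of each bin under
uniform random sampling, normalized to 1 — is estimated by reweighting the
per-MCS bin visitation with 1/w(bin) (log-sum-exp normalization). Estimates
are invariant to a constant shift of all log-weights. The total genotype
count C(N², K)·2^K is computed with log-gamma; for the default size it is
10^144.7, and the measured Ω(f ≥ 0.99) of order 10^−16..−17 makes plain
why the reference ensemble cannot be built by naive sampling.

Two properties matter for how the samples are used downstream:

* with *any* fixed weights, the stationary distribution conditioned on a
  bin is uniform over that bin's genotypes, so bin-conditioned statistics
  are unbiased even from imperfectly converged weights;
* `sample_fitness_band` exploits the same fact with a single active band:
  a Wang-Landau climb reaches the band from a random genotype, then moves
  leaving the band are rejected, giving uniform samples of the conditioned
  ensemble at matched fitness (the reference against which evolved
  genotypes are compared at f ≥ 0.99).

Mixing is the known cost of band confinement: a confined chain cannot
tunnel through fitness space, so *structural* observables at intermediate
fitness (notably the bistable fraction) equilibrate slowly there. At high
fitness (f ≥ 0.99) the band is what the analysis conditions on anyway and
the confined chain reproduces the expected reference behavior (broad
essential-edge distribution, all genotypes bistable). For intermediate-f
reference samples the package instead records genotypes during the late,
small-factor Wang-Landau stages, whose flat-histogram drive spreads them
near-uniformly over bins while repeatedly tunneling; these are
near-equilibrium rather than exact, a deliberate desk-scale trade-off
discussed with the test scales below.

## Evolutionary simulation

A population of 1,000 genotypes is founded by uniform random networks.
Each generation of Evo50 ranks by fitness (stable sort, ties broken by
index for reproducibility), preserves the top 500 unchanged, and gives each
preserved genotype one mutated copy. Evo90 preserves the top 900 and draws
100 parents uniformly *with replacement* from the preserved set (the
protocol is ambiguous on replacement; with-replacement matches the stated
copy count). Fitness is computed once per new genotype and cached. After
150 (Evo50) or 200 (Evo90) generations the ancestor chain of the fittest
individual is traced to its founder: one lineage per replicate, with
consecutive entries differing by at most one mutation move. Per-generation
population mean/max fitness curves are emitted alongside.

The fitness-capped protocol truncates every fitness at a cap (0.99 in the
steady-state experiments): once all preserved individuals sit at the cap,
selection among them is neutral and the run continues as neutral evolution,
with snapshots of capped individuals every 2,000 generations.

## Comparative analyses

* **Robustness** r is the mean fitness over the K single-edge-deletion
  variants (no replacement edge); an edge is *essential* if its deletion
  fitness falls below 0.8 (configurable; the split between near-neutral and
  near-zero deletion fitnesses at high f makes the exact threshold
  uncritical).
* **Bistability** is detected by hysteresis: an up-sweep of I from 0 to 1 in
  steps ΔI, each grid point warm-started from the previous converged state
  (the first point cold-started from all-0.5), and a mirrored down-sweep
  with its own cold start at I = 1. The genotype is bistable when the
  branches differ anywhere by more than x_th — strict criterion ΔI = 0.001,
  x_th = 10⁻⁶; loose ΔI = 0.01, x_th = 0.5. Loose-bistable implies
  strict-bistable. Bistable genotypes are subtyped by where the saddle-node
  jumps fall: both sweeps jumping inside (0,1) is a toggle, one a one-way
  switch, none (branches merely split) unswitchable. The jump threshold
  (0.1 change between adjacent grid points) separates branch-following
  drift from saddle-node jumps at these parameters and is configurable;
  subtype labels are informational.
* **Effective nodes** n_N counts nodes with a directed path to the output,
  the output itself included (length-0 path; this makes n_N = N for
  strongly connected graphs). **Path counts** enumerate simple directed
  input→output paths by DFS, pruned to nodes that can reach the output,
  with a saturation cap (default 10⁶).
* **Motifs**: auto-activation/repression; mutual activation/repression over
  unordered pairs; coherent feed-forward loops over ordered triples (direct
  sign equal to the product of the two-step signs); positive feedback loops
  as directed 3-cycles with positive sign product — 2-node positive loops
  are reported separately under the mutual counts rather than folded in;
  and mutual activation/repression with auto-activation of both partners.
  All are verified against exhaustive subgraph scans on small graphs.
* **Sub-bin reweighting**: when evolved and reference collections are
  compared inside one fitness bin, the bin is split into ten sub-bins and
  each evolved sample is weighted by (reference count)/(evolved count) in
  its sub-bin, so the two fitness distributions coincide before any
  statistic is compared. Reference mass in sub-bins without evolved samples
  is flagged as a coverage gap. Within [0.99, 1.0] the reference mass
  concentrates in the lowest sub-bins (Ω keeps falling super-exponentially
  inside the bin), so the reweighting effectively anchors comparisons near
  f ≈ 0.99.

## Problem sizes

The published campaign used 10 production runs of 10⁷ MCS (≈ 50,000
reference samples per bin) and 10⁵ Evo50 replicates. The package's own
runs are desk-scale by design; protocols (population 1000, 150/200
generations, 100 bins, update and recording schedules) are never scaled,
only counts and chain lengths:

* test suite — Wang-Landau at 25,000 MCS on the full model (spans all 100
  bins; modification factor reaches ~10⁻³), with genotypes recorded during
  stages below factor 0.1 as intermediate-fitness reference samples; one
  band-confined chain of 6,000 MCS at f ≥ 0.99; 16 Evo50 replicates; the
  144-genotype space handled exhaustively;
* `scripts/acceptance.py` — 100 Evo50 replicates, three independent
  band-confined reference chains of 8,000 MCS at f ≥ 0.99, robustness
  evaluated on up to 4,000 evolved genotypes.

What desk scale does and does not show: the genotypic-entropy shape, the
robustness enhancement at matched fitness, the essential-edge contrast and
the f → 1 saturation of the reference bistable fraction all reproduce
clearly at these sizes. The *delayed emergence* of bistability (evolved
P2(f) below the reference across the rise region) is a ~0.1–0.3 effect that
requires a reference equilibrated at intermediate fitness; at desk scale
the available reference estimators there are still converging from below
(band-confined chains show a rising trend with burn-in, Wang-Landau-stage
samples tunnel only a few times per band), so the corresponding test
asserts the robust parts — monotone rise, non-inversion beyond sampling
error, saturation at 1 — rather than the full separation.

## Synthetic data and fixtures

All inputs are generated internally; there is no external data. The
fixtures module provides (a) uniform random networks at given N, K; (b)
exhaustive enumeration of genotype spaces up to 10⁵ members (the N=3, K=2
space of C(9,2)·2² = 144 genotypes is the Monte Carlo oracle: exact Ω per
bin, exact kernel symmetry); (c) a 3-node activating chain whose every edge
is essential (r = 0); and (d) a handcrafted 5-gene toggle switch at β = 6,
μ = 0.5 — an auto-activating core gene driven by the input directly and
through a relay, and repressed by a constitutively-ON auto-activating
gene, so the core's drive crosses both saddle-nodes of its bistable window
inside I ∈ [0, 1]. These fixtures emulate the *mechanics* of the study
(genotype space, dynamics, bistability), not empirical gene-expression
data; passing tests certify the algorithms, not biological realism.

## Known limitations

* Deterministic dynamics only: no expression noise, no continuous-time
  variant; very-long capped runs are known to exploit determinism (the
  motivation for the 0.99 cap).
* Reference equilibration at intermediate fitness is the binding
  desk-scale constraint, as discussed above.
* Neutral-space connectivity analysis is out of scope.
* The Wang-Landau schedule (initial factor 1.0, 80% flatness, halving,
  stop 10⁻⁶) is conventional, not tuned; all of it is configurable.
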