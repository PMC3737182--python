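# Methods

This note documents the model implemented by `sweepis`, its assumptions,
the tunable parameters, the synthetic-data generator, and the numerical
choices, in enough detail that a reader can judge what the package's tests
do and do not establish.

## Data and coding

The input is a phased binary SNP matrix of the chromosomes carrying a known
selected allele, together with a per-chromosome mask marking which alleles
descend from the ancestral haplotype (the chromosome on which the selected
mutation arose).  The mask is an *input*: inferring ancestral segments from
raw polymorphism (e.g. with an HMM) is out of scope.  Each row's masked
block must be contiguous and contain the selected site; non-contiguous
blocks are rejected because the model excludes double cross-overs back into
the ancestral state.

Each chromosome is coded as (R₁, R₂, M₁ … M_k): the number of SNPs retained
left/right of the selected site, plus the columns inside the block carrying
a non-ancestral allele (new mutations since the sweep began).  When the
ancestral allelic states are not given explicitly they are taken as the
per-column majority among masked entries.  Mutation coordinates are ordered
most-recent first; because the order cannot be observed directly when two
mutations have disjoint carrier sets, we order by carrier-set size
(smaller = more recent) with ties broken by position — a convention, not an
inference.

With m_L and m_R SNPs flanking the selected site, the recombination classes
form a grid of (m_L + 1)(m_R + 1) states, which is what makes regions of
hundreds of kilobases tractable.

## Trajectory model

The mutant's frequency path follows the discrete Wright–Fisher model with
genotypic selection; fitnesses 1, 1 + s₂, 1 + s₁ for aa/Aa/AA, the additive
scheme s₁ = s, s₂ = s/2 being the default.  Paths are sampled *backward*
from I₀ = round(2N₀·x₀) copies: each step draws
I_t ~ Binomial(2N_t, Y′) where Y′ inverts the deterministic selection map
(bisection to 10⁻¹² relative; the map is monotone on [0, 1]).  A path ends
at the generation T (the allele age) where the count reaches zero; only
paths founded by a single copy (I_{T-1} = 1) have positive forward
probability.  The importance weight of a path is

    log w = log P_F − log P_B + log 2N_T,

the forward Wright–Fisher probability over the backward proposal, times the
chromosome count at the founding generation (the mutational-influx factor —
a constant under constant N; for time-varying N we take the chromosome
count 2N_T, a convention that is surfaced rather than hidden).  Paths
exceeding t_max = 4·(2N₀) generations are discarded and counted, not
truncated.  X-linked loci use N_e = ¾ of the autosomal size throughout.

## Ancestral process conditional on a trajectory

The coded configuration evolves backward with per-generation hazards:

* **Coalescence** — the carriers form a subpopulation of I_t chromosomes, so
  the total rate is C(n,2)/I_t per generation, allocated n(n_k − 1)/2 to
  same-type mergers within type k (the standard sampling-recursion
  reversal); the deficit corresponds to cross-type collisions, which are
  inconsistent with the data and absorb probability.
* **Mutation** — the clock of a lineage runs at μ times its *observable*
  fraction: the retained genetic fraction of its coded segment at
  observation, carried unchanged through backward flank extensions and
  averaged when lineages merge.  Material a lineage acquires by backward
  extension is truncated away (forward) before observation, so it cannot
  carry observable mutations; charging it would penalise long sweep
  histories spuriously.  Under infinitely-many-sites the most recent
  coordinate of a singleton type is removed; if the shifted code equals an
  existing type the lineage merges into it (the coordinate must be a
  sample singleton).
* **Recombination** — the one model component not available in closed form
  from the literature this package reimplements, so it is stated here
  precisely as this package's model.  Ancestral material at map distance d
  from the selected site escapes to the background at per-generation rate
  d·(1 − X_u), giving the survival law S(d, t) = exp(−d·C(t)) with
  C(t) = Σ_{u=t+1}^{T−1}(1 − X_u), independently per flank.  Differencing
  adjacent survivals yields the expected exact-extent class frequencies
  P_[h](t) among carriers (they partition to one).  A lineage with break at
  interval a extends backward — the reversal of the escape that set its
  break — at rate r_int(a) times the donor frequency, with the restored
  extent b > a drawn in proportion to the selected-class donor frequency
  P_side(b, v)·X_v; donors of shorter extent cannot restore the flank and
  contribute a deficit.  Extents never shrink backward (double migrations
  excluded).  The waiting hazard between events uses the classical total
  rate γ(v, n) = C(n,2)/(λ_v X_v) + Σθ_i/2 + Σρ_i/2 (per 2N₀ generations;
  divided by 2N₀ for the per-generation geometric scan), so intact lineages
  pay the ρβ_i/2 survival charge that penalises implausibly long sweep
  histories.

An alternative "escape-reversal" convention — extension hazard
r_int(a)·(1 − X_v) with conditional extent law and an explicit
interior-escape death hazard — is implemented behind the
`selected_donor`/`paper_hazard` flags.  On data from the package's own
generator it recovers s comparably, but on the G6PD worked example it
shifts the likelihood peak upward by roughly a factor two; the
selected-donor/classical-hazard convention above is the default because it
reproduces both the simulation-study recovery and the worked example.

The proposal chooses among all admissible events in proportion to their
terms, so each accepted step multiplies the weight by ħ/(2γ), identically
for all four event kinds; the sampler cross-checks this identity against
the direct target/proposal ratio in debug mode.  A path is absorbed when a
single lineage with the intact founder code remains (the sweep's founder
carries the full ancestral haplotype by construction); a lone non-founder
lineage keeps taking mutation/recombination moves until it reaches the
founder code or the trajectory ends (rejection, weight zero), as are paths
whose next event falls beyond the trajectory.

### Exact oracle

On small instances the same measure is solved exactly by dynamic
programming over (configuration, generation): V(cfg, T−1) = 1 at the
absorbed state, and one backward induction per generation with hazard
min(γ_g, 1) and move mass w/(2γ_g).  The importance sampler's mean weight
is unbiased for this value by construction, and the test-suite asserts the
agreement for two-locus and small multilocus instances for both the Python
reference sampler and the numba kernel.  Multilocus weights are
heavy-tailed (a small fraction of paths carries much of the mass), so
agreement tests use small instances where the Monte-Carlo standard error is
honest.

## Likelihood, smoothing, intervals, age

L(s) is the double Monte-Carlo average of trajectory weight × mean
genealogy weight.  For a grid of s (25 log-spaced points by default; 15 in
the shipped reproduction scripts) the default estimator shares one
trajectory pool across the grid: each grid value anchors M backward
trajectories, every trajectory is reweighted to every s by multiple
importance sampling with the balance heuristic (the mixture of the anchors'
backward laws as the effective proposal), and the per-trajectory mean
genealogy weight — which depends on the trajectory alone — is computed once
(K paths) and reused.  The entire curve then shares a single noise
realisation, which is the strong form of common random numbers; the
pointwise estimator remains available (`estimate_loglik`, and automatically
for time-varying demography).

The raw curve is smoothed on log₁₀(s) by tricube-weighted local-linear
least squares with bandwidth 0.3 of the grid span (a fixed default standing
in for a by-eye choice); ŝ is the argmax of the smoothed curve evaluated on
a dense sub-grid.  The 95% interval is the profile-likelihood set
{s : ℓ(ŝ) − ℓ(s) ≤ 1.92} by linear interpolation, clamped to the grid with
a warning when the curve does not drop below the cutoff.  The allele-age
posterior reweights the sampled trajectory ages by trajectory weight × mean
genealogy weight at s = ŝ.

## Synthetic-data generator

`simulate_dataset` emulates the study conditions: θ = 4Nμ = 500,
ρ = 4Nr = 500, N = 10,000 diploids, present-day mutant frequency 0.60,
additive selection.  Sample size and marker count are not fixed by those
conditions; the defaults are 20 sampled chromosomes (so 12 carriers at
x₀ = 0.6, a realistic resequencing panel) and 121 markers uniform in
genetic distance with the selected site centred — dense enough that the
infinitely-many-sites placement of sweep-era mutations onto marker columns
is not column-limited at θ = 500 (the coding depends on marker positions
only through the map).

The generator (i) simulates a forward trajectory from one copy and observes
it at a random generation whose frequency lies within ±0.002 of x₀,
accepting paths in proportion to their sojourn in that band — i.e. the
flux measure matching the inference model; observing at first passage
instead biases the data toward unusually fast sweeps, which is material at
Ns = 50; (ii) builds the carriers' coalescent tree inside the trajectory
(pair hazard 1/I_t per generation); (iii) truncates ancestral flanks along
each branch with per-interval escape hazard r_int·(1 − X_u), so a leaf's
extent is the innermost escape on its root path; (iv) drops new mutations
on retained segments at rate μβ per generation onto unused marker columns
(infinitely-many-sites on the typed grid); and (v) draws background alleles
i.i.d. per column from Uniform(0,1) frequencies — adequate because the
model deliberately ignores background haplotype structure.

What the generator does *not* emulate: background linkage disequilibrium,
recurrent mutation, gene conversion, marker ascertainment, double
cross-overs restoring ancestral material, and selected-donor recombination
during the forward process.  Passing recovery tests therefore demonstrates
internal consistency of the method under its own assumptions plus escape
physics, not robustness to those real-data features.

## Numerical choices

* All probabilities in log space; binomial log-pmfs via log-gamma; weight
  averages by log-sum-exp.
* Per-generation hazards capped at 1 (can bind only when I_v is of order
  n²); the cap is applied identically in sampler and oracle.
* Waiting times by inverse-CDF on the cumulative log-survival, which is
  distributionally identical to generation-by-generation Bernoulli trials.
* Event tie-breaking and type bookkeeping follow deterministic construction
  order, so runs are bit-reproducible given the seed.
* The numba kernels (constant N only) mirror the reference implementation
  exactly; capacity limits are 64 distinct types and 16 mutation
  coordinates per type.
* Monte-Carlo standard errors use the delta method on the per-trajectory
  weights and understate the error when weights are heavy-tailed; they are
  reported as diagnostics, not used as tolerances.

## Problem sizes in the shipped scripts

The reproduction script and the end-to-end tests use 15 grid points with
M = 30 trajectories per anchor and K = 250 genealogies per trajectory
(≥ 10⁵ importance-sampling iterations per curve), and fix the synthetic
dataset's seed while the run seed drives all sampling.  These sizes were
chosen as the package's desk-scale defaults; the estimator is the same at
any budget and the original experiments (10⁶ iterations, 8 replicates per
setting) can be reproduced by raising M, K and the replicate count.

## Known limitations

* The expected class-frequency model and the recombination move rates are
  this package's own closed forms (see above); they are validated against
  forward simulation and the package's generator, not against an external
  implementation.
* The time-varying-demography path is pure Python and slow; the kernels
  assume constant N.
* Weights are heavy-tailed for large n or long maps; effective sample sizes
  should be inspected (rejection and acceptance counts are logged).
* The two-locus oracle is exponential in the number of distinct types and
  guarded accordingly.
* At weak selection (Ns of order 50) the estimator's likelihood surface is
  nearly flat over a two- to four-fold range of s above the truth, and the
  recovered MLE on this package's own synthetic data is biased upward by a
  factor of roughly 1.5-4 with large Monte-Carlo swing; moderate and strong
  selection (Ns of order 500) and the worked example are recovered well.
  The reproduction script reports whatever the estimator computes.
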