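# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limitations of the `hostvar` pipeline.

## Diversity of chemical phenotypes

Relative abundances for diversity are computed from dry-weight-standardized
intensities, **not** from Hellinger-transformed ones. The Hellinger
transform (row-wise square root of relative abundances) is applied only
before ordination and distance computation, where it tames the
double-zero problem of sparse community-style matrices; applied before
diversity it would distort the proportions that the Hill framework
interprets. A `PeakTable` passed to the diversity functions can of course
carry any transform the user prefers.

The Hill number of order q of a simplex vector p is
`(Σ pᵢ^q)^(1/(1−q))`; q = 1 is handled by the analytic Shannon limit
`exp(−Σ pᵢ ln pᵢ)` rather than by numerically approaching 1 (a regression
test checks continuity at q = 1 ± 1e-4), and q = 0 returns the count of
nonzero entries. Zero abundances contribute nothing at any order.

Hierarchical partitioning uses **equal unit weights**: γ is the Hill
number of the unweighted mean of the units' relative-abundance vectors; α
is `[(1/N) Σᵢ Σₛ p_{is}^q]^{1/(1−q)}` for q ≠ 1 and the exponential of the
mean within-unit Shannon entropy at q = 1; β = γ/α. Equal weighting is the
only convention under which β is interpretable as an effective number of
distinct units on the closed range [1, N], which is how the among-
population "number of chemotypes" is read. Plants whose intensity row is
entirely zero are excluded with a warning (their relative abundances are
undefined). Groups with one usable unit report β as missing. The
same machinery is applied at two scales: plants within a population, and
equally weighted population profiles within the global pool.

Bootstrap SEs resample **units** (plants) with replacement within their
group — never compounds, which are the variables, not the replicates —
and report the SD over replicates; the seed is recorded in the output.

## Ordination and discriminant analysis

NMDS minimizes Kruskal stress-1, `sqrt(Σ(d−d̂)²/Σd²)`, alternating
isotonic regression of the configuration distances on the rank order of
the observed dissimilarities (PAVA, which directly minimizes the stress
numerator) with SMACOF/Guttman majorization updates of the configuration.
Convergence is declared when stress falls by less than 1e-6 or after 500
iterations; the best of `n_starts` restarts (default 20) is kept, with the
first start warm-started from the classical (principal-coordinates)
solution — this reliably escapes the point-ordering local minima that
plague low-dimensional NMDS from purely random starts. Stress is reported
on the 0–100 scale used in the ordination literature.

LDA solves `S_B v = λ S_W v` by a dense generalized symmetric
eigendecomposition, retains `min(classes − 1, features)` axes scaled to
unit pooled within-class variance, and reports per-axis eigenvalue shares
("proportion of trace"). When the within-class scatter is singular —
which happens whenever rare compounds make classes linearly separable — a
ridge of `1e-6 × trace(S_W)/p` is added and a warning is logged; the
factor is configurable. Classification assigns to the largest class
posterior under **equal priors** (the study's populations are
near-balanced; equal priors avoid sample-size artifacts); empirical
priors are a constructor flag.

Resampled validation draws disjoint train/validation subsets per
iteration (defaults 90/45 at the study's sample size; the bundled
synthetic demo uses 80/40 because its certain-status subset has 120
plants), redraws any split whose training classes have fewer than two
members (counted, not raised), and summarizes the per-iteration held-out
accuracy by its mean and 2.5/97.5 percentiles — the interval is over
iterations, matching how such validation CIs are usually reported. The
default feature set is the compounds detected in every population, since
rare compounds induce the separable pathology above.

Null models: `permute_plants` shuffles status labels over plants (whole
chemotypes are reassigned, preserving the chemical covariance structure);
`permute_within_compound` shuffles each compound independently across
plants (preserving marginals, destroying covariance). Each permutation
re-runs the full resampled validation with `inner_iter` iterations
(default 100 — a deliberate scaling of the observed analysis's 10,000,
since the null mean stabilizes far faster than the tails);
`p = (1 + #{null mean ≥ observed}) / (n_perm + 1)`.

## Hierarchical Bayesian preference model

Egg counts per female over H substrates follow a Dirichlet–multinomial
hierarchy (individual preferences πᵢ around population preference Π with
concentration κ). The sampler is Gibbs on πᵢ — conjugate:
πᵢ | yᵢ, Π, κ ~ Dirichlet(κΠ + yᵢ) — with Metropolis-within-Gibbs updates
of Π (Dirichlet proposal centred at the current value) and of log κ
(random walk). Proposal scales adapt only during burn-in, targeting
acceptance in 0.2–0.5; final acceptance rates are reported in the fit
metadata. Defaults are 20,000 iterations with 5,000 burn-in.

The κ prior is half-Cauchy with scale 25, weakly informative on the scale
where κ distinguishes "females agree" (tens) from "females idiosyncratic"
(units); a Gamma(1, 0.001) alternative is selectable. A test checks the
sampler's κ posterior against a grid evaluation of the exact
Dirichlet-multinomial marginal likelihood.

Survival is analyzed two ways, because two different questions are asked
of the same counts: the multinomial machinery applied to the vector of
survivor counts across sources gives *relative support* (which source
holds the surviving larvae), while a per-source Beta-binomial with a flat
prior gives each source's *survival fraction* (the quantity plotted in
performance figures). Both are returned, labelled.

The Bayesian ANOVA of larval mass models `y_gk ~ N(μ + δ_g, 1/τ_g)` with
μ ~ N(0, precision 0.001), δ_g ~ N(0, ψ_g), ψ_g from a folded-t
(location 0, precision 0.001) with 2 degrees of freedom — the df is not
pinned down by the model statement, so it is a documented, configurable
choice — and τ_g ~ Gamma(1, 1), allowing non-homogeneous group variances.
μ, δ_g, τ_g have conjugate Gibbs updates (via per-group sufficient
statistics, so the cost per sweep is independent of sample size); ψ_g
uses adaptive Metropolis on the log scale. Only μ + δ_g is identified,
and it is stored directly as `group_mean`. Groups contributing a single
observation are excluded with a warning. Full-scale defaults are
1,000,000 iterations over 3 chains with 5,000 burn-in and 1/100 thinning;
the bundled demo and the acceptance script run 10,000–60,000 iterations,
which suffices for the group-mean summaries because the Gibbs sampler
mixes quickly on this model.

ETPIs are 2.5/97.5 percentiles with linear interpolation (type-7) — the
convention matters for the exact endpoints and is fixed here. Compact
letters for ETPI overlap use insert-and-absorb: start from one letter
covering all groups, split it on every non-overlapping pair, drop
absorbed subsets; overlapping pairs always share a letter,
non-overlapping pairs never do.

## Tetraploid population genetics

Genotype posteriors multiply the 5-component genotype likelihood by a
Hardy–Weinberg Binomial(4, p) prior at the **global** non-reference
allele frequency and normalize; the posterior mean dosage (continuous in
[0, 4]) is the genotype estimate used everywhere downstream. The ML
estimation of p itself belongs to the upstream caller; the pipeline
accepts p as input (and the minimal VCF reader falls back to a per-locus
EM under HWE only when no AF field is present). Cells with an all-zero
likelihood row become missing dosages, and covariance uses
pairwise-complete loci.

F_ST is a Nei-style G_ST computed as a **ratio of sums** across loci:
`Σ(H_T − H_S) / ΣH_T` with `H_T = 2p̄(1−p̄)` from the unweighted mean
frequency of the scoped populations and `H_S` the mean within-population
heterozygosity. The ratio-of-sums form is robust to low-heterozygosity
loci that would make a mean-of-ratios unstable. Population means are
unweighted because sample sizes per population are near-equal in the
emulated design; weighting is a flag. CIs are percentile bootstraps over
loci (default 1,000 draws, seeded). Monomorphic scopes return NaN with a
warning rather than 0/0.

Isolation by distance is a one-sided (r > 0) Mantel test of pairwise F_ST
against great-circle distance, with the +1/+1 permutation p-value
convention, so p ≥ 1/(n_perm + 1) always.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *design* of the motivating study, with the
following defaults:

* **Peak table** — 7 populations (3 colonized, 3 uncolonized, 1
  uncertain) × 20 plants × 49 compounds; 28 compounds guaranteed present
  in every population, 5 restricted to colonized and 2 to uncolonized
  populations, the rest sporadic; dry mass uniform on 100–200 mg.
  Intensities are lognormal (within-group log-SD 0.5) with
  population-level shifts (log-SD 0.3) and a status effect applied to
  half of the shared compounds; `effect_size` is that shift in
  within-group-SD units, default 0.8 — a moderate, realistic separation
  chosen once so that held-out classification succeeds clearly without
  being trivial. Presence/absence is Bernoulli per plant × compound. No
  distributional claim is made about real HPLC intensities: the lognormal
  + occupancy structure is a stand-in matching sparsity, not chemistry.
* **Genotypes** — Balding–Nichols divergence: per-population frequencies
  Beta-distributed around an ancestral Beta(0.8, 0.8) frequency with
  drift F = 0.025 (chosen to give genome-average F_ST ≈ 0.02, the weak
  structure typical of outcrossing crop-derived populations), 5
  populations of (15, 14, 14, 14, 14) individuals, 16,920 loci, Poisson
  read depth (mean 8) and symmetric per-read error 0.005. Genotypes are
  Binomial(4, p_k); likelihoods are exact binomial read likelihoods. The
  model has an analytic expectation — E[F_ST] ≈ F(K−1)/(K−F) — used in
  recovery tests. Linkage, selection, base-quality structure and
  reference bias are deliberately absent.
* **Preference** — 40 females, three substrates (two hosts + a control),
  Π = (0.5, 0.35, 0.15), κ = 20, Poisson(30) eggs truncated at 1.
* **Performance** — per-source Binomial survival of 60 larvae and
  lognormal masses with specified mean/SD per source.

Passing tests on these data show the *estimators* are correct and
well-calibrated under the stated models; they cannot show that real peak
tables or read data satisfy those models.

## Orchestration and determinism

A master seed deterministically derives a fixed child seed per named
stage (seed-sequence over a stage registry), so toggling one stage never
shifts another's stream; two runs with the same configuration are
byte-identical in their JSON summaries (floats rounded to 10 decimal
places before serialization purely to keep the files readable). All
warnings raised inside stages are captured once each into the run log.
The bundled default configuration runs every stage at demonstration scale
(reduced chain lengths, permutation counts and locus numbers, documented
above) so a complete run takes well under a minute; full-scale settings
are the library defaults and are exposed as configuration keys and CLI
flags.

## Known limitations

* "Multiple Mantel" analyses are implemented as pairwise Mantel tests;
  partial Mantel (controlling a third matrix) is intentionally not
  provided.
* The LDA assumes shared within-class covariance; no quadratic variant.
* The preference model has no covariates and no zero-inflation; females
  who lay zero eggs are dropped as uninformative rather than modelled.
* F_ST estimation from posterior-mean dosages inherits whatever shrinkage
  the HWE prior induces at low depth; at the default depth 8 this is
  visible as a mean absolute dosage error of ~0.3 allele copies and a
  mild compression of pairwise F_ST spread.
* NMDS reports the best local optimum found; as with any NMDS, global
  optimality is not guaranteed.
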