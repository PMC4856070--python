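# Methods

## Model

`bmnb` fits a GBLUP-style hierarchical model for count phenotypes recorded
across several environments.  With y_ijkt the count for replicate t of line
j in block k of environment i,

    y_ijkt | g_j, gE_ij ~ NB(μ_ijk, r),        log μ_ijk = η_ijk,
    η_ijk = E_i + R(E)_ik + g_j + gE_ij,
    g ~ N(0, G1 σ₁²),     gE ~ N(0, (I_I ⊗ G1) σ₂²),

where G1 is the genomic relationship matrix WWᵀ/q built from 0/1 marker
codes (or the identity when lines are treated as i.i.d.), and the Kronecker
identity factor assumes independence of the interaction across
environments.  The NB parameterization is mean/dispersion: E[y] = μ,
Var[y] = μ + μ²/r, so r → ∞ recovers the Poisson; the Poisson model is run
as the same sampler with r fixed at a large value (1000 for mean counts
below 50, 5000 up to 200, 10000 beyond — boundaries assigned to the larger,
safer value).

Writing the NB pmf in logistic form with shifted environment coefficients
β*_i = β_i − log r makes every full conditional available in closed form
after two augmentations: Pólya-Gamma weights ω_ijkt ~ PG(y_ijkt + r, η*_ijk)
linearize the likelihood in (β*, g, gE), and Chinese-restaurant-table counts
L_ijkt ~ CRT(y_ijkt, r) make the conditional of r a gamma distribution,

    r | L, π ~ Gamma(a0 + Σ L_ijkt,  rate  b0 − Σ log(1 − π_ijkt)),

with π = logistic(η*).  Conditionals: β* and the random-effect blocks are
Gaussian with precision (prior precision + ZᵀDωZ) and a κ = (y − r)/2
pseudo-response; the variance components are scaled inverse chi-square
χ⁻²(ν + n_b, (bᵀG⁻¹b + νS)/(ν + n_b)).

## Scan order

The dispersion conditional above is derived with ω integrated out, so the
implemented scan is

    L → r → ω → β* → b1 → b2 → σ₁² → σ₂² → (σβ²),

i.e. ω is refreshed immediately after r changes and before any Gaussian
block uses κ = (y − r)/2 — a partially collapsed Gibbs sampler.  Refreshing
ω *before* the r step instead couples a stale ω (drawn under the old r) with
the new κ in the Gaussian updates; empirically that variant is explosive
(an upward excursion of r drives β* far negative, the gamma rate collapses
to b0 and r diverges), whereas the implemented order passes a
successive-conditional ("getting it right") simulation test: alternating
prior draws, data simulation and Gibbs transitions leaves the prior
marginals of β*, σ², r invariant on a tiny model.

## Priors and defaults

Real-data defaults (weakly informative): β* ~ N_p(0, 10⁴·I) with σβ² fixed
at 1, σ₁², σ₂² ~ χ⁻²(3, 0.001), r ~ Gamma(0.01, 1/0.01).  σβ² is sampled
only when ν_β, S_β are supplied explicitly.  Simulation-study priors
(`PriorSpec.simulation`): χ⁻²(0.50002, 4.0002) for both variances and
Gamma(0.001, 1/0.001) for r — approximately flat.  An improper flat β*
prior is available; because cell-means environment coding plus per-
environment block indicators is rank deficient, the sampler then drops the
last block column of each environment (the proper prior regularizes the
full coding instead).  No thinning by default; a `thin` option exists.

## Pólya-Gamma and CRT samplers

PG(b, c) draws use the infinite-convolution-of-gammas representation
truncated after 32 terms, with the remainder replaced by one gamma variate
matched to the remainder's exact mean and variance (closed forms of
Σ 1/((k−1/2)²+z) and its derivative, with series branches near z = 0).
The first two moments are exact for every (b, c); the truncation error is
confined to higher cumulants of a tail that carries ≲1% of the mass, and
the sampler handles arbitrary real b — including b = y + r ≈ 10³ under the
fixed-r Poisson model — while vectorizing across records.  Moment tests
over b ∈ {0.5, …, 1000}, c ∈ {0, …, 10} and a two-sample KS additivity test
(PG(b1+b2,c) vs PG(b1,c)+PG(b2,c)) enforce correctness.  CRT(y, r) keeps
the defining O(y) Bernoulli construction (counts here are at most a few
hundred), vectorized over records with precomputed trial indices; a
gamma-rate approximation for very large y exists in the literature but is
deliberately not used.

## Numerical choices

* π and log(1−π) are computed with `logaddexp`/`log1p` identities; the NB
  log-likelihood uses log-gamma throughout, so no clamping of η* is needed
  anywhere (stable primitives replace the cruder clamp-at-±30 alternative).
* Gaussian conditionals are drawn via Cholesky factors of the precision;
  the b2 update exploits the block structure of I ⊗ G1, costing I
  independent J-dimensional solves per scan.
* G1 gets a 10⁻⁶ ridge only if its Cholesky fails (marker-derived GRMs are
  frequently rank deficient); the GRM itself is the plain WWᵀ/q with no
  allele-frequency centering.
* Missing marker calls surviving the MAF/missingness filter (defaults 0.05
  and 10%) are imputed to the marker's modal code, logged.
* Chains abort with a diagnostic on any non-finite state.
* Every stochastic routine takes an explicit `numpy.random.Generator`; one
  seed reproduces a whole run bit-identically (replication seeds are
  spawned via `SeedSequence`).

## Synthetic data

`simulate_panel` draws from exactly the generative model above, so recovery
tests exercise the sampler under correct specification.  The named
configurations mirror the simulation study: I = 3 environments, J = 20
genotypes, β = (1.5, −1, 1), σ₁² = σ₂² = 0.5, r = 5, n ∈ {5, 10, 20, 40}
replicates per cell, with G1 = I (scenario 1) or 0.7·I + 0.3·J (scenario 2,
imitating the between-line correlation of real genomic data).  What the
generator does **not** emulate: real marker data (G1 is specified directly,
not built from simulated genotypes), unbalanced replication, missing
plots, zero inflation beyond what the NB produces, and model
misspecification of any kind — passing recovery tests therefore shows
sampler correctness, not robustness to violations of the model.

## Test and study scales

Recovery checks run 4,000 iterations with 2,000 burn-in over 10
replications (5 at n = 40), a scale at which the replication-averaged
posterior means sit comfortably inside twice the cross-replication SDs of
the reference table; the library defaults remain 20,000/10,000 (simulation)
and 60,000/30,000 (real-data fits).  The tiny-model oracle compares Gibbs
posterior means against a dense-grid posterior on the unaugmented NB
likelihood (tolerance 0.05); conditional-distribution oracles use KS tests
at α = 0.01 on 10⁴ draws.

## Cross-validation

Folds are a seeded uniform random partition of records (sizes differing by
at most one), re-randomized (bounded) until every training complement
contains every environment; per-environment stratification is available by
flag.  Predictions for held-out records use the posterior draws of g and gE
as sampled — lines absent from a training fold are predicted through their
prior-conditional draws, which is what makes marker-informed G1 useful.
Spearman correlations use average ranks (counts tie often) and are reported
as missing for constant vectors.  Scenario comparisons (S1–S4: lines i.i.d.
vs marker GRM, with/without the interaction) rank scenarios per environment
by Cor (descending) and MSEP (ascending), averaging the two ranks.

## Known limitations

* Single trait, single dispersion parameter shared across environments.
* No zero-inflated extension.
* The CRT step is O(Σy); astronomical counts would need the gamma-rate
  shortcut.
* Normal/log-normal baselines for count data are out of scope (standard
  GBLUP software fits those).
* Real multi-environment data can be strongly unbalanced; the design code
  supports it, but the recovery evidence here is from balanced panels.
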