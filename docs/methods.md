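# Methods

## Data model

The data are counts `y_gbc` from a completely randomised design with groups
`g = 1..G`, clusters `b = 1..B_g` nested in groups, and nominal categories
`c = 1..C`.  Each cluster contributes a full count vector with total
`m_gb = Σ_c y_gbc`; `m_g = Σ_b m_gb` is the group total, `n = Σ_g B_g` the
number of clusters and `N = nC` the number of cells.  The working model is
`y_gb ~ multinomial(m_gb, π_g)`; the central concern is that biological
variation between clusters (litters, animals, donors) makes the realised
covariance larger than the multinomial one.

Two accommodations are implemented:

1. **Quasi-likelihood**: `Cov(y_gb) = ϕ Σ(y_gb)` with
   `Σ(y_gb) = m_gb (Diag(π_g) − π_gᵀπ_g)`.  The mean structure (and hence
   all point estimates) is untouched; every covariance, and therefore every
   standard error, is scaled by `ϕ` (by `√ϕ`).
2. **Dirichlet-multinomial (DM)**: cluster probabilities are draws
   `π_gb ~ Dirichlet(α_g)`, giving
   `Cov(y_gb) = ((m_gb + α_g·)/(1 + α_g·)) Σ(y_gb)` with `α_g· = Σ_c α_gc`.
   At common cluster size `m` the implied dispersion is
   `ϕ_DM = (m + α)/(1 + α)`, which tends to 1 (the multinomial limit) as
   `α → ∞` and is bounded above by `m`.

## Parameters of interest

Comparisons are defined by two row-centred contrast matrices: `A` (I×C)
builds within-group log odds `δ_g = A log π_gᵀ` and `B` (J×G) compares them
between groups.  The joint parameter is

    θ = (B ⊗ A) (log π₁ᵀ, …, log π_Gᵀ)ᵀ,

a K = I·J vector of log odds ratios ordered by group comparison and, within
each, by category contrast.  Dunnett-type (versus a reference level),
Tukey-type (all pairs) and each-versus-grand-mean matrices are generated on
demand; arbitrary matrices can be supplied, and rows must sum to zero unless
validation is explicitly disabled.  Row subsetting is an explicit user
operation (`ContrastPair.subset`), never automatic.

An equivalent parametrisation acts on the baseline-category coefficients β
(category 1 baseline, group 1 reference): with `A*` equal to `A` without its
first column and `B0` equal to `B` with its first column zeroed,
`(B0 ⊗ A*) β = (B ⊗ A) · stacked log π` for every probability table.  Both
routes are implemented and tested against each other to 1e−12.

## Estimation

With group as the only factor, the multinomial MLE is the pooled group
proportion `π̂_gc = Σ_b y_gbc / m_g` (closed form).  With additive
cluster-level factors (e.g., a donor block), the baseline-category logit
likelihood is maximised by Newton iteration with the exact Fisher
information; convergence is declared when the maximum absolute score falls
below 1e−8 (at most 100 iterations), and coefficients drifting past ±30 on
the logit scale raise a separation error.  The parameter count `P` is
`G(C−1)` in the group-only case and the number of estimated coefficients
otherwise.

Lack of fit is measured by Pearson's `χ² = Σ (y − m π̂)² / (m π̂)` and the
deviance `D = 2 Σ y log(y / (m π̂))`, summed over all cells, with the usual
convention `0·log(0/μ) = 0`.  The four dispersion estimators are

    ϕ̂_P = χ² / df                 df = N − n − P
    ϕ̂_D = D / df
    ϕ̂_F = (χ² − (N − n)·s̄) / df
    ϕ̂_A = (χ² / df) / (1 + s̄)

where `s̄` is the mean over all N cells of the relative residual
`s_gbc = (y_gbc − m_gb π̂_gc)/(m_gb π̂_gc)`.  Pearson and deviance are the
classical moment estimators; the Farrington and Afroz variants subtract or
divide out the small-sample bias that `χ²` accrues on sparse tables, and the
Afroz estimator is the least-biased choice and the default.  No floor at 1
is applied (quasi-likelihood admits underdispersion); a negative Farrington
estimate (possible for extreme negative `s̄`) is floored at 1e−6 with a
warning.  `df ≥ 1` is required — a saturated model cannot support a
dispersion estimate.

The DM model is fitted per group (groups are independent) by maximising the
DM log-likelihood over `log α_g`, which makes the positivity constraint
implicit.  The optimiser is L-BFGS-B with the analytic digamma gradient,
started from method-of-moments values (pooled proportions scaled by a
moment estimate of `α·`), bounded above at `α = 1e8`.  The covariance of the
log-shape estimates is the inverse observed information, computed by
central differences with step 1e−4 — the per-group dimension is small
(C ≤ ~10), so this is cheap and robust.  When a group shows no
between-cluster variation the likelihood is maximised on the multinomial
boundary; totals `α_g· > 1e5` are flagged as boundary fits with a warning
(the likelihood is numerically flat there and the implied dispersion is
within 5e−4 of 1 for any m ≤ 100).

Because every row of `A` sums to zero, `A log π_g = A log α_g`: contrasts of
log shapes equal contrasts of log mean probabilities, so
`θ̂ = (B ⊗ A) · stacked log α̂` with covariance
`(B ⊗ A) V̂_{log α} (B ⊗ A)ᵀ`.  This makes the unconstrained log-shape
parametrisation exactly equivalent, for these contrasts, to
mean-parametrised DM regressions.

## Simultaneous inference

The delta method gives each group's log-odds covariance

    Σ_g = m_g⁻¹ (A Diag(π_g)⁻¹ Aᵀ − A 1 1ᵀ Aᵀ),

(the second term vanishes for row-centred A but is computed as written),
and the joint covariance

    V = (B ⊗ I_I) · blockdiag(ϕΣ₁, …, ϕΣ_G) · (B ⊗ I_I)ᵀ.

Tests use `t_k = θ̂_k / √V̂_kk` compared against the two-sided equicoordinate
quantile `q` of a central multivariate t with correlation `R̂`
(standardised `V̂`) and `df = N − n − P`.  The residual df is the natural
choice given that the same df standardises the dispersion estimate; it is
configurable (`df=inf` switches to multivariate-normal quantiles, also
exposed for the DM model, whose reference df is not clear-cut).  Adjusted
p-values are `p_k = 1 − P(max_j |T_j| ≤ |t_k|)` and simultaneous intervals
are `exp(θ̂_k ± q √V̂_kk)`.

Rectangle probabilities `P(max |T_k| ≤ q)` are evaluated with scipy's
quasi-Monte-Carlo integrators for the multivariate t and normal
distributions, seeded for reproducibility.  The default integration budget
achieves about 5e−5 absolute accuracy (measured against a 2·10⁶-point
reference); requesting `tol < 1e−4` increases the point budget
proportionally.  The critical value solves
`P(max ≤ q) = 1 − α` by Brent root-finding on the deterministic
(seed-fixed) probability, bracketed between the unadjusted two-sided
t-quantile and the Bonferroni quantile, which bound the root for any
correlation structure.  A correlation matrix that is numerically not
positive semidefinite is repaired by eigenvalue clipping at 1e−10 with a
loud warning.  More than 1000 simultaneous comparisons are rejected with a
pointer to Bonferroni — beyond that size the QMC quantile is neither fast
nor reliable.

Decision consistency (`|t_k| > q ⇔ p_k < α`) holds up to the integration
tolerance; the tests check it outside a ±2e−3 band around α.

## Zero cells

A category with zero counts in *every* cluster of a group makes `log π̂`
infinite.  The pseudo-observation heuristic adds a count of 1 to exactly one
cluster per affected group×category cell: either a seeded uniformly random
cluster or the cluster with the largest total (ties to the lowest cluster
position, for determinism).  Both appear in practice — random assignment is
natural inside simulation loops, the largest cluster perturbs the observed
proportions least.  Neither is applied by default: the adjustment alters the
data and must be opted into.  Cluster-level zeros are ordinary data and are
never touched.  A group with no counts at all cannot be repaired and raises
an error.

## Synthetic data generator

`simulate_dataset` draws, for each cluster, `π_gb ~ Dirichlet(α π_g)` with
`α = (ϕ − m)/(1 − ϕ)` and then `y_gb ~ multinomial(m, π_gb)`.  With common
cluster size and dispersion the generated data satisfy both the
quasi-multinomial and the DM covariance structure simultaneously, so both
model families are correctly specified under the default generator — a
deliberate property of the study design.  Options mirror the harder
settings: per-group `ϕ` (heterogeneous dispersion) and cluster sizes drawn
as Poisson(m) truncated at 1 (truncation avoids empty clusters; the
dispersion target then refers to the mean size).

What the generator does **not** emulate: latent-logit (logistic-normal)
overdispersion, where the mean–variance relation differs from the DM one and
all methods here are known to become liberal; covariate-driven cluster
heterogeneity; ordinal category structure; missing or truncated cluster
records.  Passing operating-characteristic tests therefore demonstrates
correctness under cluster-compounded multinomial variation, not robustness
to arbitrary real-data violations.

Reference conditions used throughout the tests and the acceptance script
follow the simulation design: G=4 groups, C=3 categories, Dunnett-type
contrasts on both margins, B_g ∈ {20, 50} clusters of size m ∈ {50, 100},
dispersion ϕ ∈ {1.01, …, 8}, nominal level α = 0.05, 1000 replicates for
headline numbers (Monte-Carlo SE ≈ 0.007 at a rate of 0.05).  Scaled-down
replicate counts (300–400) are used for secondary in-suite checks, with
correspondingly widened Monte-Carlo bands.

## Study harness

`run_study` replays the full pipeline per replicate and reports

* **FWER** — share of datasets with at least one rejected true null,
* **power** — proportion of false nulls rejected, pooled over datasets,
* **coverage** — share of datasets whose simultaneous intervals contain
  every true `θ_k`,

each with the binomial Monte-Carlo standard error `√(p̂(1−p̂)/nsim)`.
Per-replicate seeds derive deterministically from (master seed, scenario
index, replicate index) via numpy `SeedSequence` spawn keys, so studies are
exactly reproducible and safe to parallelise.  Replicates where a method
fails (unadjusted zero cells, non-convergence) are counted per method and
excluded from that method's denominator rather than silently dropped.

Two exact algebraic shortcuts keep the harness fast without changing any
decision: the plain and all quasi methods share `R̂`, df and critical value
(their t statistics differ only by the factor `1/√ϕ̂`), and an FWER-only run
needs a single tail probability at `max |t_k|` over the true nulls instead
of K adjusted p-values.

## Known limitations

* A single global ϕ is estimated; strongly group-heterogeneous dispersion
  makes the quasi methods liberal.  Per-group DM totals `α_g·` capture this
  case; per-group ϕ estimation is not implemented.
* The DM standard errors come from the observed information of a per-group
  fit; very small groups (2–3 clusters) give unstable Hessians.
* One-sided alternatives, step-down procedures and FDR control are out of
  scope; the adjustment is the single-step max-t procedure throughout.
* The multinomial GLM supports additive factor covariates only (no
  continuous covariates, interactions or weights).
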