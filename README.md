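# odmc — multiple comparisons for overdispersed multinomial data

`odmc` performs simultaneous inference on sets of log odds ratios estimated
from **clustered multinomial count data** — the kind of data produced by
toxicology studies (litters of foetuses classified as alive / malformed /
dead), differential blood counts (leukocytes per animal classified into cell
types) or flow cytometry (cells per sample classified by marker state).
Counts from the same cluster (litter, animal, sample) are correlated, so the
data are usually **overdispersed** relative to a plain multinomial model:
ignoring this inflates the type I error of every comparison, badly.

The package is aimed at biostatisticians who need, in one coherent
procedure:

* flexible **contrast machinery** for the comparisons of interest — a
  row-centred matrix `A` (I×C) picks category odds, a matrix `B` (J×G)
  picks group comparisons, and the parameter vector is
  `θ = (B ⊗ A) · (log π₁ᵀ, …, log π_Gᵀ)ᵀ`, a vector of K = I·J log odds
  ratios (Dunnett, Tukey and grand-mean contrasts are built in);
* **overdispersion corrections**: four quasi-likelihood dispersion
  estimators — Pearson `ϕ̂_P = χ²/df`, deviance `ϕ̂_D = D/df`, Farrington
  `ϕ̂_F = (χ² − (N−n)·s̄)/df` and Afroz `ϕ̂_A = ϕ̂_P/(1+s̄)`, with
  `df = N − n − P` — or, alternatively, a **Dirichlet-multinomial (DM)
  model** fitted by maximum likelihood per group;
* **single-step max-t multiplicity adjustment**: the critical value is the
  two-sided equicoordinate quantile `q` of a multivariate t distribution
  with the estimated correlation `R̂` of the contrast estimates, giving
  adjusted p-values and simultaneous confidence intervals
  `exp(θ̂_k ± q·SE_k)` that jointly cover at 1−α;
* a **zero-cell heuristic**: when a category is observed in no cluster of a
  group, a single pseudo-count of 1 is added to one cluster (random or
  largest), restoring finite estimates and standard errors;
* a **simulation harness** that generates Dirichlet-multinomial data at a
  specified dispersion ϕ (via `α = (ϕ−m)/(1−ϕ)`, so that
  `(m+α)/(1+α) = ϕ`) and measures the family-wise error rate, power and
  simultaneous coverage of each method.

## Worked example

Counts live in long format, one row per (group, cluster, category):

```csv
group,cluster,category,count
control,g1b1,alive,28
control,g1b1,malformed,1
control,g1b1,dead,1
...
```

With a Dunnett-type contrast on both margins (each category's odds versus
the baseline category, each dose versus control), the `fit` command runs the
whole pipeline:

```sh
odmc fit --counts example_counts.csv --contrasts example_contrasts.json \
         --model quasi --dispersion afroz --seed 1
```

```
# model: quasi
# dispersion: afroz
# phi_hat: 2.171226444888936
# df: 66
# K: 4
# alpha: 0.05
# crit: 2.526010037748154
...
label	log_estimate	se	t	p_adj	odds_ratio	ci_lower	ci_upper
malformed/alive: low-control	-0.00241838	0.297672	-0.00812431	1	0.997585	0.47032	2.11595
dead/alive: low-control	0.237532	0.459382	0.51707	0.964882	1.26812	0.397377	4.04683
malformed/alive: high-control	0.575364	0.285344	2.01639	0.159293	1.77778	0.864662	3.65518
dead/alive: high-control	1.54045	0.39708	3.87943	0.000947849	4.66667	1.71158	12.7238
```

Reading the output: the data show clear extra-multinomial variation
(`ϕ̂_A ≈ 2.17`), so every standard error has been inflated by √2.17 relative
to a plain multinomial fit.  After the max-t adjustment across the K=4
simultaneous hypotheses (critical value 2.53 instead of the unadjusted
t-quantile 2.00), only the dead/alive odds at the high dose differ
significantly from control: the odds ratio is 4.67 with simultaneous 95%
confidence interval [1.71, 12.72] and adjusted p ≈ 0.001.  The same
comparison under `--model plain` would report smaller intervals that are not
justified by the data.

The same workflow is available as a library:

```python
from odmc import read_counts, ContrastPair, dunnett_matrix, run_inference

ct = read_counts("example_counts.csv")
cp = ContrastPair(dunnett_matrix(ct.n_categories), dunnett_matrix(ct.n_groups),
                  category_labels=ct.categories, group_labels=ct.group_levels)
res = run_inference(ct, cp, model="quasi", dispersion_method="afroz", seed=1)
print(res.phi_hat, res.crit, res.p_adj)
```

Other entry points: `odmc adjust-zeros` (pseudo-observation adjustment with
a JSON report), `odmc simulate` (one synthetic dataset from a scenario
config) and `odmc study` (FWER / power / coverage over a scenario grid).

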