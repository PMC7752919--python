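# Methods

This note records the statistical choices behind `metacohort`: the models,
their assumptions, the defaults and why, what the synthetic generator does
and does not emulate, and known limitations.

## Per-feature technical correction

Each feature is modeled independently within a dataset with a linear mixed
model: fixed effects for the center of origin (sum-to-zero coded), MSI
status (its own "unknown" level, so no samples are dropped) and the three
array quality metrics (mean-centered); a random intercept for the scan
batch (scanning day; plate for the RNA-seq design, which omits the metric
and MSI terms).  Variance components are estimated by REML through
statsmodels `MixedLM`.

Decisions and degenerate cases:

* **Batch as a random effect, removed via BLUPs.**  The shrunken per-batch
  predictions are subtracted, so small or noisy batches are corrected
  conservatively.  A fixed-effect batch option (`batch_as_fixed=True`)
  exists for users who prefer full subtraction.
* **OLS fallback.**  When a feature has a single batch level, a boundary
  (zero) batch-variance estimate, or a failed mixed fit, the model is refit
  by OLS without the batch term and the feature is flagged.  When the true
  batch variance is zero the two paths agree.
* **Grand-mean preservation.**  Sum-to-zero coding makes level effects sum
  to zero over *levels*, but with unbalanced designs not over *samples*;
  the estimated technical component is therefore centered across samples
  before subtraction, preserving each feature's grand mean exactly under
  any imbalance.
* **MSI is estimated but retained.**  Whether corrected values should keep
  MSI-associated signal is an interpretation question; it is kept here as a
  biological covariate (removing it would erase real tumor biology), and
  the estimate only serves to keep it out of the technical terms.
* **Aliased design columns** are dropped greedily (first column wins), and
  a single-level center term is dropped with a log message.

## First-PC gene summarization

For a gene with probesets P (rows) over samples, the first eigenvector *v*
of the probeset covariance matrix (denominator n−1) defines the score
`s = v' (x − mean)`.  The score is mapped to the intensity scale by an
affine transform targeting mean `Σ w_p mean_p / Σ w_p` and SD
`Σ w_p sd_p / Σ w_p` with `w_p = |v_p|`; the sign is made canonical by
requiring non-negative correlation with the probeset of maximal |loading|
(ties broken by annotation order).  Consequences:

* the output is invariant to the arbitrary sign returned by the
  eigendecomposition backend and to probeset ordering;
* weights must be non-negative for the target mean to be a convex
  combination, hence |loadings| rather than signed loadings ("squared" and
  "signed" are available as options for sensitivity analyses);
* single-probeset genes pass through untouched; genes whose probesets have
  zero total variance return the constant mean row with a warning;
* PCA is covariance-based because probesets share the log2 intensity
  scale; a correlation-based switch exists.

## Standardization to the reference cohort

The pipeline order is fixed: correct → summarize → quantile-normalize →
standardize → truncate → merge.  Quantile normalization maps every sample's
sorted values onto the reference quantile profile (mean of sorted reference
samples), averaging tied values over their rank span; a feature-count
mismatch is linearly interpolated only on request.

The gene-wise robust standardization uses a **weighted median** (smallest
value whose cumulative weight reaches half the total, midpoint at exact
halves) and a **weighted MAD** with the same rule and *no* consistency
constant — the reference side uses the raw unweighted MAD, so a constant
would not cancel and is applied on neither side.  A zero weighted MAD
triggers a location-only shift (logged).

**IPW weights.**  For each dataset D, a logistic regression of dataset
affiliation (D vs reference) is built over gender, age, site, MSI and stage
by forward stepwise selection on AIC, starting from the intercept-only
model and stopping when no addition improves the AIC; covariates hit by
complete separation are skipped with a warning.  Weights are the
probability ratio, truncated at 5 so no sample dominates.

*Direction of the ratio.*  The default (`pd_over_pr`) follows the ratio
Pd/Pr of the modeled probabilities of belonging to D versus the reference.
Note that this direction up-weights samples *typical of D*; reweighting D
to resemble the reference composition — the direction under which
covariate balance (standardized mean differences against the reference)
provably improves — is the inverse, available as
`direction="pr_over_pd"`.  Both are exposed because the appropriate
direction is a modeling intent the software cannot infer; balance
diagnostics in the test suite use the conventional (`pr_over_pd`)
direction.

Whether the reference's own median/MAD should be weighted is a second open
choice; they are unweighted here (the reference defines the target scale).

Truncation to the reference per-gene [min, max] happens after
standardization; merging keeps the gene intersection (association requires
complete rows) and drops unknown-stage samples with per-dataset counts
logged.

## Association battery

* Tertile groups are rank-based (cut at n/3 and 2n/3 using minimum ranks),
  so ties never straddle a boundary — tied samples all fall in the lower
  group — and the grouping is invariant under strictly monotone transforms
  of expression.  Fewer than three distinct values is an error.
* Cox models use the Breslow tie approximation by default (Efron as an
  option); the overall test is a likelihood-ratio test against the null
  (the null partial likelihood is the same model at β = 0), pairwise
  contrasts are Wald z-tests, and CIs are Wald intervals on the log scale.
  Monotone-likelihood configurations (a group with all or no events) are
  flagged, with estimates reported under a warning.  Models are unadjusted
  beyond the group factor; "adjusted group means" belong to the stage
  linear model.
* The stage model is OLS on the stage factor; with no further covariates
  the adjusted means equal per-stage sample means, with t-based 95% CIs.
  Constant expression is reported as F = 0 rather than NaN.
* Kaplan–Meier curves come from lifelines' product-limit estimator; empty
  groups are omitted with a warning.
* Endpoint-specific selection: relapse uses stages I–III only; overall
  survival is split into pre-metastatic (I–III) and metastatic (IV)
  strata; unknown stage is always excluded; rectum samples of designated
  datasets can be excluded from outcome analyses.
* The significance threshold used in examples and reports is 5%.

## Deterministic calculators

* `de_filter` removes genes under the read-count floor *before*
  Benjamini–Hochberg adjustment (when raw p-values are supplied), then
  applies `padj < cutoff` and `|lfc| > cutoff`.  The base of the
  fold-change column is declared by the caller (`lfc_base`), because
  published thresholds are ambiguous between log2 and log10 conventions;
  the default assumes log2.
* Overlap statistics: intersection count, Jaccard `|A∩B|/|A∪B|`, and the
  one-sided hypergeometric upper tail for enrichment.
* ΔΔCt assumes doubling efficiency; duplicate wells are averaged in Ct
  space before any differencing (the two orders commute because ΔΔCt is
  linear in Ct).
* Percent input uses the dilution-adjusted formula
  `100 · 2^((Ct_input − log2(1/f)) − Ct_IP)` with the input fraction `f` a
  required explicit argument, since unreported dilution handling is the
  main source of irreproducible ChIP-qPCR numbers.

## The synthetic generator

`generate_meta_cohort` emulates the structure the pipeline is built for:
several datasets whose probeset values are
`intercept + loading × gene signal + center offset + batch offset +
metric slopes · metrics + noise`, with per-dataset clinical composition
tables (gender/site/MSI/stage probabilities, age mean) that drift across
datasets, an MSI expression shift on a fraction of genes, and survival
endpoints drawn from an exponential hazard
`h0 · exp(β · z_target)` with administrative censoring — chosen for its
closed-form event probability `1 − exp(−h·C)` under the null.  Relapse
follow-up exists only for stages I–III, mirroring how relapse endpoints
are defined.  One seeded RNG is spawned into a structure stream plus one
stream per dataset with a documented draw order, so runs are byte-for-byte
reproducible and appending datasets does not perturb earlier ones.

Defaults (4 datasets × 120 samples, 400 genes with 1–4 probesets,
`batch_effect_sd` 1.0 and `center_effect_sd` 0.5 log2 units, noise SD 0.3,
baseline hazard 0.02/month with 60-month censoring, log HR = log 2 per SD
of the target gene) are desk-scale stand-ins for a meta-cohort three orders
of magnitude larger.  Scan batches default to 10 per dataset (~12 arrays
per scanning day); a much coarser batch structure leaves the REML variance
component with too few degrees of freedom and the estimate collapses to
the boundary.  The generator does **not** emulate probe-level (CEL) data,
count overdispersion, copy-number structure, platform-specific probe
affinity, or informative censoring — so a green test establishes that the
pipeline recovers the stated generative structure, not that it removes
every artifact of real arrays.

## Numerical notes and limitations

* Weighted-median midpoint interpolation triggers on exact cumulative-weight
  halves (relative tolerance 1e-12); with continuous weights it is rare.
* The stepwise logistic fit declares separation on non-finite estimates or
  optimizer failure; near-separation can still produce extreme weights,
  which the truncation at 5 bounds.
* Mixed-model fits use statsmodels' default optimizer sequence; a
  zero-boundary batch variance (below 1e-10) is treated as "no usable
  random effect" and routed to the OLS fallback.
* Per-feature mixed models are fitted independently (no information
  sharing across features); with very few samples per batch the BLUPs
  shrink heavily and residual batch signal survives correction.
* The corrector's `transform` is only valid for the samples seen at fit
  time: batch predictions and the design are sample-specific by
  construction.
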