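# Methods

This note documents the models, algorithms and design choices behind
`tcrbm`, in the order the pipeline runs them.

## Synthetic trial generator

The generator (`tcrbm.synthetic`) emulates a four-cohort, 45-patient
single-infusion trial of an NY-ESO-1-directed TCR T-cell product, which is
the default study condition for every test and the acceptance script:

- **Clinical table.** Cohort sizes drawn with weights 12/13/5/15 out of 45;
  cohorts 1–2 receive standard fludarabine + cyclophosphamide
  lymphodepletion, cohort 3 cyclophosphamide only, cohort 4 a reduced
  regimen. Responder probabilities per cohort default to 0.50/0.31/0.20/0.27
  (the observed investigator-assessed response rates). Transduced cell dose
  is log-normal around 3×10⁹ cells, clipped to the protocol window
  [1×10⁹, 6×10⁹]; body weight is normal (70, 15) kg truncated at 40 kg.
- **Cytokines.** Log concentrations follow the same LME the analysis fits
  (categorical timepoint grid: baseline −7, day 0, 1, 4, 7, weeks 2–8),
  with a post-infusion activation pulse peaking days 4–7, a responder ×
  time elevation for the proinflammatory analytes, a pre-infusion responder
  elevation for IL-15, and σ_b = σ_e = 0.5 on the natural-log scale. Values
  below the per-analyte LLOQ are reported at the LLOQ and flagged censored.
  The study does not publish per-analyte LLOQs, so defaults are chosen per
  analyte to produce realistic censoring (GM-CSF and IL-17A mostly below
  LLOQ, the others mostly quantifiable) and are configurable, not inferred.
- **Flow product panel.** Viable CD3 counts ~ Poisson(50 000) with a 5%
  low-viability acquisition rate (≈3000 cells) to exercise the QC rule;
  CD8⁺Pentamer⁺ frequency 0.20 of viable CD3, CD4⁺Pentamer⁺ 0.02 (the
  pentamer chiefly stains CD8 cells). Memory composition of the
  CD8⁺Pentamer⁺ compartment is Dirichlet around
  (Naive, TSCM, CM, EM, TEMRA) = (0.18, 0.12, 0.22, 0.28, 0.20) for
  responders and (0.26, 0.14, 0.25, 0.12, 0.23) for non-responders — about
  28% vs 12% effector memory, mirroring the reported product contrast.
  Healthy-donor noise levels default to 10⁻³ (CD8 parent) and 5×10⁻⁴ (CD4).
- **Expansion.** log Cmax = 2.0 + 0.8·log(dose/kg) + 1.0·1[standard LDR]
  + N(0, 0.8), mapped onto a fixed log-quadratic rise/decay shape peaking
  at day 7 (width 0.55 in log-days) and sampled on the qPCR monitoring
  grid with 0.25 multiplicative noise; copies below 50/µg report 0
  (detection limit). The log-quadratic shape reproduces the monotone
  dose→Cmax and LDR→Cmax associations with minimal parameters.
- **Expression.** 120 endogenous probes hosting a bundled toy gene-set
  collection, plus 10 housekeeping, 6 positive (geometric ladder) and 8
  negative probes. Counts are negative-binomial (dispersion 0.08) around
  log-normal gene means with a per-sample lane factor (SD 0.2 log2), the
  over-dispersion typical of nCounter data. Ten pre-infusion and five
  at-progression biopsies by default; macrophage-set genes shift −1 log2 at
  progression, interferon-downstream genes +1.5 log2 in non-responder
  pre-infusion samples, antigen-presentation genes −0.8 log2 at progression.
  Genes unique to the bundled checkpoint set beyond its first five stay off
  panel so the coverage filter has realistic work.
- **Survival.** PFS and OS are exponential with log-hazard −0.6 per unit of
  centered log Cmax (higher expansion, longer survival) around medians of
  105 and 540 days, administratively censored at 730 days.

Everything is driven by one `numpy` generator seeded from the
configuration, so identical configurations give byte-identical written
datasets. Ground-truth parameters (including each patient's true log Cmax)
are stored on the dataset.

**What the generator does not emulate:** event-level FCS data, assay drift
and batch effects, informative dropout, correlated analytes, second
infusions, or adverse events. Passing tests demonstrate that the estimators
recover the generating mechanisms they target; they cannot certify behavior
under real-data pathologies outside that structure.

## Flow post-processing

QC retains a sample only if both phenotyping panels have ≥ 5000 viable CD3⁺
cells (5000 itself is retained; the rule removes strictly-below). Flooring
compares the pentamer parent *frequency* against the noise level (the
maximum over negative-control samples, tracked per population name),
separately for the CD4 and CD8 parents; a floored parent is set to 0 and
its memory children to missing, and the operation is idempotent and local
to the pentamer subtree. Missing values propagate (never imputed); rank
tests drop them pairwise. The "number of transduced cells in sample" in the
per-phenotype formula is the infused product's transduced cell dose, so
outputs are infused cells and cells/kg.

## Expansion kinetics

Cmax is the maximum over all post-infusion points with ties broken to the
earliest day; the search window is unbounded because the protocol does not
cap it. AUC is the linear-scale trapezoid on [0, 28] with no extrapolation
beyond the observed range; fewer than two usable points yield a missing
value with a warning. Week-4 persistence is the value at the sampled day
nearest day 28 within ±3 days, else missing, with distance ties resolved to
the earlier day. Values below the qPCR detection limit enter the AUC as 0
and are excluded from log-scale regressions.

## Left-censored linear mixed model

The model is log concentration ~ responder × categorical timepoint with a
scalar random subject intercept and independent residuals (continuous-time
AR-1 error variants are deliberately not implemented; the independence
model is the one kept for all analytes). The marginal likelihood integrates
each subject's product of observed densities and censored CDF terms over
the random intercept with adaptive Gauss–Hermite quadrature:

- 30 nodes by default, centered per subject at the conditional mode (found
  by damped Newton on the concave 1-D objective) with curvature-matched
  scale. For subjects with no censored values the transformed integrand is
  exactly Gaussian, so the quadrature is exact and the likelihood equals
  the closed-form normal LME value to machine precision — the uncensored
  limit is an identity, not an approximation.
- Optimization is L-BFGS-B on (β, log σ_b, log σ_e) with analytic gradients
  (the quadrature centering is held fixed when differentiating; the induced
  gradient error is of the order of the quadrature error). Three starts by
  default (variance parameters jittered ±0.7 on the log scale,
  seed-controlled) guard against local maxima. Convergence is judged by the
  gradient norm, since the line search can terminate at noise level.
- Analytes with ≤ 1 censored value are refit as ordinary normal LMEs
  (flags cleared, value taken at the LLOQ), matching the convention of the
  original analysis.
- The fixed-effect covariance is the β block of the inverse observed
  information (numerical Hessian of the full parameter vector), so Wald
  intervals account for variance-parameter uncertainty.

**Degrees of freedom.** Small-sample (Kenward–Roger-type) machinery is
defined for normal LMEs, not censored ones. Per-contrast denominator df are
therefore computed by Satterthwaite's formula using the REML-type expected
information of the *uncensored* normal model on the same design at the
fitted variances — for balanced random-intercept designs and
between-subject contrasts this gives exactly n_subjects − n_groups. The
approximation is recorded in the fit metadata (`df_method`).

Ratios are natural-log contrasts exponentiated at output, so the internal
log base is unobservable. Timepoints with fewer than two uncensored
observations are dropped from the contrast table with a warning rather than
extrapolated.

## Expression pipeline

**Normalization** follows the fixed recipe (per panel, alternatives
rejected): positive-control lane scaling, mean + 2 SD negative-probe
background subtraction floored at 0, housekeeping geometric-mean content
normalization of endogenous probes, rounding half away from zero, log2
after flooring at 1 (so background-zero genes map to 0 — this zero-handling
dialect is recorded in the output metadata, as results are comparable only
within-dialect). The scaling references default to the arithmetic mean
across samples of per-sample geometric means, the documented behavior of
the reference tool. A consequence worth stating precisely: a sample's own
scale cancels exactly in its lane factor, but the data-driven reference is
shared, so multiplying one sample's counts by c rescales the whole pre-log
matrix by exactly (new reference)/(old reference) — one global constant
that preserves every between-sample and between-gene contrast. Callers who
need bit-identical output across such rescalings (e.g. cross-batch
comparisons) can pin `code_count_reference`/`sample_content_reference`
explicitly; the test suite checks both forms at machine precision.

**Moderated t.** Per-gene two-group comparisons on log2 expression with
empirical-Bayes variance shrinkage: prior df d₀ and variance s₀² are
estimated by moment matching on log sample variances (digamma/trigamma
inversion via Newton), the posterior variance is
(d₀s₀² + d_g s_g²)/(d₀ + d_g) and the moderated t uses d₀ + d_g df. d₀ = 0
reproduces the ordinary two-sample t; genes constant across all samples are
flagged with t = 0.

**Paired pre/progression comparisons** reuse the LME machinery with
censoring disabled (log2 expression ~ timepoint + random patient
intercept). The original analysis does not state whether set-level
comparisons used per-gene models or set-averaged expression; both are
provided and labeled (`set:<name>` targets average the set's genes).

**Per-gene Cox PFS models** are single-covariate Efron-ties fits
(lifelines) with tightened Newton precision; monotone likelihoods are
flagged and the estimate capped at |log HR| = 15 rather than claiming a
finite MLE.

**Gene-set tests.** Sets are filtered to ≥ 5 overlapping non-constant panel
genes and ≥ 50% coverage of the original set. The global statistic is
√Σt² over set genes; the competitive Fisher odds ratio cross-tabulates
membership with nominal p < 0.05, with a Haldane 0.5 correction only when a
cell is empty. Both tests permute *sample labels* (the hypotheses are
defined against a grouping; gene sampling would test a different null) and
recompute the full gene-level statistics each time, with the moderated
(not ordinary) t inside the permutation for consistency with the observed
statistic. p = (1 + #{permutation ≥/≤ observed})/(B + 1), B = 5000 by
default; designs with fewer than 20 distinct labelings switch to exact
enumeration. Seeds are required everywhere. No multiplicity adjustment is
applied anywhere; all p-values are nominal by design.

## Correlate statistics

Clopper–Pearson bounds come from the beta-quantile representation of the
binomial tails; display rounding is half away from zero (2 decimals for
bounds, whole percent for rates), which is required to reproduce
conventional efficacy-table formatting. Wilcoxon rank-sum uses exact
enumeration for m + n ≤ 20 without ties, otherwise the tie- and
continuity-corrected normal approximation. Spearman's test uses the
t reference on n − 2 df. Bootstrapped median regression resamples subjects
with replacement around a least-absolute-deviation point fit; the two-sided
p-value is the sign-crossing fraction 2·min(frac ≤ 0, frac ≥ 0) clipped to
[1/B, 1] (the source does not state a convention; a normal-approximation
alternative is available via the returned bootstrap draws' SE in
`statsmodels`, and the choice is documented here as the package's own).
Kaplan–Meier medians read off the product-limit curve (uncensored even-n
convention: the time where survival first reaches ≤ 0.5, i.e. the lower
central order statistic) with Brookmeyer–Crowley confidence intervals —
the efficacy-table CI method is not stated in the source, so this standard
choice is labeled. Welch t and one-way ANOVA are provided as thin contracts
for the pre-infusion cytokine comparisons.

## Pipeline and reproducibility

`run_all` chains simulate → flow → expansion → cytokines → expression →
correlates, logging record counts after each filter (QC removals, floored
samples, dropped gene sets) and writing a manifest with the configuration
hash, seed, package version and SHA-256 digests of every artifact;
identical configuration + seed reproduces identical digests. Permutation
and bootstrap counts are configurable, with the source defaults (5000
permutations, 10 000 bootstraps) preserved as the named profile `paper` and
a `fast` profile (500/1000) for routine runs.

## Problem sizes used by the test suite

Simulation-backed tests use sizes chosen to make Monte-Carlo bands tight
enough to be meaningful while keeping the default suite fast: censored-LME
recovery runs 200 replicates of 40 subjects × 8 timepoints at ~25%
censoring (bias and coverage criteria); permutation calibration runs 500
null sets at B = 500; directional end-to-end checks run 20 virtual trials
at the default n = 45; smaller property tests use 10–30 replicates with
correspondingly loose bands. The acceptance script uses 100 recovery
replicates, 300 null sets and 10 virtual trials and reports each problem
size next to its value.

## Known limitations

- The censored-LME df approximation ignores censoring's effect on the
  information; with heavy censoring the reported df are optimistic.
- The quadrature-based likelihood assumes a scalar random intercept; random
  slopes or cross-analyte correlation are out of scope.
- The moderated-t prior fit assumes a common variance prior across genes of
  a panel; panels are normalized and tested separately.
- Bootstrap median regression can be unstable when group medians sit on
  data points with many ties; the LAD fit falls back to a zero coefficient
  only in the fully degenerate all-equal case.
- Synthetic survival is exponential; the Cox model is correctly specified
  under the generator, so proportional-hazards diagnostics are untested.
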