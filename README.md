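# tcrbm — biomarker correlates for engineered TCR T-cell therapy trials

`tcrbm` implements the complete biomarker-correlates analysis of an
open-label TCR T-cell therapy trial in synovial sarcoma (autologous T cells
transduced with an affinity-enhanced TCR against NY-ESO-1 on HLA-A\*02),
packaged for reuse: flow-cytometry product phenotyping with
negative-control flooring and transduced-cell count inference, transgene
qPCR expansion kinetics (Cmax, AUC day 0–28, week-4 persistence),
left-censored longitudinal cytokine mixed models, nCounter-style expression
normalization with permutation gene-set statistics, and the efficacy /
correlate statistics (exact binomial intervals, rank tests, bootstrapped
median regression, Kaplan–Meier / log-rank / Cox).

Patient-level trial data is controlled-access, so the package ships a
first-class synthetic-trial generator that reproduces the statistical
structure of every data domain — cohort design, lymphodepletion regimens
(LDR), dose rules, responder-dependent effects, left-censoring, probe-class
count structure, censored survival — with the generating parameters stored
alongside, so every stage is testable end to end against known ground
truth.

## The statistics at the core

**Left-censored linear mixed model (cytokines).** For analyte
concentration $y_{it}$ of subject $i$ at timepoint $t$,

$$\log y_{it} = \beta_0 + \gamma_t + \delta\,r_i + \eta_t\,r_i + b_i + \varepsilon_{it},
\qquad b_i \sim N(0,\sigma_b^2),\ \varepsilon_{it} \sim N(0,\sigma_e^2),$$

with $r_i$ the responder indicator. Values below the assay's lower limit of
quantification (LLOQ) contribute $\Phi\big((\log \mathrm{LLOQ} - \mu_{it} - b_i)/\sigma_e\big)$
instead of a density; the subject-level integral over $b_i$ is evaluated by
adaptive Gauss–Hermite quadrature (exact for subjects without censored
values, so the likelihood degenerates to the standard LME when nothing is
censored). Responder/non-responder geometric-mean ratios per timepoint are
Wald contrasts $\exp(L'\hat\beta)$ with t references on Satterthwaite
(Kenward–Roger-style) denominator degrees of freedom computed from the
uncensored-normal REML information of the same design. Analytes with ≤ 1
censored value are fit as ordinary normal LMEs.

**nCounter normalization.** Per panel: lane scaling by
positive-control geometric means (reference = arithmetic mean of per-sample
geometric means), background subtraction at mean + 2 SD of the negative
probes, housekeeping geometric-mean content normalization of endogenous
probes, rounding half away from zero, then $\log_2$ after flooring at 1.

**Gene-set permutation tests.** Per-gene empirical-Bayes moderated
t-statistics (scaled inverse-chi-square prior fit by digamma/trigamma
moment matching); gene-set global significance $\sqrt{\sum_{g\in S} t_g^2}$
with p-values from sample-label permutations (default B = 5000, exact
enumeration when fewer than 20 distinct labelings exist); competitive
Fisher odds ratios cross-tabulating set membership against nominal p < 0.05,
permutation-calibrated on the Fisher exact p. Sets require ≥ 5
non-constant panel genes and ≥ 50% coverage. All p-values are nominal.

**Flow product phenotyping.** Samples need ≥ 5000 viable CD3+ cells in both
phenotyping panels; pentamer parent gates below the healthy-donor
negative-control maximum are floored to 0 with children set missing; the
CD4/CD8 pentamer split is inferred from product counts; absolute transduced
cells of memory phenotype $X$ are
(split fraction) × (transduced cell dose) × (phenotype frequency), per kg
body weight.

**Efficacy.** Exact Clopper–Pearson intervals for per-cohort response
rates; Kaplan–Meier medians with Brookmeyer–Crowley intervals; log-rank and
Efron-ties Cox models for survival correlates such as log Cmax vs PFS.

## Worked example

```python
from tcrbm import SimulationConfig, simulate_trial, efficacy_table, wilcoxon_rank_sum
from tcrbm.flow import phenotype_dose_table
from tcrbm.censored_lme import fit_censored_lme, wald_ratio_timecourse

trial = simulate_trial(SimulationConfig(seed=7))   # 45-patient virtual trial
print(efficacy_table(trial.patients)[["n", "responders", "orr_pct", "ci_low", "ci_high"]])

pf = trial.patients_frame.reset_index(drop=True)
doses, rejected = phenotype_dose_table(trial.flow, trial.noise_levels, trial.patients)
em = doses[(doses.parent == "CD8Pent") & (doses.phenotype == "EM")].merge(
    pf[["patient_id", "responder"]], on="patient_id")
r = em.loc[em.responder, "n_cells_per_kg"] / 1e6
n = em.loc[~em.responder, "n_cells_per_kg"] / 1e6
print(f"EM cells/kg (millions): responders {r.median():.1f} vs "
      f"non-responders {n.median():.1f}, Wilcoxon p = {wilcoxon_rank_sum(r, n)['p']:.2g}")

cyt = trial.cytokines.merge(pf[["patient_id", "responder"]], on="patient_id")
fit = fit_censored_lme(cyt[cyt.analyte == "IFNg"], analyte="IFNg")
day4 = wald_ratio_timecourse(fit).set_index("day").loc[4.0]
print(f"IFNg day 4 ratio = {day4['ratio']:.2f} "
      f"(95% CI {day4['ci_lo']:.2f}-{day4['ci_hi']:.2f}, p = {day4['p']:.2g}), "
      f"{fit.n_censored} values below LLOQ")
```

prints

```
         n  responders  orr_pct  ci_low  ci_high
cohort
1       13           6     46.0    0.19     0.75
2       14           4     29.0    0.08     0.58
3        5           1     20.0    0.01     0.72
4       13           5     38.0    0.14     0.68
EM cells/kg (millions): responders 11.1 vs non-responders 3.6, Wilcoxon p = 7.8e-07
IFNg day 4 ratio = 3.54 (95% CI 2.38-5.27, p = 4.1e-09), 5 values below LLOQ
```

The efficacy table applies the exact interval to this virtual trial's own
response counts; the product comparison recovers the generator's
effector-memory enrichment in responders; the cytokine ratio is the
censored-LME geometric-mean contrast at day 4 post-infusion.

The `tcrbm` console script exposes the same stages
(`simulate`, `flow`, `expansion`, `cytokines`, `expression`, `correlates`,
`run-all`); `tcrbm run-all --seed 1 --out report/` writes the full report
with a manifest of SHA-256 digests that reproduces bit-identically under
the same configuration and seed.

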