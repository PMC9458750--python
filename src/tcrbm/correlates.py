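"""Efficacy and correlate statistics.

Exact Clopper-Pearson response-rate intervals, Wilcoxon rank-sum and
Spearman tests, bootstrapped median (LAD) regression, logistic
association, Welch t / ANOVA conveniences, and Kaplan-Meier /
log-rank / Cox survival summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import PatientRecord, patients_frame


@dataclass
class BinomialSummary:
    k: int
    n: int
    orr: float
    ci_low: float
    ci_high: float
    level: float


@dataclass
class SurvivalSummary:
    group: str
    n: int
    events: int
    km_median: float          # nan when survival never drops to 0.5
    median_ci_low: float
    median_ci_high: float


def round_half_away(x: float, decimals: int = 2) -> float:
    """Display rounding, half away from zero (banker's rounding is not used)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialSummary:
    """Exact binomial confidence interval for a response rate.

    The lower bound solves P(X >= k | p) = (1-level)/2 (0 when k = 0), the
    upper bound solves P(X <= k | p) = (1-level)/2 (1 when k = n), via the
    beta-quantile representation of the binomial tail.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    alpha = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha, k + 1, n - k))
    return BinomialSummary(k=int(k), n=int(n), orr=k / n, ci_low=lo, ci_high=hi, level=level)


def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Missing values are dropped. Exact null enumeration when m + n <= 20
    with no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("each group needs >= 1 non-missing value")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 20 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return {"W": float(res.statistic), "p": float(res.pvalue), "exact": bool(len(pooled) <= 20 and no_ties)}


def spearman_test(x, y) -> dict:
    """Spearman rank correlation with the t-reference test on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    n = len(x)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    return {"rho": float(rho), "p": p, "n": n}


def bootstrap_median_regression(
    y, group=None, covariates=None, B: int = 10000, seed: int = 0
) -> dict:
    """Median (LAD) regression with a bootstrap two-sided p-value.

    The point estimate comes from least-absolute-deviation regression of y
    on the group indicator plus covariates; subjects are resampled with
    replacement and the model refit. p = 2 * min(frac(coef* <= 0),
    frac(coef* >= 0)), clipped to [1/B, 1]. Without a group indicator the
    intercept (the adjusted median) is summarized instead.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    if B < 100:
        raise ValueError("B must be >= 100")
    n = len(y)
    parts = [np.ones(n)]
    names = ["Intercept"]
    target = "Intercept"
    if group is not None:
        g = np.asarray(group, float)
        if len(np.unique(g)) < 2:
            raise ValueError("group indicator must take two values")
        if min((g == u).sum() for u in np.unique(g)) < 2:
            raise ValueError("need >= 2 subjects per group")
        parts.append(g)
        names.append("group")
        target = "group"
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        for j in range(cov.shape[1]):
            parts.append(cov[:, j])
            names.append(f"x{j}")
    X = np.column_stack(parts)

    def lad_coef(yy, XX):
        if np.allclose(yy, yy[0]):
            return np.concatenate([[yy[0]], np.zeros(XX.shape[1] - 1)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.QuantReg(yy, XX).fit(q=0.5, max_iter=200)
        return model.params

    coef = lad_coef(y, X)[names.index(target)]
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for i in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            boot[i] = lad_coef(y[idx], X[idx])[names.index(target)]
        except Exception:
            boot[i] = np.nan
    boot = boot[~np.isnan(boot)]
    if len(boot) == 0 or np.allclose(y, y[0]):
        return {"coef": 0.0 if np.allclose(y, y[0]) else float(coef), "p": 1.0, "B": B}
    frac_le = float((boot <= 0).mean())
    frac_ge = float((boot >= 0).mean())
    p = min(max(2.0 * min(frac_le, frac_ge), 1.0 / B), 1.0)
    return {"coef": float(coef), "p": p, "B": B}


def logistic_association(response, x) -> dict:
    """Single-covariate logistic regression with a Wald p-value.

    Complete separation is flagged; no finite MLE is claimed in that case.
    """
    import statsmodels.api as sm

    response = np.asarray(response, bool)
    x = np.asarray(x, float)
    if response.all() or (~response).all():
        raise ValueError("both response classes must be present")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(response.astype(float), X).fit(disp=0, maxiter=200)
            separated = not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3
        except Exception:
            return {"coef": math.nan, "p": math.nan, "separated": True}
    if separated:
        return {"coef": float(fit.params[1]), "p": math.nan, "separated": True}
    return {"coef": float(fit.params[1]), "p": float(fit.pvalues[1]), "separated": False}


def welch_t(x, y) -> dict:
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def anova_oneway(*groups) -> dict:
    res = stats.f_oneway(*[np.asarray(g, float) for g in groups])
    return {"F": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Survival


def km_logrank_cox(
    times, events, groups=None, covariate=None, level: float = 0.95
) -> dict:
    """Kaplan-Meier summaries plus a log-rank or Cox test.

    With ``groups``: per-group product-limit medians (Brookmeyer-Crowley
    CIs) and the two-group log-rank p. With ``covariate``: a
    single-covariate Cox model (Efron ties) returning log HR and Wald p.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test
    from lifelines.utils import median_survival_times

    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if events.sum() < 1:
        raise ValueError("no events: medians missing, tests undefined")
    out: dict = {"summaries": []}

    def km_summary(label, t, e):
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=str(label), alpha=1 - level)
        med = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        return SurvivalSummary(
            group=str(label), n=len(t), events=int(e.sum()),
            km_median=med if math.isfinite(med) else math.nan,
            median_ci_low=lo if math.isfinite(lo) else math.nan,
            median_ci_high=hi if math.isfinite(hi) else math.nan,
        )

    if groups is not None:
        groups = np.asarray(groups)
        labels = pd.unique(groups)
        for lab in labels:
            m = groups == lab
            out["summaries"].append(km_summary(lab, times[m], events[m]))
        if len(labels) == 2:
            m = groups == labels[0]
            lr = logrank_test(times[m], times[~m], events[m], events[~m])
            out["logrank_p"] = float(lr.p_value)
    else:
        out["summaries"].append(km_summary("all", times, events))
    if covariate is not None:
        frame = pd.DataFrame({"T": times, "E": events, "x": np.asarray(covariate, float)})
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="T", event_col="E",
                    fit_options={"precision": 1e-11, "max_steps": 500})
        out["log_hr"] = float(cph.params_["x"])
        out["cox_p"] = float(cph.summary.loc["x", "p"])
    return out


# ---------------------------------------------------------------------------
# Efficacy table


def efficacy_table(patients: list[PatientRecord], level: float = 0.95) -> pd.DataFrame:
    """Per-cohort response-rate summary with exact CIs and KM medians.

    Mirrors a trial efficacy table: responders/n, ORR as whole percent, the
    Clopper-Pearson interval rounded to 2 decimals (half away from zero),
    and median PFS/OS with Brookmeyer-Crowley CIs.
    """
    frame = patients_frame(patients)
    rows = []
    for cohort, grp in frame.groupby("cohort"):
        k = int(grp["responder"].sum())
        n = len(grp)
        cp = clopper_pearson(k, n, level)
        row = {
            "cohort": cohort,
            "n": n,
            "responders": k,
            "orr_pct": round_half_away(100.0 * k / n, 0),
            "ci_low": round_half_away(cp.ci_low, 2),
            "ci_high": round_half_away(cp.ci_high, 2),
        }
        for prefix in ("pfs", "os"):
            try:
                surv = km_logrank_cox(grp[f"{prefix}_days"], grp[f"{prefix}_event"])
                s = surv["summaries"][0]
                row[f"median_{prefix}_days"] = s.km_median
                row[f"median_{prefix}_ci_low"] = s.median_ci_low
                row[f"median_{prefix}_ci_high"] = s.median_ci_high
            except ValueError:
                row[f"median_{prefix}_days"] = math.nan
                row[f"median_{prefix}_ci_low"] = math.nan
                row[f"median_{prefix}_ci_high"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cohort")
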