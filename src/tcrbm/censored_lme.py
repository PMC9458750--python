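"""Left-censored linear mixed-effects model for longitudinal cytokines.

Model: log concentration ~ responder x timepoint fixed effects + random
subject intercept, errors independent. Values below the assay LLOQ are
left-censored: their likelihood contribution is the normal CDF at log LLOQ
rather than a density, integrated together with the subject's observed
densities over the random intercept.

The marginal likelihood is evaluated with adaptive Gauss-Hermite quadrature
on the one-dimensional random intercept (default 30 nodes), centered at the
per-subject conditional mode with matched curvature. For subjects without
censored values the integrand is exactly Gaussian, so the quadrature is
exact and the censored likelihood coincides with the standard normal-LME
likelihood (identical value, not just argmax) whenever no value is
censored.

Following the source analysis convention, analytes with at most one
censored value are fit as ordinary normal LMEs (the censored flag is
cleared and the value treated as observed at the LLOQ).

Denominator degrees of freedom for Wald tests are computed from the
REML-type expected information of the uncensored normal model on the same
design (a Kenward-Roger-style small-sample approximation; exact
Kenward-Roger machinery is defined only for normal LMEs, so this auxiliary
computation is recorded in the fit metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp
from scipy.stats import t as t_dist

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class CensoredLMEFit:
    """Maximum-likelihood fit of the censored random-intercept model."""

    analyte: str
    beta: pd.Series
    sigma_b: float
    sigma_e: float
    vcov: pd.DataFrame
    loglik: float
    n_censored: int
    converged: bool
    design_info: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Likelihood machinery (generic: y, X, subject index, censoring indicator)


class _CensoredLMM:
    """Vectorized marginal likelihood for one analyte's data.

    Rows must be sorted by subject. ``y`` holds log values for observed rows
    and log LLOQ thresholds for censored rows.
    """

    def __init__(self, y, X, subject, censored, n_quad=30):
        order = np.argsort(subject, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        self.cens = np.asarray(censored, bool)[order]
        subject = np.asarray(subject)[order]
        _, self.sub_idx, counts = np.unique(
            subject, return_inverse=True, return_counts=True
        )
        self.n_sub = len(counts)
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.n_obs_per_sub = np.bincount(self.sub_idx, weights=(~self.cens))
        z, w = hermgauss(n_quad)
        self.qz = z
        self.logqw = np.log(w)
        self.p = self.X.shape[1]

    # -- conditional mode of the random intercept, Newton iterations --
    def _mode(self, r, sigma_b, sigma_e):
        cens = self.cens
        # init: mode ignoring censored terms
        sum_r = np.bincount(self.sub_idx, weights=np.where(cens, 0.0, r), minlength=self.n_sub)
        prec0 = 1.0 / sigma_b**2 + self.n_obs_per_sub / sigma_e**2
        b = (sum_r / sigma_e**2) / prec0
        for _ in range(50):
            u = (r - b[self.sub_idx]) / sigma_e
            lam = np.where(cens, np.exp(-0.5 * u * u - 0.5 * _LOG_2PI - log_ndtr(u)), 0.0)
            grad_obs = np.where(cens, -lam / sigma_e, (r - b[self.sub_idx]) / sigma_e**2)
            g = np.bincount(self.sub_idx, weights=grad_obs, minlength=self.n_sub) - b / sigma_b**2
            curv_obs = np.where(cens, lam * (u + lam) / sigma_e**2, 1.0 / sigma_e**2)
            h = np.bincount(self.sub_idx, weights=curv_obs, minlength=self.n_sub) + 1.0 / sigma_b**2
            step = g / h
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return b, h  # h = -f''(b) > 0

    def loglik_grad(self, beta, log_sigma_b, log_sigma_e):
        """Marginal log-likelihood and its gradient wrt (beta, log sb, log se)."""
        sigma_b = np.exp(log_sigma_b)
        sigma_e = np.exp(log_sigma_e)
        r = self.y - self.X @ beta
        b_hat, neg_f2 = self._mode(r, sigma_b, sigma_e)
        scale = 1.0 / np.sqrt(neg_f2)  # (n_sub,)
        B = b_hat[:, None] + np.sqrt(2.0) * scale[:, None] * self.qz[None, :]  # (S,K)
        R = r[:, None] - B[self.sub_idx]  # (n_obs, K)
        U = R / sigma_e
        log_cdf = log_ndtr(U)
        log_pdf = -0.5 * U * U - 0.5 * _LOG_2PI - log_sigma_e
        obs_term = np.where(self.cens[:, None], log_cdf, log_pdf)
        f = np.add.reduceat(obs_term, self.starts, axis=0)  # (S,K)
        f += -0.5 * (B / sigma_b) ** 2 - 0.5 * _LOG_2PI - log_sigma_b
        core = f + self.qz[None, :] ** 2 + self.logqw[None, :]
        ll_sub = logsumexp(core, axis=1) + 0.5 * np.log(2.0) + np.log(scale)
        ll = float(ll_sub.sum())

        # posterior node weights per subject
        pi = np.exp(core - ll_sub[:, None] + 0.5 * np.log(2.0) + np.log(scale)[:, None])
        pi /= pi.sum(axis=1, keepdims=True)

        lam = np.where(self.cens[:, None], np.exp(log_pdf + log_sigma_e - log_cdf), 0.0)
        # d f / d beta through each observation row
        g_obs = np.where(self.cens[:, None], -lam / sigma_e, R / sigma_e**2)  # (n_obs,K)
        g_row = (g_obs * pi[self.sub_idx]).sum(axis=1)
        grad_beta = self.X.T @ g_row
        # d f / d log sigma_e
        h_obs = np.where(self.cens[:, None], -lam * U, -1.0 + U * U)
        grad_lse = float((np.add.reduceat(h_obs, self.starts, axis=0) * pi).sum())
        # d f / d log sigma_b
        grad_lsb = float(((-1.0 + (B / sigma_b) ** 2) * pi).sum())
        return ll, np.concatenate([grad_beta, [grad_lsb, grad_lse]])


class _TobitLM:
    """Censored regression without a random intercept (sigma_b fixed at 0)."""

    def __init__(self, y, X, censored):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.cens = np.asarray(censored, bool)
        self.p = self.X.shape[1]

    def loglik_grad(self, beta, log_sigma_b, log_sigma_e):
        sigma_e = np.exp(log_sigma_e)
        r = self.y - self.X @ beta
        u = r / sigma_e
        log_pdf = -0.5 * u * u - 0.5 * _LOG_2PI - log_sigma_e
        log_cdf = log_ndtr(u)
        ll = float(np.where(self.cens, log_cdf, log_pdf).sum())
        lam = np.where(self.cens, np.exp(log_pdf + log_sigma_e - log_cdf), 0.0)
        g_row = np.where(self.cens, -lam / sigma_e, r / sigma_e**2)
        grad_beta = self.X.T @ g_row
        grad_lse = float(np.where(self.cens, -lam * u, -1.0 + u * u).sum())
        return ll, np.concatenate([grad_beta, [0.0], [grad_lse]])


def _maximize(model, beta0, lsb0, lse0, n_starts=3, seed=0, fix_sigma_b=None):
    rng = np.random.default_rng(seed)
    p = model.p

    def negll(x):
        ll, g = model.loglik_grad(x[:p], x[p], x[p + 1])
        return -ll, -g

    bounds = [(None, None)] * p + [(np.log(1e-6), np.log(1e3)), (np.log(1e-6), np.log(1e3))]
    if fix_sigma_b is not None:
        val = np.log(max(fix_sigma_b, 1e-300)) if fix_sigma_b > 0 else -np.inf
        bounds[p] = (max(val, np.log(1e-6)), max(val, np.log(1e-6)))
    starts = [np.concatenate([beta0, [lsb0, lse0]])]
    for _ in range(max(0, n_starts - 1)):
        jitter = np.zeros(p + 2)
        jitter[p:] = rng.uniform(-0.7, 0.7, size=2)
        starts.append(starts[0] + jitter)
    best = None
    for x0 in starts:
        if fix_sigma_b is not None:
            x0 = x0.copy()
            x0[p] = bounds[p][0]
        res = minimize(
            negll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _numerical_hessian(model, x_opt, p):
    """Central differences of the analytic gradient."""
    n = len(x_opt)
    H = np.zeros((n, n))
    for k in range(n):
        h = 1e-5 * (1.0 + abs(x_opt[k]))
        xp = x_opt.copy(); xp[k] += h
        xm = x_opt.copy(); xm[k] -= h
        _, gp = model.loglik_grad(xp[:p], xp[p], xp[p + 1])
        _, gm = model.loglik_grad(xm[:p], xm[p], xm[p + 1])
        H[:, k] = -(gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Design construction for the responder x timepoint model


def build_design(data: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix for log y ~ C(day) * responder with treatment coding.

    Reference level is the earliest timepoint. Returns (X, column names,
    info dict with day list / column index maps).
    """
    days = sorted(data["day"].unique())
    ref = days[0]
    resp = data["responder"].astype(float).to_numpy()
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for d in days[1:]:
        cols.append((data["day"] == d).astype(float).to_numpy())
        names.append(f"day[{d:g}]")
    cols.append(resp)
    names.append("responder")
    inter_cols = {ref: "responder"}
    for d in days[1:]:
        cols.append((data["day"] == d).astype(float).to_numpy() * resp)
        names.append(f"day[{d:g}]:responder")
        inter_cols[d] = f"day[{d:g}]:responder"
    X = np.column_stack(cols)
    return X, names, {"days": days, "ref_day": ref, "interaction_cols": inter_cols}


def fit_censored_lme(
    data: pd.DataFrame,
    analyte: str | None = None,
    n_quad: int = 30,
    n_starts: int = 3,
    seed: int = 0,
    fix_sigma_b: float | None = None,
) -> CensoredLMEFit:
    """Fit the censored responder x timepoint LME for one analyte.

    ``data`` columns: patient_id, day, value, lloq, censored, responder.
    Censored rows contribute the normal CDF at log LLOQ. Analytes with at
    most one censored value are fit as ordinary (uncensored) normal LMEs.
    """
    if analyte is None:
        analytes = data["analyte"].unique() if "analyte" in data else ["analyte"]
        if len(analytes) != 1:
            raise ValueError("pass a single analyte's rows or specify analyte=")
        analyte = str(analytes[0])
    elif "analyte" in data:
        data = data[data["analyte"] == analyte]
    data = data.reset_index(drop=True)
    if data["censored"].all():
        raise ValueError(f"{analyte}: all observations are censored")
    groups = data.groupby("responder")["patient_id"].nunique()
    if len(groups) < 2 or groups.min() < 2:
        raise ValueError(f"{analyte}: need >=2 subjects in each responder group")

    cens = data["censored"].to_numpy(bool).copy()
    if cens.sum() <= 1:
        cens[:] = False  # <=1 censored value: ordinary normal LME
    y = np.where(cens, np.log(data["lloq"].to_numpy(float)), np.log(data["value"].to_numpy(float)))
    X, names, dinfo = build_design(data)
    subject = pd.factorize(data["patient_id"])[0]

    return _fit_generic(
        y, X, subject, cens, names, analyte, dinfo,
        data=data, n_quad=n_quad, n_starts=n_starts, seed=seed, fix_sigma_b=fix_sigma_b,
    )


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    subject: np.ndarray,
    censored: np.ndarray | None = None,
    names: list[str] | None = None,
    n_quad: int = 30,
    n_starts: int = 3,
    seed: int = 0,
    fix_sigma_b: float | None = None,
) -> CensoredLMEFit:
    """Generic interface: fit y ~ X beta + random subject intercept.

    With ``censored`` all-False this is a plain normal LME evaluated through
    the same (exact, for Gaussian integrands) quadrature path.
    """
    censored = np.zeros(len(y), bool) if censored is None else np.asarray(censored, bool)
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return _fit_generic(
        np.asarray(y, float), np.asarray(X, float), np.asarray(subject), censored,
        names, "response", {}, data=None, n_quad=n_quad, n_starts=n_starts,
        seed=seed, fix_sigma_b=fix_sigma_b,
    )


def _fit_generic(
    y, X, subject, cens, names, analyte, dinfo, data,
    n_quad, n_starts, seed, fix_sigma_b,
):
    p = X.shape[1]
    # starting values from censoring-ignoring least squares
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sub_means = pd.Series(resid).groupby(pd.Series(subject)).mean()
    sb0 = max(float(sub_means.std(ddof=0)), 1e-2)
    se0 = max(float(np.std(resid, ddof=0)) * 0.8, 1e-2)
    if fix_sigma_b == 0.0:
        model = _TobitLM(y, X, cens)
    else:
        model = _CensoredLMM(y, X, subject, cens, n_quad=n_quad)
    res = _maximize(model, beta0, np.log(sb0), np.log(se0),
                    n_starts=n_starts, seed=seed, fix_sigma_b=fix_sigma_b)
    x_opt = res.x
    beta = pd.Series(x_opt[:p], index=names)
    sigma_b = 0.0 if fix_sigma_b == 0.0 else float(np.exp(x_opt[p]))
    sigma_e = float(np.exp(x_opt[p + 1]))

    H = _numerical_hessian(model, x_opt, p)
    Hbb = H[:p, :p]
    try:
        vcov_full = np.linalg.inv(H)
        vcov_beta = vcov_full[:p, :p]
        if np.any(np.diag(vcov_beta) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov_beta = np.linalg.pinv(Hbb)
    ll, grad = model.loglik_grad(x_opt[:p], x_opt[p], x_opt[p + 1])
    # the optimizer may stop on a line-search failure with the gradient
    # already at noise level; judge convergence by the gradient itself
    converged = np.linalg.norm(grad[:p]) < 1e-3 * (1 + abs(ll))
    if not converged:
        warnings.warn(f"{analyte}: censored LME may not have converged", stacklevel=2)
    return CensoredLMEFit(
        analyte=analyte,
        beta=beta,
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        vcov=pd.DataFrame(vcov_beta, index=names, columns=names),
        loglik=float(ll),
        n_censored=int(cens.sum()),
        converged=converged,
        design_info={**dinfo, "X": X, "subject": subject, "names": names,
                     "censored": cens, "data": data},
        meta={
            "df_method": "satterthwaite_reml_on_uncensored_design",
            "n_quad": n_quad,
            "n_starts": n_starts,
        },
    )


# ---------------------------------------------------------------------------
# Degrees of freedom and Wald contrasts


def approximate_df(fit: CensoredLMEFit, contrast: np.ndarray) -> float:
    """Satterthwaite denominator df from the uncensored-normal REML information.

    Uses the fit's design and variance estimates in a standard normal-LME
    information calculation (censoring ignored), the documented stand-in for
    Kenward-Roger machinery on censored fits. For balanced random-intercept
    designs and between-subject contrasts this reduces to
    (n_subjects - n_groups) exactly.
    """
    L = np.asarray(contrast, float)
    ctx = fit.design_info.get("_df_cache")
    if ctx is None:
        X = fit.design_info["X"]
        subject = np.asarray(fit.design_info["subject"])
        n, p = X.shape
        sb2 = max(fit.sigma_b, 1e-8) ** 2
        se2 = fit.sigma_e**2
        Z = (subject[:, None] == np.unique(subject)[None, :]).astype(float)
        V = se2 * np.eye(n) + sb2 * (Z @ Z.T)
        Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        C = np.linalg.inv(XtVinv @ X)
        G = [Z @ Z.T, np.eye(n)]  # d V / d sigma_b^2, d V / d sigma_e^2
        P = Vinv - XtVinv.T @ C @ XtVinv
        info = np.empty((2, 2))
        PG = [P @ Gk for Gk in G]
        for i in range(2):
            for j in range(2):
                info[i, j] = 0.5 * np.einsum("ij,ji->", PG[i], PG[j])
        # p x p pieces: enough to evaluate any contrast's df cheaply
        M = [C @ (XtVinv @ Gk @ XtVinv.T) @ C for Gk in G]
        ctx = {"C": C, "M": M, "W": np.linalg.pinv(info), "resid_df": float(n - p)}
        fit.design_info["_df_cache"] = ctx
    A = float(L @ ctx["C"] @ L)
    g = np.array([float(L @ Mk @ L) for Mk in ctx["M"]])
    denom = float(g @ ctx["W"] @ g)
    if denom <= 0 or A <= 0:
        return ctx["resid_df"]
    df = 2.0 * A * A / denom
    return float(min(df, ctx["resid_df"])) if df > 0 else ctx["resid_df"]


def wald_ratio_timecourse(fit: CensoredLMEFit, level: float = 0.95) -> pd.DataFrame:
    """Responder/non-responder geometric-mean-ratio time course with Wald tests.

    Per timepoint the contrast is the responder main effect plus that
    timepoint's interaction; p-values come from a t reference with
    Satterthwaite df and the CI is the exponentiated Wald interval.
    Timepoints with fewer than 2 uncensored observations are dropped with a
    warning.
    """
    if not fit.converged:
        raise ValueError(f"{fit.analyte}: fit did not converge")
    names = list(fit.beta.index)
    days = fit.design_info.get("days")
    if days is None:
        raise ValueError("fit was not built from a responder x timepoint design")
    inter = fit.design_info["interaction_cols"]
    data = fit.design_info.get("data")
    cens = fit.design_info["censored"]
    rows = []
    for day in days:
        if data is not None:
            n_unc = int(((data["day"] == day) & ~cens).sum())
            if n_unc < 2:
                warnings.warn(
                    f"{fit.analyte}: day {day} has <2 uncensored observations; dropped",
                    stacklevel=2,
                )
                continue
        L = np.zeros(len(names))
        L[names.index("responder")] = 1.0
        col = inter[day]
        if col != "responder":
            L[names.index(col)] = 1.0
        if not np.any(L):
            raise ValueError("singular contrast")
        est = float(L @ fit.beta.to_numpy())
        se = float(np.sqrt(L @ fit.vcov.to_numpy() @ L))
        df = approximate_df(fit, L)
        if se == 0:
            pval = 0.0 if est != 0 else 1.0
            tcrit = 0.0
        else:
            tstat = est / se
            pval = float(2.0 * t_dist.sf(abs(tstat), df))
            tcrit = float(t_dist.ppf(0.5 + level / 2.0, df))
        rows.append(
            {
                "analyte": fit.analyte,
                "day": day,
                "log_ratio": est,
                "ratio": float(np.exp(est)),
                "ci_lo": float(np.exp(est - tcrit * se)),
                "ci_hi": float(np.exp(est + tcrit * se)),
                "se": se,
                "df": df,
                "p": pval,
            }
        )
    return pd.DataFrame(rows)


def ratio_heatmap_matrix(timecourses: list[pd.DataFrame]) -> pd.DataFrame:
    """Analyte x timepoint matrix of responder/non-responder ratios."""
    long = pd.concat(timecourses, ignore_index=True)
    return long.pivot(index="analyte", columns="day", values="ratio")
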