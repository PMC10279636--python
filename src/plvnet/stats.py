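"""Mixed-model inference on network-metric tables.

For each metric the model is

    value ~ condition * emotion + (1 | subject)

fit by REML: condition and emotion as sum-coded fixed factors with their
interaction, and a random intercept per subject capturing the repeated-
measures dependence.  Fixed terms are tested with type-III F tests using
the Satterthwaite approximation for denominator degrees of freedom;
significant interactions are characterised with emmeans-style pairwise
emotion contrasts within each condition, FDR-adjusted with the
Benjamini-Hochberg step-up procedure (the 12 within-condition contrasts
per metric form one adjustment family).

The random-intercept model admits an exact one-dimensional profiled REML
likelihood (per-subject covariance ``sigma2*I + tau2*J`` via Woodbury), so
the fit is computed here directly — a bounded scalar optimisation over the
variance ratio — rather than through a general mixed-model optimizer; the
test suite cross-validates estimates, F tests and contrasts against
statsmodels' MixedLM and R's lmerTest/emmeans.  Satterthwaite degrees of
freedom use the delta method on the REML information, as in lmerTest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMMFit",
    "InferenceResult",
    "fit_lmm",
    "f_tests",
    "pairwise_contrasts",
    "bh_adjust",
    "analyze_metric_table",
]

REQUIRED_COLUMNS = ("subject", "condition", "emotion", "metric", "value")


def _sum_code(levels: list[str], value: str) -> np.ndarray:
    """Sum-to-zero (deviation) coding; last level carries -1."""
    k = len(levels)
    row = np.zeros(k - 1)
    if value == levels[-1]:
        row[:] = -1.0
    else:
        row[levels.index(value)] = 1.0
    return row


def _design_row(cond: str, emo: str, cond_levels, emo_levels) -> np.ndarray:
    c = _sum_code(cond_levels, cond)
    e = _sum_code(emo_levels, emo)
    return np.concatenate([[1.0], c, e, np.outer(c, e).ravel()])


@dataclass
class LMMFit:
    """A fitted random-intercept model plus everything inference needs."""

    metric: str
    cond_levels: list[str]
    emo_levels: list[str]
    beta: np.ndarray
    beta_cov: np.ndarray  # (X' V^-1 X)^-1 at the REML estimates
    sigma2: float  # residual variance
    tau2: float  # subject-intercept variance
    term_slices: dict = field(repr=False, default_factory=dict)
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _group_sizes: np.ndarray = field(repr=False, default=None)
    _group_index: list = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return len(self._y)

    @property
    def variance_components(self) -> dict:
        return {"residual": self.sigma2, "subject_intercept": self.tau2}

    def cell_mean_row(self, cond: str, emo: str) -> np.ndarray:
        return _design_row(cond, emo, self.cond_levels, self.emo_levels)


@dataclass
class InferenceResult:
    """F tests, FDR-adjusted contrasts and variance components."""

    metric: str
    f_tests: pd.DataFrame
    contrasts: pd.DataFrame
    variance_components: dict


def fit_lmm(table: pd.DataFrame, metric: str) -> LMMFit:
    """REML fit of ``value ~ condition * emotion + (1 | subject)``.

    Factor levels are taken in sorted order (deterministic across runs);
    estimates are reproducible to well below 1e-6.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table lacks columns {missing}")
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    if sub["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    cond_levels = sorted(sub["condition"].unique())
    emo_levels = sorted(sub["emotion"].unique())
    if len(cond_levels) < 2 or len(emo_levels) < 2:
        raise ValueError("both factors need >= 2 levels")

    X = np.stack(
        [
            _design_row(c, e, cond_levels, emo_levels)
            for c, e in zip(sub["condition"], sub["emotion"])
        ]
    )
    y = sub["value"].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular fixed-effect design: some condition x emotion cell is empty"
        )
    groups = sub["subject"].to_numpy()

    # per-subject blocks for the closed-form REML machinery
    order = np.argsort(groups, kind="stable")
    Xo, yo, go = X[order], y[order], groups[order]
    _, starts = np.unique(go, return_index=True)
    starts = np.sort(starts)
    bounds = list(starts) + [len(yo)]
    group_index = [slice(bounds[i], bounds[i + 1]) for i in range(len(starts))]
    sizes = np.array([s.stop - s.start for s in group_index])

    nc, ne = len(cond_levels) - 1, len(emo_levels) - 1
    term_slices = {
        "condition": slice(1, 1 + nc),
        "emotion": slice(1 + nc, 1 + nc + ne),
        "condition:emotion": slice(1 + nc + ne, 1 + nc + ne + nc * ne),
    }

    fit = LMMFit(
        metric=metric,
        cond_levels=cond_levels,
        emo_levels=emo_levels,
        beta=np.zeros(X.shape[1]),
        beta_cov=np.zeros((X.shape[1], X.shape[1])),
        sigma2=1.0,
        tau2=0.0,
        term_slices=term_slices,
        _X=Xo,
        _y=yo,
        _group_sizes=sizes,
        _group_index=group_index,
    )
    fit.sigma2, fit.tau2 = _reml_estimate(fit)
    fit.beta, fit.beta_cov = _gls(fit, fit.sigma2, fit.tau2)[:2]
    return fit


def _profile_negll(fit: LMMFit, lam: float) -> tuple[float, float]:
    """Negative profiled REML log-likelihood at variance ratio tau2/sigma2.

    Returns (negll, sigma2_hat(lam)); sigma2 is profiled out in closed
    form: sigma2_hat = quad / (N - p) for the normalised covariance
    I + lam * J per block.
    """
    n, p = fit._X.shape
    _, _, ll0, parts = _gls(fit, 1.0, lam, return_parts=True)
    logdet_v0, logdet_xtvx0, quad0 = parts
    floor = 1e-12 * (1.0 + float(np.var(fit._y)))
    sigma2 = max(quad0 / (n - p), floor)
    negll = 0.5 * (
        logdet_v0 + (n - p) * np.log(sigma2) + logdet_xtvx0 + quad0 / sigma2
    )
    return negll, sigma2


def _reml_estimate(fit: LMMFit) -> tuple[float, float]:
    """REML variance components by bounded 1-D search over tau2/sigma2."""

    def objective(u: float) -> float:
        return _profile_negll(fit, np.exp(u))[0]

    res = minimize_scalar(
        objective, bounds=(-16.0, 16.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam_hat = float(np.exp(res.x))
    neg_at_hat = float(res.fun)
    neg_at_zero, _ = _profile_negll(fit, 0.0)
    if neg_at_zero <= neg_at_hat:
        lam_hat = 0.0
    _, sigma2 = _profile_negll(fit, lam_hat)
    return sigma2, lam_hat * sigma2


def _gls(fit: LMMFit, sigma2: float, tau2: float, return_parts: bool = False):
    """GLS beta, its covariance, and REML log-likelihood at (sigma2, tau2).

    Exploits V_s = sigma2*I + tau2*J per subject block (Woodbury), so the
    whole computation is O(sum n_s * p^2).
    """
    X, y = fit._X, fit._y
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet_v = 0.0
    quad_parts = []
    for sl in fit._group_index:
        xs, ys = X[sl], y[sl]
        ns = xs.shape[0]
        c = tau2 / (sigma2 + ns * tau2)
        xs_sum, ys_sum = xs.sum(axis=0), ys.sum()
        xtvx += (xs.T @ xs - c * np.outer(xs_sum, xs_sum)) / sigma2
        xtvy += (xs.T @ ys - c * xs_sum * ys_sum) / sigma2
        logdet_v += (ns - 1) * np.log(sigma2) + np.log(sigma2 + ns * tau2)
        quad_parts.append((xs, ys, c, xs_sum, ys_sum))
    beta_cov = np.linalg.inv(xtvx)
    beta = beta_cov @ xtvy
    quad = 0.0
    for xs, ys, c, xs_sum, ys_sum in quad_parts:
        r = ys - xs @ beta
        r_sum = r.sum()
        quad += (r @ r - c * r_sum**2) / sigma2
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    reml_ll = -0.5 * (logdet_v + logdet_xtvx + quad)
    if return_parts:
        return beta, beta_cov, reml_ll, (logdet_v, logdet_xtvx, quad)
    return beta, beta_cov, reml_ll


def _varcomp_cov(fit: LMMFit) -> np.ndarray:
    """Asymptotic covariance of (sigma2_hat, tau2_hat): inverse observed
    REML information, by central finite differences of the log-likelihood."""
    theta = np.array([fit.sigma2, fit.tau2])
    h = np.maximum(1e-4 * np.abs(theta), 1e-7 * fit.sigma2)
    # keep sigma2 strictly positive when differencing
    h[0] = min(h[0], 0.49 * theta[0])

    def ll(t):
        return _gls(fit, t[0], t[1])[2]

    hess = np.zeros((2, 2))
    f0 = ll(theta)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        hess[i, i] = (ll(theta + ei) - 2 * f0 + ll(theta - ei)) / h[i] ** 2
    ei = np.array([h[0], 0.0])
    ej = np.array([0.0, h[1]])
    hess[0, 1] = hess[1, 0] = (
        ll(theta + ei + ej) - ll(theta + ei - ej) - ll(theta - ei + ej) + ll(theta - ei - ej)
    ) / (4 * h[0] * h[1])
    info = -hess
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


def _satterthwaite_df(fit: LMMFit, ell: np.ndarray, varcomp_cov: np.ndarray) -> float:
    """Satterthwaite df for the variance of a single contrast l'beta."""
    theta = np.array([fit.sigma2, fit.tau2])
    h = np.maximum(1e-4 * np.abs(theta), 1e-7 * fit.sigma2)
    h[0] = min(h[0], 0.49 * theta[0])

    def g(t):
        cov = _gls(fit, t[0], t[1])[1]
        return float(ell @ cov @ ell)

    grad = np.zeros(2)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        grad[i] = (g(theta + ei) - g(theta - ei)) / (2 * h[i])
    g0 = g(theta)
    denom = float(grad @ varcomp_cov @ grad)
    if denom <= 0:
        return float(fit.n_obs - fit._X.shape[1])
    df = 2.0 * g0**2 / denom
    return float(np.clip(df, 1.0, 1e7))


def f_tests(fit: LMMFit) -> pd.DataFrame:
    """Type-III F tests with Satterthwaite denominator df per fixed term.

    Multi-df terms use the eigendecomposition approach: the contrast block
    is rotated into independent single-df contrasts, each gets its own
    Satterthwaite df, and those are pooled into one denominator df.
    """
    vcov_theta = _varcomp_cov(fit)
    rows = []
    for term, sl in fit.term_slices.items():
        q = sl.stop - sl.start
        L = np.zeros((q, len(fit.beta)))
        L[np.arange(q), np.arange(sl.start, sl.stop)] = 1.0
        M = L @ fit.beta_cov @ L.T
        evals, evecs = np.linalg.eigh(M)
        lb = L.T @ evecs  # columns: contrast vectors in beta space
        f_stat = 0.0
        nus = []
        for i in range(q):
            ell = lb[:, i]
            var_i = float(evals[i])
            est_i = float(ell @ fit.beta)
            f_stat += est_i**2 / var_i
            nus.append(_satterthwaite_df(fit, ell, vcov_theta))
        f_stat /= q
        nus = np.array(nus)
        if q == 1:
            df2 = float(nus[0])
        else:
            good = nus > 2.0
            if good.all():
                e_sum = float(np.sum(nus / (nus - 2.0)))
                df2 = 2.0 * e_sum / (e_sum - q) if e_sum > q else float(np.mean(nus))
            else:
                df2 = float(np.mean(nus))
        p = float(sstats.f.sf(f_stat, q, df2))
        rows.append({"term": term, "F": f_stat, "df1": q, "df2": df2, "p": p})
    return pd.DataFrame(rows)


def pairwise_contrasts(fit: LMMFit, adjust: bool = True) -> pd.DataFrame:
    """Pairwise emotion contrasts on marginal means within each condition.

    All emotion pairs within each condition level (e.g. 6 pairs x 2
    conditions), with Satterthwaite-df t tests; ``p_adj`` is Benjamini-
    Hochberg adjusted across the whole family.
    """
    vcov_theta = _varcomp_cov(fit)
    rows = []
    for cond in fit.cond_levels:
        for a_i in range(len(fit.emo_levels)):
            for b_i in range(a_i + 1, len(fit.emo_levels)):
                ea, eb = fit.emo_levels[a_i], fit.emo_levels[b_i]
                ell = fit.cell_mean_row(cond, ea) - fit.cell_mean_row(cond, eb)
                est = float(ell @ fit.beta)
                se = float(np.sqrt(ell @ fit.beta_cov @ ell))
                df = _satterthwaite_df(fit, ell, vcov_theta)
                t = est / se
                p = 2.0 * float(sstats.t.sf(abs(t), df))
                rows.append(
                    {
                        "condition": cond,
                        "contrast": f"{ea} - {eb}",
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "df": df,
                        "p": p,
                    }
                )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_metric_table(table: pd.DataFrame) -> dict[str, InferenceResult]:
    """Fit, test and contrast every metric present in a metric table."""
    results = {}
    for metric in sorted(table["metric"].unique()):
        fit = fit_lmm(table, metric)
        results[metric] = InferenceResult(
            metric=metric,
            f_tests=f_tests(fit),
            contrasts=pairwise_contrasts(fit),
            variance_components=fit.variance_components,
        )
    return results
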