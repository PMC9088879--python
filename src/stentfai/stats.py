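"""Statistical pipeline for the restenosis analysis.

Group comparisons, cross-validated LASSO feature selection (lambda_min and
lambda_1se models), covariate-adjusted logistic regression, ROC/AUC with
DeLong confidence intervals and Youden cutoffs, Pearson correlation with
Fisher-z intervals, and inter-rater ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def two_sample_test(x, y, method: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default, Student optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each sample needs at least 2 observations")
    if method not in {"welch", "student"}:
        raise StatsError(f"unknown method {method!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    res = sps.ttest_ind(x, y, equal_var=(method == "student"))
    return float(res.statistic), float(res.pvalue)


def categorical_test(table) -> tuple[float, float]:
    """Chi-square test without continuity correction on a 2 x k table.

    Falls back to Fisher's exact test (2 x 2 only) when any expected cell
    count is below 5; the returned statistic is then the odds ratio.
    """
    table = np.asarray(table)
    if table.ndim != 2 or (table < 0).any():
        raise StatsError("contingency table must be 2D with non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("contingency table has an empty margin")
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        res = sps.fisher_exact(table)
        return float(res.statistic), float(res.pvalue)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------


@dataclass
class LassoSelectionResult:
    lambdas: np.ndarray
    cv_deviance_mean: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    coef_min: dict  # feature -> original-scale coefficient (nonzero only)
    coef_1se: dict
    selected_min: list
    selected_1se: list
    auc_min: float
    auc_1se: float
    converged: bool


def _l1_path_fit(Xs, y, lambdas, n, tol=1e-4, max_iter=5000):
    """Warm-started L1 logistic fits along a descending lambda path."""
    clf = LogisticRegression(
        penalty="l1",
        solver="saga",
        warm_start=True,
        fit_intercept=True,
        tol=tol,
        max_iter=max_iter,
        random_state=0,  # saga shuffles; pin for reproducibility
    )
    coefs, intercepts, converged = [], [], True
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs, y)
        if clf.n_iter_[0] >= max_iter:
            converged = False
        coefs.append(clf.coef_[0].copy())
        intercepts.append(float(clf.intercept_[0]))
    return np.array(coefs), np.array(intercepts), converged


def lasso_select(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_decades: float = 4.0,
) -> LassoSelectionResult:
    """L1-penalised logistic feature selection with K-fold cross-validation.

    Features are standardised internally; the penalty grid is 100 points
    log-spaced over four decades down from lambda_max (the smallest penalty
    at which all coefficients are zero). Cross-validated binomial deviance
    selects lambda_min, and lambda_1se is the largest penalty whose mean
    deviance lies within one standard error of the minimum. Reported
    coefficients are on the original feature scale.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    if X.isna().any().any() or np.isnan(y.astype(float)).any():
        raise StatsError("missing values: apply complete-case filtering upstream")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    if (sd == 0).any():
        bad = [names[i] for i in np.where(sd == 0)[0]]
        raise StatsError(f"constant features: {bad}")
    Xs = (Xv - mu) / sd

    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    lambdas = np.logspace(
        np.log10(lam_max), np.log10(lam_max) - lambda_decades, n_lambdas
    )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.empty((folds, n_lambdas))
    converged = True
    for k, (tr, te) in enumerate(skf.split(Xs, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise StatsError("a CV fold lost one outcome class; need >=2 per class")
        coefs, icepts, ok = _l1_path_fit(Xs[tr], y[tr], lambdas, len(tr))
        converged &= ok
        eta = Xs[te] @ coefs.T + icepts  # (n_te, n_lambdas)
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        yy = y[te][:, None]
        dev[k] = -2.0 * np.mean(yy * np.log(p) + (1 - yy) * np.log(1 - p), axis=0)

    dev_mean = dev.mean(axis=0)
    dev_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(dev_mean))
    lambda_min = float(lambdas[i_min])
    within = np.where(dev_mean <= dev_mean[i_min] + dev_se[i_min])[0]
    i_1se = int(within.min())  # lambdas descend, so the first index is largest
    lambda_1se = float(lambdas[i_1se])

    coefs_full, icepts_full, ok = _l1_path_fit(Xs, y, lambdas, n)
    converged &= ok

    def _model(i):
        beta_std = coefs_full[i]
        nz = np.abs(beta_std) > 1e-6
        beta_orig = beta_std / sd
        coef = {names[j]: float(beta_orig[j]) for j in np.where(nz)[0]}
        eta = Xs @ beta_std + icepts_full[i]
        auc = _mann_whitney_auc(eta[y == 1], eta[y == 0]) if nz.any() else 0.5
        return coef, [names[j] for j in np.where(nz)[0]], auc

    coef_min, sel_min, auc_min = _model(i_min)
    coef_1se, sel_1se, auc_1se = _model(i_1se)
    return LassoSelectionResult(
        lambdas=lambdas,
        cv_deviance_mean=dev_mean,
        cv_deviance_se=dev_se,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
        coef_min=coef_min,
        coef_1se=coef_1se,
        selected_min=sel_min,
        selected_1se=sel_1se,
        auc_min=float(auc_min),
        auc_1se=float(auc_1se),
        converged=bool(converged),
    )


# ---------------------------------------------------------------------------
# Adjusted logistic regression
# ---------------------------------------------------------------------------

DEFAULT_ADJUSTERS = (
    "age_years",
    "male",
    "hyperlipidemia",
    "diabetes",
    "hypertension",
    "smoking",
    "prior_mi",
)


@dataclass
class AdjustedLogisticResult:
    odds_ratios: dict  # predictor -> {"or", "ci_low", "ci_high", "p"}
    adjusters: list
    converged: bool
    separation: bool = False


def fit_adjusted_logistic(
    records: pd.DataFrame,
    predictors,
    adjusters=DEFAULT_ADJUSTERS,
    outcome: str = "isr",
) -> AdjustedLogisticResult:
    """Maximum-likelihood logistic fit with Wald 95% CIs per predictor.

    Continuous predictors enter per unit as given; the FAI enters per +1 HU,
    so an odds ratio above 1 means a less negative (more inflamed) FAI
    raises the restenosis odds.
    """
    predictors = list(predictors)
    adjusters = [a for a in adjusters if a not in predictors]
    cols = predictors + adjusters
    df = records[[outcome] + cols].dropna()
    y = df[outcome].to_numpy(dtype=float)
    X = sm.add_constant(df[cols].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise StatsError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            fit = model.fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            fit = model.fit(disp=0, maxiter=500, method="bfgs")
            converged = False
    separation = (
        bool(np.abs(fit.params.drop("const")).max() > 15)
        or bool(fit.bse.max() > 100)
        or not np.all(np.isfinite(fit.bse))
    )
    if separation:
        warnings.warn(
            "possible separation: odds-ratio confidence intervals unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    out = {}
    with np.errstate(over="ignore"):
        for name in predictors:
            beta = float(fit.params[name])
            se = float(fit.bse[name])
            out[name] = {
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": float(fit.pvalues[name]),
            }
    return AdjustedLogisticResult(
        odds_ratios=out,
        adjusters=adjusters,
        converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# ROC / AUC / Youden
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    ci: tuple[float, float]  # DeLong 95% CI
    thresholds: np.ndarray  # score >= threshold called positive
    sensitivity: np.ndarray
    specificity: np.ndarray


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity with half credit for ties."""
    m, n = len(pos), len(neg)
    ranks = _midrank(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _delong_var(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC from the structural components."""
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_curve_auc(scores, labels) -> RocResult:
    """ROC curve, Mann-Whitney AUC and DeLong 95% CI.

    Orientation: higher score means the positive class (for the FAI, less
    negative attenuation predicts restenosis).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise StatsError("both classes must be present for a ROC curve")
    auc = _mann_whitney_auc(pos, neg)
    sd = np.sqrt(_delong_var(pos, neg))
    z = 1.959963984540054
    ci = (max(auc - z * sd, 0.0), min(auc + z * sd, 1.0))
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocResult(
        auc=auc, ci=ci, thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr
    )


def youden_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the cutoff with higher specificity. The returned
    cutoff calls scores >= cutoff positive.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    if len(j) == 0 or not np.isfinite(j).any():
        raise StatsError("degenerate ROC")
    jmax = j.max()
    tied = np.where(j >= jmax - 1e-12)[0]
    best = tied[np.argmax(roc.specificity[tied])]
    return (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )


def binormal_operating_point(
    cutoff: float,
    pos_mean: float,
    pos_sd: float,
    neg_mean: float,
    neg_sd: float,
) -> tuple[float, float]:
    """Closed-form (sensitivity, specificity) at a cutoff for two normals.

    Higher scores are positive: sensitivity = P(pos > cutoff),
    specificity = P(neg <= cutoff).
    """
    sens = float(sps.norm.sf(cutoff, loc=pos_mean, scale=pos_sd))
    spec = float(sps.norm.cdf(cutoff, loc=neg_mean, scale=neg_sd))
    return sens, spec


def binormal_auc(pos_mean, pos_sd, neg_mean, neg_sd) -> float:
    """Closed-form AUC for two normal score distributions."""
    return float(
        sps.norm.cdf((pos_mean - neg_mean) / np.hypot(pos_sd, neg_sd))
    )


def subgroup_roc(records: pd.DataFrame, key: str = "vessel",
                 score: str = "peri_stent_fai_hu", outcome: str = "isr") -> dict:
    """Per-stratum ROC; strata with a single outcome class map to None."""
    out = {}
    for stratum, sub in records.groupby(key):
        if sub[outcome].nunique() < 2:
            out[stratum] = None
            continue
        out[stratum] = roc_curve_auc(sub[score].to_numpy(), sub[outcome].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Correlation and agreement
# ---------------------------------------------------------------------------


def pearson_with_ci(x, y) -> tuple[float, tuple[float, float], float]:
    """Pearson r with Fisher-z 95% CI and two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise StatsError("need paired samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("constant input has undefined correlation")
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(len(x) - 3)
    zc = 1.959963984540054
    ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    return float(r), ci, float(p)


@dataclass
class ICCResult:
    estimate: float
    ci: tuple[float, float]
    model: str = "ICC(2,1): two-way random, absolute agreement, single measures"
    degenerate: bool = False


def icc_absolute(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Inter-rater ICC(2,1) with an F-based 95% CI.

    Two-way random effects, absolute agreement, single measures, from the
    two-way ANOVA mean squares (rows = subjects, columns = raters); the
    confidence interval follows McGraw & Wong. ``ratings`` is an
    (n_subjects, n_raters) array with no missing cells.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 5 or ratings.shape[1] < 2:
        raise StatsError("need >= 5 subjects rated by >= 2 raters")
    if np.isnan(ratings).any():
        raise StatsError("missing cells are not supported")
    if np.allclose(ratings, ratings.flat[0]):
        return ICCResult(estimate=1.0, ci=(np.nan, np.nan), degenerate=True)
    n, k = ratings.shape
    grand = ratings.mean()
    row_m = ratings.mean(axis=1)
    col_m = ratings.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return ICCResult(estimate=0.0, ci=(np.nan, np.nan), degenerate=True)
    icc = (msr - mse) / denom

    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci = (float(lower), float(upper))
    else:
        ci = (np.nan, np.nan)
    return ICCResult(estimate=float(icc), ci=ci)


# ---------------------------------------------------------------------------
# Group-comparison table (pipeline helper)
# ---------------------------------------------------------------------------


def group_comparison(
    records: pd.DataFrame,
    continuous: list,
    binary: list,
    outcome: str = "isr",
    method: str = "welch",
) -> dict:
    """Mean +/- SD and t-test per continuous variable, counts and
    chi-square/Fisher per binary variable, split on the outcome."""
    g0 = records[records[outcome] == 0]
    g1 = records[records[outcome] == 1]
    out = {}
    for name in continuous:
        x0, x1 = g0[name].dropna(), g1[name].dropna()
        stat, p = two_sample_test(x1, x0, method=method)
        out[name] = {
            "nonisr_mean": float(x0.mean()),
            "nonisr_sd": float(x0.std()),
            "isr_mean": float(x1.mean()),
            "isr_sd": float(x1.std()),
            "p": p,
        }
    for name in binary:
        a, b = int(g0[name].sum()), int(g1[name].sum())
        table = [[a, len(g0) - a], [b, len(g1) - b]]
        _, p = categorical_test(table)
        out[name] = {
            "nonisr_count": a,
            "nonisr_pct": round(100 * a / len(g0), 1),
            "isr_count": b,
            "isr_pct": round(100 * b / len(g1), 1),
            "p": p,
        }
    return out
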