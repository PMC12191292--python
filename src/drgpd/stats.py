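"""Cohort-level statistics for the DRG imaging metrics.

Implements the analysis plan used to relate the imaging metrics (DRG-PD,
DRG-T2, DRG-Vol) to small-fibre-neuropathy (SFN) status: Mann-Whitney U
group comparisons with Cliff's delta effect sizes, the rank identity
AUC = (delta + 1)/2 and full ROC curves, Spearman correlations, ICC(2,1)
inter-rater agreement, multivariable linear and logistic regression with
AIC / McFadden pseudo-R^2, and a Lilliefors-type Kolmogorov-Smirnov
normality check.  `sfn_analysis` orchestrates the whole plan over a cohort
table.

Two-sided alpha = 0.05 throughout; no multiplicity adjustment by default
(exploratory analysis), with an optional Holm correction.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from ._errors import ValidationError

__all__ = [
    "GroupComparison",
    "RegressionFit",
    "ICCResult",
    "ROCResult",
    "mann_whitney",
    "cliffs_delta",
    "delta_to_auc",
    "roc_auc",
    "spearman",
    "icc_agreement",
    "icc_consistency",
    "logistic_fit",
    "linear_fit",
    "ks_normality",
    "binomial_null_deviance",
    "sfn_analysis",
]


# ---------------------------------------------------------------------------
# result containers


@dataclasses.dataclass
class GroupComparison:
    """Two-group comparison: medians/IQRs, Mann-Whitney U, Cliff's delta."""

    n_pos: int
    n_neg: int
    median_pos: float
    iqr_pos: tuple[float, float]
    median_neg: float
    iqr_neg: tuple[float, float]
    u_stat: float
    p_value: float
    delta: float
    delta_abs: float
    delta_ci_low: float
    delta_ci_high: float


@dataclasses.dataclass
class RegressionFit:
    """Coefficient table plus fit diagnostics for a linear or logistic model."""

    table: pd.DataFrame  # columns: term, estimate, std_error, z_or_t, p_value
    n: int
    k: int  # number of coefficients incl. intercept
    kind: str  # "logistic" | "linear"
    deviance: float | None = None  # logistic: residual deviance (-2 loglik)
    null_deviance: float | None = None
    aic: float | None = None
    mcfadden_r2: float | None = None
    lr_p: float | None = None
    resid_var: float | None = None  # linear: residual variance
    separation_flag: bool = False


@dataclasses.dataclass
class ICCResult:
    """Intraclass correlation, two-way random effects, absolute agreement,
    single measures (ICC(2,1)), with an F-distribution 95% CI."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    model: str = "two-way agreement, single measures"


@dataclasses.dataclass
class ROCResult:
    """ROC staircase plus the midrank (Mann-Whitney) AUC."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# rank-based comparisons


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    Exact enumeration when ``n_x * n_y <= 400`` and there are no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size * y.size <= 400 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _dominance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.sign(x[:, None] - y[None, :])


def cliffs_delta(
    x, y, ci_method: str = "normal", n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Cliff's delta by direct pair counting, with a 95% CI.

    ``delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x n_y)``.  The default CI
    is the consistent-variance normal method on the delta scale with the
    asymmetric endpoint shrinkage that keeps the interval inside [-1, 1]
    (the transformation of Feng & Cliff); ``ci_method="bootstrap"`` gives a
    seeded percentile bootstrap instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    m, n = x.size, y.size
    dom = _dominance(x, y)
    delta = float(dom.mean())
    if min(m, n) < 2:
        return delta, (-1.0, 1.0)

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(0, m, m)]
            yb = y[rng.integers(0, n, n)]
            reps[b] = _dominance(xb, yb).mean()
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return delta, (float(max(lo, -1.0)), float(min(hi, 1.0)))

    di = dom.mean(axis=1)
    dj = dom.mean(axis=0)
    s2 = (
        n**2 * np.sum((di - delta) ** 2)
        + m**2 * np.sum((dj - delta) ** 2)
        - np.sum((dom - delta) ** 2)
    ) / (m * n * (m - 1) * (n - 1))
    s2 = max(s2, 0.0)
    z = sps.norm.ppf(0.975)
    if s2 == 0.0:
        return delta, (delta, delta)
    denom_lo = 1 - delta**2 + z**2 * s2
    root = z * np.sqrt(s2) * np.sqrt(max(1 - 2 * delta**2 + delta**4 + z**2 * s2, 0.0))
    lo = (delta - delta**3 - root) / denom_lo
    hi = (delta - delta**3 + root) / denom_lo
    return delta, (float(max(lo, -1.0)), float(min(hi, 1.0)))


def delta_to_auc(delta: float) -> float:
    """Rank identity linking Cliff's delta to the ROC AUC: ``(delta+1)/2``.

    Exact under the shared midrank tie convention: both statistics reduce to
    ``P(X > Y) + 0.5 P(X = Y)``.
    """
    if not -1.0 <= delta <= 1.0:
        raise ValidationError(f"delta must be in [-1, 1], got {delta}")
    return (delta + 1.0) / 2.0


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC of ``scores`` for binary ``labels``.

    The AUC is the midrank (Mann-Whitney) statistic — ties contribute 1/2 —
    so it matches ``delta_to_auc(cliffs_delta(pos, neg))`` to machine
    precision.  The staircase is swept over all distinct thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(
        thresholds=thr, sensitivities=tpr, specificities=1.0 - fpr, auc=float(auc)
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks) with t-approximation p.

    Constant input yields ``(nan, nan)`` — the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# agreement


def _icc_mean_squares(ratings: np.ndarray):
    n, k = ratings.shape
    grand = ratings.mean()
    row_m = ratings.mean(axis=1)
    col_m = ratings.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sse = np.sum((ratings - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_agreement(ratings, ci: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Standard mean-square decomposition (subject, rater, residual) with the
    F-distribution confidence bounds of McGraw & Wong.  ``ratings`` is an
    (n_subjects x n_raters) complete matrix.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 5 or r.shape[1] < 2:
        raise ValidationError("ratings must be (>=5 subjects) x (>=2 raters)")
    if not np.all(np.isfinite(r)):
        raise ValidationError("ratings matrix must be complete (no missing values)")
    n, k = r.shape
    msr, msc, mse = _icc_mean_squares(r)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong CI for ICC(A,1)
    alpha = 1.0 - ci
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_obs = msr / mse
        fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
        fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
        del f_obs
    else:
        lo = hi = 1.0
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi), n_subjects=n)


def icc_consistency(ratings) -> float:
    """Consistency-type single-measures ICC (insensitive to rater offsets)."""
    r = np.asarray(ratings, dtype=float)
    n, k = r.shape
    msr, _, mse = _icc_mean_squares(r)
    return float((msr - mse) / (msr + (k - 1) * mse))


# ---------------------------------------------------------------------------
# regression


def _check_design(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name offending columns by greedy rank growth
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cols = kept + [j]
            if np.linalg.matrix_rank(X[:, cols]) == len(kept):
                bad.append(design.columns[j])
            else:
                kept.append(j)
        raise ValidationError(f"design matrix is rank-deficient; offending columns: {bad}")


def binomial_null_deviance(n_pos: int, n: int) -> float:
    """Deviance of the intercept-only Bernoulli model with ``n_pos`` of ``n``
    positive outcomes: ``-2 [n_pos ln p + (n - n_pos) ln (1-p)]``, p = n_pos/n."""
    if not 0 < n_pos < n:
        raise ValidationError("need both outcome classes")
    p = n_pos / n
    return -2.0 * (n_pos * np.log(p) + (n - n_pos) * np.log(1.0 - p))


def logistic_fit(design: pd.DataFrame, outcome, standardize: bool = False) -> RegressionFit:
    """Multivariable logistic regression by maximum likelihood (IRLS).

    Returns Wald z and p per coefficient, residual deviance, AIC
    (= deviance + 2k), McFadden pseudo-R^2 and the likelihood-ratio p
    against the intercept-only model.  Complete or quasi-complete
    separation is flagged, not raised.  An intercept is prepended.
    Covariates enter on their native scales by default; ``standardize``
    z-scores non-binary columns for numerical conditioning (coefficients
    then refer to SD units).
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValidationError("outcome is constant; both classes required")
    design = pd.DataFrame(design)
    if standardize:
        design = design.copy()
        for col in design.columns:
            v = design[col].astype(float)
            if v.nunique() > 2 and v.std(ddof=0) > 0:
                design[col] = (v - v.mean()) / v.std(ddof=0)
    X = sm.add_constant(design.astype(float), prepend=True, has_constant="add")
    _check_design(X)

    separation = False
    with np.errstate(all="ignore"):
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # PerfectSeparationError and friends
            separation = True
            fit = sm.Logit(y, X).fit_regularized(alpha=1e-8, disp=0, maxiter=500)
    mu = fit.predict(X)
    if np.any(np.abs(fit.params) > 30) or np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
        separation = True

    k = X.shape[1]
    llf = float(fit.llf)
    n_pos = int(y.sum())
    null_dev = binomial_null_deviance(n_pos, y.size)
    deviance = -2.0 * llf
    ll_null = -null_dev / 2.0
    lr = 2.0 * (llf - ll_null)
    table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": np.asarray(fit.params, float),
            "std_error": np.asarray(fit.bse, float),
            "z_or_t": np.asarray(fit.params, float) / np.asarray(fit.bse, float),
            "p_value": np.asarray(fit.pvalues, float),
        }
    )
    return RegressionFit(
        table=table,
        n=int(y.size),
        k=k,
        kind="logistic",
        deviance=deviance,
        null_deviance=null_dev,
        aic=deviance + 2 * k,
        mcfadden_r2=1.0 - llf / ll_null,
        lr_p=float(sps.chi2.sf(lr, k - 1)) if k > 1 else float("nan"),
        separation_flag=separation,
    )


def linear_fit(design: pd.DataFrame, outcome) -> RegressionFit:
    """Multivariable linear regression (OLS) with t statistics and two-sided p."""
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    design = pd.DataFrame(design)
    X = sm.add_constant(design.astype(float), prepend=True, has_constant="add")
    if y.size <= X.shape[1]:
        raise ValidationError("need n > number of coefficients")
    _check_design(X)
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": np.asarray(fit.params, float),
            "std_error": np.asarray(fit.bse, float),
            "z_or_t": np.asarray(fit.tvalues, float),
            "p_value": np.asarray(fit.pvalues, float),
        }
    )
    return RegressionFit(
        table=table,
        n=int(y.size),
        k=X.shape[1],
        kind="linear",
        resid_var=float(fit.mse_resid),
        aic=float(fit.aic),
    )


# ---------------------------------------------------------------------------
# normality


@lru_cache(maxsize=8)
def _lilliefors_null(n: int, n_replicates: int, seed: int) -> tuple[float, ...]:
    """Monte-Carlo null distribution of the KS statistic with moment-estimated
    normal parameters (Lilliefors setting); cached per (n, replicates, seed)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_replicates, n))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return tuple(np.maximum(d_plus, d_minus))


def ks_normality(
    x, n_replicates: int = 10_000, random_state: int = 0
) -> tuple[float, float]:
    """One-sample KS test against a normal with moment-estimated parameters.

    Estimating the mean and SD from the data invalidates the standard KS
    null distribution (Lilliefors's observation); the p-value is therefore
    Monte-Carlo: ``(1 + #{D_null >= D}) / (1 + n_replicates)`` with a seeded
    null table shared across calls of the same sample size.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 observations")
    if np.unique(x).size == 1:
        return float("nan"), float("nan")
    mu = x.mean()
    sd = x.std(ddof=1)
    d = float(sps.kstest(x, "norm", args=(mu, sd)).statistic)
    null = np.asarray(_lilliefors_null(x.size, n_replicates, random_state))
    p = (1.0 + np.sum(null >= d)) / (1.0 + n_replicates)
    return d, float(p)


# ---------------------------------------------------------------------------
# cohort orchestration

REQUIRED_COLUMNS = [
    "id",
    "age",
    "sex",
    "phenotype",
    "alpha_gal",
    "lyso_gb3",
    "prior_fd_therapy",
    "sfn",
    "drg_pd",
    "drg_t2",
    "drg_vol",
]

STRATA = [
    ("all", lambda d: np.ones(len(d), dtype=bool)),
    ("m", lambda d: (d["sex"] == "m").to_numpy()),
    ("f", lambda d: (d["sex"] == "f").to_numpy()),
    ("classical", lambda d: (d["phenotype"] == "classical").to_numpy()),
    ("classical;m", lambda d: ((d["phenotype"] == "classical") & (d["sex"] == "m")).to_numpy()),
    ("classical;f", lambda d: ((d["phenotype"] == "classical") & (d["sex"] == "f")).to_numpy()),
    ("benign", lambda d: (d["phenotype"] == "late_onset_benign").to_numpy()),
    ("benign;m", lambda d: ((d["phenotype"] == "late_onset_benign") & (d["sex"] == "m")).to_numpy()),
    ("benign;f", lambda d: ((d["phenotype"] == "late_onset_benign") & (d["sex"] == "f")).to_numpy()),
]

METRICS = ["drg_vol", "drg_t2", "drg_pd"]

SPEARMAN_COVARIATES = ["age", "bmi", "lyso_gb3", "alpha_gal", "ienfd_leg", "ienfd_thigh"]

LOGISTIC_COVARIATES = [
    "age",
    "sex_male",
    "lyso_gb3",
    "alpha_gal",
    "drg_pd",
    "drg_t2",
    "drg_vol",
    "phenotype_classical",
    "prior_fd_therapy",
]


def _group_comparison(values: np.ndarray, sfn: np.ndarray) -> GroupComparison | None:
    pos = values[sfn == 1]
    neg = values[sfn == 0]
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        return None
    u, p = mann_whitney(pos, neg)
    delta, (lo, hi) = cliffs_delta(pos, neg)
    return GroupComparison(
        n_pos=pos.size,
        n_neg=neg.size,
        median_pos=float(np.median(pos)),
        iqr_pos=tuple(np.percentile(pos, [25, 75])),
        median_neg=float(np.median(neg)),
        iqr_neg=tuple(np.percentile(neg, [25, 75])),
        u_stat=u,
        p_value=p,
        delta=delta,
        delta_abs=abs(delta),
        delta_ci_low=lo,
        delta_ci_high=hi,
    )


def sfn_analysis(cohort: pd.DataFrame, holm: bool = False) -> dict:
    """Run the full SFN analysis plan over a cohort table.

    Produces stratified group comparisons of the three DRG metrics (overall,
    by sex, by phenotype and phenotype-by-sex), the Spearman matrix of
    metrics versus continuous covariates, one linear model per metric, the
    nine-covariate logistic model for SFN, and a ROC analysis of DRG-PD per
    phenotype.  Strata in which SFN does not vary are emitted as None
    sentinels rather than errors.  No multiplicity adjustment by default
    (exploratory analysis); ``holm=True`` adds Holm-adjusted p-values to
    the group comparisons under ``holm_p``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table is missing columns: {missing}")
    d = cohort.copy()
    d["sex_male"] = (d["sex"] == "m").astype(int)
    d["phenotype_classical"] = (d["phenotype"] == "classical").astype(int)

    comparisons: dict[tuple[str, str], GroupComparison | None] = {}
    for name, selector in STRATA:
        sel = selector(d)
        sub = d.loc[sel]
        sfn = sub["sfn"].to_numpy(dtype=float)
        for metric in METRICS:
            if np.unique(sfn[np.isfinite(sfn)]).size < 2:
                comparisons[(name, metric)] = None
                continue
            comparisons[(name, metric)] = _group_comparison(
                sub[metric].to_numpy(dtype=float), sfn
            )

    spearman_rows = []
    for metric in METRICS:
        for cov in SPEARMAN_COVARIATES:
            if cov not in d.columns:
                continue
            pair = d[[metric, cov]].dropna()
            if len(pair) >= 3:
                rho, p = spearman(pair[metric], pair[cov])
            else:
                rho, p = float("nan"), float("nan")
            spearman_rows.append({"metric": metric, "covariate": cov, "rho": rho, "p_value": p})
    spearman_table = pd.DataFrame(spearman_rows)

    lin_covs = ["age", "sex_male", "alpha_gal", "lyso_gb3", "phenotype_classical", "prior_fd_therapy"]
    linear_models = {}
    for metric in METRICS:
        sub = d[lin_covs + [metric]].dropna()
        linear_models[metric] = linear_fit(sub[lin_covs], sub[metric])

    logistic = None
    sub = d[LOGISTIC_COVARIATES + ["sfn"]].dropna()
    if sub["sfn"].nunique() == 2:
        logistic = logistic_fit(sub[LOGISTIC_COVARIATES], sub["sfn"])

    roc = {}
    for pheno, key in [("classical", "classical"), ("late_onset_benign", "benign")]:
        sub = d.loc[d["phenotype"] == pheno, ["drg_pd", "sfn"]].dropna()
        if sub["sfn"].nunique() == 2:
            roc[key] = roc_auc(sub["drg_pd"], sub["sfn"])
        else:
            roc[key] = None

    holm_p = None
    if holm:
        from statsmodels.stats.multitest import multipletests

        keys = [k for k, v in comparisons.items() if v is not None]
        if keys:
            adj = multipletests([comparisons[k].p_value for k in keys], method="holm")[1]
            holm_p = dict(zip(keys, adj))

    return {
        "group_comparisons": comparisons,
        "holm_p": holm_p,
        "spearman": spearman_table,
        "linear_models": linear_models,
        "logistic": logistic,
        "roc": roc,
    }


def comparisons_to_frame(comparisons: dict) -> pd.DataFrame:
    """Flatten the stratified group comparisons into a tidy table."""
    rows = []
    for (stratum, metric), gc in comparisons.items():
        row = {"stratum": stratum, "metric": metric}
        if gc is not None:
            row.update(
                n_pos=gc.n_pos,
                n_neg=gc.n_neg,
                median_pos=gc.median_pos,
                median_neg=gc.median_neg,
                u_stat=gc.u_stat,
                p_value=gc.p_value,
                delta=gc.delta,
                delta_abs=gc.delta_abs,
                delta_ci_low=gc.delta_ci_low,
                delta_ci_high=gc.delta_ci_high,
            )
        rows.append(row)
    return pd.DataFrame(rows)
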