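"""Cohort-level association statistics.

Implements the statistical toolkit the cohort analysis runs on predicted
methylation ages: Pearson correlation, ordinary least squares with Wald
intervals, the sequential-covariate model ladder comparing nested fits by
ANOVA, the characteristics table with Shapiro-Wilk-routed group tests, the
methylation-age/graft-age ratio summary, and two-group location tests
(Mann-Whitney, Student's t, paired Wilcoxon).

Conventions, documented once and applied everywhere:

* categorical covariates are dummy-encoded with levels sorted
  alphabetically and the first level as reference;
* array-processing batch enters every regression as a fixed-effect
  covariate, including the "unadjusted" PGD model;
* quantiles use linear interpolation (R type-7);
* no multiple-testing adjustment across characteristics-table rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateDataError,
    PairingError,
    ValidationError,
)
from .io import SampleTable

__all__ = [
    "RegressionFit",
    "ModelLadder",
    "CohortTable",
    "correlate",
    "fit_linear",
    "two_group_test",
    "sequential_models",
    "cohort_table",
    "ratio_summary",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    """An OLS fit: named coefficients, Wald 95% CIs, p-values, RSS."""

    params: pd.Series
    conf_int: pd.DataFrame          # columns "lower", "upper"
    pvalues: pd.Series
    rss: float
    n: int
    df_resid: int
    covariates: list[str]

    def __post_init__(self) -> None:
        lo, hi = self.conf_int["lower"], self.conf_int["upper"]
        if not ((lo <= self.params + 1e-12) & (self.params <= hi + 1e-12)).all():
            raise ValidationError("confidence bounds do not bracket estimates")
        if self.rss < -1e-12:
            raise ValidationError("negative residual sum of squares")

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.conf_int.loc[name]
        return float(row["lower"]), float(row["upper"])


@dataclass
class ModelLadder:
    """Nested OLS fits plus ANOVA F-tests between successive models."""

    fits: list[RegressionFit]
    labels: list[str]
    anova_p: list[float]            # len(fits) - 1, comparing k vs k-1
    improved: list[bool]            # significant at alpha
    alpha: float = 0.05
    term: str = "pgd"

    def __post_init__(self) -> None:
        rss = [f.rss for f in self.fits]
        if any(b > a + 1e-8 for a, b in zip(rss, rss[1:])):
            raise ValidationError("RSS increased down a nested ladder")

    def to_frame(self) -> pd.DataFrame:
        """Report shaped like the sequential-models table: one row per
        model with its RSS, the PGD coefficient with 95% CI, and p-value."""
        rows = []
        for k, (label, fit) in enumerate(zip(self.labels, self.fits)):
            lo, hi = fit.ci(self.term)
            rows.append({
                "model": label,
                "rss": fit.rss,
                "pgd_effect": fit.coef(self.term),
                "ci_lower": lo,
                "ci_upper": hi,
                "p_pgd": float(fit.pvalues[self.term]),
                "anova_p_vs_previous": (np.nan if k == 0
                                        else self.anova_p[k - 1]),
                "significant_improvement": (False if k == 0
                                            else self.improved[k - 1]),
            })
        return pd.DataFrame(rows)


@dataclass
class CohortTable:
    """Per-variable group summaries, routed tests, and p-values."""

    rows: pd.DataFrame
    group_labels: tuple[str, str] = ("control", "case")
    alpha_normality: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def correlate(x, y) -> tuple[float, float, float]:
    """Pearson product-moment correlation.

    Returns ``(r, r_squared, p)`` with the two-sided p-value from the
    t-distribution on n - 2 degrees of freedom.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if xv.size < 3:
        raise ValidationError("need n >= 3 for a correlation p-value")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValidationError("non-finite values in correlation input")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError("zero variance in correlation input")
    res = stats.pearsonr(xv, yv)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


# ---------------------------------------------------------------------------
# design encoding and OLS
# ---------------------------------------------------------------------------


def _encode_design(design: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode categoricals; reference = first level alphabetically."""
    cols: dict[str, np.ndarray] = {}
    for name in design.columns:
        col = design[name]
        if col.isna().any():
            raise ValidationError(f"covariate {name!r} has missing values")
        if pd.api.types.is_bool_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        elif pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            levels = sorted(map(str, pd.unique(col.astype(str))))
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (
                    col.astype(str) == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=design.index)


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    aliased = []
    for j in range(X.shape[1]):
        keep = [k for k in range(X.shape[1]) if k != j]
        if np.linalg.matrix_rank(X[:, keep]) == rank:
            aliased.append(names[j])
    return aliased


def fit_linear(
    response,
    design: pd.DataFrame,
    *,
    always_adjust: pd.DataFrame | pd.Series | None = None,
) -> RegressionFit:
    """Ordinary least squares with Wald 95% confidence intervals.

    ``design`` holds named covariates (numeric, boolean, or categorical);
    ``always_adjust`` appends adjustment covariates — typically the
    array-processing batch — that belong in every model.  Categorical
    encoding: alphabetical first level is the reference.  Rank-deficient
    designs raise :class:`CollinearityError` naming the aliased columns.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    if isinstance(always_adjust, pd.Series):
        always_adjust = always_adjust.to_frame()
    if always_adjust is not None:
        overlap = set(design.columns) & set(always_adjust.columns)
        if overlap:
            always_adjust = always_adjust.drop(columns=sorted(overlap))
        design = pd.concat(
            [design.reset_index(drop=True),
             always_adjust.reset_index(drop=True)], axis=1)
    if len(design) != y.size:
        raise ValidationError("response and design lengths differ")
    X = _encode_design(design)
    names = ["intercept", *X.columns]
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        aliased = _find_aliased(mat, names)
        raise CollinearityError(
            f"rank-deficient design; aliased columns: {aliased}",
            aliased=aliased,
        )
    res = sm.OLS(y, pd.DataFrame(mat, columns=names)).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return RegressionFit(
        params=res.params,
        conf_int=ci,
        pvalues=res.pvalues,
        rss=float(res.ssr),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
        covariates=list(design.columns),
    )


def anova_nested(small: RegressionFit, big: RegressionFit) -> tuple[float, float]:
    """F-test comparing nested OLS fits via their residual sums of squares.

    F = ((RSS_small - RSS_big)/(df_small - df_big)) / (RSS_big/df_big).
    """
    df_num = small.df_resid - big.df_resid
    if df_num <= 0:
        raise ValidationError("models are not strictly nested")
    if big.df_resid <= 0:
        raise ValidationError("saturated larger model; no residual df")
    num = (small.rss - big.rss) / df_num
    den = big.rss / big.df_resid
    if den <= 0:
        return math.inf, 0.0
    f = num / den
    p = float(stats.f.sf(f, df_num, big.df_resid))
    return float(f), p


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------


def _exact_mann_whitney_ok(a: np.ndarray, b: np.ndarray) -> bool:
    combined = np.concatenate([a, b])
    return combined.size <= 20 and np.unique(combined).size == combined.size


def two_group_test(
    values,
    group,
    *,
    mode: str = "auto",
    pair_id=None,
) -> tuple[float, float]:
    """Two-sided two-group location test; returns ``(statistic, p)``.

    Modes
    -----
    ``mann_whitney``
        Exact distribution when combined n <= 20 without ties, otherwise
        the normal approximation with tie correction.
    ``t``
        Student's t (equal variances), for normally distributed variables.
    ``wilcoxon_paired``
        Wilcoxon signed-rank on pairs matched by ``pair_id`` across the two
        groups (e.g. hypoxia vs normoxia measurements per subject).
    ``auto``
        Shapiro-Wilk on group-centered residuals at alpha = 0.05 routes to
        ``t`` (normal) or ``mann_whitney`` (non-normal).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group)
    if v.shape != g.shape:
        raise ValidationError("values and group must be equal length")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError(f"group must be binary, got levels {levels}")
    a = v[g == levels[0]]
    b = v[g == levels[1]]
    if min(a.size, b.size) < 2:
        raise ValidationError("need >= 2 observations per group")

    if mode == "auto":
        resid = np.concatenate([a - a.mean(), b - b.mean()])
        if np.ptp(resid) == 0:
            mode = "t"
        else:
            mode = ("t" if stats.shapiro(resid).pvalue >= 0.05
                    else "mann_whitney")

    if mode == "t":
        if np.ptp(v) == 0:
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)

    if mode == "mann_whitney":
        if np.ptp(v) == 0:
            # every assignment of tied ranks is equally extreme
            return float(a.size * b.size / 2.0), 1.0
        method = "exact" if _exact_mann_whitney_ok(a, b) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)

    if mode == "wilcoxon_paired":
        if pair_id is None:
            raise PairingError("wilcoxon_paired requires pair_id")
        pid = np.asarray(pair_id)
        ids_a = pid[g == levels[0]]
        ids_b = pid[g == levels[1]]
        if (np.unique(ids_a).size != ids_a.size
                or sorted(ids_a) != sorted(ids_b)):
            raise PairingError("pair ids do not match one-to-one across groups")
        a_sorted = a[np.argsort(ids_a)]
        b_sorted = b[np.argsort(ids_b)]
        diff = a_sorted - b_sorted
        if np.all(diff == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(a_sorted, b_sorted, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)

    raise ValidationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# sequential model ladder
# ---------------------------------------------------------------------------

_LADDER = [
    ("PGD", []),
    ("+ donor age", ["donor_age"]),
    ("+ donor sex, BMI, CMV status, and White ethnicity",
     ["donor_sex", "donor_bmi", "cmv_group", "donor_white"]),
    ("+ recipient age, sex, BMI, and White ethnicity; and transplant "
     "indication",
     ["recipient_age", "recipient_sex", "recipient_bmi", "recipient_white",
      "indication"]),
]


def sequential_models(
    table: SampleTable,
    meth_age,
    *,
    alpha: float = 0.05,
) -> ModelLadder:
    """Fit the four nested PGD models and compare successive fits by ANOVA.

    Model 0 regresses methylation age on PGD adjusting for batch alone;
    models 1-3 sequentially add donor age; donor sex/BMI/CMV/White; and
    recipient age/sex/BMI/White plus transplant indication.  Every model
    carries batch.  Missing covariates raise rather than dropping subjects.
    """
    df = table.data
    y = np.asarray(meth_age, dtype=float)
    if y.size != len(df):
        raise ValidationError("meth_age length does not match sample table")
    needed = sorted({c for _, cs in _LADDER for c in cs})
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise ValidationError(f"sample table lacks ladder covariates: {absent}")
    for c in needed:
        if df[c].isna().any():
            raise ValidationError(f"covariate {c!r} has missing values")

    batch = df[["batch"]]
    fits: list[RegressionFit] = []
    labels: list[str] = []
    cols: list[str] = ["pgd"]
    for label, extra in _LADDER:
        cols = cols + extra
        fits.append(fit_linear(y, df[cols], always_adjust=batch))
        labels.append(label)
    anova_p = []
    improved = []
    for small, big in zip(fits, fits[1:]):
        _, p = anova_nested(small, big)
        anova_p.append(p)
        improved.append(p < alpha)
    return ModelLadder(fits=fits, labels=labels, anova_p=anova_p,
                       improved=improved, alpha=alpha, term="pgd")


# ---------------------------------------------------------------------------
# cohort characteristics table
# ---------------------------------------------------------------------------


def _quartiles(v: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return float(q1), float(med), float(q3)


def cohort_table(
    table: SampleTable,
    *,
    group: str = "pgd",
    variables: list[str] | None = None,
    alpha_normality: float = 0.05,
) -> CohortTable:
    """Characteristics table comparing the two exposure groups.

    Continuous variables are Shapiro-Wilk tested (on group-centered
    residuals, alpha = 0.05): normal ones are shown as mean (SD) and
    compared by Student's t-test, non-normal ones as median [IQR] by
    Mann-Whitney U.  Categorical and boolean variables are shown as N (%)
    and compared by chi-squared — Yates-corrected for 2x2 tables.  A
    categorical with a single observed level is reported without a test.
    """
    df = table.data
    if group not in df.columns:
        raise ValidationError(f"grouping column {group!r} absent")
    g = df[group].astype(bool).to_numpy()
    if min(g.sum(), (~g).sum()) < 2:
        raise ValidationError("need >= 2 subjects per group")
    if variables is None:
        skip = {"sample_id", group, "entry_time", "event_time", "event"}
        variables = [c for c in df.columns if c not in skip]

    rows = []
    for name in variables:
        col = df[name]
        is_continuous = (pd.api.types.is_numeric_dtype(col)
                         and not pd.api.types.is_bool_dtype(col))
        a = col[~g]
        b = col[g]
        if is_continuous:
            av, bv = a.to_numpy(float), b.to_numpy(float)
            resid = np.concatenate([av - av.mean(), bv - bv.mean()])
            if np.ptp(resid) == 0:
                normal = True
            else:
                normal = stats.shapiro(resid).pvalue >= alpha_normality
            if normal:
                _, p = two_group_test(col.to_numpy(float), g, mode="t")
                summ = [f"{v.mean():.1f} ({v.std(ddof=1):.1f})"
                        for v in (av, bv)]
                test = "t"
            else:
                _, p = two_group_test(col.to_numpy(float), g,
                                      mode="mann_whitney")
                summ = []
                for v in (av, bv):
                    q1, med, q3 = _quartiles(v)
                    summ.append(f"{med:.1f} [{q1:.1f}, {q3:.1f}]")
                test = "mann_whitney"
            rows.append({"variable": name, "type": "continuous",
                         "group0": summ[0], "group1": summ[1],
                         "test": test, "p": p, "normal": normal})
        else:
            counts = pd.crosstab(col.astype(str), g)
            if counts.shape[0] < 2:
                rows.append({"variable": name, "type": "categorical",
                             "group0": _pct(a), "group1": _pct(b),
                             "test": "none (single level)", "p": np.nan,
                             "normal": np.nan})
                continue
            correction = counts.shape == (2, 2)
            chi2 = stats.chi2_contingency(counts.to_numpy(),
                                          correction=correction)
            rows.append({"variable": name, "type": "categorical",
                         "group0": _pct(a), "group1": _pct(b),
                         "test": "chi2" + (" (Yates)" if correction else ""),
                         "p": float(chi2.pvalue), "normal": np.nan})
    return CohortTable(rows=pd.DataFrame(rows),
                       alpha_normality=alpha_normality)


def _pct(col: pd.Series) -> str:
    n = len(col)
    parts = []
    for lev, cnt in col.astype(str).value_counts().sort_index().items():
        parts.append(f"{lev}: {cnt} ({100 * cnt / n:.0f}%)")
    return "; ".join(parts)


# ---------------------------------------------------------------------------
# ratio summary
# ---------------------------------------------------------------------------


def ratio_summary(meth_age, graft_age) -> tuple[float, tuple[float, float]]:
    """Median and IQR of the per-subject methylation-age/graft-age ratio.

    Quantiles use linear interpolation (R type-7).  Returns
    ``(median, (q1, q3))``.
    """
    m = np.asarray(meth_age, dtype=float)
    a = np.asarray(graft_age, dtype=float)
    if m.shape != a.shape:
        raise ValidationError("meth_age and graft_age must be equal length")
    if np.any(a <= 0):
        raise ValidationError("graft_age must be positive")
    ratio = m / a
    q1, med, q3 = _quartiles(ratio)
    return med, (q1, q3)
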