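"""Association statistics for the cohort analyses.

Covers the test battery used to compare SRE with non-SRE patients: exact and
asymptotic 2x2 tests, the rank-sum test for continuous attributes, odds
ratios, multivariable logistic regression with reference-coded categorical
predictors, ANCOVA-style group comparison with Bonferroni family correction,
partial correlation by the residual method, and the p < 0.1 univariate entry
rule for model building.

Computation is delegated to scipy.stats and statsmodels; this module fixes the
conventions (two-sided exact p as the sum of point hypergeometric
probabilities not exceeding the observed table's, midrank ties, Wald CIs,
Woolf CIs for crude odds ratios) and attaches the warnings the downstream
report needs (expected counts below 5, separation, degenerate margins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .cohort import Cohort, CrossTab2x2, cross_tab

__all__ = [
    "TestResult",
    "EffectEstimate",
    "ModelSpec",
    "Predictor",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "odds_ratio_2x2",
    "wilcoxon_rank_sum",
    "logistic_fit",
    "ancova_group_test",
    "partial_correlation",
    "select_univariate",
    "auto_2x2_test",
    "UnivariateResult",
]


@dataclass
class TestResult:
    method: str
    p_two_sided: float
    statistic: Optional[float] = None
    df: Optional[float] = None
    warnings: list = field(default_factory=list)
    significant_bonferroni: Optional[bool] = None

    def __post_init__(self):
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class EffectEstimate:
    term: str
    ratio: float
    ci_low: float
    ci_high: float
    p: float
    reference: Optional[str] = None
    diagnostics: list = field(default_factory=list)

    def __post_init__(self):
        if not self.diagnostics and not (self.ci_low <= self.ratio <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def _as_table(table) -> np.ndarray:
    if isinstance(table, CrossTab2x2):
        return table.as_array()
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("expected a 2x2 table of nonnegative integer counts")
    return t.astype(int)


def _margins(t: np.ndarray):
    return t.sum(axis=1), t.sum(axis=0)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test.

    p is the sum of point hypergeometric probabilities (over tables with the
    observed margins) not exceeding the observed table's probability, with a
    relative tolerance guard for floating-point ties.  A table with a zero
    margin is degenerate: p = 1 with a warning.
    """
    t = _as_table(table)
    rows, cols = _margins(t)
    if min(rows.min(), cols.min()) == 0:
        return TestResult(method="fisher_exact", p_two_sided=1.0,
                          warnings=["degenerate margin"])
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(method="fisher_exact", p_two_sided=float(min(p, 1.0)))


def _expected(t: np.ndarray) -> np.ndarray:
    rows, cols = _margins(t)
    return np.outer(rows, cols) / t.sum()


def chi_square_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table (df = 1),
    optionally Yates-corrected; warns when any expected count is below 5."""
    t = _as_table(table)
    rows, cols = _margins(t)
    if min(rows.min(), cols.min()) == 0:
        raise ValueError("zero margin: chi-square undefined, use the exact test")
    stat, p, df, expected = stats.chi2_contingency(t, correction=yates)
    warns = []
    if expected.min() < 5:
        warns.append(
            f"expected count below 5 (min {expected.min():.2f}): "
            "asymptotic p unreliable, prefer the exact test")
    return TestResult(method="chi_square_yates" if yates else "chi_square",
                      statistic=float(stat), df=float(df),
                      p_two_sided=float(p), warnings=warns)


def auto_2x2_test(table) -> TestResult:
    """Dialect rule: exact test when any expected count is below 5, Pearson
    chi-square otherwise (the result records which ran)."""
    t = _as_table(table)
    rows, cols = _margins(t)
    if min(rows.min(), cols.min()) == 0 or _expected(t).min() < 5:
        return fisher_exact_2x2(t)
    return chi_square_2x2(t, yates=False)


def odds_ratio_2x2(table, continuity_correction: bool = False) -> EffectEstimate:
    """Crude odds ratio (a*d)/(b*c) with Woolf logit 95% CI.

    With a zero cell the ratio is undefined; pass
    ``continuity_correction=True`` to add 0.5 to every cell (flagged in the
    diagnostics).
    """
    t = _as_table(table).astype(float)
    diag = []
    if np.any(t == 0):
        if not continuity_correction:
            raise ValueError(
                "zero cell: odds ratio undefined without continuity correction")
        t = t + 0.5
        diag.append("0.5 continuity correction applied (zero cell)")
    (a, b), (c, d) = t
    ratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = np.exp(np.log(ratio) + np.array([-z, z]) * se)
    p = 2 * stats.norm.sf(abs(np.log(ratio)) / se)
    return EffectEstimate(term="odds_ratio", ratio=float(ratio),
                          ci_low=float(lo), ci_high=float(hi), p=float(p),
                          diagnostics=diag)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact when the combined sample size is at most 20 and tie-free; otherwise
    the normal approximation with tie correction.  The method actually used is
    recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= 20 and not ties
    method = "exact" if exact else "asymptotic"
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(method=f"wilcoxon_rank_sum_{method}",
                      statistic=float(stat), p_two_sided=float(min(p, 1.0)))


@dataclass
class Predictor:
    name: str
    kind: str  # binary | continuous | categorical
    reference: Optional[str] = None  # required for categorical

    def __post_init__(self):
        if self.kind not in ("binary", "continuous", "categorical"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical predictor {self.name!r} needs a reference level")


@dataclass
class ModelSpec:
    outcome: str
    predictors: list  # of Predictor
    entry_threshold: float = 0.1  # univariate p for model entry


_SEPARATION_COEF = 15.0  # |log OR| beyond this flags (quasi-)separation


def _design(df: pd.DataFrame, predictors) -> pd.DataFrame:
    cols = {}
    refs = {}
    for p in predictors:
        s = df[p.name]
        if p.kind == "binary":
            cols[p.name] = s.astype(float)
        elif p.kind == "continuous":
            cols[p.name] = pd.to_numeric(s).astype(float)
        else:
            levels = [l for l in pd.unique(s) if l != p.reference]
            if p.reference not in set(s):
                raise ValueError(
                    f"reference level {p.reference!r} absent from {p.name!r}")
            for lev in sorted(map(str, levels)):
                key = f"{p.name}[{lev}]"
                cols[key] = (s.astype(str) == lev).astype(float)
                refs[key] = p.reference
    X = pd.DataFrame(cols, index=df.index)
    return X, refs


def logistic_fit(cohort, spec: ModelSpec) -> list:
    """Maximum-likelihood logistic regression; one EffectEstimate per
    non-intercept term (exponentiated coefficient, Wald 95% CI).

    Categorical predictors are dummy-coded against their declared reference
    level.  A term whose estimate diverges (perfect or quasi-separation) is
    flagged "separated" and its ratio is a diagnostic, not a valid estimate.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else pd.DataFrame(cohort)
    y = df[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome must have both classes")
    X, refs = _design(df, spec.predictors)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix rank-deficient after encoding")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs")
    conf = fit.conf_int()
    out = []
    np_err = np.seterr(over="ignore")  # separated terms overflow exp -> inf
    for term in X.columns:
        if term == "const":
            continue
        coef = float(fit.params[term])
        lo, hi = (float(conf.loc[term, 0]), float(conf.loc[term, 1]))
        diag = []
        if abs(coef) > _SEPARATION_COEF or not np.isfinite(fit.bse[term]) \
                or fit.bse[term] > 1e3:
            diag.append("separated")
        if not fit.mle_retvals.get("converged", True):
            diag.append("not converged")
        out.append(EffectEstimate(
            term=term,
            ratio=float(np.exp(coef)),
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            p=float(fit.pvalues[term]),
            reference=refs.get(term),
            diagnostics=diag,
        ))
    np.seterr(**np_err)
    return out


def ancova_group_test(outcome, group, covariates=None,
                      alpha_family: int = 1) -> TestResult:
    """Linear-model group comparison adjusting for covariates
    (outcome ~ group + covariates); returns the group-term p with a
    Bonferroni significance flag at 0.05 / alpha_family."""
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    X = pd.DataFrame({"group": g})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            X[c] = pd.to_numeric(cov[c]).astype(float).to_numpy()
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few observations for the model terms")
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = [c for c in X.columns if c != "const"]
        raise ValueError(f"rank-deficient design; check collinearity among {bad}")
    fit = sm.OLS(y, X).fit()
    p = float(fit.pvalues["group"])
    alpha = 0.05 / max(int(alpha_family), 1)
    return TestResult(method="ancova", statistic=float(fit.tvalues["group"]),
                      df=float(fit.df_resid), p_two_sided=p,
                      significant_bonferroni=bool(p < alpha))


def partial_correlation(x, y, controls=None) -> TestResult:
    """Partial Pearson correlation of x and y given control covariates.

    Residual method: regress x and y on [1, controls], correlate residuals;
    two-sided t test with df = n - k - 2 for k controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.column_stack([np.asarray(c, dtype=float) for c in controls])
    n, k = x.size, Z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of controls + 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    A = np.column_stack([np.ones(n), Z])
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    df = n - k - 2
    warns = []
    # a variable fully explained by the controls has (numerically) zero
    # residual variance: its partial correlation with anything is zero
    if np.std(rx) < 1e-10 * np.std(x) or np.std(ry) < 1e-10 * np.std(y):
        warns.append("residuals numerically constant after controls")
        return TestResult(method="partial_correlation", statistic=0.0,
                          df=float(df), p_two_sided=1.0, warnings=warns)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return TestResult(method="partial_correlation", statistic=r, df=float(df),
                      p_two_sided=p)


@dataclass
class UnivariateResult:
    name: str
    test: Optional[TestResult]
    retained: bool


def select_univariate(cohort, candidates, outcome: str = "sre",
                      threshold: float = 0.1) -> list:
    """Univariate screen for model entry: keep candidates whose two-group
    test against the binary outcome has p below ``threshold``.

    Binary candidates use the auto 2x2 dialect; continuous candidates the
    rank-sum test.  Untestable candidates are skipped with a warning record.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else pd.DataFrame(cohort)
    out = []
    y = df[outcome].astype(bool)
    for name in candidates:
        if name not in df.columns:
            out.append(UnivariateResult(name, None, False))
            continue
        s = df[name]
        try:
            if s.dropna().isin([True, False]).all() or s.dtype == bool:
                sb = s.astype(bool)
                tab = CrossTab2x2(
                    int((sb & y).sum()), int((sb & ~y).sum()),
                    int((~sb & y).sum()), int((~sb & ~y).sum()),
                    row_label=name, col_label=outcome)
                res = auto_2x2_test(tab)
            else:
                vals = pd.to_numeric(s, errors="coerce")
                mask = vals.notna()
                res = wilcoxon_rank_sum(vals[mask & y], vals[mask & ~y])
        except (ValueError, TypeError):
            out.append(UnivariateResult(name, None, False))
            continue
        out.append(UnivariateResult(name, res, res.p_two_sided < threshold))
    return out
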