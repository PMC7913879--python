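"""Cohort statistics: normality screening, sex comparisons, a
Bonferroni-corrected correlation screen, and stepwise multivariate linear
regression of muscle strength on the candidate predictors.

The stepwise selector follows the classic SPSS convention: at each step
the excluded candidate with the smallest partial-F p-value enters if
p < p_enter (default 0.05), then the included predictor with the largest
p-value leaves if p > p_remove (default 0.10); iteration stops when
nothing changes or a previously visited predictor set recurs.  For a
single added or removed regressor the partial F-test is exactly the
squared t-test on its coefficient, so coefficient p-values are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .exceptions import DegenerateDataError, DomainError

__all__ = [
    "ks_normality",
    "sex_compare",
    "bonferroni_alpha",
    "round_2sf",
    "CorrelationResult",
    "correlation_screen",
    "adjusted_r2",
    "StepwiseOLS",
    "StepwiseOLSResults",
    "stepwise_regression",
]


def ks_normality(values, method: str = "ks") -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and SD (ddof=1).  With
    estimated parameters the plain KS p-value (``method='ks'``) is only
    approximate (anticonservative); ``method='lilliefors'`` applies the
    Lilliefors correction.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise DomainError(f"normality test needs >= 5 values, got {v.size}")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("constant sample: normality test undefined")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors
        stat, p = lilliefors(v, dist="norm")
        return float(stat), float(p)
    if method != "ks":
        raise DomainError(f"unknown method {method!r}")
    stat, p = sps.kstest(v, "norm", args=(float(np.mean(v)), sd))
    return float(stat), float(p)


def sex_compare(group_a, group_b, variant: str = "student"
                ) -> tuple[float, float, float]:
    """Two-sided unpaired t-test between two groups -> (t, df, p).

    Default is the Student pooled-variance test; ``variant='welch'``
    uses the Welch unequal-variance form.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 values")
    equal_var = variant == "student"
    if variant not in ("student", "welch"):
        raise DomainError(f"unknown t-test variant {variant!r}")
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of a difference
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateDataError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(a.size + b.size - 2) if equal_var else float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha/m for m comparisons."""
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise DomainError(f"comparison count must be >= 1, got {m}")
    return alpha / m


def round_2sf(x: float) -> float:
    """Round to two significant figures (for reporting corrected levels)."""
    if x == 0.0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + 1)


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    outcome: str
    r: float
    p: float
    significant_bonferroni: bool
    degenerate: bool = False


def correlation_screen(table: pd.DataFrame, outcome: str, variables: list[str],
                       alpha: float = 0.05, m: int = 24
                       ) -> list[CorrelationResult]:
    """Pearson r of each variable with the outcome, flagged at alpha/m.

    Results are sorted by |r| descending; zero-variance variables are
    flagged degenerate (r undefined) and placed last, unranked.
    """
    y = table[outcome].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise DomainError("correlation screen needs >= 3 rows")
    a_corr = bonferroni_alpha(alpha, m)
    yc = y - y.mean()
    sy = float(np.sqrt((yc ** 2).sum()))
    ranked, degen = [], []
    for var in variables:
        x = table[var].to_numpy(dtype=float)
        xc = x - x.mean()
        sx = float(np.sqrt((xc ** 2).sum()))
        if sx == 0.0 or sy == 0.0:
            degen.append(CorrelationResult(var, outcome, float("nan"), float("nan"),
                                           False, degenerate=True))
            continue
        r = float((xc @ yc) / (sx * sy))
        r = min(1.0, max(-1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
        ranked.append(CorrelationResult(var, outcome, r, p, p < a_corr))
    ranked.sort(key=lambda c: (-abs(c.r), c.variable))
    return ranked + degen


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1) for k predictors."""
    if n <= k + 1:
        raise DomainError(f"need n > k + 1 (n={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class StepTrace:
    """One selector step: which variable moved and the partial-F p-value."""
    action: str      # "add" | "remove"
    variable: str
    p_value: float


class StepwiseOLSResults:
    """Fitted stepwise model: selected predictors, OLS estimates, trace.

    Attributes
    ----------
    selected : list of str
        Predictors in the final model, in entry order.
    params, pvalues, bse : pandas Series
        OLS coefficient estimates, p-values and standard errors
        (including the intercept, "const").
    rsquared, rsquared_adj : float
    steps : list of StepTrace
    """

    def __init__(self, model: "StepwiseOLS", selected: list[str],
                 steps: list[StepTrace], ols_results) -> None:
        self.model = model
        self.selected = list(selected)
        self.steps = steps
        self._ols = ols_results
        self.params = ols_results.params
        self.pvalues = ols_results.pvalues
        self.bse = ols_results.bse
        self.nobs = int(ols_results.nobs)
        k = len(selected)
        self.rsquared = float(ols_results.rsquared) if k else 0.0
        self.rsquared_adj = adjusted_r2(self.rsquared, self.nobs, k)

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(exog[self.selected], has_constant="add")
        return np.asarray(self._ols.predict(X))

    def summary(self) -> str:
        lines = [f"Stepwise OLS: {self.model.outcome} ~ "
                 + (" + ".join(self.selected) if self.selected else "1"),
                 f"n = {self.nobs}, R^2 = {self.rsquared:.4f}, "
                 f"adj. R^2 = {self.rsquared_adj:.4f}", "", "Steps:"]
        for s in self.steps:
            lines.append(f"  {s.action:6s} {s.variable:24s} p = {s.p_value:.4g}")
        if not self.steps:
            lines.append("  (no variable entered)")
        lines += ["", "Coefficients:"]
        for name in self.params.index:
            lines.append(f"  {name:24s} {self.params[name]:12.5g}"
                         f"   se {self.bse[name]:10.4g}"
                         f"   p {self.pvalues[name]:.4g}")
        return "\n".join(lines)


class StepwiseOLS:
    """Stepwise multivariate linear regression model.

    Parameters
    ----------
    data : DataFrame
        Cohort table with outcome and candidate columns.
    outcome : str
        Dependent variable column.
    candidates : list of str
        Candidate predictor columns; must be finite and non-constant.
    p_enter, p_remove : float
        Partial-F entry and removal thresholds (defaults 0.05 / 0.10).

    Ties on the entry p-value break toward the alphabetically first
    variable; a visited-state set guards against add/remove cycling.
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 candidates: list[str], p_enter: float = 0.05,
                 p_remove: float = 0.10) -> None:
        if p_enter > p_remove:
            raise DomainError("p_enter must be <= p_remove to avoid thrashing")
        self.data = data
        self.outcome = outcome
        self.candidates = list(candidates)
        self.p_enter = float(p_enter)
        self.p_remove = float(p_remove)
        self._y = data[outcome].to_numpy(dtype=float)
        for c in self.candidates:
            x = data[c].to_numpy(dtype=float)
            if not np.isfinite(x).all():
                raise DomainError(f"candidate {c!r} has non-finite values")
            if np.std(x) == 0.0:
                raise DomainError(f"candidate {c!r} is constant")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       candidates: list[str] | None = None,
                       **kwargs) -> "StepwiseOLS":
        if candidates is None:
            candidates = [c for c in data.columns
                          if c != outcome
                          and pd.api.types.is_numeric_dtype(data[c])]
        return cls(data, outcome, candidates, **kwargs)

    def _fit_ols(self, included: list[str]):
        X = sm.add_constant(self.data[included], has_constant="add") \
            if included else pd.DataFrame(
                {"const": np.ones(len(self._y))}, index=self.data.index)
        return sm.OLS(self._y, X).fit()

    def fit(self) -> StepwiseOLSResults:
        included: list[str] = []
        steps: list[StepTrace] = []
        visited = {frozenset()}
        max_k = len(self._y) - 2  # keep n > k + 1 at every step
        while True:
            changed = False
            # --- entry ---
            best_var, best_p = None, None
            if len(included) < max_k:
                for c in sorted(set(self.candidates) - set(included)):
                    res = self._fit_ols(included + [c])
                    p = float(res.pvalues[c])
                    if np.isnan(p):  # collinear with included set, or no residual df
                        continue
                    if best_p is None or p < best_p:
                        best_var, best_p = c, p
            if best_var is not None and best_p < self.p_enter:
                state = frozenset(included + [best_var])
                if state in visited:
                    break
                included.append(best_var)
                visited.add(state)
                steps.append(StepTrace("add", best_var, best_p))
                changed = True
            # --- removal ---
            if included:
                res = self._fit_ols(included)
                pvals = res.pvalues.drop("const").fillna(0.0)
                worst = pvals.idxmax()
                worst_p = float(pvals[worst])
                if worst_p > self.p_remove:
                    state = frozenset(v for v in included if v != worst)
                    if state in visited:
                        break
                    included.remove(worst)
                    visited.add(state)
                    steps.append(StepTrace("remove", worst, worst_p))
                    changed = True
            if not changed:
                break
        return StepwiseOLSResults(self, included, steps, self._fit_ols(included))


def stepwise_regression(table: pd.DataFrame, outcome: str,
                        candidates: list[str], p_in: float = 0.05,
                        p_out: float = 0.10) -> StepwiseOLSResults:
    """Convenience wrapper: build and fit a :class:`StepwiseOLS` model."""
    return StepwiseOLS(table, outcome, candidates,
                       p_enter=p_in, p_remove=p_out).fit()
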