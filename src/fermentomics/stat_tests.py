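"""Shared statistical operators.

One-way ANOVA, Shapiro-Wilk/Levene assumption checks, Tukey HSD with a
compact-letter display (CLD), per-variable two-factor effect attribution, and
Spearman rank correlation with an exact small-n permutation p-value.

Assumption-check results are reported, never used to switch methods silently.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssumptionReport",
    "PosthocResult",
    "assumption_checks",
    "one_way_anova",
    "tukey_cld",
    "two_factor_attribution",
    "spearman",
]


@dataclass
class AssumptionReport:
    shapiro_p: float
    levene_p: float
    degenerate: bool = False


def _as_groups(values: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {str(k): np.asarray(v, dtype=float) for k, v in values.items()}


def assumption_checks(values: Mapping[str, Sequence[float]]) -> AssumptionReport:
    """Shapiro-Wilk normality (on pooled residuals) and Levene homoscedasticity."""
    groups = _as_groups(values)
    resid = np.concatenate([g - g.mean() for g in groups.values()])
    if resid.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(resid) == 0:
        return AssumptionReport(shapiro_p=float("nan"), levene_p=float("nan"), degenerate=True)
    shapiro_p = float(stats.shapiro(resid).pvalue)
    levene_p = float(stats.levene(*groups.values()).pvalue)
    return AssumptionReport(shapiro_p=shapiro_p, levene_p=levene_p)


def one_way_anova(values: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classic between/within F decomposition; returns (F, p).

    Degenerate input (zero variance everywhere with equal means) yields
    ``(nan, nan)`` rather than an exception, so bulk screens can proceed.
    """
    groups = _as_groups(values)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp([a.mean() for a in arrays]) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass
class PosthocResult:
    """Tukey HSD pairwise p-values plus a compact-letter display."""

    means: dict[str, float]
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    alpha: float = 0.05


def _cld(groups: list[str], significant: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact-letter display.

    ``groups`` must already be ordered (descending mean); significant pairs
    end up sharing no letter, non-significant pairs share at least one.
    """
    def absorb(cols: list[set[str]]) -> list[set[str]]:
        uniq: list[set[str]] = []
        for c in cols:
            if c and c not in uniq:
                uniq.append(c)
        return [c for c in uniq if not any(c is not d and c < d for d in uniq)]

    columns: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) not in significant:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append({g for g in col if g != a})
                new_cols.append({g for g in col if g != b})
            else:
                new_cols.append(col)
        columns = absorb(new_cols)
    # letter order follows the first (highest-mean) group of each column
    uniq = sorted(columns, key=lambda c: min(groups.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(uniq):
        for g in col:
            letters[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(letters[g])) for g in groups}


def tukey_cld(values: Mapping[str, Sequence[float]], alpha: float = 0.05) -> PosthocResult:
    """Tukey honestly-significant-differences test with letter grouping.

    Pairwise p-values come from the studentized-range distribution; letters
    are assigned by the insert-and-absorb CLD construction in order of
    descending group mean (letter ``a`` marks the highest-mean clique).
    """
    groups = _as_groups(values)
    if len(groups) < 2:
        raise ValueError("post hoc comparison needs at least 2 groups")
    names = list(groups)
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.tukey_hsd(*[groups[n] for n in names])
    pmat = pd.DataFrame(np.asarray(res.pvalue), index=names, columns=names)
    np.fill_diagonal(pmat.values, np.nan)
    means = {n: float(groups[n].mean()) for n in names}
    ordered = sorted(names, key=lambda n: (-means[n], n))
    significant = {
        frozenset((a, b))
        for a, b in itertools.combinations(names, 2)
        if pmat.loc[a, b] < alpha
    }
    letters = _cld(ordered, significant)
    return PosthocResult(means=means, pairwise_p=pmat, letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# Two-factor attribution ("matrix effect" / "time effect")
# ---------------------------------------------------------------------------

def two_factor_attribution(
    data: pd.DataFrame,
    value_cols: Sequence[str],
    matrix_col: str = "treatment",
    time_col: str = "time_h",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-variable two-way ANOVA with partial eta-squared contributions.

    For each variable a main-effects ANOVA on the categorical predictors
    (substrate/"matrix" and time) is fit; ``contribution`` is the partial
    eta-squared of the factor, expressed in %, and a variable is flagged a
    descriptor of the factor level with the highest mean when that factor's
    p-value falls below ``alpha``.

    Returns a tidy frame: variable, factor, ss, p, contribution_pct,
    significant, descriptor_level, tie (lexicographic tie-break flag).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (matrix_col, time_col):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")
    rows = []
    for var in value_cols:
        df = data[[matrix_col, time_col]].copy()
        df["y"] = pd.to_numeric(data[var])
        model = smf.ols(f"y ~ C({matrix_col}) + C({time_col})", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(model, typ=2)
        ss_total = float(table["sum_sq"].sum())
        tol = 1e-12 * max(ss_total, 1.0)  # scrub numerically-zero sums of squares
        ss_resid = float(table.loc["Residual", "sum_sq"])
        ss_resid = 0.0 if ss_resid < tol else ss_resid
        for factor, col in ((f"C({matrix_col})", matrix_col), (f"C({time_col})", time_col)):
            ss = float(table.loc[factor, "sum_sq"])
            ss = 0.0 if ss < tol else ss
            p = float(table.loc[factor, "PR(>F)"])
            if ss == 0.0:
                p = 1.0
            denom = ss + ss_resid
            if denom <= 0:
                contribution = 0.0
            else:
                contribution = 100.0 * ss / denom
            if math.isnan(p) and ss_resid == 0 and ss > 0:
                p = 0.0  # exact separation: all variance between levels
            level_means = df.groupby(col, observed=True)["y"].mean()
            top = level_means.max()
            top_levels = sorted(str(l) for l, m in level_means.items() if m == top)
            rows.append({
                "variable": var,
                "factor": col,
                "ss": ss,
                "p": p,
                "contribution_pct": contribution,
                "significant": bool(p < alpha),
                "descriptor_level": top_levels[0] if p < alpha else "none",
                "tie": len(top_levels) > 1,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman rank correlation with an exact small-n p-value
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _exact_rho_null(n: int) -> np.ndarray:
    """Null distribution of Spearman rho over all n! tie-free rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    mean = base.mean()
    denom = float(((base - mean) ** 2).sum())
    rhos = np.empty(math.factorial(n))
    centered = base - mean
    for i, perm in enumerate(itertools.permutations(centered)):
        rhos[i] = float(np.dot(centered, perm)) / denom
    return rhos


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    For n <= 9 with no ties in either vector, p is exact: the fraction of the
    n! rank permutations with \\|rho\\| at least as large as observed.  With
    ties or larger n, the usual t approximation on average ranks is used.
    Constant input has undefined rho and returns ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if n <= 9 and tie_free:
        null = _exact_rho_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
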