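"""Per-peak ANOVA via nested linear-model F-tests.

All tests reduce to one statistic: for models 1 ⊂ 2 with residual sums
of squares RSS1 ≥ RSS2 and effective parameter counts p1 < p2,

    f = ((RSS1 − RSS2) / (p2 − p1)) / (RSS2 / (n − p2)),   f ~ F(p2−p1, n−p2).

One-way ANOVA compares the intercept-only model with the group-means
model.  The factorial analysis tests each main factor by comparing the
full main-effects model with and without that factor (order-independent,
type-II style) and the genotype x diet interaction by comparing the
main-effects model against main effects plus interaction.  Designs with
empty cells are handled by dropping inestimable (all-zero) columns and
using design-matrix ranks as the effective parameter counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAIN_FACTORS = ("diet", "genotype", "week")
INTERACTION = ("genotype", "diet")

__all__ = [
    "NestedModelFit", "fit_linear_model", "f_test_nested", "one_way_anova",
    "factorial_anova", "anova_all_peaks", "bonferroni_threshold",
    "round_one_significant",
]


@dataclass
class NestedModelFit:
    """Least-squares fit summary: RSS, effective rank, sample size."""

    rss: float
    p: int
    n: int
    dropped_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rss < -1e-12:
            raise ValueError("rss must be non-negative")
        if self.p > self.n:
            raise ValueError("more parameters than observations")


def _dummies(values: pd.Series) -> tuple[np.ndarray, list[str], list]:
    """Treatment-coded indicator columns (first level is the baseline)."""
    levels = sorted(pd.unique(values), key=str)
    cols = [(values == lv).to_numpy(dtype=float) for lv in levels[1:]]
    names = [f"{values.name}[{lv}]" for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(values), 0)),
            names, levels)


def build_design_matrix(
    factors: pd.DataFrame,
    terms: list,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + treatment dummies for each term.

    ``terms`` holds factor names or pairs (interaction).  All-zero
    columns — indicators of empty cells — are dropped and reported.
    """
    n = len(factors)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for t in terms:
        if isinstance(t, (tuple, list)):
            a, b = t
            xa, na, _ = _dummies(factors[a].astype(str).rename(a))
            xb, nb, _ = _dummies(factors[b].astype(str).rename(b))
            for i in range(xa.shape[1]):
                for j in range(xb.shape[1]):
                    cols.append(xa[:, i] * xb[:, j])
                    names.append(f"{na[i]}:{nb[j]}")
        else:
            x, nm, _ = _dummies(factors[t].astype(str).rename(t))
            for i in range(x.shape[1]):
                cols.append(x[:, i])
                names.append(nm[i])
    X = np.column_stack(cols)
    keep = np.any(X != 0, axis=0)
    dropped = [nm for nm, k in zip(names, keep) if not k]
    X = X[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    return X, names, dropped


def fit_linear_model(
    response: np.ndarray,
    design_terms: list,
    sample_factors: pd.DataFrame,
) -> NestedModelFit:
    """OLS fit of a treatment-coded model; returns RSS and effective rank."""
    y = np.asarray(response, dtype=float)
    X, _, dropped = build_design_matrix(sample_factors, design_terms)
    return _fit_matrix(y, X, dropped)


def _fit_matrix(y: np.ndarray, X: np.ndarray,
                dropped: list[str]) -> NestedModelFit:
    n = len(y)
    if X.shape[1] == 0:
        raise ValueError("zero-rank design")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank == 0:
        raise ValueError("zero-rank design")
    if n <= rank:
        raise ValueError("sample size must exceed model rank")
    resid = y - X @ beta
    rss = float(resid @ resid)
    return NestedModelFit(max(rss, 0.0), int(rank), n, tuple(dropped))


def f_test_nested(fit1: NestedModelFit, fit2: NestedModelFit,
                  tol: float = 1e-9) -> tuple[float, float]:
    """F-test of nested models (fit1 reduced, fit2 full).

    Degenerate cases: equal RSS gives (0, 1); a saturated full model
    (RSS2 = 0) with remaining reduced-model residual gives (inf, 0).
    """
    if fit1.n != fit2.n:
        raise ValueError("fits use different sample sizes")
    if fit1.p >= fit2.p:
        raise ValueError("model 1 must be strictly nested in model 2")
    scale = max(fit1.rss, fit2.rss, 1.0)
    if fit1.rss < fit2.rss - tol * scale:
        raise ValueError("reduced model fits better than full: not nested")
    n, p1, p2 = fit1.n, fit1.p, fit2.p
    num = max(fit1.rss - fit2.rss, 0.0) / (p2 - p1)
    if fit2.rss <= tol * scale and fit2.rss <= tol:
        if num <= tol:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = num / (fit2.rss / (n - p2))
    p = float(stats.f.sf(f, p2 - p1, n - p2))
    return float(f), p


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classic one-way ANOVA: H0 is equality of all k group means.

    Equivalent to the pooled two-sided t-test when k = 2.  Constant
    responses yield (0, 1).
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(np.asarray(groups), name="group")
    counts = g.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if len(y) <= len(counts):
        raise ValueError("N must exceed the number of groups")
    fac = pd.DataFrame({"group": g})
    fit1 = fit_linear_model(y, [], fac)
    fit2 = fit_linear_model(y, ["group"], fac)
    return f_test_nested(fit1, fit2)


def factorial_anova(
    response: np.ndarray,
    sample_factors: pd.DataFrame,
    factors: tuple[str, ...] = MAIN_FACTORS,
    interaction: tuple[str, str] = INTERACTION,
) -> dict:
    """Four tests for one peak: each main factor plus the interaction.

    Main factors are tested against the full main-effects model
    (removing one factor at a time); the interaction is tested by
    adding it to the main-effects model.  Returns ``f_<factor>`` /
    ``p_<factor>`` pairs plus bookkeeping flags.
    """
    y = np.asarray(response, dtype=float)
    out: dict = {}
    flags: list[str] = []
    if np.allclose(y, y[0]):
        for fac in list(factors) + ["interaction"]:
            out[f"f_{fac}"] = 0.0
            out[f"p_{fac}"] = 1.0
        out["flags"] = "degenerate:constant-response"
        return out

    full_main = fit_linear_model(y, list(factors), sample_factors)
    for fac in factors:
        reduced_terms = [t for t in factors if t != fac]
        reduced = fit_linear_model(y, reduced_terms, sample_factors)
        if reduced.p >= full_main.p:
            out[f"f_{fac}"], out[f"p_{fac}"] = 0.0, 1.0
            flags.append(f"inestimable:{fac}")
            continue
        f, p = f_test_nested(reduced, full_main)
        out[f"f_{fac}"], out[f"p_{fac}"] = f, p
    with_int = fit_linear_model(y, list(factors) + [list(interaction)],
                                sample_factors)
    if with_int.dropped_columns:
        flags.append("dropped:" + ",".join(with_int.dropped_columns))
    if with_int.p <= full_main.p:
        out["f_interaction"], out["p_interaction"] = 0.0, 1.0
        flags.append("inestimable:interaction")
    else:
        f, p = f_test_nested(full_main, with_int)
        out["f_interaction"], out["p_interaction"] = f, p
    out["flags"] = ";".join(flags)
    return out


def anova_all_peaks(matrix, sample_sheet: pd.DataFrame,
                    week_categorical: bool = True) -> pd.DataFrame:
    """Factorial ANOVA for every peak of a sample-averaged matrix.

    Returns a DataFrame indexed by peak m/z with F and p columns for
    diet, genotype, week and the genotype x diet interaction.  Per-peak
    failures are recorded in ``flags`` instead of aborting the table.
    """
    if matrix.level != "sample-averaged":
        raise ValueError("ANOVA expects the sample-averaged matrix")
    sheet = sample_sheet.drop_duplicates("sample_id").set_index("sample_id")
    factors = sheet.loc[list(matrix.data.columns),
                        ["genotype", "diet", "week"]].copy()
    factors["week"] = factors["week"].astype(str if week_categorical else float)
    rows = []
    for mz, profile in matrix.data.iterrows():
        try:
            res = factorial_anova(profile.to_numpy(), factors)
        except ValueError as exc:            # pragma: no cover - defensive
            warnings.warn(f"peak {mz}: {exc}", stacklevel=2)
            res = {"flags": f"error:{exc}"}
        res["peak_mz"] = float(mz)
        rows.append(res)
    table = pd.DataFrame(rows).set_index("peak_mz").sort_index()
    return table


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def round_one_significant(x: float) -> float:
    """Round to one significant digit, as thresholds are reported."""
    if x == 0:
        return 0.0
    from math import floor, log10
    k = -int(floor(log10(abs(x))))
    return round(x, k)
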