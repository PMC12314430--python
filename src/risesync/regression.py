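"""Linear-model workflow: response preparation, OLS fits with
reference-coded categorical terms, backward elimination with a
nested-model comparison, variance inflation factors, and the predictor
correlation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "TermStat",
    "ModelFit",
    "ModelComparison",
    "NormalityCheck",
    "prepare_responses",
    "build_design",
    "fit_lm",
    "backward_eliminate",
    "vif",
    "predictor_correlations",
]

# categorical terms and their reference levels (reference-coded contrasts)
DEFAULT_CATEGORICAL: dict[str, object] = {"weight": "weak", "onset_complexity": 0}


@dataclass(frozen=True)
class TermStat:
    name: str  # expanded column name, e.g. "weight[strong]"
    b: float
    se: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    beta_std: Optional[float]  # None for the intercept


@dataclass(frozen=True)
class ModelFit:
    response: str
    terms: tuple[str, ...]  # model terms (factors, not expanded columns)
    stats: tuple[TermStat, ...]
    n: int
    df_resid: int
    rsquared: float
    llf: float
    fvalue: float
    f_df: tuple[int, int]
    term_columns: Mapping[str, tuple[str, ...]] = field(repr=False, default=None)
    ssr: float = float("nan")

    def coef_table(self) -> pd.DataFrame:
        """Coefficient table in Factor/b/SE/t/CI/beta layout."""
        return pd.DataFrame(
            {
                "Factor": [s.name for s in self.stats],
                "b": [s.b for s in self.stats],
                "SE": [s.se for s in self.stats],
                "t": [s.t for s in self.stats],
                "p": [s.p for s in self.stats],
                "CI95_low": [s.ci_low for s in self.stats],
                "CI95_high": [s.ci_high for s in self.stats],
                "beta": [s.beta_std for s in self.stats],
            }
        )


@dataclass(frozen=True)
class ModelComparison:
    """Nested-model comparison (F test plus likelihood-ratio chi-square)."""

    f: float
    df1: int
    df2: int
    p: float
    lr_chi2: float
    lr_p: float


@dataclass(frozen=True)
class NormalityCheck:
    w: float
    p: float
    transformed: bool


def prepare_responses(
    item_table: pd.DataFrame,
    log_columns: Sequence[str] = ("rise_time_ms", "median_abs_ms"),
    raw_columns: Sequence[str] = ("median_signed_ms",),
) -> tuple[pd.DataFrame, dict[str, NormalityCheck]]:
    """Log-transform the skewed responses; leave signed asynchrony raw.

    Adds ``log_<col>`` columns (natural log) and returns Shapiro-Wilk
    diagnostics per response. Nonpositive values in a log target raise
    with the offending row indices.
    """
    out = item_table.copy()
    checks: dict[str, NormalityCheck] = {}
    for col in log_columns:
        if col not in out.columns:
            continue
        bad = out.index[out[col] <= 0].tolist()
        if bad:
            raise ValueError(
                f"nonpositive values in log-transform target {col!r} at rows {bad}"
            )
        out[f"log_{col}"] = np.log(out[col])
        w, p = scipy.stats.shapiro(out[f"log_{col}"])
        checks[f"log_{col}"] = NormalityCheck(float(w), float(p), True)
    for col in raw_columns:
        if col not in out.columns:
            continue
        w, p = scipy.stats.shapiro(out[col])
        checks[col] = NormalityCheck(float(w), float(p), False)
    return out, checks


def build_design(
    table: pd.DataFrame,
    terms: Sequence[str],
    categorical: Mapping[str, object] = DEFAULT_CATEGORICAL,
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Expand model terms into a numeric design matrix (no intercept).

    Categorical terms become reference-coded dummy columns named
    ``term[level]``; the mapping term -> expanded columns is returned so
    factors can be tested and eliminated as whole blocks.
    """
    columns: dict[str, np.ndarray] = {}
    term_columns: dict[str, tuple[str, ...]] = {}
    n = len(table)
    for term in terms:
        x = table[term]
        if term in categorical or isinstance(x.dtype, pd.CategoricalDtype) or x.dtype == object:
            ref = categorical.get(term)
            levels = (
                list(x.cat.categories)
                if isinstance(x.dtype, pd.CategoricalDtype)
                else sorted(pd.unique(x))
            )
            if ref is None:
                ref = levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {term!r}")
            names = []
            for level in levels:
                if level == ref:
                    continue
                name = f"{term}[{level}]"
                columns[name] = (x == level).to_numpy(dtype=float)
                names.append(name)
            term_columns[term] = tuple(names)
        else:
            columns[term] = x.to_numpy(dtype=float)
            term_columns[term] = (term,)
    design = pd.DataFrame(columns, index=table.index) if columns else pd.DataFrame(
        index=table.index
    )
    return design, term_columns


def fit_lm(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    categorical: Mapping[str, object] = DEFAULT_CATEGORICAL,
) -> ModelFit:
    """Ordinary least squares of ``response`` on ``terms`` with intercept.

    Standardized betas are computed post hoc as b * sd(x)/sd(y) per
    expanded column. Rank-deficient designs raise naming the collinear
    columns.
    """
    y = table[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"missing values in response {response!r}")
    design, term_columns = build_design(table, terms, categorical)
    X = sm.add_constant(design, has_constant="add")
    if len(table) <= X.shape[1]:
        raise ValueError("not enough rows for the requested model")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(design.to_numpy(), rowvar=False)
        bad = [
            f"{design.columns[i]}~{design.columns[j]}"
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-10
        ] or list(design.columns)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    tvals = np.asarray(res.tvalues)
    pvals = np.asarray(res.pvalues)
    ci = np.asarray(res.conf_int(alpha=0.05))
    sd_y = float(np.std(y, ddof=1))
    stats = []
    for i, name in enumerate(X.columns):
        if name == "const":
            beta = None
            label = "Intercept"
        else:
            sd_x = float(np.std(X[name].to_numpy(), ddof=1))
            beta = float(params[i] * sd_x / sd_y) if sd_y > 0 else None
            label = name
        stats.append(
            TermStat(
                label,
                float(params[i]),
                float(bse[i]),
                float(tvals[i]),
                float(pvals[i]),
                float(ci[i, 0]),
                float(ci[i, 1]),
                beta,
            )
        )
    fvalue = float(res.fvalue) if design.shape[1] else float("nan")
    return ModelFit(
        response=response,
        terms=tuple(terms),
        stats=tuple(stats),
        n=len(y),
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        llf=float(res.llf),
        fvalue=fvalue,
        f_df=(int(res.df_model), int(res.df_resid)),
        term_columns=term_columns,
        ssr=float(res.ssr),
    )


def _term_pvalue(fit: ModelFit, table: pd.DataFrame, term: str) -> float:
    """p-value for dropping ``term``: coefficient t test for single
    columns, partial F test for categorical blocks."""
    cols = fit.term_columns[term]
    if len(cols) == 1:
        stat = next(s for s in fit.stats if s.name == cols[0])
        return stat.p
    reduced_terms = [t for t in fit.terms if t != term]
    reduced = fit_lm(table, fit.response, reduced_terms)
    comp = compare_nested(fit, reduced)
    return comp.p


def compare_nested(full: ModelFit, reduced: ModelFit) -> ModelComparison:
    """F test (and LR chi-square) of a reduced model against the full one."""
    df1 = reduced.df_resid - full.df_resid
    df2 = full.df_resid
    if df1 <= 0:
        return ModelComparison(0.0, 0, df2, 1.0, 0.0, 1.0)
    f = ((reduced.ssr - full.ssr) / df1) / (full.ssr / df2)
    f = max(f, 0.0)
    p = float(scipy.stats.f.sf(f, df1, df2))
    lr = max(2.0 * (full.llf - reduced.llf), 0.0)
    lr_p = float(scipy.stats.chi2.sf(lr, df1))
    return ModelComparison(float(f), int(df1), int(df2), p, float(lr), lr_p)


def backward_eliminate(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    categorical: Mapping[str, object] = DEFAULT_CATEGORICAL,
    alpha: float = 0.05,
) -> tuple[ModelFit, ModelFit, ModelComparison]:
    """Backward elimination: drop the least significant term until all
    remaining terms reach ``alpha``; categorical factors leave as blocks.

    Returns ``(full_fit, final_fit, comparison)`` where the comparison is
    the nested-model F test of the final against the full model.
    """
    full = fit_lm(table, response, terms, categorical)
    current = full
    current_terms = list(terms)
    while current_terms:
        pvals = {t: _term_pvalue(current, table, t) for t in current_terms}
        worst = max(pvals, key=lambda t: (pvals[t], current_terms.index(t)))
        if pvals[worst] < alpha:
            break
        current_terms = [t for t in current_terms if t != worst]
        current = fit_lm(table, response, current_terms, categorical)
    comparison = compare_nested(full, current)
    return full, current, comparison


def vif(
    table: pd.DataFrame,
    terms: Sequence[str],
    categorical: Mapping[str, object] = DEFAULT_CATEGORICAL,
) -> pd.Series:
    """Variance inflation factor per expanded design column.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the remaining
    columns (with intercept). Perfectly collinear columns report inf.
    """
    design, _ = build_design(table, terms, categorical)
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictor columns")
    X = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        others = sm.add_constant(np.delete(X, j, axis=1), has_constant="add")
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def predictor_correlations(
    table: pd.DataFrame,
    columns: Sequence[str],
    alpha: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with multiple-test-adjusted flags.

    Returns ``(r, p, flagged)`` DataFrames; ``flagged`` marks pairs with
    p < ``alpha``. Constant columns yield NaN correlations (never
    flagged).
    """
    k = len(columns)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            x = table[columns[i]].to_numpy(dtype=float)
            y = table[columns[j]].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rij, pij = scipy.stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=columns, columns=columns)
    p_df = pd.DataFrame(p, index=columns, columns=columns)
    flagged = (p_df < alpha) & ~np.eye(k, dtype=bool)
    return r_df, p_df, flagged
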