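"""Regression statistics for the environmental analyses.

Implements the two complementary inference routes used on richness and
turnover fields, both conditioned on spatial filters:

* **partial (semipartial) regression** — the independent contribution of
  each environmental predictor after accounting for the spatial filters
  and the other predictors, as semipartial R-squared with extra
  sum-of-squares F tests;
* **all-subsets AICc model selection** — every nonempty subset of the
  predictors (filters always included), ranked by small-sample-corrected
  AIC, with Akaike weights and standardized regression coefficients.

The analysis cell set (rows) must be identical across all models in a
comparison: AICc values are only comparable at a fixed n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .exceptions import InvalidSpecError, UndefinedStatisticError
from .grid import CellField

__all__ = [
    "PredictorSet",
    "PartialRegressionResult",
    "ModelSelectionRow",
    "vif",
    "partial_regression",
    "model_selection",
    "pearson",
]


@dataclass
class PredictorSet:
    """Aligned predictor matrix with optional spatial-filter conditioning.

    ``values`` is (n_cells, p); ``filters`` is (n_cells, k) or None.  Rows
    must correspond to the same analysis cell set as any response used with
    this object, with no missing values.
    """

    names: list[str]
    values: np.ndarray
    filters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise InvalidSpecError("number of predictor names does not match columns")
        if np.isnan(self.values).any():
            raise InvalidSpecError("predictor matrix contains missing values")
        if self.filters is not None:
            self.filters = np.atleast_2d(np.asarray(self.filters, dtype=float))
            if self.filters.shape[0] != self.values.shape[0]:
                raise InvalidSpecError("filter rows do not match predictor rows")
            if self.filters.shape[1] == 0:
                self.filters = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def k_filters(self) -> int:
        return 0 if self.filters is None else self.filters.shape[1]


def _response_vector(response: CellField | np.ndarray, n: int) -> np.ndarray:
    if isinstance(response, CellField):
        if response.missing.any():
            raise InvalidSpecError(
                "response has missing cells; restrict to the analysis cell set first"
            )
        y = response.values
    else:
        y = np.asarray(response, dtype=float)
    if y.shape != (n,):
        raise InvalidSpecError(f"response length {y.shape} does not match n={n}")
    if np.isnan(y).any():
        raise InvalidSpecError("response contains NaN")
    return y


def _design(cols: list[np.ndarray], n: int) -> np.ndarray:
    return np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))


def _fit_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """OLS fit returning (coefficients, RSS, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def _r2(rss: float, tss: float) -> float:
    return 1.0 - rss / tss if tss > 0 else np.nan


def vif(predictors: PredictorSet) -> dict[str, float]:
    """Variance inflation factors: 1 / (1 - R2_j) from regressing each
    predictor on the others (plus conditioning filters when present).

    Exact collinearity yields ``inf`` for the offending predictor, with a
    warning naming it.  Values below 10 are conventionally read as low
    collinearity.
    """
    if predictors.p < 2:
        raise InvalidSpecError("vif needs at least 2 predictors")
    X = predictors.values
    F = [predictors.filters[:, i] for i in range(predictors.k_filters)] if predictors.filters is not None else []
    out: dict[str, float] = {}
    for j, name in enumerate(predictors.names):
        xj = X[:, j]
        others = [X[:, i] for i in range(predictors.p) if i != j] + F
        tss = float(((xj - xj.mean()) ** 2).sum())
        if tss == 0:
            raise UndefinedStatisticError(f"predictor {name!r} has zero variance")
        _, rss, _ = _fit_rss(_design(others, predictors.n), xj)
        r2 = _r2(rss, tss)
        if r2 >= 1 - 1e-12:
            warnings.warn(f"predictor {name!r} is exactly collinear with the others")
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


@dataclass
class PartialRegressionResult:
    """Global and per-predictor statistics of the filter-conditioned model.

    ``global_r2`` is the raw coefficient of determination of the full model
    (filters + predictors) against total variance; ``global_r2_partial`` is
    the environmental fraction after conditioning on filters — the variance
    explained by the predictors among the variance the filters leave
    unexplained.  Both are reported because either reading of a published
    "global model R2" can then be audited.  ``semipartial_r2[name]`` is
    R2(full) - R2(full minus that predictor).
    """

    n: int
    k_filters: int
    predictor_names: list[str]
    global_r2: float
    global_r2_partial: float
    global_f: float
    global_f_df: tuple[int, int]
    global_p: float
    semipartial_r2: dict[str, float] = field(default_factory=dict)
    f_values: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    df_resid: int = 0


def partial_regression(
    response: CellField | np.ndarray, predictors: PredictorSet
) -> PartialRegressionResult:
    """Semipartial regression of a field on environmental predictors,
    controlling for spatial filters and for the other predictors."""
    n, p, k = predictors.n, predictors.p, predictors.k_filters
    if n <= p + k + 2:
        raise InvalidSpecError(f"too few cells (n={n}) for p={p} predictors and k={k} filters")
    y = _response_vector(response, n)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise UndefinedStatisticError("response has zero variance")

    F = [predictors.filters[:, i] for i in range(k)] if k else []
    E = [predictors.values[:, j] for j in range(p)]

    X_full = _design(F + E, n)
    _, rss_full, rank_full = _fit_rss(X_full, y)
    if rank_full < X_full.shape[1]:
        raise InvalidSpecError("rank-deficient design: predictors/filters are collinear")
    df_resid = n - X_full.shape[1]
    r2_full = _r2(rss_full, tss)

    _, rss_filters, _ = _fit_rss(_design(F, n), y)
    r2_filters = _r2(rss_filters, tss)
    # environmental fraction of the variance the filters leave unexplained
    r2_partial = (rss_filters - rss_full) / rss_filters if rss_filters > 0 else np.nan

    f_global = ((rss_filters - rss_full) / p) / (rss_full / df_resid)
    p_global = float(sps.f.sf(f_global, p, df_resid))

    res = PartialRegressionResult(
        n=n,
        k_filters=k,
        predictor_names=list(predictors.names),
        global_r2=r2_full,
        global_r2_partial=float(r2_partial),
        global_f=float(f_global),
        global_f_df=(p, df_resid),
        global_p=p_global,
        df_resid=df_resid,
    )
    for j, name in enumerate(predictors.names):
        reduced = F + [predictors.values[:, i] for i in range(p) if i != j]
        _, rss_red, _ = _fit_rss(_design(reduced, n), y)
        res.semipartial_r2[name] = float(_r2(rss_full, tss) - _r2(rss_red, tss))
        f_j = (rss_red - rss_full) / (rss_full / df_resid)
        res.f_values[name] = float(f_j)
        res.p_values[name] = float(sps.f.sf(f_j, 1, df_resid))
    return res


@dataclass
class ModelSelectionRow:
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    r2: float
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan


def _aicc(n: int, rss: float, n_coef: int) -> float:
    # Gaussian profile likelihood with constant terms dropped consistently
    k = n_coef
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def model_selection(
    response: CellField | np.ndarray, predictors: PredictorSet
) -> list[ModelSelectionRow]:
    """All-subsets AICc model selection with filters as fixed terms.

    Every nonempty predictor subset is fitted with the spatial filters
    always included.  AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n-K-1), with K
    counting the intercept, the filters and the subset's predictors.
    Coefficients are from the fit with z-scored response and predictors
    (filters enter unstandardized), so their magnitudes rank predictor
    importance.  Rows are sorted by AICc; Akaike weights sum to 1 over the
    full candidate set.
    """
    n, p, k = predictors.n, predictors.p, predictors.k_filters
    if p > 15:
        raise InvalidSpecError("all-subsets selection is limited to p <= 15 predictors")
    y = _response_vector(response, n)
    sy = y.std(ddof=1)
    if sy == 0:
        raise UndefinedStatisticError("response has zero variance")
    yz = (y - y.mean()) / sy
    Xz = np.empty_like(predictors.values)
    for j in range(p):
        col = predictors.values[:, j]
        sd = col.std(ddof=1)
        if sd == 0:
            raise UndefinedStatisticError(f"predictor {predictors.names[j]!r} has zero variance")
        Xz[:, j] = (col - col.mean()) / sd
    F = [predictors.filters[:, i] for i in range(k)] if k else []
    tss = float((yz**2).sum())

    rows: list[ModelSelectionRow] = []
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            n_coef = 1 + k + size
            if n <= n_coef + 2:
                warnings.warn(
                    f"subset {tuple(predictors.names[j] for j in subset)} skipped: "
                    f"n={n} too small for K={n_coef}"
                )
                continue
            cols = F + [Xz[:, j] for j in subset]
            X = _design(cols, n)
            beta, rss, _ = _fit_rss(X, yz)
            coefs = {
                predictors.names[j]: float(beta[1 + k + i])
                for i, j in enumerate(subset)
            }
            rows.append(
                ModelSelectionRow(
                    predictors=tuple(predictors.names[j] for j in subset),
                    coefficients=coefs,
                    r2=_r2(rss, tss),
                    aicc=_aicc(n, rss, n_coef),
                )
            )
    if not rows:
        raise InvalidSpecError("no candidate model could be fitted")
    best = min(r.aicc for r in rows)
    rel = np.array([np.exp(-(r.aicc - best) / 2) for r in rows])
    weights = rel / rel.sum()
    for r, d, w in zip(rows, (np.array([r.aicc for r in rows]) - best), weights):
        r.delta_aicc = float(d)
        r.weight = float(w)
    rows.sort(key=lambda r: r.aicc)
    return rows


def pearson(x: CellField | np.ndarray, y: CellField | np.ndarray) -> float:
    """Sample Pearson correlation over jointly defined cells."""
    xv, xok = (x.values, ~x.missing) if isinstance(x, CellField) else (np.asarray(x, float), None)
    yv, yok = (y.values, ~y.missing) if isinstance(y, CellField) else (np.asarray(y, float), None)
    ok = np.ones(len(xv), dtype=bool)
    if xok is not None:
        ok &= xok
    else:
        ok &= ~np.isnan(xv)
    if yok is not None:
        ok &= yok
    else:
        ok &= ~np.isnan(yv)
    xs, ys = xv[ok], yv[ok]
    if len(xs) < 3:
        raise UndefinedStatisticError("pearson needs at least 3 paired values")
    if xs.std() == 0 or ys.std() == 0:
        raise UndefinedStatisticError("pearson undefined for zero-variance input")
    return float(np.corrcoef(xs, ys)[0, 1])
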