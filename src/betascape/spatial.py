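"""Spatial autocorrelation machinery.

Contains the weights builders, Moran's I and its permutation test,
distance-class correlograms, and the spatial eigenvector ("spatial
filter") workflow: truncation of the inter-cell distance matrix at the
longest minimum-spanning-tree edge, principal coordinate analysis of the
truncated matrix (PCNM), and greedy forward selection of eigenvectors that
minimizes the absolute Moran's I of regression residuals.

Distances between cell centers are great-circle kilometers on a spherical
Earth (radius 6371 km) by default; planar degree distances are available
via ``metric="degrees"``.  The truncation distance and the distance matrix
always share one metric, recorded on the filter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree

from .beta import QUEEN_OFFSETS, ROOK_OFFSETS, _shift_slices
from .exceptions import InvalidSpecError, UndefinedStatisticError
from .grid import CellField, Grid

__all__ = [
    "SpatialWeights",
    "SpatialFilterSet",
    "CorrelogramRow",
    "FilterSelection",
    "queen_weights",
    "morans_i",
    "moran_permutation_pvalue",
    "correlogram",
    "great_circle_km",
    "pairwise_distances",
    "mst_truncation",
    "pcnm",
    "select_filters",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class SpatialWeights:
    """Sparse symmetric nonnegative spatial weights with a zero diagonal."""

    n: int
    matrix: sparse.csr_matrix
    scheme: str = "queen"

    def __post_init__(self) -> None:
        m = sparse.csr_matrix(self.matrix)
        if m.shape != (self.n, self.n):
            raise InvalidSpecError("weights matrix shape does not match n")
        if m.diagonal().any():
            raise InvalidSpecError("weights matrix must have a zero diagonal")
        if (abs(m - m.T) > 1e-12).nnz:
            raise InvalidSpecError("weights matrix must be symmetric")
        if m.nnz == 0:
            raise InvalidSpecError("weights matrix has no nonzero weights")
        self.matrix = m

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def restrict(self, keep: np.ndarray) -> "SpatialWeights":
        """Weights restricted to the cells flagged in boolean ``keep``."""
        idx = np.flatnonzero(keep)
        sub = self.matrix[np.ix_(idx, idx)]
        return SpatialWeights(n=len(idx), matrix=sub, scheme=self.scheme)


def queen_weights(grid: Grid, adjacency: str = "queen") -> SpatialWeights:
    """Binary contiguity weights between land cells (8-neighbor by default)."""
    if grid.n_land < 2:
        raise InvalidSpecError("need at least 2 land cells for spatial weights")
    offsets = QUEEN_OFFSETS if adjacency == "queen" else ROOK_OFFSETS
    idx = grid.land_index
    R, C = grid.n_rows, grid.n_cols
    rows, cols = [], []
    for dr, dc in offsets:
        f_sl, n_sl = _shift_slices(R, C, dr, dc)
        fi = idx[f_sl]
        ni = idx[n_sl]
        pair = (fi >= 0) & (ni >= 0)
        rows.append(fi[pair])
        cols.append(ni[pair])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    m = sparse.csr_matrix(
        (np.ones(len(i)), (i, j)), shape=(grid.n_land, grid.n_land)
    )
    return SpatialWeights(n=grid.n_land, matrix=m, scheme=adjacency)


def _as_values(values: CellField | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(values, CellField):
        return values.values, ~values.missing
    arr = np.asarray(values, dtype=float)
    return arr, ~np.isnan(arr)


def morans_i(values: CellField | np.ndarray, w: SpatialWeights) -> float:
    """Global Moran's I: (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.

    Cells with missing values are dropped and the weights restricted to the
    remaining cells.
    """
    x, ok = _as_values(values)
    if len(x) != w.n:
        raise InvalidSpecError("values length does not match weights")
    if not ok.all():
        w = w.restrict(ok)
        x = x[ok]
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError("Moran's I needs at least 3 defined values")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise UndefinedStatisticError("Moran's I undefined for zero-variance input")
    W = w.total
    num = float(z @ (w.matrix @ z))
    return (n / W) * num / denom


def _moran_from_centered(z: np.ndarray, w: SpatialWeights) -> float:
    denom = float(z @ z)
    return (len(z) / w.total) * float(z @ (w.matrix @ z)) / denom


def moran_permutation_pvalue(
    values: CellField | np.ndarray,
    w: SpatialWeights,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    return_observed: bool = False,
):
    """Two-sided permutation p-value for Moran's I.

    ``p = min(1, 2 * min(p_lower, p_upper))`` with the observed statistic
    counted in both tails.  Permuting the values leaves the mean and the
    variance unchanged, so only the cross product is recomputed.
    """
    x, ok = _as_values(values)
    if not ok.all():
        w = w.restrict(ok)
        x = x[ok]
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError("permutation test needs at least 3 values")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise UndefinedStatisticError("Moran's I undefined for zero-variance input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = n / (w.total * denom)
    i_obs = scale * float(z @ (w.matrix @ z))
    perms = np.empty(n_permutations)
    # batch permutations: rows of P are permuted copies of z
    batch = 200
    done = 0
    A = w.matrix
    while done < n_permutations:
        k = min(batch, n_permutations - done)
        P = np.empty((k, n))
        for t in range(k):
            P[t] = z[rng.permutation(n)]
        perms[done : done + k] = scale * np.einsum("ij,ij->i", P, (A @ P.T).T)
        done += k
    p_up = (1 + np.count_nonzero(perms >= i_obs)) / (n_permutations + 1)
    p_lo = (1 + np.count_nonzero(perms <= i_obs)) / (n_permutations + 1)
    p = min(1.0, 2 * min(p_up, p_lo))
    if return_observed:
        return p, i_obs
    return p


# ---------------------------------------------------------------------------
# distances


def great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between (lat, lon) rows."""
    coords = np.asarray(coords, dtype=float)
    lat = np.radians(coords[:, 0])
    lon = np.radians(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def pairwise_distances(coords: np.ndarray, metric: str = "greatcircle") -> np.ndarray:
    """Distance matrix between (lat, lon) rows; metric 'greatcircle' (km)
    or 'degrees' (planar Euclidean in degree coordinates)."""
    if metric == "greatcircle":
        return great_circle_km(coords)
    if metric == "degrees":
        c = np.asarray(coords, dtype=float)
        d = c[:, None, :] - c[None, :, :]
        return np.sqrt((d**2).sum(axis=2))
    raise InvalidSpecError(f"unknown distance metric {metric!r}")


# ---------------------------------------------------------------------------
# correlogram


@dataclass(frozen=True)
class CorrelogramRow:
    class_index: int
    d_lo: float
    d_hi: float
    n_pairs: int
    morans_i: float
    p_value: float


def correlogram(
    values: CellField,
    grid: Grid | None = None,
    n_classes: int = 10,
    n_permutations: int = 999,
    seed: int | None = None,
    metric: str = "greatcircle",
) -> list[CorrelogramRow]:
    """Moran's I per equal-width distance class with permutation p-values.

    Classes partition (0, d_max] where d_max is the largest inter-cell
    distance, so every pair falls in exactly one class.  Classes with no
    pairs are dropped with a warning.
    """
    if n_classes < 2:
        raise InvalidSpecError("n_classes must be >= 2")
    grid = grid or values.grid
    ok = ~values.missing
    coords = grid.land_centers()[ok]
    x = values.values[ok]
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError("correlogram needs at least 3 defined values")
    D = pairwise_distances(coords, metric)
    d_max = D.max()
    if d_max <= 0:
        raise UndefinedStatisticError("all cells are coincident")
    edges = np.linspace(0, d_max, n_classes + 1)
    rng = np.random.default_rng(seed)
    rows: list[CorrelogramRow] = []
    import warnings as _warnings

    for k in range(n_classes):
        lo, hi = edges[k], edges[k + 1]
        inside = (D > lo) & (D <= hi)
        np.fill_diagonal(inside, False)
        n_pairs = int(inside.sum()) // 2
        if n_pairs == 0:
            _warnings.warn(f"distance class {k} ({lo:.3g}, {hi:.3g}] has no pairs")
            continue
        w = SpatialWeights(n=n, matrix=sparse.csr_matrix(inside.astype(float)), scheme="distance_class")
        p, i_obs = moran_permutation_pvalue(
            x, w, n_permutations=n_permutations, seed=rng, return_observed=True
        )
        rows.append(CorrelogramRow(k, float(lo), float(hi), n_pairs, i_obs, p))
    return rows


# ---------------------------------------------------------------------------
# PCNM


@dataclass
class SpatialFilterSet:
    """PCNM eigenvectors with positive eigenvalues, in descending order.

    Eigenvectors with large eigenvalues describe broad-scale spatial
    gradients; small eigenvalues describe fine-scale structure.  Columns
    are unit-norm, centered and mutually orthogonal.
    """

    truncation_t: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    kept_rule: str = "eigenvalue > 1e-9 * max"
    metric: str = "greatcircle"

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]


def mst_truncation(coords: np.ndarray, metric: str = "greatcircle") -> float:
    """Longest edge of the minimum spanning tree of the complete inter-cell
    distance graph — the smallest threshold keeping all cells connected."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise InvalidSpecError("mst_truncation needs at least 2 cells")
    D = pairwise_distances(coords, metric)
    tree = minimum_spanning_tree(D)
    return float(tree.max())


def pcnm(
    coords: np.ndarray,
    t: float | None = None,
    metric: str = "greatcircle",
    beyond_factor: float = 4.0,
    eig_tol: float = 1e-9,
) -> SpatialFilterSet:
    """Principal coordinates of neighbor matrices.

    The inter-cell distance matrix is truncated: distances beyond ``t``
    (default: the longest MST edge) are replaced by ``beyond_factor * t``
    (classical constant 4).  The truncated matrix is double-centered
    (Gower) and eigen-decomposed; eigenvectors with eigenvalues above
    ``eig_tol`` times the largest are kept as spatial filters.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise InvalidSpecError("pcnm needs at least 3 cells")
    if t is None:
        t = mst_truncation(coords, metric)
    if t <= 0:
        raise InvalidSpecError("truncation distance must be positive")
    D = pairwise_distances(coords, metric)
    D = np.where(D > t, beyond_factor * t, D)
    np.fill_diagonal(D, 0.0)
    A = -0.5 * D**2
    # Gower double-centering
    A = A - A.mean(axis=0, keepdims=True) - A.mean(axis=1, keepdims=True) + A.mean()
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eig_tol * vals.max()
    if not keep.any():
        raise UndefinedStatisticError("no positive PCNM eigenvalues: degenerate geometry")
    vals, vecs = vals[keep], vecs[:, keep]
    # eigh returns unit-norm columns; re-normalize defensively
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    return SpatialFilterSet(
        truncation_t=float(t), eigenvalues=vals, eigenvectors=vecs, metric=metric
    )


# ---------------------------------------------------------------------------
# filter selection


@dataclass
class FilterSelection:
    """Result of greedy residual-Moran's-I filter selection."""

    indices: list[int] = field(default_factory=list)
    vectors: np.ndarray | None = None
    residuals: np.ndarray | None = None
    moran_path: list[float] = field(default_factory=list)
    final_p_value: float | None = None


def select_filters(
    response: CellField | np.ndarray,
    filters: SpatialFilterSet,
    w: SpatialWeights,
    alpha: float = 0.05,
    seed: int | None = None,
    n_permutations: int = 199,
    max_k: int | None = None,
    max_candidates: int | None = None,
    min_improvement: float = 0.05,
) -> FilterSelection:
    """Greedy forward selection of spatial filters.

    At each step the candidate eigenvector that most reduces the absolute
    Moran's I of the least-squares residuals is added.  Selection stops when
    the residual autocorrelation is no longer significant (seeded
    permutation test at ``alpha``), when no candidate reduces |I| by at
    least the relative ``min_improvement`` floor, or at ``max_k`` filters.
    The improvement floor is a parsimony guard: without it the selection
    accumulates filters that each remove a negligible share of the residual
    autocorrelation while eroding the environmental terms they later
    condition.  The empty selection is valid.

    ``max_candidates`` restricts the pool to the leading (broadest-scale)
    eigenvectors, which keeps the search tractable on large grids.
    """
    y, ok = _as_values(response)
    V = filters.eigenvectors
    if not ok.all():
        V = V[ok]
        w = w.restrict(ok)
        y = y[ok]
    n = len(y)
    if V.shape[0] != n:
        raise InvalidSpecError("filter rows do not match response cells")
    if max_candidates is not None:
        V = V[:, :max_candidates]
    rng = np.random.default_rng(seed)

    sel = FilterSelection()
    chosen: list[int] = []
    # orthonormal basis of [intercept | chosen filters]
    Q = np.ones((n, 1)) / np.sqrt(n)
    resid = y - Q @ (Q.T @ y)
    if float(resid @ resid) == 0:
        raise UndefinedStatisticError("response has zero variance")
    cur_i = _moran_from_centered(resid - resid.mean(), w)
    sel.moran_path.append(cur_i)
    available = list(range(V.shape[1]))
    limit = max_k if max_k is not None else V.shape[1]

    while len(chosen) < limit and available:
        p = moran_permutation_pvalue(
            resid, w, n_permutations=n_permutations, seed=rng
        )
        if p >= alpha:
            sel.final_p_value = p
            break
        best_j, best_abs, best_resid, best_i = None, (1.0 - min_improvement) * abs(cur_i), None, None
        for j in available:
            v = V[:, j]
            v_perp = v - Q @ (Q.T @ v)
            nv = float(v_perp @ v_perp)
            if nv < 1e-12:
                continue
            r_new = resid - (float(v_perp @ resid) / nv) * v_perp
            if float(r_new @ r_new) < 1e-14 * float(y @ y):
                continue
            i_new = _moran_from_centered(r_new - r_new.mean(), w)
            if abs(i_new) < best_abs - 1e-15 and abs(i_new) < abs(cur_i):
                best_j, best_abs, best_resid, best_i = j, abs(i_new), r_new, i_new
        if best_j is None:
            sel.final_p_value = p
            break
        chosen.append(best_j)
        available.remove(best_j)
        v = V[:, best_j]
        v_perp = v - Q @ (Q.T @ v)
        Q = np.column_stack([Q, v_perp / np.linalg.norm(v_perp)])
        resid = best_resid
        cur_i = best_i
        sel.moran_path.append(cur_i)
    else:
        sel.final_p_value = moran_permutation_pvalue(
            resid, w, n_permutations=n_permutations, seed=rng
        )

    sel.indices = chosen
    sel.vectors = filters.eigenvectors[:, chosen] if chosen else np.empty((filters.eigenvectors.shape[0], 0))
    sel.residuals = resid
    return sel
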