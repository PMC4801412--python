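"""Beta-diversity components and neighborhood fields.

Pairwise dissimilarity between two cells follows the Baselga decomposition
of Sorensen dissimilarity into a turnover and a nestedness-resultant
component.  With ``a`` species shared, ``b`` exclusive to the focal cell
and ``c`` exclusive to the other cell:

    beta_sim = min(b, c) / (a + min(b, c))        (Simpson turnover)
    beta_sor = (b + c) / (2a + b + c)             (Sorensen total)
    beta_sne = beta_sor - beta_sim                (nestedness-resultant)

beta_sim is insensitive to richness differences: nested pairs
(``min(b, c) = 0`` with ``a > 0``) score 0 regardless of ``|b - c|``.
When ``a + min(b, c) = 0`` (at least one empty community) the statistic is
undefined and these functions return ``None`` rather than a number.

The *neighborhood turnover* of a cell is the mean beta_sim between the cell
and its queen-adjacent (8-cell) land neighbors; coastal and edge cells
average over the 1-8 neighbors that exist.  Undefined pairs are skipped,
and cells with no usable pair are missing.  Environmental layers get the
analogous ``.dif`` treatment: the mean *absolute* difference between the
focal cell and its neighbors (signed differences would cancel on monotone
gradients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidSpecError, UndefinedStatisticError
from .grid import CellField, Grid, PAMatrix

__all__ = [
    "BetaComponents",
    "NeighborhoodField",
    "pair_components",
    "beta_sim",
    "beta_sor_sne",
    "neighborhood_turnover",
    "neighborhood_env_diff",
    "sqrt_transform",
    "QUEEN_OFFSETS",
    "ROOK_OFFSETS",
]

QUEEN_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)
ROOK_OFFSETS: tuple[tuple[int, int], ...] = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass(frozen=True)
class BetaComponents:
    a: int
    b: int
    c: int
    beta_sim: float | None
    beta_sne: float | None
    beta_sor: float | None


@dataclass
class NeighborhoodField(CellField):
    """A :class:`CellField` whose value at each cell is the mean of a
    pairwise statistic over that cell's adjacent land cells."""

    neighbor_count: np.ndarray | None = None
    transform: str = "none"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.neighbor_count is None:
            self.neighbor_count = np.zeros(self.grid.n_land, dtype=int)
        else:
            self.neighbor_count = np.asarray(self.neighbor_count, dtype=int)


def _check_counts(a: int, b: int, c: int) -> None:
    if a < 0 or b < 0 or c < 0:
        raise InvalidSpecError(f"negative component counts (a={a}, b={b}, c={c})")


def beta_sim(a: int, b: int, c: int) -> float | None:
    """Simpson-based turnover min(b,c)/(a+min(b,c)); None when undefined."""
    _check_counts(a, b, c)
    m = min(b, c)
    denom = a + m
    if denom == 0:
        return None
    return m / denom


def beta_sor_sne(a: int, b: int, c: int) -> tuple[float | None, float | None]:
    """Sorensen dissimilarity and its nestedness-resultant component."""
    _check_counts(a, b, c)
    denom = 2 * a + b + c
    if denom == 0:
        return None, None
    sor = (b + c) / denom
    sim = beta_sim(a, b, c)
    if sim is None:
        # focal or neighbor community empty: turnover undefined, so the
        # decomposition into turnover + nestedness is undefined too
        return sor, None
    return sor, sor - sim


def pair_components(
    pam: PAMatrix, cell_i: tuple[int, int], cell_j: tuple[int, int]
) -> tuple[int, int, int]:
    """(a, b, c) species counts for a focal/adjacent cell pair."""
    idx = pam.grid.land_index
    for cell in (cell_i, cell_j):
        r, c = cell
        if not (0 <= r < pam.grid.n_rows and 0 <= c < pam.grid.n_cols) or idx[r, c] < 0:
            raise InvalidSpecError(f"cell {cell} is not a land cell")
    si = pam.incidence[idx[cell_i]]
    sj = pam.incidence[idx[cell_j]]
    a = int(np.count_nonzero(si & sj))
    b = int(np.count_nonzero(si & ~sj))
    c = int(np.count_nonzero(~si & sj))
    return a, b, c


def _offsets(adjacency: str) -> tuple[tuple[int, int], ...]:
    if adjacency == "queen":
        return QUEEN_OFFSETS
    if adjacency == "rook":
        return ROOK_OFFSETS
    raise InvalidSpecError(f"unknown adjacency {adjacency!r} (use 'queen' or 'rook')")


def neighborhood_turnover(pam: PAMatrix, adjacency: str = "queen") -> NeighborhoodField:
    """Mean beta_sim between each land cell and its adjacent land cells.

    Pairs with an undefined beta_sim (one community empty) are skipped;
    ``neighbor_count`` records the pairs actually used and cells with zero
    usable pairs are marked missing.
    """
    grid = pam.grid
    R, C, S = grid.n_rows, grid.n_cols, pam.n_species
    # scatter incidence onto the full lattice for vectorized shifting
    occ = np.zeros((R, C, S), dtype=bool)
    rc = grid.land_rc
    occ[rc[:, 0], rc[:, 1], :] = pam.incidence
    land = grid.land_mask
    rich = occ.sum(axis=2).astype(np.int64)

    beta_sum = np.zeros((R, C))
    n_used = np.zeros((R, C), dtype=int)
    for dr, dc in _offsets(adjacency):
        f_sl, n_sl = _shift_slices(R, C, dr, dc)
        pair_land = land[f_sl] & land[n_sl]
        a = np.zeros_like(rich[f_sl])
        a[pair_land] = (occ[f_sl][pair_land] & occ[n_sl][pair_land]).sum(axis=1)
        b = rich[f_sl] - a
        c = rich[n_sl] - a
        m = np.minimum(b, c)
        denom = a + m
        defined = pair_land & (denom > 0)
        contrib = np.zeros_like(beta_sum[f_sl])
        contrib[defined] = m[defined] / denom[defined]
        beta_sum[f_sl] += np.where(defined, contrib, 0.0)
        n_used[f_sl] += defined.astype(int)

    flat_sum = beta_sum[rc[:, 0], rc[:, 1]]
    flat_n = n_used[rc[:, 0], rc[:, 1]]
    missing = flat_n == 0
    values = np.zeros(grid.n_land)
    values[~missing] = flat_sum[~missing] / flat_n[~missing]
    values[missing] = np.nan
    return NeighborhoodField(
        grid=grid,
        values=values,
        missing=missing,
        name="turnover",
        units="beta_sim",
        neighbor_count=flat_n,
    )


def _shift_slices(R: int, C: int, dr: int, dc: int):
    """Aligned slices (focal, neighbor) so neighbor = focal shifted by (dr, dc)."""
    fr = slice(max(0, -dr), R - max(0, dr))
    nr = slice(max(0, dr), R - max(0, -dr))
    fc = slice(max(0, -dc), C - max(0, dc))
    nc = slice(max(0, dc), C - max(0, -dc))
    return (fr, fc), (nr, nc)


def neighborhood_env_diff(
    layer: CellField, adjacency: str = "queen", mode: str = "absolute"
) -> NeighborhoodField:
    """Mean absolute difference of a layer between each cell and its
    adjacent land cells with defined values; named ``<layer>.dif``.

    ``mode="signed"`` averages raw (focal - neighbor) differences instead;
    it is offered for sensitivity analysis only, since signed differences
    cancel on monotone gradients.
    """
    if mode not in ("absolute", "signed"):
        raise InvalidSpecError(f"unknown diff mode {mode!r}")
    grid = layer.grid
    R, C = grid.n_rows, grid.n_cols
    rc = grid.land_rc
    vals = np.full((R, C), np.nan)
    vals[rc[:, 0], rc[:, 1]] = np.where(layer.missing, np.nan, layer.values)
    ok = ~np.isnan(vals)

    diff_sum = np.zeros((R, C))
    n_used = np.zeros((R, C), dtype=int)
    for dr, dc in _offsets(adjacency):
        f_sl, n_sl = _shift_slices(R, C, dr, dc)
        usable = ok[f_sl] & ok[n_sl]
        d = np.zeros_like(diff_sum[f_sl])
        raw = vals[f_sl][usable] - vals[n_sl][usable]
        d[usable] = np.abs(raw) if mode == "absolute" else raw
        diff_sum[f_sl] += d
        n_used[f_sl] += usable.astype(int)

    flat_sum = diff_sum[rc[:, 0], rc[:, 1]]
    flat_n = n_used[rc[:, 0], rc[:, 1]]
    missing = (flat_n == 0) | layer.missing
    values = np.full(grid.n_land, np.nan)
    np.divide(flat_sum, flat_n, out=values, where=~missing)
    return NeighborhoodField(
        grid=grid,
        values=values,
        missing=missing,
        name=(layer.name + ".dif") if layer.name else "dif",
        units=layer.units,
        neighbor_count=flat_n,
    )


def sqrt_transform(field: NeighborhoodField) -> NeighborhoodField:
    """Element-wise square root, used to symmetrize skewed turnover fields."""
    defined = ~field.missing
    if np.any(field.values[defined] < 0):
        raise UndefinedStatisticError("sqrt_transform requires non-negative values")
    values = field.values.copy()
    values[defined] = np.sqrt(values[defined])
    return NeighborhoodField(
        grid=field.grid,
        values=values,
        missing=field.missing.copy(),
        name=field.name,
        units=field.units,
        neighbor_count=field.neighbor_count.copy(),
        transform="sqrt",
    )
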