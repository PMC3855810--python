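"""Neighborhood competition indices (NCI) and their conversion to the
log canopy-index scale.

NCI at a focal point is  sum_j dbh_j^alpha / dist_ij^beta  over neighboring
trees j within a fixed radius (default 30 m), with dbh in cm and distance in
m; only trees taller than the focal point count as neighbors (competition
for light).  The exponents alpha and beta weight tree size against distance
and are chosen by grid search (0 to 3 in steps of 0.2, 256 combinations) to
maximize correlation with log(CAI).  The selected NCI is converted to the
log(CAI) scale by zero-intercept median (quantile, tau = 0.5) regression, so
an empty neighborhood (NCI = 0) maps to full irradiance (CAI = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.spatial import cKDTree

from treelight.allometry import AllometryConfig
from treelight.census import CensusSnapshot, GridSpec
from treelight.lightfield import LightField

DEFAULT_ALPHA_SET = np.round(np.arange(0.0, 3.0 + 1e-9, 0.2), 10)
DEFAULT_BETA_SET = DEFAULT_ALPHA_SET.copy()


@dataclass(frozen=True)
class NCIConfig:
    """Exponents and geometric rules of the competition index."""

    alpha: float = 1.6
    beta: float = 0.4
    radius: float = 30.0
    dist_floor: float = 0.1
    taller_only: bool = True
    cell_reference_height: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.radius <= 0 or self.dist_floor <= 0:
            raise ValueError("radius and distance floor must be positive")


@dataclass
class NeighborPairs:
    """Precomputed (focal, neighbor) pairs for fast (alpha, beta) sweeps."""

    focal_idx: np.ndarray  # int, index into the focal set
    dbh_cm: np.ndarray
    dist: np.ndarray  # floored distances, m
    n_focal: int

    def nci(self, alpha: float, beta: float) -> np.ndarray:
        contrib = self.dbh_cm**alpha / self.dist**beta
        return np.bincount(self.focal_idx, weights=contrib, minlength=self.n_focal)


def neighbor_pairs(
    points: np.ndarray,
    focal_heights: np.ndarray,
    snapshot: CensusSnapshot,
    allometry: AllometryConfig,
    config: NCIConfig,
    exclude_tree_ids: np.ndarray | None = None,
) -> NeighborPairs:
    """All qualifying (focal point, neighbor tree) pairs within the radius.

    Neighbors are alive trees anywhere in the plot (margin included).  With
    the taller-only rule, a tree qualifies iff its allometric height exceeds
    the focal height.  ``exclude_tree_ids`` (aligned with ``points``) drops
    the focal tree itself from its own neighborhood.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_focal = points.shape[0]
    focal_heights = np.broadcast_to(
        np.asarray(focal_heights, dtype=float), (n_focal,)
    )
    alive = snapshot.alive
    tree_xy = alive[["x", "y"]].to_numpy(dtype=float)
    tree_dbh_cm = alive["dbh_mm"].to_numpy(dtype=float) / 10.0
    tree_h = allometry.height(alive["dbh_mm"].to_numpy())
    tree_ids = alive["tree_id"].to_numpy(dtype=str)

    kdt = cKDTree(tree_xy)
    lists = kdt.query_ball_point(points, config.radius)
    fidx, dbhs, dists = [], [], []
    for i, nbrs in enumerate(lists):
        if not nbrs:
            continue
        nbrs = np.asarray(nbrs)
        if config.taller_only:
            nbrs = nbrs[tree_h[nbrs] > focal_heights[i]]
        if exclude_tree_ids is not None and len(nbrs):
            nbrs = nbrs[tree_ids[nbrs] != exclude_tree_ids[i]]
        if len(nbrs) == 0:
            continue
        d = np.linalg.norm(tree_xy[nbrs] - points[i], axis=1)
        inside = d <= config.radius
        nbrs, d = nbrs[inside], d[inside]
        fidx.append(np.full(len(nbrs), i))
        dbhs.append(tree_dbh_cm[nbrs])
        dists.append(np.maximum(d, config.dist_floor))
    if fidx:
        return NeighborPairs(
            np.concatenate(fidx),
            np.concatenate(dbhs),
            np.concatenate(dists),
            n_focal,
        )
    return NeighborPairs(
        np.empty(0, int), np.empty(0), np.empty(0), n_focal
    )


def compute_nci(
    points: np.ndarray,
    focal_heights: np.ndarray,
    snapshot: CensusSnapshot,
    allometry: AllometryConfig,
    config: NCIConfig,
    exclude_tree_ids: np.ndarray | None = None,
) -> np.ndarray:
    """NCI values at arbitrary focal points (vectorized)."""
    pairs = neighbor_pairs(
        points, focal_heights, snapshot, allometry, config, exclude_tree_ids
    )
    return pairs.nci(config.alpha, config.beta)


def nci_for_cells(
    grid: GridSpec,
    snapshot: CensusSnapshot,
    allometry: AllometryConfig,
    config: NCIConfig = NCIConfig(),
) -> LightField:
    """NCI at every core cell center, focal height = the 2 m reference."""
    centers = grid.cell_centers()
    values = compute_nci(
        centers, config.cell_reference_height, snapshot, allometry, config
    )
    return LightField(np.arange(grid.n_cells), values, "nci")


def nci_for_trees(
    snapshot: CensusSnapshot,
    allometry: AllometryConfig,
    config: NCIConfig = NCIConfig(),
    tree_ids: np.ndarray | None = None,
) -> LightField:
    """NCI at each tree's position, focal height = its own allometric height."""
    alive = snapshot.alive
    if tree_ids is not None:
        alive = alive[alive["tree_id"].isin(np.asarray(tree_ids, dtype=str))]
    pts = alive[["x", "y"]].to_numpy(dtype=float)
    heights = allometry.height(alive["dbh_mm"].to_numpy())
    ids = alive["tree_id"].to_numpy(dtype=str)
    values = compute_nci(
        pts, heights, snapshot, allometry, config, exclude_tree_ids=ids
    )
    return LightField(ids, values, "nci")


# ---------------------------------------------------------------------------
# grid search


@dataclass
class GridSearchResult:
    """Pearson-r surfaces over the (alpha, beta) grid and the selected pair."""

    alphas: np.ndarray
    betas: np.ndarray
    r_intervals: list[np.ndarray]  # one |alphas| x |betas| surface per interval
    r_pooled: np.ndarray
    alpha_star: float
    beta_star: float

    @property
    def n_combinations(self) -> int:
        return len(self.alphas) * len(self.betas)

    def surface_frame(self, which: np.ndarray | None = None):
        import pandas as pd

        surf = self.r_pooled if which is None else which
        return pd.DataFrame(
            surf,
            index=pd.Index(self.alphas, name="alpha"),
            columns=pd.Index(self.betas, name="beta"),
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def grid_search(
    pairs_by_interval: Sequence[NeighborPairs],
    log_cai_by_interval: Sequence[np.ndarray],
    alphas: np.ndarray = DEFAULT_ALPHA_SET,
    betas: np.ndarray = DEFAULT_BETA_SET,
) -> GridSearchResult:
    """Sweep the (alpha, beta) grid against log(CAI) and select the best pair.

    For each combination, Pearson's r between NCI and log(CAI) is computed
    per census interval and on the pooled data; the selected pair maximizes
    the pooled |r|.  Combinations whose NCI has zero variance are recorded
    as NaN and excluded from selection; exact ties go to the smaller alpha,
    then the smaller beta (the iteration order below guarantees this with a
    strict improvement test).
    """
    if len(pairs_by_interval) != len(log_cai_by_interval):
        raise ValueError("need one log(CAI) vector per interval")
    log_cai_by_interval = [np.asarray(v, float) for v in log_cai_by_interval]
    for p, v in zip(pairs_by_interval, log_cai_by_interval):
        if p.n_focal != v.size:
            raise ValueError("focal set and light field sizes differ")
        if p.n_focal < 3:
            raise ValueError("need at least 3 focal points")
    pooled_y = np.concatenate(log_cai_by_interval)
    r_intervals = [np.full((len(alphas), len(betas)), np.nan) for _ in pairs_by_interval]
    r_pooled = np.full((len(alphas), len(betas)), np.nan)
    best = (-np.inf, np.nan, np.nan)
    for ia, a in enumerate(alphas):
        for ib, b in enumerate(betas):
            ncis = [p.nci(a, b) for p in pairs_by_interval]
            for k, (x, y) in enumerate(zip(ncis, log_cai_by_interval)):
                r_intervals[k][ia, ib] = _pearson(x, y)
            r = _pearson(np.concatenate(ncis), pooled_y)
            r_pooled[ia, ib] = r
            if not np.isnan(r) and abs(r) > best[0]:
                best = (abs(r), a, b)
    if not np.isfinite(best[0]):
        raise ValueError("no (alpha, beta) combination produced a defined correlation")
    return GridSearchResult(
        alphas=np.asarray(alphas, float),
        betas=np.asarray(betas, float),
        r_intervals=r_intervals,
        r_pooled=r_pooled,
        alpha_star=float(best[1]),
        beta_star=float(best[2]),
    )


# ---------------------------------------------------------------------------
# conversion to the log(CAI) scale


@dataclass(frozen=True)
class ConversionCoeffs:
    """Zero-intercept polynomial mapping NCI -> log(CAI).

    ``scope`` records whether the fit is interval-specific ("ts") or pooled
    over both intervals ("tg").
    """

    b1: float
    b2: float | None = None
    scope: str = "ts"


def fit_conversion(
    nci_values: np.ndarray,
    log_cai_values: np.ndarray,
    degree: int = 1,
    tau: float = 0.5,
) -> ConversionCoeffs:
    """Median regression of log(CAI) on NCI with the intercept forced to 0.

    Solved exactly as a least-absolute-deviations linear program (HiGHS):
    minimize sum_i |y_i - (b1 x_i + b2 x_i^2)|.  Degree 1 is used for grid
    cells, degree 2 for trees (the tree relationship is curved).  Only the
    median (tau = 0.5) is supported.
    """
    if tau != 0.5:
        raise NotImplementedError("only the median (tau = 0.5) is supported")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(nci_values, dtype=float)
    y = np.asarray(log_cai_values, dtype=float)
    if x.size != y.size or x.size < degree + 1:
        raise ValueError("need at least degree+1 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all NCI values identical")
    cols = [x] if degree == 1 else [x, x**2]
    X = np.column_stack(cols)
    n, p = X.shape
    # variables: [b (p, free), u+ (n), u- (n)];  X b + u+ - u- = y
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    A_eq = sp.hstack([sp.csr_matrix(X), sp.identity(n), -sp.identity(n)], format="csr")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    b = res.x[:p]
    return ConversionCoeffs(
        b1=float(b[0]), b2=float(b[1]) if degree == 2 else None
    )


def apply_conversion(
    nci_field: LightField | np.ndarray, coeffs: ConversionCoeffs
) -> LightField | np.ndarray:
    """Evaluate the fitted zero-intercept polynomial on NCI values.

    NCI = 0 maps to 0 on the log(CAI) scale, i.e. CAI = 1 (full irradiance).
    Output may exceed the range of observed log(CAI): extreme NCI outliers
    map to extremely low values.
    """
    if isinstance(nci_field, LightField):
        if nci_field.kind != "nci":
            raise ValueError("apply_conversion expects a raw NCI field")
        vals = apply_conversion(nci_field.values, coeffs)
        return LightField(nci_field.ids, vals, "log_cai")
    x = np.asarray(nci_field, dtype=float)
    out = coeffs.b1 * x
    if coeffs.b2 is not None:
        out = out + coeffs.b2 * x**2
    return out
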