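"""Canopy index: shade index from canopy occupancy, converted to a light
estimate by distribution matching.

A canopy census records presence/absence of vegetation in six height layers
(0-2, 2-5, 5-10, 10-20, 20-30, >=30 m) on a 5 m grid.  The shade index at a
focal point is a weighted sum of occupied layer-cells lying fully above the
point and closer than 20 m horizontally.  Shade is then mapped to the canopy
index (CAI, fraction of full irradiance) by matching the empirical shade
distribution at 2 m height against a reference irradiance distribution:
the least-shaded cell receives the reference's highest irradiance quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import lognorm, rankdata

from treelight.allometry import AllometryConfig
from treelight.census import CensusSnapshot, GridSpec
from treelight.lightfield import LightField

#: Fixed height-layer bounds in m (lower, upper); the top layer is open.
LAYERS: tuple[tuple[float, float], ...] = (
    (0.0, 2.0),
    (2.0, 5.0),
    (5.0, 10.0),
    (10.0, 20.0),
    (20.0, 30.0),
    (30.0, np.inf),
)

#: Horizontal support of the shade kernel in m.
SHADE_RADIUS = 20.0

#: Reference height for grid-cell focal points in m (the height a recruit
#: must have surpassed during a census interval).
CELL_REFERENCE_HEIGHT = 2.0


@dataclass
class CanopyCensus:
    """One year's canopy occupancy: six boolean grids on a 5 m lattice."""

    year: int
    origin_x: float
    origin_y: float
    resolution: float
    occupancy: np.ndarray  # (6, ny, nx) boolean

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.ndim != 3 or occ.shape[0] != len(LAYERS):
            raise ValueError("occupancy must be (6, ny, nx)")
        self.occupancy = occ

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape[1:]

    def cell_centers(self) -> np.ndarray:
        ny, nx = self.shape
        xs = self.origin_x + self.resolution * (np.arange(nx) + 0.5)
        ys = self.origin_y + self.resolution * (np.arange(ny) + 0.5)
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


def default_kernel(distance_m: np.ndarray) -> np.ndarray:
    """Default horizontal shade kernel 1/(1+d), zero beyond 20 m."""
    d = np.asarray(distance_m, dtype=float)
    return np.where(d < SHADE_RADIUS, 1.0 / (1.0 + d), 0.0)


@dataclass
class ShadeWeights:
    """Horizontal kernel and per-layer weights of the shade index.

    The exact weighting used with real canopy census data is site-specific;
    the defaults here (kernel 1/(1+d), unit layer weights) are simple,
    monotone stand-ins and fully configurable.
    """

    kernel: Callable[[np.ndarray], np.ndarray] = default_kernel
    layer_weights: np.ndarray = field(
        default_factory=lambda: np.ones(len(LAYERS))
    )

    def __post_init__(self) -> None:
        w = np.asarray(self.layer_weights, dtype=float)
        if w.shape != (len(LAYERS),) or (w < 0).any():
            raise ValueError("layer weights must be 6 non-negative numbers")
        self.layer_weights = w


@dataclass
class IrradianceReference:
    """Parametric distribution of relative irradiance in (0, 1].

    Default: a lognormal with median 2% of full irradiance (log-mean
    ln 0.02) and log-sd 1.0, truncated above at 1 — a synthetic stand-in for
    a measured understory irradiance distribution, fully configurable.
    """

    log_mean: float = float(np.log(0.02))
    log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    def ppf(self, q) -> np.ndarray:
        vals = lognorm.ppf(q, s=self.log_sd, scale=np.exp(self.log_mean))
        return np.minimum(vals, 1.0)


def shade_index(
    points: np.ndarray,
    heights: np.ndarray,
    census: CanopyCensus,
    weights: ShadeWeights | None = None,
) -> np.ndarray:
    """Shade index at focal points with per-point reference heights.

    A layer contributes iff its lower bound is at or above the reference
    height; within a layer, each occupied cell whose center lies strictly
    closer than 20 m adds ``kernel(distance) * layer_weight``.
    """
    if weights is None:
        weights = ShadeWeights()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    heights = np.broadcast_to(np.asarray(heights, dtype=float), (points.shape[0],))
    ny, nx = census.shape
    if (
        (points[:, 0] < census.origin_x)
        | (points[:, 0] > census.origin_x + nx * census.resolution)
        | (points[:, 1] < census.origin_y)
        | (points[:, 1] > census.origin_y + ny * census.resolution)
    ).any():
        raise ValueError("focal point outside the canopy census extent")
    centers = census.cell_centers()
    shade = np.zeros(points.shape[0])
    flat_occ = census.occupancy.reshape(len(LAYERS), -1)
    for li, (low, _high) in enumerate(LAYERS):
        if weights.layer_weights[li] == 0:
            continue
        occ_idx = np.flatnonzero(flat_occ[li])
        if occ_idx.size == 0:
            continue
        tree = cKDTree(centers[occ_idx])
        active = np.flatnonzero(heights <= low)
        if active.size == 0:
            continue
        neighbor_lists = tree.query_ball_point(points[active], SHADE_RADIUS)
        for pi, nbrs in zip(active, neighbor_lists):
            if not nbrs:
                continue
            d = np.linalg.norm(centers[occ_idx][nbrs] - points[pi], axis=1)
            shade[pi] += weights.layer_weights[li] * weights.kernel(d).sum()
    return shade


class ShadeToCAI:
    """Monotone decreasing mapping from shade index to canopy index.

    Built by rank-based quantile matching: a shade value at empirical
    quantile q (plotting position (i-0.5)/n, average ranks for ties) maps to
    the reference distribution's (1-q) irradiance quantile.  Values outside
    the calibrated shade range are clamped to the end values, so shade below
    the observed minimum maps to the mapping's maximum irradiance.
    """

    def __init__(self, shade_values: np.ndarray, reference: IrradianceReference):
        shade_values = np.asarray(shade_values, dtype=float)
        if shade_values.size < 2 or np.ptp(shade_values) == 0:
            raise ValueError("calibration needs at least two distinct shade values")
        n = shade_values.size
        q = (rankdata(shade_values, method="average") - 0.5) / n
        cai = reference.ppf(1.0 - q)
        order = np.argsort(shade_values, kind="stable")
        xs, ys = shade_values[order], cai[order]
        keep = np.concatenate([[True], np.diff(xs) > 0])
        self._x = xs[keep]
        self._y = ys[keep]

    def __call__(self, shade) -> np.ndarray:
        return np.interp(np.asarray(shade, dtype=float), self._x, self._y)


def calibrate(
    shade_values: np.ndarray, reference: IrradianceReference | None = None
) -> ShadeToCAI:
    """Fit the shade-to-CAI quantile mapping from cell shades at 2 m height."""
    return ShadeToCAI(shade_values, reference or IrradianceReference())


def cai_for_cells(
    censuses: Sequence[CanopyCensus],
    grid: GridSpec,
    weights: ShadeWeights | None = None,
    reference: IrradianceReference | None = None,
) -> LightField:
    """CAI at every core grid-cell center at 2 m height, averaged over years.

    Each yearly canopy census is calibrated separately (the shade-to-CAI
    mapping is refit on that year's cell shades) and the yearly CAI values
    are averaged arithmetically.
    """
    if not censuses:
        raise ValueError("need at least one canopy census")
    centers = grid.cell_centers()
    yearly = []
    for census in censuses:
        shade = shade_index(
            centers, CELL_REFERENCE_HEIGHT, census, weights
        )
        mapping = calibrate(shade, reference)
        yearly.append(mapping(shade))
    values = np.mean(yearly, axis=0)
    return LightField(np.arange(grid.n_cells), values, "cai")


def cai_for_trees(
    snapshot: CensusSnapshot,
    allometry: AllometryConfig,
    censuses: Sequence[CanopyCensus],
    grid: GridSpec,
    weights: ShadeWeights | None = None,
    reference: IrradianceReference | None = None,
    tree_ids: np.ndarray | None = None,
) -> LightField:
    """CAI at the crown top of each (alive) tree, averaged over years.

    The quantile mapping is calibrated on cell shades at 2 m (as for cells)
    and applied to each tree's shade at its allometric height.  A tree taller
    than all occupied layers has shade 0 and receives the mapping's maximum
    irradiance.
    """
    if not censuses:
        raise ValueError("need at least one canopy census")
    alive = snapshot.alive
    if tree_ids is not None:
        alive = alive[alive["tree_id"].isin(np.asarray(tree_ids, dtype=str))]
    pts = alive[["x", "y"]].to_numpy(dtype=float)
    heights = allometry.height(alive["dbh_mm"].to_numpy())
    centers = grid.cell_centers()
    yearly = []
    for census in censuses:
        cell_shade = shade_index(centers, CELL_REFERENCE_HEIGHT, census, weights)
        mapping = calibrate(cell_shade, reference)
        tree_shade = shade_index(pts, heights, census, weights)
        yearly.append(mapping(tree_shade))
    values = np.mean(yearly, axis=0)
    return LightField(alive["tree_id"].to_numpy(dtype=str), values, "cai")


# ---------------------------------------------------------------------------
# file I/O


def write_canopy_census(census: CanopyCensus, path: str | Path) -> None:
    """Delimited text: year, cell_x, cell_y, L1..L6 as 0/1 (one row per cell)."""
    ny, nx = census.shape
    centers = census.cell_centers()
    flat = census.occupancy.reshape(len(LAYERS), -1).T.astype(int)
    df = pd.DataFrame(
        {
            "year": census.year,
            "cell_x": centers[:, 0],
            "cell_y": centers[:, 1],
            **{f"L{i+1}": flat[:, i] for i in range(len(LAYERS))},
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_canopy_census(path: str | Path) -> CanopyCensus:
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["year", "cell_x", "cell_y"] + [f"L{i+1}" for i in range(len(LAYERS))]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    xs = np.sort(df["cell_x"].unique())
    ys = np.sort(df["cell_y"].unique())
    res = float(xs[1] - xs[0]) if len(xs) > 1 else float(ys[1] - ys[0])
    nx, ny = len(xs), len(ys)
    ix = np.searchsorted(xs, df["cell_x"].to_numpy())
    iy = np.searchsorted(ys, df["cell_y"].to_numpy())
    occ = np.zeros((len(LAYERS), ny, nx), dtype=bool)
    for li in range(len(LAYERS)):
        occ[li, iy, ix] = df[f"L{li+1}"].to_numpy() > 0
    return CanopyCensus(
        year=int(df["year"].iloc[0]),
        origin_x=float(xs[0] - res / 2),
        origin_y=float(ys[0] - res / 2),
        resolution=res,
        occupancy=occ,
    )
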