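"""Census domain types, file I/O, and deterministic data-preparation rules.

Tree census tables record, for every free-standing woody stem >= 10 mm dbh,
its position, species, and diameter at breast height (dbh, stored in mm
throughout the package).  From two consecutive censuses we derive the raw
material of the demographic models: per-cell recruit counts and per-tree
annualized diameter increments.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Columns of the on-disk census format, in order.
CENSUS_COLUMNS = [
    "tree_id",
    "species_id",
    "x",
    "y",
    "dbh_mm",
    "alive",
    "palm",
    "main_stem",
    "stem_issue",
]

#: Minimum dbh of a living stem (mm); also the presence threshold for recruits.
MIN_DBH_MM = 10.0


class CensusFormatError(ValueError):
    """Raised when a census file violates the documented format."""


@dataclass(frozen=True)
class TreeRecord:
    """A single stem in one census.

    ``main_stem`` marks the largest stem of a multi-stem tree; ``stem_issue``
    marks stems whose point of measurement moved or that broke and resprouted
    (such records are excluded from growth analysis).
    """

    tree_id: str
    species_id: str
    x: float
    y: float
    dbh_mm: float
    alive: bool = True
    palm: bool = False
    main_stem: bool = True
    stem_issue: bool = False


@dataclass
class CensusSnapshot:
    """All trees of one census, stored as a DataFrame with ``CENSUS_COLUMNS``."""

    census_year: int
    plot_width: float
    plot_height: float
    trees: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.trees
        missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
        if missing:
            raise CensusFormatError(f"snapshot missing columns: {missing}")
        df = df[CENSUS_COLUMNS].reset_index(drop=True)
        df["tree_id"] = df["tree_id"].astype(str)
        df["species_id"] = df["species_id"].astype(str)
        for col in ("x", "y", "dbh_mm"):
            df[col] = pd.to_numeric(df[col])
        for col in ("alive", "palm", "main_stem", "stem_issue"):
            df[col] = df[col].astype(bool)
        if df["tree_id"].duplicated().any():
            dup = df.loc[df["tree_id"].duplicated(), "tree_id"].iloc[0]
            raise CensusFormatError(f"duplicate tree_id {dup!r}")
        alive = df[df["alive"]]
        if len(alive):
            if (alive["dbh_mm"] <= 0).any():
                raise CensusFormatError("alive tree with non-positive dbh")
            oob = (
                (alive["x"] < 0)
                | (alive["x"] > self.plot_width)
                | (alive["y"] < 0)
                | (alive["y"] > self.plot_height)
            )
            if oob.any():
                bad = alive.loc[oob, "tree_id"].iloc[0]
                raise CensusFormatError(
                    f"tree {bad!r} outside plot bounds "
                    f"({self.plot_width} x {self.plot_height} m)"
                )
        self.trees = df

    @classmethod
    def from_records(
        cls,
        census_year: int,
        plot_width: float,
        plot_height: float,
        records: list[TreeRecord],
    ) -> "CensusSnapshot":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
        return cls(census_year, plot_width, plot_height, df)

    @property
    def alive(self) -> pd.DataFrame:
        return self.trees[self.trees["alive"]]

    def __len__(self) -> int:
        return len(self.trees)


@dataclass
class CensusInterval:
    """Two consecutive censuses of the same plot.

    ``interval_years`` defaults to the census-year difference for every tree;
    a per-tree override Series (indexed by tree_id) may be supplied when
    measurement dates differ between trees.
    """

    start: CensusSnapshot
    end: CensusSnapshot
    interval_years: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.end.census_year <= self.start.census_year:
            raise ValueError("end census must be later than start census")
        if (self.start.plot_width, self.start.plot_height) != (
            self.end.plot_width,
            self.end.plot_height,
        ):
            raise ValueError("snapshots have different plot geometry")
        if self.interval_years is not None and (self.interval_years <= 0).any():
            raise ValueError("interval length must be positive")

    def years_for(self, tree_ids: pd.Series) -> np.ndarray:
        default = float(self.end.census_year - self.start.census_year)
        if self.interval_years is None:
            return np.full(len(tree_ids), default)
        out = self.interval_years.reindex(tree_ids).to_numpy(dtype=float)
        out = np.where(np.isnan(out), default, out)
        return out


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid tiling the core region (plot minus a margin).

    Cells are half-open ``[x0, x0+cell)`` so each point falls in exactly one
    cell; cell ids are row-major from the core origin (x fastest).
    """

    cell_size: float
    margin: float
    origin_x: float
    origin_y: float
    core_width: float
    core_height: float

    @property
    def nx(self) -> int:
        return int(round(self.core_width / self.cell_size))

    @property
    def ny(self) -> int:
        return int(round(self.core_height / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell centers, row-major (x fastest)."""
        xs = self.origin_x + self.cell_size * (np.arange(self.nx) + 0.5)
        ys = self.origin_y + self.cell_size * (np.arange(self.ny) + 0.5)
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_id(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major cell index for each point; -1 for points outside the core."""
        ix = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        iy = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        out = np.where(inside, (iy * self.nx + ix), -1).astype(int)
        return out


def partition_core(
    plot_width: float,
    plot_height: float,
    margin: float = 30.0,
    cell_size: float = 5.0,
) -> GridSpec:
    """Grid the core region (the plot minus ``margin`` on each side).

    A 1000 x 500 m plot with a 30 m margin and 5 m cells yields the
    940 x 440 m core tiled by 188 x 88 = 16,544 cells.
    """
    core_w = plot_width - 2 * margin
    core_h = plot_height - 2 * margin
    if core_w <= 0 or core_h <= 0:
        raise ValueError("margin leaves no core region")
    for dim, name in ((core_w, "width"), (core_h, "height")):
        ratio = dim / cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"core {name} {dim} m is not divisible by cell size {cell_size} m"
            )
    return GridSpec(
        cell_size=cell_size,
        margin=margin,
        origin_x=margin,
        origin_y=margin,
        core_width=core_w,
        core_height=core_h,
    )


def apply_rounding(dbh_mm):
    """Round dbh down to the nearest 5 mm for stems below 55 mm.

    Emulates the historical field protocol in which small stems were only
    recorded to 5 mm precision in the first census of an interval.  Accepts
    scalars or arrays; dbh must be positive.
    """
    arr = np.asarray(dbh_mm, dtype=float)
    if (arr <= 0).any():
        raise ValueError("dbh must be positive")
    out = np.where(arr < 55.0, np.floor(arr / 5.0) * 5.0, arr)
    if np.isscalar(dbh_mm) or np.ndim(dbh_mm) == 0:
        return float(out)
    return out


def extract_recruits(interval: CensusInterval, grid: GridSpec) -> pd.DataFrame:
    """Count recruits per (core cell, species).

    A recruit is a tree absent (or dead, or below the 10 mm presence
    threshold) in the first census and alive with dbh >= 10 mm in the second.
    Trees in the margin are excluded.  Returns the dense table: one row per
    (cell_id, species_id) for every species with at least one recruit
    anywhere, including explicit zero counts, with cell center coordinates
    attached.
    """
    start, end = interval.start, interval.end
    present_start = set(
        start.trees.loc[
            start.trees["alive"] & (start.trees["dbh_mm"] >= MIN_DBH_MM), "tree_id"
        ]
    )
    cand = end.trees[end.trees["alive"] & (end.trees["dbh_mm"] >= MIN_DBH_MM)]
    recruits = cand[~cand["tree_id"].isin(present_start)].copy()
    recruits["cell_id"] = grid.cell_id(
        recruits["x"].to_numpy(), recruits["y"].to_numpy()
    )
    recruits = recruits[recruits["cell_id"] >= 0]

    species = sorted(recruits["species_id"].unique())
    counts = (
        recruits.groupby(["cell_id", "species_id"]).size().rename("count")
    )
    full_index = pd.MultiIndex.from_product(
        [np.arange(grid.n_cells), species], names=["cell_id", "species_id"]
    )
    table = counts.reindex(full_index, fill_value=0).reset_index()
    centers = grid.cell_centers()
    table["cell_x"] = centers[table["cell_id"].to_numpy(), 0]
    table["cell_y"] = centers[table["cell_id"].to_numpy(), 1]
    return table


def extract_growth_records(
    interval: CensusInterval, use_rounding: bool = False
) -> pd.DataFrame:
    """Annualized dbh increments for trees alive in both censuses.

    Palms and stems with measurement-position issues are excluded; only the
    main stem of multi-stem trees is kept.  With ``use_rounding`` both census
    dbh values below 55 mm are floored to 5 mm before differencing, matching
    intervals in which the first census recorded small stems at 5 mm
    precision.  Growth may be negative (measurement error).
    """
    start, end = interval.start, interval.end
    a = start.trees[
        start.trees["alive"]
        & ~start.trees["palm"]
        & start.trees["main_stem"]
        & ~start.trees["stem_issue"]
    ][["tree_id", "species_id", "x", "y", "dbh_mm"]]
    b = end.trees[
        end.trees["alive"] & ~end.trees["stem_issue"]
    ][["tree_id", "dbh_mm"]]
    merged = a.merge(b, on="tree_id", suffixes=("0", "1"))
    years = interval.years_for(merged["tree_id"])
    if (years <= 0).any():
        raise ValueError("interval length must be positive")
    d0 = merged["dbh_mm0"].to_numpy(dtype=float)
    d1 = merged["dbh_mm1"].to_numpy(dtype=float)
    if use_rounding:
        d0 = apply_rounding(d0)
        d1 = apply_rounding(d1)
    out = pd.DataFrame(
        {
            "tree_id": merged["tree_id"],
            "species_id": merged["species_id"],
            "x": merged["x"],
            "y": merged["y"],
            "dbh0": merged["dbh_mm0"].astype(float),
            "obs_growth": (d1 - d0) / years,
            "interval_years": years,
        }
    )
    return out.reset_index(drop=True)


def compute_abundance(snapshot: CensusSnapshot) -> pd.Series:
    """Number of living individuals per species over the whole plot."""
    alive = snapshot.alive
    return alive.groupby("species_id").size().rename("abundance")


# ---------------------------------------------------------------------------
# file I/O


def write_census(snapshot: CensusSnapshot, path: str | Path, sep: str = "\t") -> None:
    """Write a snapshot as delimited text with a metadata comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# census_year={snapshot.census_year} "
            f"plot_width={snapshot.plot_width} plot_height={snapshot.plot_height}\n"
        )
        df = snapshot.trees.copy()
        for col in ("alive", "palm", "main_stem", "stem_issue"):
            df[col] = df[col].astype(int)
        df.to_csv(fh, sep=sep, index=False)


def read_census(path: str | Path) -> CensusSnapshot:
    """Read a census file written by :func:`write_census`.

    The delimiter (comma or tab) is autodetected from the header line.
    Malformed rows are reported with their line number.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    meta = {"census_year": 0, "plot_width": np.inf, "plot_height": np.inf}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k in meta:
                        meta[k] = float(v)
            body_start = i + 1
        else:
            break
    body = "\n".join(lines[body_start:])
    header_line = lines[body_start] if body_start < len(lines) else ""
    sep = "\t" if "\t" in header_line else ","
    try:
        df = pd.read_csv(io.StringIO(body), sep=sep, dtype={"tree_id": str, "species_id": str})
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise CensusFormatError(f"{path}: cannot parse census body: {exc}") from exc
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise CensusFormatError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "dbh_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: one for the header line, one for 1-based numbering
            lineno = body_start + row + 2
            raise CensusFormatError(
                f"{path}: non-numeric {col}={df[col].iloc[row]!r} at line {lineno}"
            )
        df[col] = coerced
    return CensusSnapshot(
        census_year=int(meta["census_year"]),
        plot_width=float(meta["plot_width"]),
        plot_height=float(meta["plot_height"]),
        trees=df,
    )
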