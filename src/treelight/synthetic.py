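"""Synthetic forest stands with known demographic ground truth.

Generates census snapshots, canopy occupancy, and recruitment/growth
observations from the same hierarchical models the package fits, so every
downstream stage can be tested by parameter recovery without access to any
restricted census data.  The stand emulates a lowland tropical forest:
basal area ~32 m^2/ha, canopy height capped at 33 m, log-series species
abundances, and (optionally) Thomas-process clustering of conspecifics.
The stand structure beyond those targets (dbh distribution, crown model,
clustering scales) is a documented package choice, not taken from any
particular site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from treelight.allometry import AllometryConfig
from treelight.canopy import LAYERS, CanopyCensus
from treelight.census import CensusSnapshot, GridSpec
from treelight.growth import ErrorModel, GrowthHypers, predict_growth
from treelight.lightfield import LightField
from treelight.recruitment import RecruitHypers, predict_recruits

#: Lower truncation for sampled clumping parameters (numerical stability).
K_FLOOR = 0.05
K_CEIL = 100.0


@dataclass(frozen=True)
class StandConfig:
    """Targets and knobs of the synthetic stand.

    dbh values (mm) are drawn from a lognormal truncated at the 10 mm
    census threshold; trees are added until the basal area reaches the
    target (within 10%).  Species identities follow a log-series rank
    abundance; positions are uniform or Thomas-clustered.
    """

    plot_width: float = 300.0
    plot_height: float = 300.0
    basal_area: float = 32.0  # m^2 / ha
    canopy_height_cap: float = 33.0
    richness: int = 60
    log_series_p: float = 0.995
    dbh_log_mean: float = float(np.log(25.0))  # mm
    dbh_log_sd: float = 1.3
    dbh_max_mm: float = 2000.0
    clustered: bool = False
    parent_intensity: float = 5e-4  # Thomas parents per m^2 per species
    offspring_sd: float = 10.0  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.plot_width, self.plot_height, self.basal_area, self.richness) <= 0:
            raise ValueError("stand dimensions and targets must be positive")
        if not 0 < self.log_series_p < 1:
            raise ValueError("log-series shape must be in (0, 1)")


def _log_series_abundances(richness, p, n_trees, rng):
    """Relative abundances for `richness` species from a log-series sample."""
    raw = stats.logser.rvs(p, size=richness, random_state=rng).astype(float)
    return np.sort(raw)[::-1] / raw.sum()


def generate_stand(config: StandConfig = StandConfig()) -> CensusSnapshot:
    """Draw a census snapshot meeting the basal-area target within 10%."""
    rng = np.random.default_rng(config.seed)
    area_ha = config.plot_width * config.plot_height / 1e4
    target_m2 = config.basal_area * area_ha

    kept: list[float] = []
    total = 0.0
    chunk = 1024
    done = False
    for _attempt in range(10_000):
        draw = np.exp(
            config.dbh_log_mean + config.dbh_log_sd * rng.standard_normal(chunk)
        )
        draw = np.clip(draw, 10.0, config.dbh_max_mm)
        ba = np.pi * (draw / 2000.0) ** 2  # m^2 (dbh mm -> radius m)
        for d_i, ba_i in zip(draw, ba):
            if total + ba_i > 1.1 * target_m2:
                continue  # skip a tree that would overshoot the 10% band
            kept.append(d_i)
            total += ba_i
            if total >= target_m2:
                done = True
                break
        if done:
            break
    else:
        raise RuntimeError("basal-area target unattainable within attempts bound")
    dbh_mm = np.asarray(kept)
    n = dbh_mm.size

    weights = _log_series_abundances(config.richness, config.log_series_p, n, rng)
    species_idx = rng.choice(config.richness, size=n, p=weights)
    species_id = np.array([f"sp{i:03d}" for i in range(config.richness)])[species_idx]

    if config.clustered:
        x = np.empty(n)
        y = np.empty(n)
        for s in range(config.richness):
            mask = species_idx == s
            m = int(mask.sum())
            if m == 0:
                continue
            n_parents = max(
                1,
                rng.poisson(
                    config.parent_intensity * config.plot_width * config.plot_height
                ),
            )
            px = rng.uniform(0, config.plot_width, n_parents)
            py = rng.uniform(0, config.plot_height, n_parents)
            pick = rng.integers(0, n_parents, m)
            x[mask] = np.mod(px[pick] + config.offspring_sd * rng.standard_normal(m),
                             config.plot_width)
            y[mask] = np.mod(py[pick] + config.offspring_sd * rng.standard_normal(m),
                             config.plot_height)
    else:
        x = rng.uniform(0, config.plot_width, n)
        y = rng.uniform(0, config.plot_height, n)

    df = pd.DataFrame(
        {
            "tree_id": [f"t{i:06d}" for i in range(n)],
            "species_id": species_id,
            "x": x,
            "y": y,
            "dbh_mm": dbh_mm,
            "alive": True,
            "palm": False,
            "main_stem": True,
            "stem_issue": False,
        }
    )
    return CensusSnapshot(
        census_year=0,
        plot_width=config.plot_width,
        plot_height=config.plot_height,
        trees=df,
    )


def generate_canopy_census(
    snapshot: CensusSnapshot,
    allometry: AllometryConfig,
    year: int = 0,
    resolution: float = 5.0,
) -> CanopyCensus:
    """Rasterize tree crowns into six-layer occupancy grids.

    A layer cell is occupied iff some tree's crown disk (centered on the
    stem, radius from the crown model) overlaps the cell horizontally and
    the crown's vertical extent [top - depth, top] intersects the layer.
    """
    nx = int(np.ceil(snapshot.plot_width / resolution))
    ny = int(np.ceil(snapshot.plot_height / resolution))
    occ = np.zeros((len(LAYERS), ny, nx), dtype=bool)
    alive = snapshot.alive
    xs = alive["x"].to_numpy(float)
    ys = alive["y"].to_numpy(float)
    dbh = alive["dbh_mm"].to_numpy(float)
    radius = allometry.crown_radius(dbh)
    bottom, top = allometry.crown_extent(dbh)
    for xi, yi, r, lo, hi in zip(xs, ys, radius, bottom, top):
        layer_hit = [
            li for li, (l0, l1) in enumerate(LAYERS) if hi > l0 and lo < l1
        ]
        if not layer_hit:
            continue
        ix0 = max(int((xi - r) // resolution), 0)
        ix1 = min(int((xi + r) // resolution), nx - 1)
        iy0 = max(int((yi - r) // resolution), 0)
        iy1 = min(int((yi + r) // resolution), ny - 1)
        for iy in range(iy0, iy1 + 1):
            cy0, cy1 = iy * resolution, (iy + 1) * resolution
            dy = max(cy0 - yi, 0.0, yi - cy1)
            for ix in range(ix0, ix1 + 1):
                cx0, cx1 = ix * resolution, (ix + 1) * resolution
                dx = max(cx0 - xi, 0.0, xi - cx1)
                if dx * dx + dy * dy <= r * r:
                    for li in layer_hit:
                        occ[li, iy, ix] = True
    return CanopyCensus(
        year=year, origin_x=0.0, origin_y=0.0, resolution=resolution, occupancy=occ
    )


@dataclass
class TruthSet:
    """Ground-truth species parameters and the hypers they were drawn from."""

    recruit_params: pd.DataFrame | None  # a_r, b_r, k indexed by species_id
    growth_params: pd.DataFrame | None  # a_g, b_g, c, d indexed by species_id
    recruit_hypers: RecruitHypers | None
    growth_hypers: GrowthHypers | None
    seed: int = 0

    def write(self, path) -> None:
        frames = []
        if self.recruit_params is not None:
            frames.append(self.recruit_params)
        if self.growth_params is not None:
            frames.append(self.growth_params)
        pd.concat(frames, axis=1).to_csv(path, sep="\t")


def draw_species_params(
    abundance: pd.Series,
    recruit_hypers: RecruitHypers | None = RecruitHypers(),
    growth_hypers: GrowthHypers | None = GrowthHypers(),
    seed: int = 0,
) -> TruthSet:
    """Draw species-level true parameters from the community hyper-models.

    a_r, b_r (and a_g, b_g, c) are Normal around regressions on
    ln(abundance); k is Uniform(0, 100] truncated below at 0.05; d is
    lognormal with (delta_1, delta_2).
    """
    rng = np.random.default_rng(seed)
    la = np.log(abundance.to_numpy(dtype=float))
    idx = abundance.index
    recruit = None
    growth = None
    if recruit_hypers is not None:
        h = recruit_hypers
        recruit = pd.DataFrame(
            {
                "a_r": h.alpha_r1 + h.alpha_r2 * la
                + h.sigma_ra * rng.standard_normal(len(la)),
                "b_r": h.beta_r1 + h.beta_r2 * la
                + h.sigma_rb * rng.standard_normal(len(la)),
                "k": np.clip(rng.uniform(0.0, K_CEIL, len(la)), K_FLOOR, K_CEIL),
            },
            index=idx,
        )
    if growth_hypers is not None:
        g = growth_hypers
        growth = pd.DataFrame(
            {
                "a_g": g.alpha_g1 + g.alpha_g2 * la
                + g.sigma_ga * rng.standard_normal(len(la)),
                "b_g": g.beta_g1 + g.beta_g2 * la
                + g.sigma_gb * rng.standard_normal(len(la)),
                "c": g.gamma_1 + g.gamma_2 * la
                + g.sigma_g * rng.standard_normal(len(la)),
                "d": np.exp(g.delta_1 + g.delta_2 * rng.standard_normal(len(la))),
            },
            index=idx,
        )
    return TruthSet(
        recruit_params=recruit,
        growth_params=growth,
        recruit_hypers=recruit_hypers,
        growth_hypers=growth_hypers,
        seed=seed,
    )


def simulate_light_field(
    ids: np.ndarray | None = None,
    mode: str = "latent_lognormal",
    log_mean: float = float(np.log(0.02)),
    log_sd: float = 1.0,
    seed: int = 0,
    snapshot: CensusSnapshot | None = None,
    allometry: AllometryConfig | None = None,
    grid: GridSpec | None = None,
    canopy_censuses: list[CanopyCensus] | None = None,
) -> LightField:
    """Cell light values on the canopy-index scale, in (0, 1].

    ``latent_lognormal`` draws independent values whose logs are
    Normal(log_mean, log_sd), clipped at full irradiance — light unrelated
    to the stand, for likelihood-level tests.  ``from_canopy`` rasterizes
    the stand's crowns into canopy occupancy and computes the canopy index
    at cell centers, so light reflects the actual neighborhood structure.
    """
    if mode == "latent_lognormal":
        if ids is None:
            raise ValueError("latent_lognormal mode needs focal ids")
        rng = np.random.default_rng(seed)
        logs = log_mean + log_sd * rng.standard_normal(len(np.asarray(ids)))
        return LightField(ids, np.exp(np.minimum(logs, 0.0)), "cai")
    if mode == "from_canopy":
        from treelight.canopy import cai_for_cells

        if snapshot is None or allometry is None or grid is None:
            raise ValueError("from_canopy mode needs snapshot, allometry, grid")
        censuses = canopy_censuses or [generate_canopy_census(snapshot, allometry)]
        return cai_for_cells(censuses, grid)
    raise ValueError(f"unknown light-field mode {mode!r}")


def recruitment_scenario(
    n_species: int = 60, n_cells: int = 2000, seed: int = 0
) -> dict:
    """Canonical recruitment simulation for recovery studies.

    Species abundances are log-uniform between 20 and 30,000 individuals
    (the span of a diverse tropical plot); ground-truth parameters come from
    the default community hypers; cell light is latent lognormal.  Returns
    abundance, truth, light, and the dense recruit table.
    """
    rng = np.random.default_rng(seed)
    abun = np.sort(
        np.exp(rng.uniform(np.log(20), np.log(30_000), n_species))
    ).astype(int)[::-1]
    abundance = pd.Series(
        np.maximum(abun, 20), index=[f"sp{i:03d}" for i in range(n_species)]
    )
    truth = draw_species_params(abundance, growth_hypers=None, seed=seed + 1)
    light = simulate_light_field(np.arange(n_cells), seed=seed + 2)
    table = simulate_recruit_counts(truth, light, seed=seed + 3)
    return {"abundance": abundance, "truth": truth, "light": light, "table": table}


def growth_scenario(
    n_species: int = 40, n_trees: int = 5000, seed: int = 0
) -> dict:
    """Canonical growth simulation: trees assigned to species proportionally
    to abundance, initial dbh lognormal around 25 mm, 5-year interval,
    default measurement-error model, per-tree light latent lognormal with
    median 5% of full irradiance (trees sit higher in the canopy than the
    2 m cell reference)."""
    rng = np.random.default_rng(seed)
    abun = np.sort(
        np.exp(rng.uniform(np.log(30), np.log(30_000), n_species))
    ).astype(int)[::-1]
    abundance = pd.Series(
        np.maximum(abun, 30), index=[f"sp{i:03d}" for i in range(n_species)]
    )
    truth = draw_species_params(abundance, recruit_hypers=None, seed=seed + 1)
    species = rng.choice(
        abundance.index.to_numpy(), size=n_trees, p=abundance / abundance.sum()
    )
    dbh0 = np.clip(np.exp(np.log(25.0) + rng.standard_normal(n_trees)), 10, 800)
    ids = np.array([f"t{i:05d}" for i in range(n_trees)])
    light = simulate_light_field(ids, log_mean=float(np.log(0.05)), seed=seed + 2)
    records = simulate_growth_observations(
        truth, light, dbh0, species, 5.0, seed=seed + 3
    )
    return {
        "abundance": abundance,
        "truth": truth,
        "light": light,
        "records": records,
    }


def simulate_recruit_counts(
    truth: TruthSet, light: LightField, seed: int = 0
) -> pd.DataFrame:
    """Negative-binomial recruit counts per (cell, species) from true params.

    The predictor is the centered log light value of each cell; returns the
    dense recruit table (cell_id, species_id, count).
    """
    if truth.recruit_params is None:
        raise ValueError("truth set has no recruitment parameters")
    rng = np.random.default_rng(seed)
    log_light = np.log(light.values) if light.kind == "cai" else light.values
    x = log_light - log_light.mean()
    rows = []
    for sp, p in truth.recruit_params.iterrows():
        mu = predict_recruits(p["a_r"], p["b_r"], x)
        prob = p["k"] / (p["k"] + mu)
        counts = rng.negative_binomial(p["k"], prob)
        rows.append(
            pd.DataFrame({"cell_id": light.ids, "species_id": sp, "count": counts})
        )
    return pd.concat(rows, ignore_index=True)


def simulate_growth_observations(
    truth: TruthSet,
    light: LightField,
    dbh0_mm: np.ndarray,
    species_id: np.ndarray,
    interval_years: float | np.ndarray = 5.0,
    error: ErrorModel = ErrorModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Observed annual growth: lognormal process error around the predicted
    growth plus the two-component measurement-error mixture.

    ``light`` provides per-tree values aligned with ``dbh0_mm`` and
    ``species_id``.  Returns growth records with the latent true growth in
    a ``true_growth`` column for recovery tests.
    """
    if truth.growth_params is None:
        raise ValueError("truth set has no growth parameters")
    rng = np.random.default_rng(seed)
    dbh0 = np.asarray(dbh0_mm, dtype=float)
    n = dbh0.size
    years = np.broadcast_to(np.asarray(interval_years, dtype=float), (n,))
    log_light = np.log(light.values) if light.kind == "cai" else light.values
    x = log_light - log_light.mean()
    p = truth.growth_params.reindex(species_id)
    pred = predict_growth(
        p["a_g"].to_numpy(), p["b_g"].to_numpy(), p["c"].to_numpy(), x, dbh0
    )
    true = pred * np.exp(p["d"].to_numpy() * rng.standard_normal(n))
    large = rng.uniform(size=n) < error.f
    sd = np.where(large, error.sd2, error.sd1(dbh0)) / years
    obs = true + sd * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "tree_id": light.ids,
            "species_id": species_id,
            "dbh0": dbh0,
            "obs_growth": obs,
            "interval_years": years,
            "log_light": log_light,
            "true_growth": true,
        }
    )
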