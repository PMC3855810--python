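"""Light-response classification and between-model comparison.

Species are grouped by their light-response exponent b: negative (b < 0),
decelerating (0 < b < 1), or accelerating (b > 1) — either from the
posterior mean or, more stringently, requiring the whole 95% credible
interval inside one region (otherwise "unclassified").  The interpretation
of b as a light-response exponent holds only on the log canopy-index scale,
so classification of fits that used the raw untransformed NCI as predictor
is refused.  The module also measures agreement of light-response estimates
between two fits (Pearson r, mean signed deviation from the 1:1 line,
major-axis slope) and orchestrates the full synthetic pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLASSES = ("negative", "decelerating", "accelerating")
#: Light-estimate kinds whose b parameter is interpretable as a response exponent.
CLASSIFIABLE_KINDS = ("log_cai", "cai", "nci_ts", "nci_tg")


@dataclass(frozen=True)
class Classification:
    species_id: str
    by_mean: str
    by_ci: str  # one of CLASSES or "unclassified"


def _region(v: float) -> str:
    if v < 0:
        return "negative"
    if v > 1:
        return "accelerating"
    return "decelerating"


def classify(mean: float, ci_low: float, ci_high: float, species_id: str = "",
             light_kind: str = "log_cai") -> Classification:
    """Classify one species' light response by posterior mean and by 95% CI.

    Boundary values 0 and 1 of the mean are assigned to "decelerating" (a
    measure-zero convention).  The CI-based class requires the entire
    interval strictly inside one open region.
    """
    if light_kind not in CLASSIFIABLE_KINDS:
        raise ValueError(
            "light-response classification is only valid on the log(canopy "
            f"index) scale, not for light estimate {light_kind!r}"
        )
    if ci_low > ci_high or not (ci_low <= mean <= ci_high):
        raise ValueError("need ci_low <= mean <= ci_high")
    by_mean = _region(mean)
    if ci_high < 0:
        by_ci = "negative"
    elif ci_low > 1:
        by_ci = "accelerating"
    elif ci_low > 0 and ci_high < 1:
        by_ci = "decelerating"
    else:
        by_ci = "unclassified"
    return Classification(species_id, by_mean, by_ci)


def classify_fit(summary: pd.DataFrame, param: str = "b_r",
                 light_kind: str = "log_cai") -> pd.DataFrame:
    """Classify every species of a fit from its wide species summary."""
    rows = []
    for sp, r in summary.iterrows():
        c = classify(
            r[f"{param}_mean"], r[f"{param}_lo"], r[f"{param}_hi"],
            species_id=str(sp), light_kind=light_kind,
        )
        rows.append({"species_id": c.species_id, "by_mean": c.by_mean, "by_ci": c.by_ci})
    return pd.DataFrame(rows).set_index("species_id")


def consistency_table(runs: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Count species classified identically across all runs.

    ``runs`` maps run ids to classification frames (columns by_mean, by_ci).
    A species counts toward a class iff every run assigns it that class;
    otherwise it is "inconsistent".  For the CI criterion, species
    unclassified in every run are reported separately as "unclassified".
    """
    frames = list(runs.values())
    if not frames:
        raise ValueError("no runs to compare")
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no overlapping species between runs")
    out = {}
    for crit in ("by_mean", "by_ci"):
        cols = pd.concat([f.loc[common, crit] for f in frames], axis=1)
        same = cols.nunique(axis=1) == 1
        first = cols.iloc[:, 0]
        counts = {c: int(((first == c) & same).sum()) for c in CLASSES}
        counts["unclassified"] = int(((first == "unclassified") & same).sum())
        counts["inconsistent"] = int((~same).sum())
        out[crit] = counts
    return pd.DataFrame(out).T[list(CLASSES) + ["unclassified", "inconsistent"]]


@dataclass(frozen=True)
class Agreement:
    pearson_r: float
    mean_deviation: float  # mean(model2 - model1)
    major_axis_slope: float
    n_species: int


def cross_model_agreement(b1: pd.Series, b2: pd.Series) -> Agreement:
    """Agreement of light-response estimates between two fits.

    Computed on the species shared by both fits: Pearson r, the mean signed
    deviation of model 2 from model 1, and the major-axis (first principal
    component) slope of model 2 on model 1.
    """
    shared = b1.index.intersection(b2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared species")
    u = b1.loc[shared].to_numpy(float)
    v = b2.loc[shared].to_numpy(float)
    if np.std(u) == 0 and np.std(v) == 0:
        r = 1.0
        slope = 1.0
    else:
        r = float(np.corrcoef(u, v)[0, 1])
        cu, cv = u - u.mean(), v - v.mean()
        suu, svv, suv = np.sum(cu * cu), np.sum(cv * cv), np.sum(cu * cv)
        # major axis: slope of the leading eigenvector of the 2x2 covariance
        if suv == 0:
            slope = np.inf if svv > suu else 0.0
        else:
            slope = float(
                (svv - suu + np.sqrt((svv - suu) ** 2 + 4 * suv**2)) / (2 * suv)
            )
    return Agreement(
        pearson_r=r,
        mean_deviation=float(np.mean(v - u)),
        major_axis_slope=slope,
        n_species=int(len(shared)),
    )


# ---------------------------------------------------------------------------
# pipeline orchestration


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stand": {"plot_width": 200.0, "plot_height": 200.0, "richness": 30},
    "grid": {"margin": 30.0, "cell_size": 5.0},
    "light": {"mode": "from_canopy", "log_mean": float(np.log(0.02)), "log_sd": 1.0},
    "recruitment": {"enabled": True, "burn_in": 200, "samples": 600, "n_chains": 2},
    "growth": {"enabled": False, "burn_cycles": 200, "sample_cycles": 300},
    "nci": {"enabled": True, "fit_with_converted": True},
}


def _merge_config(config: Mapping | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if config:
        for k, v in config.items():
            if k not in merged:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, Mapping):
                for kk, vv in v.items():
                    if kk not in merged[k] and not (
                        k == "stand" or k == "light"
                    ):
                        raise ValueError(f"unknown config key {k}.{kk}")
                    merged[k][kk] = vv
            else:
                merged[k] = v
    return merged


def run_pipeline(config: Mapping | None = None, outdir: str | Path = "out") -> dict:
    """Synthetic end-to-end run: stand -> light -> NCI search -> conversion
    -> hierarchical fits -> classification and agreement tables.

    Returns a dict of result objects and writes delimited tables plus the
    resolved config to ``outdir``.  Fully reproducible under the seed.
    """
    from treelight import census, nci as nci_mod, recruitment, synthetic
    from treelight.allometry import AllometryConfig
    from treelight.lightfield import LightField

    cfg = _merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict = {"config": cfg}

    stand_cfg = synthetic.StandConfig(seed=seed, **cfg["stand"])
    snapshot = synthetic.generate_stand(stand_cfg)
    grid = census.partition_core(
        stand_cfg.plot_width, stand_cfg.plot_height,
        cfg["grid"]["margin"], cfg["grid"]["cell_size"],
    )
    abundance = census.compute_abundance(snapshot)
    allometry = AllometryConfig(canopy_height_cap=stand_cfg.canopy_height_cap)

    cell_light = synthetic.simulate_light_field(
        np.arange(grid.n_cells), mode=cfg["light"]["mode"],
        log_mean=cfg["light"]["log_mean"], log_sd=cfg["light"]["log_sd"],
        seed=seed + 1, snapshot=snapshot, allometry=allometry, grid=grid,
    )
    truth = synthetic.draw_species_params(abundance, seed=seed + 2)
    table = synthetic.simulate_recruit_counts(truth, cell_light, seed=seed + 3)
    results["truth"] = truth

    classifications: dict[str, pd.DataFrame] = {}
    if cfg["recruitment"]["enabled"]:
        rcfg = recruitment.MCMCConfig(
            n_chains=int(cfg["recruitment"]["n_chains"]),
            burn_in=int(cfg["recruitment"]["burn_in"]),
            samples=int(cfg["recruitment"]["samples"]),
            seed=seed + 4,
        )
        fit_cai = recruitment.fit_recruitment(table, cell_light, abundance, rcfg)
        results["recruitment_cai"] = fit_cai
        sp_sum = fit_cai.species_summary()
        sp_sum.to_csv(outdir / "recruitment_cai_species.tsv", sep="\t")
        fit_cai.hyper_summary().to_csv(outdir / "recruitment_cai_hypers.tsv", sep="\t")
        classifications["log_cai"] = classify_fit(sp_sum, "b_r", "log_cai")

    if cfg["nci"]["enabled"]:
        pairs = nci_mod.neighbor_pairs(
            grid.cell_centers(), 2.0, snapshot, allometry, nci_mod.NCIConfig()
        )
        gs = nci_mod.grid_search([pairs], [np.log(cell_light.values)])
        results["grid_search"] = gs
        gs.surface_frame().to_csv(outdir / "nci_grid_search.tsv", sep="\t")
        best_nci = pairs.nci(gs.alpha_star, gs.beta_star)
        coeffs = nci_mod.fit_conversion(best_nci, np.log(cell_light.values), degree=1)
        results["conversion"] = coeffs
        nci_ts = LightField(cell_light.ids, nci_mod.apply_conversion(best_nci, coeffs),
                            "log_cai")
        if cfg["nci"]["fit_with_converted"] and cfg["recruitment"]["enabled"]:
            fit_nci = recruitment.fit_recruitment(table, nci_ts, abundance, rcfg)
            results["recruitment_nci_ts"] = fit_nci
            sp2 = fit_nci.species_summary()
            sp2.to_csv(outdir / "recruitment_nci_ts_species.tsv", sep="\t")
            classifications["nci_ts"] = classify_fit(sp2, "b_r", "nci_ts")
            agree = cross_model_agreement(
                results["recruitment_cai"].species_summary()["b_r_mean"],
                sp2["b_r_mean"],
            )
            results["agreement"] = agree

    if cfg["growth"]["enabled"]:
        from treelight import growth as growth_mod

        core = snapshot.alive[
            grid.cell_id(snapshot.alive["x"].to_numpy(), snapshot.alive["y"].to_numpy())
            >= 0
        ]
        tree_light = synthetic.simulate_light_field(
            core["tree_id"].to_numpy(dtype=str),
            log_mean=cfg["light"]["log_mean"] + 1.0,
            log_sd=cfg["light"]["log_sd"], seed=seed + 5,
        )
        records = synthetic.simulate_growth_observations(
            truth, tree_light, core["dbh_mm"].to_numpy(),
            core["species_id"].to_numpy(), seed=seed + 6,
        )
        gcfg = growth_mod.GrowthMCMCConfig(
            burn_cycles=int(cfg["growth"]["burn_cycles"]),
            sample_cycles=int(cfg["growth"]["sample_cycles"]),
            seed=seed + 7,
        )
        fit_g = growth_mod.fit_growth(records, tree_light, abundance, config=gcfg)
        results["growth_cai"] = fit_g
        fit_g.species_summary().to_csv(outdir / "growth_cai_species.tsv", sep="\t")
        fit_g.hyper_summary().to_csv(outdir / "growth_cai_hypers.tsv", sep="\t")

    if len(classifications) >= 2:
        consistency = consistency_table(classifications)
        consistency.to_csv(outdir / "classification_consistency.tsv", sep="\t")
        results["consistency"] = consistency

    resolved = json.dumps(cfg, indent=2, default=float)
    (outdir / "config_resolved.json").write_text(resolved)
    if "agreement" in results:
        a = results["agreement"]
        (outdir / "agreement.json").write_text(json.dumps(a.__dict__, indent=2))
    return results
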