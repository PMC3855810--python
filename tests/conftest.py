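import numpy as np
import pandas as pd
import pytest

from treelight import census, synthetic
from treelight.allometry import AllometryConfig
from treelight.census import CensusSnapshot, TreeRecord


@pytest.fixture(scope="session")
def small_stand() -> CensusSnapshot:
    """A ~0.8 ha synthetic stand reused by geometry-level tests."""
    cfg = synthetic.StandConfig(
        plot_width=90.0, plot_height=90.0, richness=15, seed=11
    )
    return synthetic.generate_stand(cfg)


@pytest.fixture(scope="session")
def allometry() -> AllometryConfig:
    return AllometryConfig()


@pytest.fixture()
def three_tree_snapshot() -> CensusSnapshot:
    records = [
        TreeRecord("t1", "spA", 10.0, 10.0, 120.0),
        TreeRecord("t2", "spA", 30.0, 40.0, 55.0, palm=True),
        TreeRecord("t3", "spB", 70.0, 20.0, 10.0, alive=False),
    ]
    return CensusSnapshot.from_records(1985, 100.0, 100.0, records)


def make_snapshot(rows, year=1990, width=100.0, height=100.0):
    """Build a snapshot from (tree_id, species, x, y, dbh, **flags) tuples."""
    records = []
    for row in rows:
        tid, sp, x, y, dbh, *rest = row
        flags = rest[0] if rest else {}
        records.append(TreeRecord(tid, sp, x, y, dbh, **flags))
    return CensusSnapshot.from_records(year, width, height, records)


@pytest.fixture(scope="session")
def recruit_scenario():
    """Simulated recruitment data with known truth: 20 species, 600 cells."""
    rng = np.random.default_rng(7)
    n_sp, n_cells = 20, 600
    abun = pd.Series(
        np.sort(rng.integers(20, 8000, n_sp))[::-1],
        index=[f"sp{i:03d}" for i in range(n_sp)],
    )
    truth = synthetic.draw_species_params(abun, growth_hypers=None, seed=8)
    light = synthetic.simulate_light_field(np.arange(n_cells), seed=9)
    table = synthetic.simulate_recruit_counts(truth, light, seed=10)
    return {"abundance": abun, "truth": truth, "light": light, "table": table}


@pytest.fixture(scope="session")
def growth_scenario():
    """Simulated growth data with known truth: 25 species, 1500 trees."""
    rng = np.random.default_rng(21)
    n_sp, n_trees = 25, 1500
    abun = pd.Series(
        np.sort(rng.integers(30, 20000, n_sp))[::-1],
        index=[f"sp{i:03d}" for i in range(n_sp)],
    )
    truth = synthetic.draw_species_params(abun, recruit_hypers=None, seed=22)
    sp = rng.choice(abun.index.to_numpy(), size=n_trees, p=abun / abun.sum())
    dbh0 = np.clip(np.exp(np.log(25) + rng.standard_normal(n_trees)), 10, 800)
    ids = np.array([f"t{i:05d}" for i in range(n_trees)])
    light = synthetic.simulate_light_field(
        ids, log_mean=float(np.log(0.05)), seed=23
    )
    records = synthetic.simulate_growth_observations(
        truth, light, dbh0, sp, 5.0, seed=24
    )
    return {"abundance": abun, "truth": truth, "light": light, "records": records}
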