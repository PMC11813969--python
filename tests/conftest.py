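import numpy as np
import pandas as pd
import pytest

from vesselkit import synthetic, traits


def make_ring(areas, groups=None, aoi=1.0, tree="t1", site="park", core="A", year=2018):
    """Build a RingAnatomy from raw areas (each vessel solitary by default)."""
    if groups is None:
        groups = [f"g{i}" for i in range(len(areas))]
    vessels = [
        traits.VesselRecord(tree, site, core, year, float(a), str(g))
        for a, g in zip(areas, groups)
    ]
    return traits.RingAnatomy(tree, site, core, year, aoi, vessels)


def vessels_frame(rows):
    """Vessel table from (tree, site, core, year, aoi, area, group) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "tree_id", "site_type", "core_id", "ring_year",
            "aoi_mm2", "lumen_area_um2", "group_id",
        ],
    ).assign(vessel_id=lambda d: np.arange(1, len(d) + 1))


def simulate_lme_data(
    seed,
    offsets=(0.0, 0.0, 0.0),
    sd_tree=0.4,
    sd_core=0.2,
    sd_resid=0.4,
    n_trees=15,
    n_years=10,
):
    """Hierarchical site/tree/core/year observations for mixed-model checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for si, site in enumerate(("park", "residential", "central")):
        for t in range(n_trees):
            b_tree = rng.normal(0.0, sd_tree)
            for core in "AB":
                b_core = rng.normal(0.0, sd_core)
                for y in range(n_years):
                    rows.append(
                        (
                            f"{site}{t:02d}", site, core, 2009 + y,
                            offsets[si] + b_tree + b_core + rng.normal(0.0, sd_resid),
                        )
                    )
    return pd.DataFrame(
        rows, columns=["tree_id", "site_type", "core_id", "ring_year", "X"]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default 45-tree synthetic cohort (seed 0)."""
    return synthetic.simulate_cohort(synthetic.default_config(seed=0))


@pytest.fixture(scope="session")
def default_trait_table(default_cohort):
    return traits.compute_trait_table(default_cohort.vessels)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast single-site cohort for structural tests."""
    cfg = synthetic.SimulationConfig(
        sites={"park": synthetic.default_config().sites["park"]},
        n_trees=5,
        aoi_mm2=4.0,
        seed=11,
    )
    return synthetic.simulate_cohort(cfg)
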