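import numpy as np
import pandas as pd
import pytest

from zlink import simulate as sim
from zlink import tables


@pytest.fixture(scope="session")
def default_sim():
    """One mid-size simulated genome shared across read-only tests:
    W present, neo-Z on chr18, realistic noise."""
    cfg = sim.SimConfig(rng_seed=11, n_scaffolds=3000, neo_z_chrom_id="chr18")
    scaffolds, truth = sim.simulate_assembly(cfg)
    coverage = sim.simulate_coverage(scaffolds, truth, cfg)
    hits, gene_map = sim.simulate_ortholog_hits(scaffolds, truth, cfg)
    return {
        "config": cfg,
        "scaffolds": scaffolds,
        "truth": truth,
        "coverage": coverage,
        "hits": hits,
        "gene_map": gene_map,
    }


@pytest.fixture(scope="session")
def noisefree_sim():
    """Noise-free genome: exact dosage, no outliers."""
    cfg = sim.SimConfig(
        rng_seed=5, n_scaffolds=1500, depth_dispersion=0.0,
        noise_outlier_fraction=0.0,
    )
    scaffolds, truth = sim.simulate_assembly(cfg)
    coverage = sim.simulate_coverage(scaffolds, truth, cfg)
    return {"config": cfg, "scaffolds": scaffolds, "truth": truth,
            "coverage": coverage}


@pytest.fixture()
def toy_coverage():
    """Five scaffolds, one male and one female library, hand-set depths."""
    frame = pd.DataFrame(
        {
            "length": [2000, 1200, 3000, 5000, 1800],
            "m1": [60.0, 60.0, 4.0, 60.0, 30.0],
            "f1": [60.0, 60.0, 4.0, 30.0, 0.0],
        },
        index=pd.Index([f"s{i}" for i in range(1, 6)], name="scaffold"),
    )
    return tables.CoverageTable(frame, {"m1": "male", "f1": "female"})
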