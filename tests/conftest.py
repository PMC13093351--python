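import numpy as np
import pandas as pd
import pytest

from genoffset import gea, synthetic as syn
from genoffset.climate_io import fit_scaler
from genoffset.synthetic import CLIMATE_VARS

#: canonical example seeds used throughout the docs and tests
DESIGN_SEED, CLIMATE_SEED, GENO_SEED, FOREST_SEED = 42, 1, 2, 3


@pytest.fixture(scope="session")
def default_design():
    return syn.generate_design(seed=DESIGN_SEED)


@pytest.fixture(scope="session")
def climate_cfg():
    return syn.default_climate_config()


@pytest.fixture(scope="session")
def default_climate(default_design, climate_cfg):
    """(trees, raster_set, dem) at full defaults: 20 sites × 25 trees."""
    return syn.generate_climate(default_design, climate_cfg, seed=CLIMATE_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_design, default_climate):
    """Full-default synthetic dataset: genotypes + truth + scaled climate."""
    trees, rs, dem = default_climate
    G, truth = syn.generate_genotypes(default_design, trees, seed=GENO_SEED)
    scaler = fit_scaler(trees, variables=list(CLIMATE_VARS))
    E = scaler.transform_table(trees)[list(CLIMATE_VARS)]
    return {"design": default_design, "trees": trees, "rasters": rs,
            "dem": dem, "G": G, "truth": truth, "scaler": scaler, "E": E}


@pytest.fixture(scope="session")
def fitted_gea(default_dataset):
    """Latent model + calibrated associations + FDR candidate set."""
    ds = default_dataset
    model = gea.fit_latent_model(ds["G"], ds["E"], K=3)
    assoc = gea.association_test(ds["G"], ds["E"], model.U)
    hits = set()
    for v in CLIMATE_VARS:
        pv = assoc.p_calibrated[v]
        hits |= set(np.asarray(pv.index)[gea.bh_fdr(pv.to_numpy(), 0.01)])
    return {"model": model, "assoc": assoc, "candidates": sorted(hits)}


@pytest.fixture
def small_genotypes():
    """Tiny hand-checkable genotype matrix over 3 areas."""
    from genoffset.genotypes import GenotypeMatrix

    dosages = np.array([
        # loci:  l1 l2 l3 l4 l5
        [0, 1, 2, 0, 0],   # area 1
        [0, 1, 2, 0, 0],
        [1, 0, 2, 0, 0],   # area 2
        [0, 0, 2, 0, 0],
        [0, 0, 1, 2, 0],   # area 3
        [0, 0, 2, 2, 0],
    ], dtype=float)
    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=[f"i{k}" for k in range(6)],
        locus_ids=["l1", "l2", "l3", "l4", "l5"],
        site_ids=np.array([1, 1, 2, 2, 3, 3]),
        area_ids=np.array([1, 1, 2, 2, 3, 3]),
    )
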