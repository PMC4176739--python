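import numpy as np
import pytest

import origingwas as og
from origingwas.experiments import true_origin_matrix


@pytest.fixture(scope="session")
def small_sim():
    """Small QTL-free dataset shared by ancestry/io tests."""
    cfg = og.SimulationConfig(
        n_chromosomes=2,
        snps_per_chromosome=300,
        n_taurus=60,
        n_indicus=60,
        n_composite=80,
        heritability_polygenic=0.0,
        seed=11,
    )
    return og.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def qtl_sim():
    """Dataset with one QTL of every segregation mode, true-origin design."""
    qtl = (
        og.QTLSpec(1, 100, "taurus_only", 0.5, 0.5, "B"),
        og.QTLSpec(1, 400, "indicus_only", 0.5, 0.5, "B"),
        og.QTLSpec(2, 100, "shared_same_phase", 0.5, 0.5, "B"),
        og.QTLSpec(2, 400, "shared_reversed_phase", 0.5, 0.5, "B"),
        og.QTLSpec(2, 700, "fixed_difference", 0.4),
    )
    cfg = og.SimulationConfig(
        n_chromosomes=2,
        snps_per_chromosome=900,
        n_taurus=500,
        n_indicus=500,
        n_composite=1000,
        qtl_specs=qtl,
        heritability_polygenic=0.0,
        # seed chosen so every tag SNP segregates in both pools (the
        # situation the subset/contrast assertions are about)
        seed=25,
    )
    return og.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def qtl_dataset(qtl_sim):
    return og.GwasDataset(
        aom=true_origin_matrix(qtl_sim),
        phenotypes=qtl_sim.phenotypes,
        groups=qtl_sim.groups,
        grm=None,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
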