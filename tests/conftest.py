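"""Shared fixtures: tiny handcrafted references and a small simulated run."""

import numpy as np
import pytest

from mitoribo.reference import GeneticCode, GenomeReference, OrfAnnotation
from mitoribo.simulate import SimulationConfig, simulate_footprints, simulate_genome


@pytest.fixture(scope="session")
def code():
    return GeneticCode.vertebrate_mitochondrial()


@pytest.fixture()
def tiny_genome():
    """90-nt genome with one 30-nt '+' ORF at [10, 40): ATG + 8 sense + TAA."""
    rng = np.random.default_rng(42)
    bases = list(rng.choice(list("ACGT"), size=90))
    cds = "ATG" + "GCTAAAGAACATCCTGTTTGGTCA" + "TAA"
    assert len(cds) == 30
    bases[10:40] = list(cds)
    genome = GenomeReference(id="chrM_tiny", sequence="".join(bases), circular=True)
    orf = OrfAnnotation(
        gene_id="g1", transcript_id="t1", strand="+", cds_start=10, cds_end=40
    )
    return genome, orf


@pytest.fixture(scope="session")
def small_sim():
    """Default small simulation: bicistronic genome, 3 control replicates."""
    config = SimulationConfig(seed=11, reads_per_replicate=5000)
    ref, orfs = simulate_genome(config)
    libs, truth = simulate_footprints(config, ref, orfs)
    return config, ref, orfs, libs, truth
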