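"""Shared fixtures: the expensive 100 kb diploid pipeline run is computed
once per session and reused by the synth round-trip and acceptance tests."""

from __future__ import annotations

import pytest

from ssrmine import (
    SimConfig,
    plant_ssrs,
    prescreen_polymorphic_loci,
    simulate_genome,
    simulate_reads,
)
from ssrmine.primers import PrimerConstraints
from ssrmine.synth import default_het_hom_specs

PIPELINE_SEED = 1
N_HET = 10
N_HOM = 10

# merged super-reads are ~170 nt, so in-silico products must fit below that
READ_SCALE_CONSTRAINTS = PrimerConstraints(product_size_range=(60, 160))


@pytest.fixture(scope="session")
def diploid_simulation():
    """100 kb diploid, 10 het + 10 hom planted loci, 30x error-free reads."""
    config = SimConfig(
        genome_length=100_000,
        coverage=30,
        seed=PIPELINE_SEED,
        fragment_mean=170,
        fragment_sd=8,
    )
    backbone = simulate_genome(config)
    specs = default_het_hom_specs(n_het=N_HET, n_hom=N_HOM)
    hap1, hap2, truth = plant_ssrs(backbone, specs, seed=PIPELINE_SEED)
    pairs, provenance = simulate_reads((hap1, hap2), config)
    return {
        "config": config,
        "specs": specs,
        "hap1": hap1,
        "hap2": hap2,
        "truth": truth,
        "pairs": pairs,
        "provenance": provenance,
    }


@pytest.fixture(scope="session")
def pipeline_result(diploid_simulation):
    """Full pre-screen (qc -> scan -> design -> single-copy -> e-PCR)."""
    return prescreen_polymorphic_loci(
        diploid_simulation["pairs"], constraints=READ_SCALE_CONSTRAINTS
    )


def map_pal_to_planted_locus(pal, hap1, truth):
    """Planted locus id whose tract lies inside the PAL's product span."""
    pos = hap1.find(pal.pair.forward)
    if pos < 0:
        return None
    t1 = truth[truth.haplotype == 0]
    for _, row in t1.iterrows():
        if pos < row.end and pos + pal.pair.product_size > row.start:
            return int(row.locus_id)
    return None
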