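"""Synthetic genomes, SSR planting with exact truth, read simulation."""

import numpy as np
import pytest

from ssrmine.motif import reverse_complement
from ssrmine.scan import classify_read, scan_read
from ssrmine.synth import (
    GenomeCapacityError,
    PlantSpec,
    SimConfig,
    plant_ssrs,
    simulate_genome,
    simulate_reads,
)

from conftest import N_HET, map_pal_to_planted_locus


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        config = SimConfig(genome_length=10_000, coverage=1, seed=7)
        assert simulate_genome(config) == simulate_genome(config)

    def test_gc_zero_gives_at_only(self):
        config = SimConfig(genome_length=2_000, coverage=1, gc_content=0.0, seed=1)
        assert set(simulate_genome(config)) <= {"A", "T"}

    def test_empirical_gc_near_target(self):
        config = SimConfig(genome_length=100_000, coverage=1, gc_content=0.4, seed=3)
        genome = simulate_genome(config)
        gc = (genome.count("G") + genome.count("C")) / len(genome)
        assert gc == pytest.approx(0.4, abs=0.02)

    def test_below_one_kilobase_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(SimConfig(genome_length=500, coverage=1))


class TestPlantSsrs:
    def _backbone(self, n=20_000, seed=5):
        return simulate_genome(SimConfig(genome_length=n, coverage=1, seed=seed))

    def test_heterozygous_allele_shifts_haplotype_length(self):
        spec = PlantSpec(motif="TTC", unit_counts=(8, 10))
        hap1, hap2, truth = plant_ssrs(self._backbone(), [spec], seed=1)
        assert len(hap2) - len(hap1) == 6  # 2 extra units x 3 bp

    def test_equal_alleles_give_identical_haplotypes(self):
        specs = [PlantSpec(motif="ATC", unit_counts=(8, 8)),
                 PlantSpec(motif="AATG", unit_counts=(5, 5))]
        hap1, hap2, _ = plant_ssrs(self._backbone(), specs, seed=1)
        assert hap1 == hap2

    def test_scanner_recovers_exact_truth(self):
        specs = [
            PlantSpec(motif="ATC", unit_counts=(8, 10)),
            PlantSpec(motif="AAG", unit_counts=(6, 6)),
            PlantSpec(motif="TTC", unit_counts=(9, 12)),
            PlantSpec(motif="AATG", unit_counts=(5, 5)),
        ]
        hap1, hap2, truth = plant_ssrs(self._backbone(40_000), specs, seed=2)
        for hap_idx, hap in enumerate((hap1, hap2)):
            rows = truth[truth.haplotype == hap_idx]
            found = {
                (l.start, l.end, l.motif_canonical, l.unit_count)
                for l in scan_read(hap)
            }
            planted = set(
                zip(rows.start, rows.end, rows.motif_canonical, rows.unit_count)
            )
            assert found == planted

    def test_compound_structure_scans_as_compound(self):
        spec = PlantSpec(
            motif="TC", unit_counts=(10, 10), structure="compound",
            second_motif="AGCG", second_count=5,
        )
        hap1, _, truth = plant_ssrs(self._backbone(), [spec], seed=3)
        loci = scan_read(hap1)
        assert [(l.motif_observed, l.unit_count) for l in loci] == [
            ("TC", 10), ("AGCG", 5)
        ]
        assert classify_read(loci) == "compound"
        assert len(truth[truth.haplotype == 0]) == 2

    def test_broken_structure_scans_as_broken(self):
        spec = PlantSpec(
            motif="ATC", unit_counts=(7, 7), structure="broken", second_count=8,
        )
        hap1, _, _ = plant_ssrs(self._backbone(), [spec], seed=4)
        loci = scan_read(hap1)
        assert [l.unit_count for l in loci] == [7, 8]
        assert classify_read(loci) == "broken"

    def test_overcrowded_genome_rejected(self):
        specs = [PlantSpec(motif="ATC", unit_counts=(20, 20), flank_length=100)
                 for _ in range(30)]
        with pytest.raises(GenomeCapacityError):
            plant_ssrs(self._backbone(5_000), specs, seed=1)

    def test_compound_junction_guard_validated(self):
        with pytest.raises(ValueError):
            PlantSpec(motif="ATC", unit_counts=(5, 5), structure="compound",
                      second_motif="AAGG", second_count=4)  # both start with A


_READ_CONFIG = SimConfig(genome_length=100_000, coverage=10, seed=9,
                         fragment_mean=300, fragment_sd=20)


@pytest.fixture(scope="module")
def diploid():
    genome = simulate_genome(_READ_CONFIG)
    return genome, genome


class TestSimulateReads:
    config = _READ_CONFIG

    def test_error_free_reads_are_haplotype_substrings(self, diploid):
        pairs, prov = simulate_reads(diploid, self.config)
        hap = diploid[0]
        for (fwd, rev), (_, row) in list(zip(pairs, prov.iterrows()))[:200]:
            frag = hap[row.start : row.start + row.fragment_length]
            assert fwd.sequence == frag[:100]
            assert rev.sequence == reverse_complement(frag)[:100]

    def test_expected_pair_count(self, diploid):
        pairs, _ = simulate_reads(diploid, self.config)
        expected = self.config.genome_length * self.config.coverage / 200
        assert len(pairs) == pytest.approx(expected, rel=0.01)

    def test_deterministic_under_seed(self, diploid):
        p1, _ = simulate_reads(diploid, self.config)
        p2, _ = simulate_reads(diploid, self.config)
        assert [(a.sequence, b.sequence) for a, b in p1] == [
            (a.sequence, b.sequence) for a, b in p2
        ]

    def test_error_rate_perturbs_bases(self, diploid):
        config = SimConfig(genome_length=100_000, coverage=2, seed=9,
                           fragment_mean=300, fragment_sd=20,
                           substitution_error_rate=0.01)
        pairs, prov = simulate_reads(diploid, config)
        hap = diploid[0]
        mismatches = bases = 0
        for (fwd, _), (_, row) in zip(pairs, prov.iterrows()):
            frag = hap[row.start : row.start + row.fragment_length]
            mismatches += sum(a != b for a, b in zip(fwd.sequence, frag[:100]))
            bases += 100
        assert mismatches / bases == pytest.approx(0.01, rel=0.2)
        # qualities encode the error model: Q20 for 1 % errors
        assert pairs[0][0].qualities[0] == 20

    def test_fragment_must_exceed_read_length(self, diploid):
        config = SimConfig(genome_length=100_000, coverage=1, seed=1,
                           fragment_mean=80.0)
        with pytest.raises(ValueError):
            simulate_reads(diploid, config)


class TestFullPipelineRoundTrip:
    """Close the loop: planted heterozygous loci are the flagged loci."""

    def test_het_flagged_hom_clean(self, diploid_simulation, pipeline_result):
        truth = diploid_simulation["truth"]
        hap1 = diploid_simulation["hap1"]
        calls = {c.pal_id: c for c in pipeline_result.calls}
        flagged_loci, unflagged_loci = set(), set()
        for pal in pipeline_result.pals:
            locus_id = map_pal_to_planted_locus(pal, hap1, truth)
            if locus_id is None:
                continue
            if calls[pal.pal_id].flagged:
                flagged_loci.add(locus_id)
            else:
                unflagged_loci.add(locus_id)
        het = set(range(N_HET))
        assert flagged_loci & het == het, "every heterozygous locus is flagged"
        assert not (flagged_loci - het), "no homozygous locus is flagged"

    def test_flagged_precision_with_sequencing_errors(self):
        """At 0.1 % substitution errors, flagged loci stay >= 90 % true."""
        from conftest import READ_SCALE_CONSTRAINTS
        from ssrmine.pipeline import prescreen_polymorphic_loci
        from ssrmine.synth import default_het_hom_specs

        config = SimConfig(genome_length=100_000, coverage=30, seed=5,
                           fragment_mean=170, fragment_sd=8,
                           substitution_error_rate=0.001)
        backbone = simulate_genome(config)
        hap1, hap2, truth = plant_ssrs(backbone, default_het_hom_specs(), seed=5)
        pairs, _ = simulate_reads((hap1, hap2), config)
        result = prescreen_polymorphic_loci(pairs, constraints=READ_SCALE_CONSTRAINTS)
        calls = {c.pal_id: c for c in result.calls}
        flagged = set()
        for pal in result.pals:
            locus_id = map_pal_to_planted_locus(pal, hap1, truth)
            if locus_id is not None and calls[pal.pal_id].flagged:
                flagged.add(locus_id)
        assert flagged, "some loci are still flagged at this error rate"
        true_het = len(flagged & set(range(N_HET)))
        assert true_het / len(flagged) >= 0.9
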