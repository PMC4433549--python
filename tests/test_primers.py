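"""Primer thermodynamics, pair design, PAL and single-copy screening."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as BioTm

from ssrmine.motif import reverse_complement
from ssrmine.primers import (
    PrimerConstraints,
    design_primer_pair,
    find_pals,
    gc_fraction,
    max_mononucleotide_run,
    primer_tm,
    screen_single_copy,
)
from ssrmine.qc import ReadRecord
from ssrmine.scan import annotate_read, scan_read
from ssrmine.synth import design_primer_site

RNG = np.random.default_rng(99)


def _rand_seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


class TestMeltingTemperature:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            primer_tm("ACGTACGTA")  # 9 nt
        with pytest.raises(ValueError):
            primer_tm("")

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError):
            primer_tm("ACGTNACGTACGT")

    def test_gc_substitution_raises_tm(self):
        # replacing an A/T by G/C at fixed length strictly increases Tm
        for _ in range(10):
            seq = list(_rand_seq(20))
            at_positions = [i for i, b in enumerate(seq) if b in "AT"]
            if not at_positions:
                continue
            i = int(RNG.choice(at_positions))
            low = primer_tm("".join(seq))
            seq[i] = "G" if seq[i] == "A" else "C"
            assert primer_tm("".join(seq)) > low

    def test_matches_published_nearest_neighbor_calculator(self):
        # independent oracle: Biopython's SantaLucia-1998 NN table with the
        # same salt correction and strand concentrations
        for _ in range(25):
            seq = _rand_seq(int(RNG.integers(15, 28)))
            ref = BioTm.Tm_NN(
                seq, nn_table=BioTm.DNA_NN3, Na=50, dnac1=25, dnac2=25, saltcorr=5
            )
            assert primer_tm(seq) == pytest.approx(ref, abs=0.5)


def _pal_read(motif="ATC", units=8):
    """Read with a tract between designed primer-admissible flank sites."""
    left = design_primer_site(RNG, forbidden_last=motif[-1])
    right = reverse_complement(design_primer_site(RNG))
    while right[0] == motif[0]:
        right = reverse_complement(design_primer_site(RNG))
    seq = _rand_seq(20) + left + motif * units + right + _rand_seq(20)
    return ReadRecord(id="pal", sequence=seq)


def _audit(pair, read_sequence, locus, constraints):
    """Independent post-hoc constraint audit (test-local logic)."""
    for primer, tm in ((pair.forward, pair.tm_forward), (pair.reverse, pair.tm_reverse)):
        n = len(primer)
        assert constraints.length_min <= n <= constraints.length_max
        gc = (primer.count("G") + primer.count("C")) / n
        assert constraints.gc_min <= gc <= constraints.gc_max
        run = max(
            len(r) for r in
            [primer[i:j] for i in range(n) for j in range(i + 1, n + 1)
             if len(set(primer[i:j])) == 1]
        )
        assert run <= constraints.max_mono_run
        assert constraints.tm_min <= tm <= constraints.tm_max
        assert tm == pytest.approx(primer_tm(primer))
    lo, hi = constraints.product_size_range
    assert lo <= pair.product_size <= hi
    assert pair.product_size == pair.reverse_end - pair.forward_start
    # product span contains the tract; primers do not overlap it
    assert pair.forward_start + len(pair.forward) <= locus.start
    assert pair.reverse_end - len(pair.reverse) >= locus.end
    # primers actually lie on the read
    f0 = pair.forward_start
    assert read_sequence[f0 : f0 + len(pair.forward)] == pair.forward
    segment = read_sequence[pair.reverse_end - len(pair.reverse) : pair.reverse_end]
    assert reverse_complement(segment) == pair.reverse


class TestDesign:
    constraints = PrimerConstraints(product_size_range=(50, 160))

    def test_tiny_flanks_yield_none(self):
        seq = "ACGTC" + "ATC" * 8 + "GTACG"
        (locus,) = scan_read(seq)
        assert design_primer_pair(seq, locus, self.constraints) is None

    def test_designed_read_yields_audited_pair(self):
        for _ in range(5):
            read = _pal_read()
            (locus,) = scan_read(read.sequence)
            pair = design_primer_pair(read.sequence, locus, self.constraints)
            assert pair is not None
            _audit(pair, read.sequence, locus, self.constraints)

    def test_panel_primer_lengths_fit_default_length_window(self):
        # the published markers were designed under default-style rules:
        # every primer length falls in the default 18-27 nt window
        from ssrmine.panel import load_packaged_panel

        constraints = PrimerConstraints()
        for rec in load_packaged_panel():
            for primer in (rec.forward_primer, rec.reverse_primer):
                assert constraints.length_min <= len(primer) <= constraints.length_max


class TestFindPals:
    constraints = PrimerConstraints(product_size_range=(50, 160))

    def test_no_flanks_gives_rate_zero(self):
        read = ReadRecord(id="r", sequence="ATC" * 10)
        anns = [annotate_read(read)]
        pals, rate = find_pals(anns, [read], self.constraints)
        assert pals == [] and rate == 0.0

    def test_designed_flanks_give_rate_one(self):
        reads = [_pal_read(m, 8) for m in ("ATC", "AAG", "AATG")]
        for i, r in enumerate(reads):
            r.id = f"r{i}"
        anns = [annotate_read(r) for r in reads]
        pals, rate = find_pals(anns, reads, self.constraints)
        assert rate == 1.0
        assert len(pals) == 3
        for pal in pals:
            read = next(r for r in reads if r.id == pal.source_read_id)
            _audit(pal.pair, read.sequence, pal.locus, self.constraints)

    def test_dinucleotide_loci_excluded(self):
        left = design_primer_site(RNG, forbidden_last="T")
        right = reverse_complement(design_primer_site(RNG))
        while right[0] == "A":
            right = reverse_complement(design_primer_site(RNG))
        read = ReadRecord(id="r", sequence=left + "AT" * 10 + right)
        anns = [annotate_read(read)]
        assert anns[0].loci  # the tract is detected...
        pals, rate = find_pals(anns, [read], self.constraints)
        assert pals == [] and rate == 0.0  # ...but not attempted


class TestSingleCopyScreen:
    constraints = PrimerConstraints(product_size_range=(50, 160))

    def _pal_and_reads(self, motif="ATC", n_reads=6):
        read = _pal_read(motif)
        ann = annotate_read(read)
        pals, _ = find_pals([ann], [read], self.constraints)
        assert len(pals) == 1
        # "coverage": shifted read windows over one consistent genome
        genome = _rand_seq(40) + read.sequence + _rand_seq(40)
        reads = [read] + [
            ReadRecord(id=f"c{i}", sequence=genome[7 * i : 7 * i + 130])
            for i in range(n_reads)
        ]
        return pals, reads

    def test_single_copy_locus_retained(self):
        pals, reads = self._pal_and_reads()
        kept = screen_single_copy(pals, reads)
        assert [p.pal_id for p in kept] == [p.pal_id for p in pals]
        assert all(p.single_copy is True for p in kept)

    def test_screen_is_idempotent(self):
        pals, reads = self._pal_and_reads()
        once = screen_single_copy(pals, reads)
        twice = screen_single_copy(once, reads)
        assert [p.pal_id for p in once] == [p.pal_id for p in twice]

    def test_shared_primer_context_rejects_both_loci(self):
        pals, reads = self._pal_and_reads()
        pal = pals[0]
        # a second genomic locus carrying the same forward primer but a
        # different upstream flank
        impostor = ReadRecord(
            id="imp", sequence=_rand_seq(30) + pal.pair.forward + _rand_seq(60)
        )
        kept = screen_single_copy(pals, reads + [impostor])
        assert kept == []

    def test_empty_read_set_leaves_pals_unscreened(self):
        pals, _ = self._pal_and_reads()
        kept = screen_single_copy(pals, [])
        assert [p.pal_id for p in kept] == [p.pal_id for p in pals]
        assert all(p.single_copy is None for p in kept)


def test_helper_metrics():
    assert gc_fraction("GGCC") == 1.0
    assert gc_fraction("ATGC") == 0.5
    assert max_mononucleotide_run("AAACCG") == 3
    assert max_mononucleotide_run("ACGT") == 1
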