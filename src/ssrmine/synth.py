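"""Synthetic diploid genomes with planted SSR loci and simulated reads.

The generator emulates the data a genome-survey experiment produces:
an i.i.d. background genome at a target GC content, a diploid pair of
haplotypes that differ only in the repeat-unit counts of planted
heterozygous SSR loci (single, compound and broken structures), and
uniform-coverage paired-end reads (2 x 100 nt by default) with an
i.i.d. substitution error model and qualities encoding the error rate.
Every operation is deterministic under its seed, and planting returns an
exact truth table so that scanning, primer design and the heterozygosity
pre-screen can be validated against planted ground truth.

The background is *sterilized*: after generation, any chance repeat tract
meeting the detection thresholds is broken by a point change, so planted
loci are the only loci above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .motif import canonical_motif, is_primitive, reverse_complement
from .qc import ReadRecord
from .scan import ScanThresholds, scan_read

_BASES = "ACGT"
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on 2-bit codes
_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenomeCapacityError(ValueError):
    """Requested loci (with flanks) do not fit in the genome."""


@dataclass(frozen=True)
class PlantSpec:
    """One SSR locus to plant.

    ``unit_counts`` gives the repeat-unit count per haplotype; unequal
    counts make the locus heterozygous.  ``structure``:

    * ``single`` — one perfect tract;
    * ``compound`` — the tract is followed by ``second_motif`` x
      ``second_count`` (a different motif class);
    * ``broken`` — the tract is interrupted and continues with
      ``second_count`` further units of the same motif.
    """

    motif: str
    unit_counts: tuple[int, int]
    flank_length: int = 60
    structure: str = "single"
    second_motif: Optional[str] = None
    second_count: int = 0
    interruption: str = ""
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        if not is_primitive(self.motif):
            raise ValueError(f"motif {self.motif!r} is not primitive")
        if min(self.unit_counts) < 2 or self.flank_length < 0:
            raise ValueError("unit counts must be >= 2 and flank length >= 0")
        if self.structure not in ("single", "compound", "broken"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "compound":
            if self.second_motif is None or self.second_count < 2:
                raise ValueError("compound spec needs second_motif and second_count >= 2")
            if canonical_motif(self.second_motif) == canonical_motif(self.motif):
                raise ValueError("compound components must differ in motif class")
            # junction guards: neither component may extend into the other
            if (
                self.second_motif[0] == self.motif[0]
                or self.second_motif[-1] == self.motif[-1]
            ):
                raise ValueError(
                    "compound junction would extend a component; choose motifs "
                    "with distinct first and last bases"
                )
        if self.structure == "broken" and self.second_count < 2:
            raise ValueError("broken spec needs second_count >= 2")
        last_motif = (
            self.second_motif
            if self.structure == "compound" and self.second_motif
            else self.motif
        )
        if self.left_flank and self.left_flank[-1] == self.motif[-1]:
            raise ValueError(
                "left flank must end in a base that breaks the tract periodicity"
            )
        if self.right_flank and self.right_flank[0] == last_motif[0]:
            raise ValueError(
                "right flank must start with a base that breaks the tract periodicity"
            )

    def _interruption(self) -> str:
        if self.interruption:
            return self.interruption
        # one base breaking periodicity on both sides of the gap
        avoid = {self.motif[0], self.motif[-1]}
        return next(b for b in _BASES if b not in avoid)

    def allele_components(self, haplotype: int) -> list[tuple[str, int, str]]:
        """Component tracts (sequence, unit_count, motif) for one haplotype."""
        units = self.unit_counts[haplotype]
        first = (self.motif * units, units, self.motif)
        if self.structure == "single":
            return [first]
        if self.structure == "compound":
            assert self.second_motif is not None
            return [first, (self.second_motif * self.second_count,
                            self.second_count, self.second_motif)]
        return [first, (self.motif * self.second_count, self.second_count, self.motif)]

    def allele_sequence(self, haplotype: int) -> str:
        comps = self.allele_components(haplotype)
        if self.structure == "broken":
            return comps[0][0] + self._interruption() + comps[1][0]
        return "".join(c[0] for c in comps)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters: genome, library geometry, error model."""

    genome_length: int
    coverage: float = 30.0
    gc_content: float = 0.5
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 20.0
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.substitution_error_rate <= 0.1:
            raise ValueError("substitution error rate must be in [0, 0.1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")


def simulate_genome(config: SimConfig) -> str:
    """I.i.d. background sequence at the target GC content."""
    if config.genome_length < 1000:
        raise ValueError("genome_length must be >= 1 kb")
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=config.genome_length, p=p).astype(np.uint8)
    return _CODE_TO_ASCII[codes].tobytes().decode("ascii")


def sterilize(
    sequence: str,
    thresholds: ScanThresholds | None = None,
    seed: int = 0,
    max_rounds: int = 20,
) -> str:
    """Break every above-threshold chance tract with a point substitution."""
    rng = np.random.default_rng(seed)
    thresholds = thresholds or ScanThresholds()
    seq = list(sequence)
    for _ in range(max_rounds):
        loci = scan_read("".join(seq), thresholds)
        if not loci:
            return "".join(seq)
        for loc in loci:
            mid = (loc.start + loc.end) // 2
            current = seq[mid]
            seq[mid] = rng.permutation([b for b in _BASES if b != current])[0]
    raise RuntimeError("sterilization did not converge")


def plant_ssrs(
    haploid: str,
    specs: Sequence[PlantSpec],
    seed: int = 0,
    thresholds: ScanThresholds | None = None,
) -> tuple[str, str, pd.DataFrame]:
    """Insert SSR loci into a sterilized backbone; return diploid + truth.

    Loci are inserted (not overwritten) at evenly spaced backbone
    positions, each wrapped in guard bases so the planted tract cannot
    extend into its flanks.  Haplotype 2 differs from haplotype 1 only at
    loci with unequal allele unit counts.  The truth table has one row
    per component tract per haplotype: locus_id, haplotype, start, end,
    motif_observed, motif_canonical, unit_count, structure.
    """
    backbone = sterilize(haploid, thresholds, seed=seed)
    n = len(specs)
    if n == 0:
        return backbone, backbone, pd.DataFrame(
            columns=["locus_id", "haplotype", "start", "end", "motif_observed",
                     "motif_canonical", "unit_count", "structure"]
        )
    slot = len(backbone) // (n + 1)
    max_insert = max(
        max(len(sp.left_flank) or 1, 0)
        + max(len(sp.allele_sequence(0)), len(sp.allele_sequence(1)))
        + max(len(sp.right_flank) or 1, 0)
        for sp in specs
    )
    margin = max(sp.flank_length for sp in specs)
    if slot < max_insert + 2 * margin + 2:
        raise GenomeCapacityError(
            f"{n} loci (insert <= {max_insert} bp, flank {margin} bp) do not "
            f"fit a {len(backbone)} bp genome"
        )
    positions = [slot * (i + 1) for i in range(n)]

    haps: list[str] = []
    rows = []
    for hap in (0, 1):
        parts = []
        prev = 0
        offset = 0
        for i, (pos, sp) in enumerate(zip(positions, specs)):
            chunk = backbone[prev:pos]
            allele = sp.allele_sequence(hap)
            comps = sp.allele_components(hap)
            last_motif = comps[-1][2]
            # flanks (or single guard bases) breaking periodicity at both
            # insertion boundaries so planted tracts cannot extend
            lf = sp.left_flank or next(b for b in _BASES if b != sp.motif[-1])
            rf = sp.right_flank or next(b for b in _BASES if b != last_motif[0])
            parts.append(chunk)
            parts.append(lf)
            start = pos + offset + len(lf)
            parts.append(allele)
            parts.append(rf)
            # truth rows for component tracts
            cursor = start
            for ci, (cseq, cunits, cmotif) in enumerate(comps):
                rows.append(
                    {
                        "locus_id": i,
                        "haplotype": hap,
                        "start": cursor,
                        "end": cursor + len(cseq),
                        "motif_observed": cmotif,
                        "motif_canonical": canonical_motif(cmotif),
                        "unit_count": cunits,
                        "structure": sp.structure,
                    }
                )
                cursor += len(cseq)
                if sp.structure == "broken" and ci == 0:
                    cursor += len(sp._interruption())
            offset += len(lf) + len(allele) + len(rf)
            prev = pos
        parts.append(backbone[prev:])
        haps.append("".join(parts))
    truth = pd.DataFrame(rows).sort_values(["haplotype", "start"]).reset_index(drop=True)
    return haps[0], haps[1], truth


def simulate_reads(
    diploid: tuple[str, str],
    config: SimConfig,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], pd.DataFrame]:
    """Uniform paired-end reads from a diploid, 50/50 per haplotype.

    Fragment lengths are normal (mean/sd from the config, clipped to at
    least the read length); the expected pair count is
    genome_length x coverage / (2 x read_length).  Substitution errors
    are i.i.d. per base; every base gets the Phred score of the
    configured error rate (Q40 cap).  Deterministic under the seed.
    Returns the pairs and a provenance table (pair, haplotype, start,
    fragment_length).
    """
    if config.fragment_mean <= config.read_length:
        raise ValueError("fragment mean must exceed the read length")
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    hap_arrays = []
    for hap in diploid:
        arr = np.frombuffer(hap.encode("ascii"), dtype=np.uint8)
        codes = np.zeros(len(arr), dtype=np.uint8)
        for code, base in enumerate(b"ACGT"):
            codes[arr == base] = code
        hap_arrays.append(codes)
    n_pairs = int(round(config.genome_length * config.coverage / (2 * L)))
    hap_choice = rng.integers(0, 2, size=n_pairs)
    frag_lens = np.clip(
        np.round(rng.normal(config.fragment_mean, config.fragment_sd, size=n_pairs)),
        L,
        None,
    ).astype(np.int64)
    rate = config.substitution_error_rate
    q = 40 if rate <= 0 else min(40, int(round(-10 * np.log10(rate))))
    quals = [q] * L

    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    prov_rows = []
    offsets = np.arange(L)
    for hap_idx in (0, 1):
        sel = np.flatnonzero(hap_choice == hap_idx)
        if sel.size == 0:
            continue
        codes = hap_arrays[hap_idx]
        flen = np.minimum(frag_lens[sel], len(codes))
        starts = rng.integers(0, len(codes) - flen + 1)
        fwd = codes[starts[:, None] + offsets]
        rev = _COMP_CODE[codes[(starts + flen - 1)[:, None] - offsets]]
        if rate > 0:
            for mat in (fwd, rev):
                mask = rng.random(mat.shape) < rate
                shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
                mat[mask] = (mat[mask] + shift[mask]) % 4
        fwd_ascii = _CODE_TO_ASCII[fwd]
        rev_ascii = _CODE_TO_ASCII[rev]
        for row, pair_idx in enumerate(sel):
            name = f"sim{pair_idx}"
            r1 = ReadRecord(
                id=f"{name}/1",
                sequence=fwd_ascii[row].tobytes().decode("ascii"),
                qualities=list(quals),
                mate_id=f"{name}/2",
            )
            r2 = ReadRecord(
                id=f"{name}/2",
                sequence=rev_ascii[row].tobytes().decode("ascii"),
                qualities=list(quals),
                mate_id=f"{name}/1",
            )
            pairs.append((r1, r2))
            prov_rows.append(
                {
                    "pair": name,
                    "haplotype": hap_idx,
                    "start": int(starts[row]),
                    "fragment_length": int(flen[row]),
                }
            )
    order = np.argsort([int(p["pair"][3:]) for p in prov_rows], kind="stable")
    pairs = [pairs[i] for i in order]
    provenance = pd.DataFrame([prov_rows[i] for i in order]).reset_index(drop=True)
    return pairs, provenance


def design_primer_site(
    rng: np.random.Generator,
    length: int = 20,
    forbidden_last: str = "",
    max_tries: int = 20_000,
) -> str:
    """A random primer-admissible site under the default constraints.

    Rejection-samples GC-biased ``length``-mers until one satisfies the
    default primer windows (Tm, GC, run length), contains no SSR tract
    and — when ``forbidden_last`` is given — does not end in that base
    (so it cannot extend an adjacent planted tract).
    """
    from .primers import PrimerConstraints  # local import: avoid cycle

    constraints = PrimerConstraints()
    for _ in range(max_tries):
        codes = rng.choice(4, size=length, p=[0.22, 0.28, 0.28, 0.22])
        site = _CODE_TO_ASCII[codes.astype(np.uint8)].tobytes().decode("ascii")
        if forbidden_last and site[-1] == forbidden_last:
            continue
        if not constraints.primer_admissible(site):
            continue
        if scan_read(site):
            continue
        return site
    raise RuntimeError("could not sample an admissible primer site")


def default_het_hom_specs(
    n_het: int = 10,
    n_hom: int = 10,
    base_units: int = 8,
    het_extra_units: int = 2,
    flank_length: int = 60,
    seed: int = 20_14,
) -> list[PlantSpec]:
    """A standard 10 het + 10 hom panel of PAL-compatible tri+ loci.

    Motifs cycle through distinct tri/tetra classes; heterozygous loci
    differ by ``het_extra_units`` units between haplotypes.  Each locus is
    wrapped in designed 20-nt flank sites that admit a primer under the
    default constraints, so the loci are amplifiable by construction
    (PAL-compatible).  Unit counts are kept moderate so tracts survive
    low-complexity filtering.
    """
    motifs = [
        "ATC", "AAG", "ACT", "AGG", "ACC", "ATG", "AGC", "ACG", "AAT", "AAC",
        "AGT", "CCG", "ATCC", "AAGG", "ACTC", "AGGC", "AATG", "AACC", "AGCC", "ATGG",
    ]
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_het + n_hom):
        motif = motifs[i % len(motifs)]
        if i < n_het:
            counts = (base_units, base_units + het_extra_units)
        else:
            counts = (base_units, base_units)
        left = design_primer_site(rng, forbidden_last=motif[-1])
        # the reverse primer anneals to the opposite strand: sample an
        # admissible primer and plant its reverse complement
        while True:
            right = reverse_complement(design_primer_site(rng))
            if right[0] != motif[0]:
                break
        specs.append(
            PlantSpec(
                motif=motif,
                unit_counts=counts,
                flank_length=flank_length,
                left_flank=left,
                right_flank=right,
            )
        )
    return specs
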