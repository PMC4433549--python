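"""Detection of perfect SSR tracts in reads.

A tract is reported for unit length ``k`` when a primitive ``k``-mer motif
repeats perfectly for at least the per-``k`` minimum number of contiguous
units (defaults: 6 units for dinucleotides, 4 for tri- and
tetranucleotides, 3 for penta- and hexanucleotides).  Reads carrying more
than one tract are classified as *compound* (different canonical motifs)
or *broken* (same canonical motif, interrupted); single-tract reads are
*single*.  Coordinates are 0-based half-open on the read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

from .motif import canonical_motif, is_primitive
from .qc import ReadRecord

CLASS_SINGLE = "single"
CLASS_COMPOUND = "compound"
CLASS_BROKEN = "broken"

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ScanThresholds:
    """Minimum contiguous repeat units per motif length."""

    min_units: dict[int, int] = field(
        default_factory=lambda: {2: 6, 3: 4, 4: 4, 5: 3, 6: 3}
    )

    def __post_init__(self) -> None:
        if any(v < 2 for v in self.min_units.values()):
            raise ValueError("min_units must be >= 2 for every motif length")


@dataclass(frozen=True)
class SSRLocus:
    """One perfect repeat tract on a read.

    ``motif_observed`` is the unit as phased at ``start``;
    ``motif_canonical`` is its class representative.  The tract covers
    ``sequence[start:end]`` = ``motif_observed * unit_count``.
    """

    read_id: str
    start: int
    end: int
    motif_observed: str
    motif_canonical: str
    unit_count: int

    @property
    def k(self) -> int:
        return len(self.motif_observed)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadRepeatAnnotation:
    read_id: str
    loci: tuple[SSRLocus, ...]
    classification: Optional[str]  # None when the read has no tract


def _candidate_tracts(sequence: str, k: int, min_units: int):
    """Maximal period-k runs yielding >= min_units whole units."""
    L = len(sequence)
    i = 0
    while i + k < L:
        if sequence[i] in _ACGT and sequence[i] == sequence[i + k]:
            j = i
            while j + k < L and sequence[j] in _ACGT and sequence[j] == sequence[j + k]:
                j += 1
            # sequence[i : j + k] has period k
            units = (j - i + k) // k
            motif = sequence[i : i + k]
            if units >= min_units and _ACGT.issuperset(motif) and is_primitive(motif):
                yield i, i + units * k, motif, units
            i = j + 1
        else:
            i += 1


def scan_read(
    sequence: str,
    thresholds: ScanThresholds | None = None,
    read_id: str = "",
) -> list[SSRLocus]:
    """All maximal perfect SSR tracts in ``sequence`` meeting thresholds.

    ``N`` never matches.  When tracts of different unit lengths overlap,
    the tract covering more bases wins; on equal coverage the shorter
    motif wins (deterministic greedy resolution).  Reported loci are
    non-overlapping and sorted by start, and none can be extended by a
    whole unit on either side.
    """
    thresholds = thresholds or ScanThresholds()
    sequence = sequence.upper()
    candidates = []
    for k, mu in sorted(thresholds.min_units.items()):
        candidates.extend(
            (start, end, motif, units)
            for start, end, motif, units in _candidate_tracts(sequence, k, mu)
        )
    # longest tract first; ties -> shorter motif, then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    chosen: list[tuple[int, int, str, int]] = []
    for cand in candidates:
        if all(cand[1] <= s or cand[0] >= e for s, e, _, _ in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])
    return [
        SSRLocus(
            read_id=read_id,
            start=s,
            end=e,
            motif_observed=m,
            motif_canonical=canonical_motif(m),
            unit_count=u,
        )
        for s, e, m, u in chosen
    ]


def classify_read(loci: list[SSRLocus] | tuple[SSRLocus, ...]) -> str:
    """single / broken / compound for a read with >= 1 tract.

    Broken: several tracts of one canonical motif (an interrupted repeat);
    compound: tracts of at least two different canonical motifs.
    """
    if not loci:
        raise ValueError("classification requires at least one locus")
    if len(loci) == 1:
        return CLASS_SINGLE
    motifs = {loc.motif_canonical for loc in loci}
    return CLASS_BROKEN if len(motifs) == 1 else CLASS_COMPOUND


def annotate_read(
    read: ReadRecord, thresholds: ScanThresholds | None = None
) -> ReadRepeatAnnotation:
    loci = tuple(scan_read(read.sequence, thresholds, read_id=read.id))
    return ReadRepeatAnnotation(
        read_id=read.id,
        loci=loci,
        classification=classify_read(loci) if loci else None,
    )


def annotate_reads(
    reads: Iterable[ReadRecord], thresholds: ScanThresholds | None = None
) -> Iterator[ReadRepeatAnnotation]:
    for read in reads:
        yield annotate_read(read, thresholds)


def motif_frequency_table(
    annotations: Iterable[ReadRepeatAnnotation],
) -> pd.Series:
    """Locus counts per canonical motif, sorted descending.

    Ties are broken lexicographically on the motif, so the ordering is
    total.  The counts partition the total number of loci.
    """
    counts: dict[str, int] = {}
    for ann in annotations:
        for loc in ann.loci:
            counts[loc.motif_canonical] = counts.get(loc.motif_canonical, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(
        [c for _, c in items],
        index=pd.Index([m for m, _ in items], name="motif"),
        name="loci",
        dtype=int,
    )


def ssr_density(total_loci: int, total_bases: int) -> float:
    """Genomic spacing of SSR loci in kb per locus (one decimal).

    E.g. 175,607 loci in 5 million 2 x 100 nt read pairs (1e9 bases) is
    one locus per 5.7 kb.  Zero loci gives ``inf`` rather than an error.
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if total_loci == 0:
        return math.inf
    return round(total_bases / total_loci / 1000.0, 1)
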