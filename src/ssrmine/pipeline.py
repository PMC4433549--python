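"""End-to-end marker pre-screening: QC -> scan -> design -> e-PCR.

Composes the individual stages into the read-to-candidate-marker
workflow: quality-filter and merge read pairs, detect SSR tracts, design
flanking primers for tri+ nucleotide loci, keep locus-specific (single
copy) primer pairs, measure in-silico amplicon lengths and flag loci
that look heterozygous in the sequenced individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .epcr import PolymorphismCall, prioritize_candidates, screen_pals
from .primers import PALocus, PrimerConstraints, find_pals, screen_single_copy
from .qc import QCParams, QCSummary, ReadRecord, qc_pipeline
from .scan import ReadRepeatAnnotation, ScanThresholds, annotate_reads


@dataclass
class PrescreenResult:
    reads: list[ReadRecord]
    qc_summary: QCSummary
    annotations: list[ReadRepeatAnnotation]
    pals: list[PALocus]
    design_rate: float
    calls: list[PolymorphismCall]
    ranked: list[PALocus] = field(default_factory=list)

    @property
    def flagged(self) -> list[PolymorphismCall]:
        return [c for c in self.calls if c.flagged]


def prescreen_polymorphic_loci(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    qc_params: QCParams | None = None,
    thresholds: ScanThresholds | None = None,
    constraints: PrimerConstraints | None = None,
    min_support: int = 2,
) -> PrescreenResult:
    """Run the full pre-screen on raw read pairs.

    For 2 x 100 nt libraries pass a ``PrimerConstraints`` with a product
    size range that fits the merged-read length (e.g. 60-160 bp);
    amplicons are only observable where the whole product lies within a
    single (merged) read.
    """
    reads, qc_summary = qc_pipeline(pairs, qc_params, merge=True)
    annotations = [a for a in annotate_reads(reads, thresholds) if a.loci]
    pals, rate = find_pals(annotations, reads, constraints)
    pals = screen_single_copy(pals, reads)
    calls = screen_pals(pals, reads, min_support=min_support)
    ranked = prioritize_candidates(pals, calls)
    return PrescreenResult(
        reads=reads,
        qc_summary=qc_summary,
        annotations=annotations,
        pals=pals,
        design_rate=rate,
        calls=calls,
        ranked=ranked,
    )
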