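"""In-silico PCR and length-polymorphism pre-screening.

Each PAL's primers are located in the (QC'd, pair-merged) read set; every
read that contains the forward primer followed 3' by the reverse
complement of the reverse primer yields one amplicon-length observation.
A locus whose observations fall into two or more well-supported length
bins differing by at least one repeat unit is flagged as potentially
heterozygous in the sequenced individual — the cheap pre-screen that
enriches for polymorphic markers before any wet-lab testing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .motif import reverse_complement
from .primers import PALocus, PrimerPair
from .qc import ReadRecord

DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class AmpliconObservation:
    pal_id: str
    read_id: str
    product_length: int


@dataclass(frozen=True)
class PolymorphismCall:
    """Length histogram and heterozygosity flag for one PAL.

    ``flagged`` requires at least two product-length bins, each supported
    by the minimum read count, differing by at least the minimum spacing
    (one repeat unit by default).
    """

    pal_id: str
    length_histogram: dict[int, int] = field(default_factory=dict)
    flagged: bool = False

    @property
    def n_observations(self) -> int:
        return sum(self.length_histogram.values())

    @property
    def allele_spread(self) -> int:
        supported = sorted(self.length_histogram)
        return supported[-1] - supported[0] if supported else 0


def epcr_amplicons(
    pair: PrimerPair,
    reads: Iterable[ReadRecord],
    pal_id: str = "",
) -> list[AmpliconObservation]:
    """Amplicon lengths of ``pair`` across the read set.

    A read (in either orientation) yields one observation when the
    forward primer occurs and the reverse complement of the reverse
    primer occurs 3' of it; the product length runs from the forward
    primer's first base to the reverse primer site's last base.  Exact
    matching only.
    """
    rc_rev = reverse_complement(pair.reverse)
    out = []
    for read in reads:
        for seq in (read.sequence, reverse_complement(read.sequence.replace("N", "A"))):
            f = seq.find(pair.forward)
            if f == -1:
                continue
            r = seq.find(rc_rev, f + len(pair.forward))
            if r == -1:
                continue
            out.append(
                AmpliconObservation(
                    pal_id=pal_id,
                    read_id=read.id,
                    product_length=r + len(rc_rev) - f,
                )
            )
            break  # one observation per read
    return out


def flag_potentially_polymorphic(
    observations: Sequence[AmpliconObservation],
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_diff: int = 1,
) -> PolymorphismCall:
    """Call a PAL potentially polymorphic from its amplicon lengths.

    Flagged iff at least two distinct product lengths are each supported
    by >= ``min_support`` reads and some supported pair differs by
    >= ``min_diff`` bp.  ``min_diff`` should be the locus's repeat unit
    length: true SSR alleles differ by unit multiples, smaller differences
    are treated as noise.  Empty input gives an unflagged empty call.
    """
    if not observations:
        return PolymorphismCall(pal_id="", length_histogram={}, flagged=False)
    pal_id = observations[0].pal_id
    hist = Counter(obs.product_length for obs in observations)
    supported = sorted(l for l, n in hist.items() if n >= min_support)
    flagged = len(supported) >= 2 and supported[-1] - supported[0] >= min_diff
    return PolymorphismCall(
        pal_id=pal_id, length_histogram=dict(hist), flagged=flagged
    )


def screen_pals(
    pals: Sequence[PALocus],
    reads: Iterable[ReadRecord],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[PolymorphismCall]:
    """Run e-PCR and polymorphism flagging for every PAL.

    ``min_diff`` is set per locus to its repeat unit length.
    """
    read_list = list(reads)
    calls = []
    for pal in pals:
        obs = epcr_amplicons(pal.pair, read_list, pal_id=pal.pal_id)
        call = flag_potentially_polymorphic(
            obs, min_support=min_support, min_diff=pal.locus.k
        )
        if not obs:
            call = PolymorphismCall(pal_id=pal.pal_id, length_histogram={}, flagged=False)
        calls.append(call)
    return calls


def prioritize_candidates(
    pals: Sequence[PALocus],
    calls: Sequence[PolymorphismCall],
) -> list[PALocus]:
    """Rank marker candidates: flagged loci first, then the rest.

    Flagged loci sort by allele-length spread (descending), then total
    supporting reads (descending); ordering is stable, so unflagged loci
    keep their input order.
    """
    by_id = {c.pal_id: c for c in calls}
    def sort_key(item):
        idx, pal = item
        call = by_id.get(pal.pal_id)
        if call is not None and call.flagged:
            return (0, -call.allele_spread, -call.n_observations, idx)
        return (1, 0, 0, idx)
    ranked = sorted(enumerate(pals), key=sort_key)
    return [pal for _, pal in ranked]
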