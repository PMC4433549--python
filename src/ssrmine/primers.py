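"""Primer design and potentially-amplifiable-locus (PAL) screening.

An SSR locus is *potentially amplifiable* when both of its flanks on the
source read admit a PCR primer under conventional design constraints
(length 18-27 nt, melting temperature 57-63 degC, GC 20-80 %, no long
mononucleotide run, primers outside the repeat tract).  A lightweight
internal designer enumerates admissible flanking primers and returns the
best-scoring pair; melting temperatures come from the nearest-neighbor
thermodynamic model with a monovalent-salt entropy correction.

``screen_single_copy`` then keeps only loci whose primers are
locus-specific in the read set: every exact occurrence of a primer (on
either strand) must show a consistent sequence context on the *outward*
side of the amplicon.  The outward side is used deliberately: inward of
the primers lies the repeat tract, whose length legitimately differs
between the two haplotypes of a heterozygous individual, while a primer
that has landed in a second genomic copy shows a conflicting outward
flank.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .motif import reverse_complement
from .qc import ReadRecord
from .scan import ReadRepeatAnnotation, SSRLocus

# SantaLucia (1998) unified nearest-neighbor parameters.
# dH in kcal/mol, dS in cal/(mol K); table covers one strand 5'->3',
# the complementary stack has identical values.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)   # per terminal G/C
_INIT_AT = (2.3, 4.1)    # per terminal A/T
_R = 1.987  # gas constant, cal/(mol K)


def primer_tm(
    sequence: str,
    monovalent_mM: float = 50.0,
    primer_nM: float = 50.0,
) -> float:
    """Nearest-neighbor melting temperature in degC.

    Unified duplex parameters with terminal-basepair initiation terms, a
    symmetry correction for self-complementary oligos, and the
    0.368*(N-1)*ln[Na+] entropy salt correction.  Defaults (50 mM
    monovalent cation, 50 nM total primer) match common primer-design
    conditions.
    """
    n = len(sequence)
    if not 10 <= n <= 36:
        raise ValueError(f"primer length must be in [10, 36], got {n}")
    if set(sequence) - set("ACGT"):
        raise ValueError(f"ambiguous bases in primer {sequence!r}")
    dh = ds = 0.0
    for i in range(n - 1):
        h, s = _NN[sequence[i : i + 2]]
        dh += h
        ds += s
    for terminal in (sequence[0], sequence[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    selfcomp = sequence == reverse_complement(sequence)
    if selfcomp:
        ds += -1.4
    ds += 0.368 * (n - 1) * math.log(monovalent_mM / 1000.0)
    ct = primer_nM * 1e-9 / (1.0 if selfcomp else 4.0)
    return dh * 1000.0 / (ds + _R * math.log(ct)) - 273.15


def gc_fraction(sequence: str) -> float:
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def max_mononucleotide_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraints in the style of standard primer-design defaults.

    ``product_size_range`` defaults to 100-450 bp, bracketing typical SSR
    marker allele sizes; for in-silico PCR on short merged reads a
    narrower range matched to the read length is appropriate.
    ``product_size_weight`` adds a small per-bp penalty so the designer
    prefers compact amplicons among admissible pairs.
    """

    length_min: int = 18
    length_opt: int = 20
    length_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 0.20
    gc_max: float = 0.80
    product_size_range: tuple[int, int] = (100, 450)
    max_mono_run: int = 4
    product_size_weight: float = 0.1

    def __post_init__(self) -> None:
        if not (self.length_min <= self.length_opt <= self.length_max):
            raise ValueError("primer length range must satisfy min <= opt <= max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("Tm range must satisfy min <= opt <= max")
        if self.product_size_range[0] > self.product_size_range[1]:
            raise ValueError("product size range inverted")

    def primer_admissible(self, sequence: str) -> bool:
        """Check one primer against length, GC, run and Tm windows."""
        n = len(sequence)
        if not self.length_min <= n <= self.length_max:
            return False
        if set(sequence) - set("ACGT"):
            return False
        if not self.gc_min <= gc_fraction(sequence) <= self.gc_max:
            return False
        if max_mononucleotide_run(sequence) > self.max_mono_run:
            return False
        return self.tm_min <= primer_tm(sequence) <= self.tm_max


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; both primers written 5'->3' on their own strand.

    ``forward_start`` / ``reverse_end`` delimit the product span in read
    coordinates (0-based half-open), so
    ``product_size == reverse_end - forward_start``.
    """

    forward: str
    reverse: str
    forward_start: int
    reverse_end: int
    tm_forward: float
    tm_reverse: float
    product_size: int


@dataclass(frozen=True)
class PALocus:
    """An SSR locus with a designed primer pair.

    ``single_copy`` is ``None`` until ``screen_single_copy`` has run.
    """

    pal_id: str
    locus: SSRLocus
    pair: PrimerPair
    source_read_id: str
    single_copy: Optional[bool] = None


def _candidate_primers(
    segment: str, offset: int, constraints: PrimerConstraints
) -> list[tuple[int, int, str, float]]:
    """Admissible primers within ``segment`` (read coords via ``offset``).

    Returns (start, end, sequence-on-read-strand, Tm).
    """
    out = []
    L = len(segment)
    for length in range(constraints.length_min, constraints.length_max + 1):
        for a in range(0, L - length + 1):
            sub = segment[a : a + length]
            if set(sub) - set("ACGT"):
                continue
            if not constraints.gc_min <= gc_fraction(sub) <= constraints.gc_max:
                continue
            if max_mononucleotide_run(sub) > constraints.max_mono_run:
                continue
            tm = primer_tm(sub)
            if constraints.tm_min <= tm <= constraints.tm_max:
                out.append((offset + a, offset + a + length, sub, tm))
    return out


def design_primer_pair(
    read_sequence: str,
    locus: SSRLocus,
    constraints: PrimerConstraints | None = None,
) -> Optional[PrimerPair]:
    """Best admissible primer pair flanking ``locus``, or ``None``.

    The forward primer lies entirely 5' of the tract, the reverse primer
    (given 5'->3' on the opposite strand) entirely 3' of it, and the
    product span contains the tract.  Score is the summed deviation of
    both primers from the optimal length and Tm plus a small product-size
    penalty; ties break to the leftmost forward primer, then the smallest
    product.
    """
    constraints = constraints or PrimerConstraints()
    read_sequence = read_sequence.upper()
    if not (0 <= locus.start < locus.end <= len(read_sequence)):
        raise ValueError("locus does not lie on the read")
    left = _candidate_primers(read_sequence[: locus.start], 0, constraints)
    if not left:
        return None
    right = _candidate_primers(
        read_sequence[locus.end :], locus.end, constraints
    )
    if not right:
        return None
    pmin, pmax = constraints.product_size_range
    best = None
    best_key = None
    for fa, fb, fseq, ftm in left:
        fscore = abs(fb - fa - constraints.length_opt) + abs(ftm - constraints.tm_opt)
        for ra, rb, rseq_fwd, rtm in right:
            product = rb - fa
            if not pmin <= product <= pmax:
                continue
            score = (
                fscore
                + abs(rb - ra - constraints.length_opt)
                + abs(rtm - constraints.tm_opt)
                + constraints.product_size_weight * product
            )
            key = (score, fa, product)
            if best_key is None or key < best_key:
                best_key = key
                best = PrimerPair(
                    forward=fseq,
                    reverse=reverse_complement(rseq_fwd),
                    forward_start=fa,
                    reverse_end=rb,
                    tm_forward=ftm,
                    tm_reverse=rtm,
                    product_size=product,
                )
    return best


def find_pals(
    annotations: Iterable[ReadRepeatAnnotation],
    reads: Mapping[str, ReadRecord] | Iterable[ReadRecord],
    constraints: PrimerConstraints | None = None,
    min_unit_length: int = 3,
) -> tuple[list[PALocus], float]:
    """Attempt primer design for every tract of unit length >= 3.

    Dinucleotide tracts are excluded from marker development (their high
    stutter makes scoring unreliable), mirroring the screening that the
    per-unit thresholds feed.  Returns the PAL records and the fraction of
    attempted loci for which a pair was designed (0.0 when nothing was
    attempted).
    """
    if not isinstance(reads, Mapping):
        reads = {r.id: r for r in reads}
    pals: list[PALocus] = []
    attempted = 0
    for ann in annotations:
        read = reads.get(ann.read_id)
        if read is None:
            continue
        for locus in ann.loci:
            if locus.k < min_unit_length:
                continue
            attempted += 1
            pair = design_primer_pair(read.sequence, locus, constraints)
            if pair is not None:
                pals.append(
                    PALocus(
                        pal_id=f"{ann.read_id}:{locus.start}-{locus.end}",
                        locus=locus,
                        pair=pair,
                        source_read_id=ann.read_id,
                    )
                )
    rate = len(pals) / attempted if attempted else 0.0
    return pals, rate


# ---------------------------------------------------------------------------
# Single-copy screening


def _occurrences(text: str, pattern: str) -> Iterable[int]:
    pos = text.find(pattern)
    while pos != -1:
        yield pos
        pos = text.find(pattern, pos + 1)


def _prefix_consistent(contexts: list[str]) -> bool:
    """True iff every string is a prefix of the longest one."""
    if len(contexts) <= 1:
        return True
    longest = max(contexts, key=len)
    return all(longest.startswith(c) for c in contexts)


def screen_single_copy(
    pals: Sequence[PALocus],
    reads: Iterable[ReadRecord],
    context_window: int = 25,
) -> list[PALocus]:
    """Retain PALs whose primers are locus-specific in the read set.

    For each primer the outward context — the up-to-``context_window``
    bases immediately outside the amplicon at every exact occurrence on
    either strand — must be prefix-consistent across all occurrences.  A
    primer string shared by two genomic loci accumulates conflicting
    contexts and removes every PAL using it.  An empty read set screens
    nothing: all PALs are returned with ``single_copy`` left ``None``.
    The operation is idempotent.
    """
    pals = list(pals)
    read_list = list(reads)
    if not read_list:
        return pals
    texts = []
    for r in read_list:
        texts.append(r.sequence)
        texts.append(reverse_complement(r.sequence.replace("N", "A")))
    # One concatenated text with '#' separators: each pattern is searched
    # with a single C-level scan; contexts are clipped at separators.
    big = "#".join(texts)

    # For each pattern record outward contexts. Patterns are expressed on
    # the read strand: the forward primer as-is (outward side = 5',
    # upstream), the reverse primer reverse-complemented (outward = 3',
    # downstream). Contexts on the upstream side are reversed so that
    # prefix-consistency always reads outward from the primer.
    patterns: dict[tuple[str, str], list[str]] = {}
    for pal in pals:
        patterns.setdefault((pal.pair.forward, "up"), [])
        patterns.setdefault((reverse_complement(pal.pair.reverse), "down"), [])
    for (pat, side), ctxs in patterns.items():
        for pos in _occurrences(big, pat):
            if side == "up":
                seg = big[max(0, pos - context_window) : pos]
                cut = seg.rfind("#")
                if cut != -1:
                    seg = seg[cut + 1 :]
                ctxs.append(seg[::-1])
            else:
                end = pos + len(pat)
                seg = big[end : end + context_window]
                cut = seg.find("#")
                if cut != -1:
                    seg = seg[:cut]
                ctxs.append(seg)
    out = []
    for pal in pals:
        ok = _prefix_consistent(
            patterns[(pal.pair.forward, "up")]
        ) and _prefix_consistent(
            patterns[(reverse_complement(pal.pair.reverse), "down")]
        )
        if ok:
            out.append(replace(pal, single_copy=True))
    return out
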