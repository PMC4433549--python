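"""Read I/O and quality control.

Implements the pre-mining read-filtering pipeline used before SSR
detection: minimum length, minimum mean Phred quality, maximum number of
ambiguous bases, DUST low-complexity removal, exact-duplicate removal and
merging of overlapping read pairs into super-reads.

FASTQ is assumed Phred+33.  All file readers and writers are
gzip-transparent (a ``.gz`` suffix triggers compression).
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Reason codes, in the order filters are applied (cheap checks first).
REASON_LENGTH = "length"
REASON_AMBIGUITY = "ambiguity"
REASON_QUALITY = "quality"
REASON_DUST = "dust"
REASON_PASS = "pass"


class QCConfigurationError(ValueError):
    """Quality rules requested for records that carry no qualities."""


@dataclass
class ReadRecord:
    """A sequencing read (FASTQ) or bare sequence (FASTA).

    ``qualities`` are Phred scores (0-93), one per base, or ``None`` for
    FASTA input.  ``mate_id`` links the two reads of a pair.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    mate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_quality(self) -> float:
        if self.qualities is None:
            raise QCConfigurationError(
                f"read {self.id} has no qualities (FASTA input?)"
            )
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0

    def reverse_complement(self) -> "ReadRecord":
        quals = None if self.qualities is None else self.qualities[::-1]
        return ReadRecord(
            id=self.id,
            sequence=self.sequence.translate(_COMPLEMENT)[::-1],
            qualities=quals,
            mate_id=self.mate_id,
        )


@dataclass
class QCParams:
    """Thresholds of the read-filtering pipeline.

    Defaults follow the survey-sequencing QC recipe: reads shorter than
    50 nt, with mean Phred below 25 or with more than one N are dropped,
    and reads with a DUST low-complexity score of 7 or more are removed.
    Pair merging accepts the longest 3'-overlap of at least
    ``merge_min_overlap`` bases whose mismatch rate does not exceed
    ``merge_max_mismatch_rate``.
    """

    min_length: int = 50
    min_mean_quality: float = 25.0
    max_n: int = 1
    dust_threshold: float = 7.0
    merge_min_overlap: int = 10
    merge_max_mismatch_rate: float = 0.1
    merge_reject_ambiguous: bool = True

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_mean_quality, self.max_n,
               self.dust_threshold, self.merge_min_overlap) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.merge_max_mismatch_rate <= 1.0:
            raise ValueError("merge_max_mismatch_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# File I/O


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate over a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )


def read_fasta(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate over a (possibly gzipped) FASTA file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield ReadRecord(id=rec.id, sequence=str(rec.seq).upper())


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            if r.qualities is None:
                raise QCConfigurationError(
                    f"read {r.id} has no qualities; cannot write FASTQ"
                )
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def write_fasta(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            SeqIO.write(SeqRecord(Seq(r.sequence), id=r.id, description=""), fh, "fasta")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Per-read filters


def quality_filter(read: ReadRecord, params: QCParams) -> tuple[bool, str]:
    """Apply the length / ambiguity / mean-quality rules to one read.

    Returns ``(passed, reason)`` where ``reason`` is the first violated
    rule (``length``, ``ambiguity`` or ``quality``) or ``pass``.  Checks
    run cheap-first: length, then N count, then mean quality.  FASTA
    records (no qualities) raise when the quality rule would be consulted.
    """
    if len(read) < params.min_length:
        return False, REASON_LENGTH
    if read.sequence.count("N") > params.max_n:
        return False, REASON_AMBIGUITY
    if read.mean_quality() < params.min_mean_quality:
        return False, REASON_QUALITY
    return True, REASON_PASS


def dust_score(sequence: str) -> float:
    """Low-complexity score in [0, 100] via triplet over-representation.

    The whole read is treated as one window: with ``w = n - 2``
    overlapping triplets and per-triplet counts ``c_t``, the score is

        100 * sum_t C(c_t, 2) / C(w, 2)

    i.e. the number of coinciding triplet pairs divided by its maximum.
    A read whose triplets are all distinct scores 0; a homopolymer
    scores 100.  ``N`` breaks triplets (windows containing N are skipped).
    """
    n = len(sequence)
    if n < 3:
        raise ValueError("DUST score requires a sequence of length >= 3")
    counts: Counter[str] = Counter()
    for i in range(n - 2):
        t = sequence[i : i + 3]
        if "N" not in t:
            counts[t] += 1
    w = n - 2
    denom = w * (w - 1) / 2
    if denom == 0:
        return 0.0
    num = sum(c * (c - 1) / 2 for c in counts.values())
    return 100.0 * num / denom


def deduplicate(
    reads: Iterable[ReadRecord | tuple[ReadRecord, ReadRecord]],
) -> tuple[list, int]:
    """Keep the first occurrence of each exact sequence.

    Accepts single reads or ``(fwd, rev)`` pairs; a pair is a duplicate
    only when the ordered concatenation of both sequences has been seen.
    Returns ``(kept, n_removed)`` with input order preserved.
    """
    seen: set[str] = set()
    kept = []
    removed = 0
    for item in reads:
        if isinstance(item, tuple):
            key = item[0].sequence + "\x00" + item[1].sequence
        else:
            key = item.sequence
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(item)
    return kept, removed


def merge_pair(
    fwd: ReadRecord, rev: ReadRecord, params: QCParams
) -> Optional[ReadRecord]:
    """Connect an overlapping read pair into one super-read.

    ``rev`` is given in sequencing orientation and is reverse-complemented
    first.  Among admissible 3'-overlaps (at least ``merge_min_overlap``
    bases, mismatch rate at most ``merge_max_mismatch_rate``) the one with
    the fewest mismatches wins, longest on ties; in the overlap,
    disagreeing positions keep the base with the higher quality.

    When several overlaps tie on mismatch count at *different* lengths the
    true fragment length is genuinely undecidable — the typical case is a
    pair straddling a repeat tract, where a unit-shifted overlap matches
    exactly and merging would delete repeat units (a stutter-like
    artifact).  Such pairs are left unmerged (``None``) unless
    ``merge_reject_ambiguous`` is off, in which case the longest tying
    overlap wins.  Returns ``None`` when no admissible overlap exists.
    """
    rc = rev.reverse_complement()
    a, b = fwd.sequence, rc.sequence
    qa = fwd.qualities or [0] * len(a)
    qb = rc.qualities or [0] * len(b)
    max_ov = min(len(a), len(b))
    admissible: list[tuple[int, int]] = []  # (mismatches, overlap), longest first
    for ov in range(max_ov, params.merge_min_overlap - 1, -1):
        tail, head = a[len(a) - ov :], b[:ov]
        mismatches = sum(x != y for x, y in zip(tail, head))
        if mismatches / ov <= params.merge_max_mismatch_rate:
            admissible.append((mismatches, ov))
    if not admissible:
        return None
    best_mm = min(mm for mm, _ in admissible)
    tying = [ov for mm, ov in admissible if mm == best_mm]
    if len(tying) > 1 and params.merge_reject_ambiguous:
        return None
    ov = tying[0]
    off = len(a) - ov
    seq = list(a[:off])
    qual = list(qa[:off])
    for i in range(ov):
        if qb[i] > qa[off + i]:
            seq.append(b[i])
            qual.append(qb[i])
        else:
            seq.append(a[off + i])
            qual.append(qa[off + i])
    seq.extend(b[ov:])
    qual.extend(qb[ov:])
    return ReadRecord(
        id=fwd.id, sequence="".join(seq), qualities=qual, mate_id=rev.id
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class QCSummary:
    """Disjoint per-reason accounting: input = passed + sum(failed)."""

    n_input: int = 0
    n_passed: int = 0
    failed: dict = field(
        default_factory=lambda: {
            REASON_LENGTH: 0,
            REASON_AMBIGUITY: 0,
            REASON_QUALITY: 0,
            REASON_DUST: 0,
        }
    )
    n_duplicates_removed: int = 0
    n_pairs_merged: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "input": self.n_input,
                "passed": self.n_passed,
                "failed": dict(self.failed),
                "duplicates_removed": self.n_duplicates_removed,
                "pairs_merged": self.n_pairs_merged,
            },
            indent=2,
        )


def filter_reads(
    reads: Iterable[ReadRecord],
    params: QCParams | None = None,
    summary: QCSummary | None = None,
) -> Iterator[ReadRecord]:
    """Stream reads through length -> ambiguity -> quality -> DUST filters.

    Each dropped read is counted under exactly one reason (the first
    violated rule) in ``summary``.
    """
    params = params or QCParams()
    for read in reads:
        if summary is not None:
            summary.n_input += 1
        passed, reason = quality_filter(read, params)
        if passed and len(read) >= 3 and dust_score(read.sequence) >= params.dust_threshold:
            passed, reason = False, REASON_DUST
        if passed:
            if summary is not None:
                summary.n_passed += 1
            yield read
        elif summary is not None:
            summary.failed[reason] += 1


def qc_pipeline(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    params: QCParams | None = None,
    merge: bool = True,
) -> tuple[list[ReadRecord], QCSummary]:
    """Full pair-aware QC: per-read filters, pair dedup, optional merging.

    A pair survives the per-read stage only if both mates pass.  Surviving
    pairs are deduplicated on the ordered concatenated sequence, then (when
    ``merge`` is on) connected into super-reads where they overlap; pairs
    that do not merge are kept as two separate reads.
    """
    params = params or QCParams()
    summary = QCSummary()
    surviving: list[tuple[ReadRecord, ReadRecord]] = []
    for fwd, rev in pairs:
        ok = True
        for mate in (fwd, rev):
            summary.n_input += 1
            passed, reason = quality_filter(mate, params)
            if passed and dust_score(mate.sequence) >= params.dust_threshold:
                passed, reason = False, REASON_DUST
            if passed:
                summary.n_passed += 1
            else:
                summary.failed[reason] += 1
                ok = False
        if ok:
            surviving.append((fwd, rev))
    deduped, summary.n_duplicates_removed = deduplicate(surviving)
    out: list[ReadRecord] = []
    for fwd, rev in deduped:
        merged = merge_pair(fwd, rev, params) if merge else None
        if merged is not None:
            summary.n_pairs_merged += 1
            out.append(merged)
        else:
            out.extend((fwd, rev))
    return out, summary
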