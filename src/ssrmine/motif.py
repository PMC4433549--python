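"""Repeat-motif algebra: canonical SSR motif classes.

Microsatellite motifs are reported up to two symmetries of double-stranded
DNA: a tandem repeat of ``TG`` is the same tract as a repeat of ``GT``
(phase shift), and on the opposite strand it reads as a ``CA`` repeat.
All reporting in this package therefore groups motifs into equivalence
classes closed under cyclic rotation and reverse complementation, and names
each class by its lexicographically smallest member (so the ``TG``/``CA``
family is the class ``AC``, and ``TGG``/``GTG``/``GGT`` fall into ``ACC``).

Only *primitive* motifs of length 2-6 are admitted: a motif must not be a
whole-number power of a shorter string, which excludes homopolymers
(``AA`` = ``A``^2) and phase-duplicated units (``ATAT`` = ``AT``^2) so that
no tract is double-reported at two unit lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = [
    "MIN_MOTIF_LEN",
    "MAX_MOTIF_LEN",
    "MotifClass",
    "reverse_complement",
    "is_primitive",
    "canonical_motif",
    "enumerate_motif_classes",
]

MIN_MOTIF_LEN = 2
MAX_MOTIF_LEN = 6

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class InvalidAlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T}."""


class NonPrimitiveMotifError(ValueError):
    """Motif is a whole-number power of a shorter string."""


def _check_alphabet(seq: str) -> None:
    if not seq or not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET) if seq else []
        raise InvalidAlphabetError(
            f"motif must be a non-empty string over A/C/G/T, got {seq!r}"
            + (f" (invalid: {','.join(bad)})" if bad else "")
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, reversed)."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True iff ``motif`` is not a power of a shorter string.

    A string of length ``n`` is non-primitive when some proper divisor ``d``
    of ``n`` satisfies ``motif == motif[:d] * (n // d)``; homopolymers are
    the ``d = 1`` case.
    """
    _check_alphabet(motif)
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def _rotations(seq: str) -> list[str]:
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def canonical_motif(motif: str) -> str:
    """Canonical representative of ``motif``'s equivalence class.

    The class of a motif contains every cyclic rotation of the motif and of
    its reverse complement; the canonical representative is the
    lexicographically smallest member.  The map is idempotent and constant
    on each class.

    Raises
    ------
    NonPrimitiveMotifError
        If the motif is a power of a shorter string (including
        homopolymers), which are not valid SSR motifs.
    """
    if not is_primitive(motif):
        raise NonPrimitiveMotifError(
            f"{motif!r} is not a primitive motif"
        )
    return min(_rotations(motif) + _rotations(reverse_complement(motif)))


def motif_class_members(motif: str) -> frozenset[str]:
    """All motifs equivalent to ``motif`` under rotation + revcomp."""
    if not is_primitive(motif):
        raise NonPrimitiveMotifError(f"{motif!r} is not a primitive motif")
    return frozenset(_rotations(motif) + _rotations(reverse_complement(motif)))


@dataclass(frozen=True)
class MotifClass:
    """One equivalence class of repeat motifs.

    Attributes
    ----------
    canonical : str
        Lexicographically smallest member; the class label.
    k : int
        Common motif length of all members.
    members : frozenset[str]
        Every motif in the class (closed under cyclic rotation and
        reverse complementation).
    """

    canonical: str
    k: int
    members: frozenset[str]

    def __contains__(self, motif: str) -> bool:
        return motif in self.members


def enumerate_motif_classes(k: int) -> list[MotifClass]:
    """All motif classes of unit length ``k``, sorted by canonical label.

    Partitions the primitive length-``k`` strings over A/C/G/T into
    disjoint classes; e.g. there are 4 dinucleotide and 10 trinucleotide
    classes.
    """
    if not MIN_MOTIF_LEN <= k <= MAX_MOTIF_LEN:
        raise ValueError(
            f"motif length must be in [{MIN_MOTIF_LEN}, {MAX_MOTIF_LEN}], got {k}"
        )
    groups: dict[str, set[str]] = {}
    for tup in product("ACGT", repeat=k):
        m = "".join(tup)
        if not is_primitive(m):
            continue
        groups.setdefault(canonical_motif(m), set()).add(m)
    return [
        MotifClass(canonical=c, k=k, members=frozenset(ms))
        for c, ms in sorted(groups.items())
    ]
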