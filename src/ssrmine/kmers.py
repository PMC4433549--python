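"""K-mer spectra, genome-size estimation and repeat k-mer extraction.

A k-mer spectrum — the histogram of canonical k-mer multiplicities over a
read set — carries a survey-sequencing genome-size estimate: sequencing a
genome of size G to depth c places the bulk of genomic k-mers in a peak
near multiplicity c, while sequencing errors pile up at multiplicity ~1.
Cutting the spectrum at the first local minimum between the two and
dividing the remaining k-mer instances by the peak multiplicity yields G.
K-mers far above the peak (50x and beyond by default) belong to the
repetitive fraction of the genome.

K-mers are counted on the canonical strand (the lexicographic minimum of
a k-mer and its reverse complement) and packed 2 bits per base, so
``k <= 31`` fits one unsigned 64-bit word and counting is vectorized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .qc import ReadRecord

DEFAULT_K = 21
DEFAULT_REPEAT_MIN = 50

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = "ACGT"


class SpectrumEstimationError(RuntimeError):
    """The spectrum does not support a genome-size estimate."""


@dataclass(frozen=True)
class KmerCounts:
    """Multiplicity of every distinct canonical k-mer.

    ``codes`` are 2-bit-packed canonical k-mers (sorted ascending),
    ``counts`` their multiplicities.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray

    def decode(self, code: int) -> str:
        out = []
        for shift in range(2 * (self.k - 1), -1, -2):
            out.append(_CODE_BASE[(code >> shift) & 3])
        return "".join(out)

    def as_dict(self) -> dict[str, int]:
        return {self.decode(int(c)): int(n) for c, n in zip(self.codes, self.counts)}


@dataclass(frozen=True)
class KmerSpectrum:
    """Histogram: multiplicity m -> number of distinct k-mers seen m times."""

    k: int
    histogram: dict[int, int]
    total_kmer_instances: int

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.histogram):
            raise ValueError("multiplicities must be >= 1")
        total = sum(m * n for m, n in self.histogram.items())
        if total != self.total_kmer_instances:
            raise ValueError(
                f"histogram sums to {total} instances, not {self.total_kmer_instances}"
            )


@dataclass(frozen=True)
class GenomeSizeEstimate:
    size_bp: float
    coverage_peak: int
    error_cutoff: int

    def __post_init__(self) -> None:
        if self.error_cutoff >= self.coverage_peak:
            raise ValueError("error cutoff must lie below the coverage peak")


def _as_sequences(reads: Iterable[ReadRecord | str]) -> list[str]:
    return [r.sequence if isinstance(r, ReadRecord) else r for r in reads]


def kmer_counts(reads: Iterable[ReadRecord | str], k: int = DEFAULT_K) -> KmerCounts:
    """Exact canonical k-mer counts; k-mers containing N are skipped."""
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    seqs = _as_sequences(reads)
    if not seqs or max(map(len, seqs)) < k:
        raise ValueError(f"no read is as long as k = {k}")
    # One buffer with a sentinel (code 4) between reads; windows containing
    # a sentinel or an N are dropped via a cumulative bad-base count.
    buf = ("#".join(seqs)).encode("ascii")
    arr = _BASE_CODE[np.frombuffer(buf, dtype=np.uint8)]
    bad = (arr >= 4).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    n_win = len(arr) - k + 1
    valid = (cbad[k:] - cbad[:-k]) == 0  # length n_win
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    rpowers = powers[::-1].copy()
    chunks = []
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    comp = np.where(arr < 4, 3 - arr, arr).astype(np.uint8)
    cwindows = np.lib.stride_tricks.sliding_window_view(comp, k)
    step = 1 << 20
    for lo in range(0, n_win, step):
        hi = min(lo + step, n_win)
        sel = valid[lo:hi]
        if not sel.any():
            continue
        w = windows[lo:hi][sel].astype(np.uint64)
        fwd = w @ powers
        rev = cwindows[lo:hi][sel].astype(np.uint64) @ rpowers
        chunks.append(np.minimum(fwd, rev))
    if not chunks:
        codes = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    else:
        codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerCounts(k=k, codes=codes, counts=counts)


def kmer_spectrum(reads: Iterable[ReadRecord | str], k: int = DEFAULT_K) -> KmerSpectrum:
    """Spectrum of canonical k-mer multiplicities over the read set."""
    counts = kmer_counts(reads, k)
    return spectrum_from_counts(counts)


def spectrum_from_counts(counts: KmerCounts) -> KmerSpectrum:
    hist_arr = np.bincount(counts.counts)
    histogram = {int(m): int(n) for m, n in enumerate(hist_arr) if m >= 1 and n > 0}
    return KmerSpectrum(
        k=counts.k,
        histogram=histogram,
        total_kmer_instances=int(counts.counts.sum()),
    )


def estimate_genome_size(spectrum: KmerSpectrum) -> GenomeSizeEstimate:
    """Genome size from the error-cutoff / coverage-peak heuristic.

    The histogram is smoothed with a 3-wide moving average; the error
    cutoff is the first local minimum of the smoothed curve, the coverage
    peak the (unsmoothed) mode at or above the cutoff, and the size is
    the number of k-mer instances at or above the cutoff divided by the
    peak multiplicity.  Error-free spectra (no error peak at m = 1) have
    no local minimum: a cutoff of 0 is used with a warning.  A monotone
    decreasing spectrum has no coverage peak and raises
    :class:`SpectrumEstimationError`.
    """
    if not spectrum.histogram:
        raise SpectrumEstimationError("empty spectrum")
    mmax = max(spectrum.histogram)
    h = np.zeros(mmax + 2, dtype=float)
    for m, n in spectrum.histogram.items():
        h[m] = n
    s = np.convolve(h, np.ones(3) / 3.0, mode="same")
    cutoff = None
    for m in range(2, mmax + 1):
        if s[m] < s[m - 1] and s[m] <= s[m + 1]:
            cutoff = m
            break
    if cutoff is None:
        monotone = all(h[m] >= h[m + 1] for m in range(1, mmax + 1))
        if mmax >= 2 and monotone and h[1] > h[mmax]:
            raise SpectrumEstimationError(
                "monotone decreasing spectrum: no coverage peak separable from errors"
            )
        warnings.warn(
            "no error/coverage local minimum found; using the whole spectrum "
            "(error-free data?)",
            stacklevel=2,
        )
        cutoff = 0
    # mode of the smoothed curve (robust to off-by-one sampling noise in a
    # flat Poisson-like peak); ties break to the larger raw count
    lo = max(cutoff, 1)
    peak = max(range(lo, mmax + 1), key=lambda m: (s[m], h[m]))
    if peak == cutoff:  # degenerate: mode sits on the minimum itself
        peak = max(range(cutoff + 1, mmax + 1), key=lambda m: (s[m], h[m]))
    # Sub-integer peak by mean-shift: iterate the centroid of a ~2-sigma
    # window recentred on itself.  The discrete mode alone quantizes the
    # size estimate by up to 1/peak (a Poisson peak at integer depth has
    # two tied modes), and a fixed window centred on the mode inherits
    # that bias; recentring converges to the local mean irrespective of
    # which integer the mode landed on.
    refined = float(peak)
    for _ in range(50):
        half = 2.0 * math.sqrt(refined)
        a = max(lo, math.ceil(refined - half))
        b = min(mmax, math.floor(refined + half))
        weight = h[a : b + 1].sum()
        if weight <= 0:
            break
        new = float(np.arange(a, b + 1) @ h[a : b + 1]) / weight
        if abs(new - refined) < 1e-9:
            refined = new
            break
        refined = new
    instances = sum(m * n for m, n in spectrum.histogram.items() if m >= cutoff)
    return GenomeSizeEstimate(
        size_bp=instances / refined, coverage_peak=peak, error_cutoff=cutoff
    )


def extract_repeat_kmers(
    counts: KmerCounts, min_multiplicity: int = DEFAULT_REPEAT_MIN
) -> tuple[set[str], float]:
    """K-mers at or above ``min_multiplicity`` and their instance fraction.

    Returns the decoded repeat k-mer set and the fraction of all counted
    k-mer instances they account for (0.0 on an empty count set).
    """
    total = int(counts.counts.sum())
    mask = counts.counts >= min_multiplicity
    kmers = {counts.decode(int(c)) for c in counts.codes[mask]}
    fraction = float(counts.counts[mask].sum()) / total if total else 0.0
    return kmers, fraction
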