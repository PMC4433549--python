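"""Marker-panel model and summary statistics.

Models a published SSR marker panel — one row per marker with primer
pair, repeat-motif string, allele count, allele size range, quality grade,
observed heterozygosity and cross-species amplification calls — and
computes the panel summaries: unit-length class partition, allele-count
statistics, mean observed heterozygosity, cross-species transfer tallies
and the 2x2 chi-square enrichment test comparing polymorphism rates.

Motif-string grammar: one or more components ``(UNIT)n``; adjacent
components are a *compound* repeat (``(TC)10(AGCG)5``); a suffix
``,(m)`` repeats the previous unit with a new count, denoting a *broken*
repeat (``(ATC)7,(8)``).

The packaged 46-marker panel is available through
:func:`load_packaged_panel`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats as _stats

from .motif import is_primitive

PANEL_RESOURCE = "table1_markers.tsv"

CALL_HET = "het"
CALL_HOM = "hom"
CALL_HET_OOR = "het_out_of_range"
CALL_NO_AMPL = "no_ampl"
CALL_NOT_TESTED = "not_tested"
_VALID_CALLS = {CALL_HET, CALL_HOM, CALL_HET_OOR, CALL_NO_AMPL, CALL_NOT_TESTED}

UNIT_CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

_COMPONENT_RE = re.compile(r"\(([ACGT]+)\)(\d+)|,\((\d+)\)")


class MarkerParseError(ValueError):
    """A panel row failed validation; message names the offending row."""


@dataclass(frozen=True)
class MotifComponent:
    unit: str
    count: int
    broken: bool = False  # continuation of the previous unit after a break


def parse_motif_string(text: str) -> tuple[MotifComponent, ...]:
    """Parse a motif string like ``(TTC)16``, ``(TC)10(AGCG)5`` or
    ``(ATC)7,(8)`` into its components."""
    components: list[MotifComponent] = []
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _COMPONENT_RE.match(text, pos)
        if m is None:
            raise MarkerParseError(f"malformed motif string {text!r} at offset {pos}")
        if m.group(1) is not None:
            unit, count = m.group(1), int(m.group(2))
            components.append(MotifComponent(unit=unit, count=count))
        else:
            if not components:
                raise MarkerParseError(
                    f"broken suffix with no preceding unit in {text!r}"
                )
            count = int(m.group(3))
            components.append(
                MotifComponent(unit=components[-1].unit, count=count, broken=True)
            )
        pos = m.end()
    for comp in components:
        if not is_primitive(comp.unit):
            raise MarkerParseError(
                f"unit {comp.unit!r} in {text!r} is not a primitive motif"
            )
        if comp.count < 2:
            raise MarkerParseError(f"repeat count < 2 in {text!r}")
    return tuple(components)


def format_motif_string(components: Sequence[MotifComponent]) -> str:
    parts = []
    for comp in components:
        parts.append(f",({comp.count})" if comp.broken else f"({comp.unit}){comp.count}")
    return "".join(parts)


@dataclass(frozen=True)
class MarkerRecord:
    """One row of a marker panel."""

    name: str
    forward_primer: str
    reverse_primer: str
    motif_string: str
    allele_count: int
    size_min: int
    size_max: int
    quality_grade: int
    observed_het: float
    cross_species: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size_min > self.size_max:
            raise MarkerParseError(f"{self.name}: size range inverted")
        if not 0.0 <= self.observed_het <= 1.0:
            raise MarkerParseError(f"{self.name}: Ho outside [0, 1]")
        if self.allele_count < 1:
            raise MarkerParseError(f"{self.name}: allele count < 1")
        for sp, call in self.cross_species.items():
            if call not in _VALID_CALLS:
                raise MarkerParseError(f"{self.name}: unknown call {call!r} for {sp}")

    @property
    def components(self) -> tuple[MotifComponent, ...]:
        return parse_motif_string(self.motif_string)


def parse_marker_table(source: str | Path) -> list[MarkerRecord]:
    """Read a TSV marker table (``#`` comment lines allowed)."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    required = {
        "name", "forward_primer", "reverse_primer", "motif",
        "allele_count", "size_min", "size_max", "quality", "ho",
    }
    missing = required - set(df.columns)
    if missing:
        raise MarkerParseError(f"missing columns: {sorted(missing)}")
    species_cols = [c for c in df.columns if c not in required]
    records = []
    for _, row in df.iterrows():
        name = row["name"]
        try:
            parse_motif_string(row["motif"])
            rec = MarkerRecord(
                name=name,
                forward_primer=row["forward_primer"],
                reverse_primer=row["reverse_primer"],
                motif_string=row["motif"].strip(),
                allele_count=int(row["allele_count"]),
                size_min=int(row["size_min"]),
                size_max=int(row["size_max"]),
                quality_grade=int(row["quality"]),
                observed_het=float(row["ho"]),
                cross_species={sp: str(row[sp]).strip() for sp in species_cols},
            )
        except MarkerParseError as exc:
            raise MarkerParseError(f"row {name}: {exc}") from exc
        records.append(rec)
    return records


def write_marker_table(records: Sequence[MarkerRecord], path: str | Path) -> None:
    species = sorted({sp for r in records for sp in r.cross_species})
    rows = []
    for r in records:
        row = {
            "name": r.name,
            "forward_primer": r.forward_primer,
            "reverse_primer": r.reverse_primer,
            "motif": r.motif_string,
            "allele_count": r.allele_count,
            "size_min": r.size_min,
            "size_max": r.size_max,
            "quality": r.quality_grade,
            "ho": r.observed_het,
        }
        row.update({sp: r.cross_species.get(sp, CALL_NOT_TESTED) for sp in species})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_packaged_panel() -> list[MarkerRecord]:
    """The packaged 46-marker B. papyrifera panel."""
    with resources.as_file(
        resources.files("ssrmine.data").joinpath(PANEL_RESOURCE)
    ) as path:
        return parse_marker_table(path)


# ---------------------------------------------------------------------------
# Summaries


def classify_marker(record: MarkerRecord) -> str:
    """Unit-length class (di/tri/tetra/penta/hexa) of a marker.

    Compound markers classify by their *longest* unit, so a
    ``(TC)10(AGCG)5`` marker is a tetranucleotide marker; broken
    components inherit their unit.  The class is invariant under motif
    canonicalization since it depends only on unit length.
    """
    k = max(len(c.unit) for c in record.components)
    return UNIT_CLASS_NAMES[k]


def class_counts(records: Iterable[MarkerRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        cls = classify_marker(rec)
        counts[cls] = counts.get(cls, 0) + 1
    return counts


def allele_stats(records: Sequence[MarkerRecord]) -> tuple[int, int, float]:
    """(min, max, mean-to-2-decimals) of the allele-count column."""
    if not records:
        raise ValueError("allele_stats requires at least one record")
    counts = [r.allele_count for r in records]
    return min(counts), max(counts), round(sum(counts) / len(counts), 2)


def observed_het(genotypes: Sequence[Optional[tuple[int, int]]]) -> float:
    """Ho of one locus: heterozygous / non-missing individuals."""
    scored = [g for g in genotypes if g is not None]
    if not scored:
        raise ValueError("no scored genotypes at this locus")
    het = sum(1 for a, b in scored if a != b)
    return het / len(scored)


def mean_observed_het(records: Sequence[MarkerRecord]) -> float:
    """Panel mean of the Ho column, to 2 decimals (all rows included)."""
    if not records:
        raise ValueError("mean_observed_het requires at least one record")
    return round(sum(r.observed_het for r in records) / len(records), 2)


def read_genotype_matrix(source: str | Path) -> dict[str, list[Optional[tuple[int, int]]]]:
    """Individuals x loci genotype TSV with paired allele columns.

    Columns come in pairs ``<locus>.1`` / ``<locus>.2`` holding allele
    lengths in bp; empty cells are missing data.  Returns a mapping
    locus -> per-individual (allele1, allele2) or ``None``.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    loci = sorted({c[:-2] for c in df.columns if c.endswith(".1")})
    out: dict[str, list[Optional[tuple[int, int]]]] = {}
    for locus in loci:
        col = []
        for a, b in zip(df[f"{locus}.1"], df[f"{locus}.2"]):
            col.append(None if pd.isna(a) or pd.isna(b) else (int(a), int(b)))
        out[locus] = col
    return out


def cross_species_summary(
    records: Sequence[MarkerRecord], species: str
) -> dict[str, int]:
    """Transfer tallies for one species column.

    ``het`` counts heterozygous calls including out-of-range ones — two
    distinct alleles are direct evidence of polymorphism, whatever the
    size range — giving the lower bound on transferably polymorphic
    markers.  ``tested`` is all markers minus the untested ones.
    """
    if not records or any(species not in r.cross_species for r in records):
        raise KeyError(f"species {species!r} not present in all records")
    calls = [r.cross_species[species] for r in records]
    het = sum(1 for c in calls if c in (CALL_HET, CALL_HET_OOR))
    hom = sum(1 for c in calls if c == CALL_HOM)
    no_ampl = sum(1 for c in calls if c == CALL_NO_AMPL)
    not_tested = sum(1 for c in calls if c == CALL_NOT_TESTED)
    return {
        "het": het,
        "hom": hom,
        "no_ampl": no_ampl,
        "not_tested": not_tested,
        "tested": len(calls) - not_tested,
        "polymorphic_lower_bound": het,
    }


def chi_square_2x2(
    a: int, b: int, c: int, d: int, method: str = "pearson"
) -> tuple[float, int, float]:
    """2x2 contingency test on [[a, b], [c, d]].

    ``method``: ``pearson`` (chi-square without continuity correction,
    the default), ``yates`` (with correction) or ``fisher`` (exact;
    statistic is the odds ratio and df reported as 0).  Returns
    (statistic, df, p).
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("cells must be non-negative integers")
    table = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("2x2 table has a zero margin")
    if method == "pearson":
        res = _stats.chi2_contingency(table, correction=False)
        return float(res.statistic), 1, float(res.pvalue)
    if method == "yates":
        res = _stats.chi2_contingency(table, correction=True)
        return float(res.statistic), 1, float(res.pvalue)
    if method == "fisher":
        odds, p = _stats.fisher_exact(table)
        return float(odds), 0, float(p)
    raise ValueError(f"unknown method {method!r}")


def summarize_panel(records: Sequence[MarkerRecord]) -> dict:
    """Full JSON-ready panel report."""
    lo, hi, mean = allele_stats(records)
    species = sorted({sp for r in records for sp in r.cross_species})
    return {
        "n_markers": len(records),
        "class_counts": class_counts(records),
        "allele_count_min": lo,
        "allele_count_max": hi,
        "allele_count_mean": mean,
        "mean_observed_het": mean_observed_het(records),
        "cross_species": {
            sp: cross_species_summary(records, sp) for sp in species
        },
    }
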