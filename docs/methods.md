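# Methods

This note documents the models and procedures `ssrmine` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
show.

## Motif algebra

SSR motifs are equivalence classes of primitive 2–6 bp strings under two
symmetries: cyclic rotation (a tandem array of `TGG` read one base later
is an array of `GGT`) and reverse complementation (the same tract on the
opposite strand).  The canonical representative is the lexicographically
smallest member, which reproduces the conventional class labels (`AAG`,
`AAT`, `AC`, …).  Primitivity (not a power of a shorter string) excludes
homopolymers and prevents double-reporting a dinucleotide tract as a
tetranucleotide.  Exhaustive enumeration gives 4, 10, 33, 102 and 350
classes for k = 2…6; these counts are verified in the tests against an
independent brute-force closure.

## Read QC

Filters run cheap-first per read — length ≥ 50 nt, N count ≤ 1, mean
Phred ≥ 25, then DUST — and every dropped read is accounted to exactly
one reason.  FASTQ is assumed Phred+33.

**DUST.** The low-complexity score treats the whole read as one window:
with w overlapping triplets and per-triplet counts c_t, score =
100 · Σ C(c_t, 2) / C(w, 2).  All-distinct triplets score 0, a
homopolymer scores 100, and a pure dinucleotide repeat of length 100
scores ≈ 49; the default removal threshold is 7.  A consequence worth
knowing: reads consisting mostly of a long SSR tract are themselves
low-complexity and are removed — tract lengths beyond roughly a third of
the read length start approaching the threshold, which bounds the
repeat lengths that survive to the mining stage.

**Duplicate removal** keeps the first occurrence of each exact sequence
(for pairs, the ordered concatenation of both mates); no prefix or
near-duplicate collapsing.

**Pair merging.** The two mates of a short fragment overlap at their 3'
ends; merging reconstructs the fragment as a super-read.  Among
admissible overlaps (≥ 10 nt, mismatch rate ≤ 0.1) the fewest-mismatch
overlap wins, longest on ties.  When several overlaps tie at *different*
lengths the fragment length is genuinely undecidable from the pair —
the characteristic case is a fragment whose middle lies in a repeat
tract, where a unit-shifted overlap also matches perfectly.  Merging
such a pair silently deletes or duplicates repeat units, planting
stutter-like length artifacts precisely at the loci whose lengths the
pipeline later measures, so ambiguous pairs are left unmerged by default
(`merge_reject_ambiguous`).  Consensus bases in the overlap take the
higher-quality call.

## SSR scanning

For each unit length k the scanner finds maximal runs of the
periodicity predicate s[i] = s[i+k] (N never matches), truncates each
run to whole units anchored at the run start, and keeps tracts meeting
the per-k unit minima — 6 units for dinucleotides, 4 for tri- and
tetranucleotides, 3 for penta- and hexanucleotides.  Only perfect tracts
are reported; a single interrupting base splits a tract in two (the
read is then classified *broken* if the canonical motifs agree,
*compound* if they differ, with no maximum-gap restriction at read
scale).  Overlapping candidates of different unit lengths are resolved
deterministically: most bases covered wins, then the shorter motif,
then the leftmost.  Coordinates are 0-based half-open.  Density is
reported as kilobases per locus to one decimal.

## Primer design and PALs

A locus is a *potentially amplifiable locus* (PAL) when both flanks on
its read admit a primer under the constraint set: length 18–27 nt
(optimum 20), Tm 57–63 °C (optimum 60), GC 20–80 %, mononucleotide runs
≤ 4, primers outside the tract, product within a configurable size
range.  The default product range, 100–450 bp, brackets typical marker
allele sizes; for in-silico screening on ~170 nt merged reads a range
such as 60–160 bp is the appropriate configuration, since only products
wholly contained in a read are observable.  Dinucleotide loci are
excluded from design (stutter makes them hard to score on gels).

**Melting temperature** uses the unified nearest-neighbor
thermodynamic parameters with terminal-initiation terms, a symmetry
correction for self-complementary oligos and the 0.368·(N−1)·ln[Na+]
entropy salt correction, at 50 mM monovalent cation and 50 nM total
primer.  The tests cross-check it against an independent published
nearest-neighbor calculator to within 0.5 °C.

**Scoring.** Every admissible pair is scored by the summed deviation of
both primers from the optimal length and Tm plus a product-size penalty
(0.1 per bp), with ties broken to the leftmost forward primer and then
the smallest product.  The product term makes the designer prefer the
most compact admissible amplicon, which maximizes the number of reads
that can contain the product — the quantity the polymorphism pre-screen
depends on.

**Single-copy screening.** A primer that lands in more than one genomic
context amplifies unpredictably.  With only reads (no assembly), the
screen demands context consistency: every exact occurrence of a primer
across the read set (both strands) must agree on the up-to-25 nt of
sequence immediately *outside* the amplicon.  The outward side is used
deliberately — inward of the primers lies the repeat tract, whose
length legitimately differs between the haplotypes of a heterozygous
individual, whereas a second genomic copy shows a conflicting outward
flank.  Consistency is prefix-agreement (occurrences near read ends see
truncated context and cannot create false conflicts).  The screen is
idempotent, and an empty read set screens nothing (PALs pass through
flagged as unscreened).  Exact matching is used throughout; one
consequence is brittleness to sequencing errors — an error inside any
occurrence's context window removes the locus — so screened recall
degrades with error rate while precision stays high.

## e-PCR polymorphism pre-screen

For each PAL, every read containing the forward primer followed 3' by
the reverse complement of the reverse primer yields one product-length
observation.  A locus is flagged *potentially polymorphic* when at least
two distinct lengths are each supported by ≥ 2 reads and some supported
pair differs by at least one repeat unit.  Both thresholds are explicit
choices: the two-read support guards against residual artifacts, and
the unit-multiple rule reflects that true SSR alleles differ by unit
multiples — sub-unit differences are noise.  Candidates are ranked
flagged-first (by allele spread, then support), giving the ordering in
which one would take loci to the bench.

## k-mer profiling and genome size

K-mers are counted on the canonical strand (lexicographic minimum of
k-mer and reverse complement), 2-bit packed, k ≤ 31, default k = 21.
The genome-size estimator follows the standard survey heuristic: smooth
the multiplicity histogram (3-wide moving average), cut at the first
local minimum separating the sequencing-error peak from the coverage
peak, locate the coverage peak, and divide the k-mer instances above the
cutoff by the peak depth.  Two numerical refinements matter at desk
scale: the mode is taken on the smoothed histogram (a Poisson-like peak
at integer depth has two tied modes, and raw argmax flips between them),
and the divisor is a sub-integer mean-shift refinement of the mode
(iterated centroid of a ~2σ window recentred on itself).  Without the
refinement the integer mode quantizes the estimate by up to 1/peak —
about 6 % at 16× k-mer depth — which is the difference between passing
and failing a 5 % recovery check.  Error-free spectra have no error
peak; the estimator then uses the whole spectrum with a warning.  A
monotone decreasing spectrum has no separable peak and raises an error.
Note that 100 nt reads carry k-mer depth (L−k+1)/L ≈ 0.8× the base
depth, so the peak of a 30× library sits near 24, not 30.

Repeat k-mers are those at or above a multiplicity threshold (default
50×); the module reports the set and the fraction of instances it
accounts for, but does not assemble repeat contigs or classify repeat
families.

## Synthetic data

The generator emulates a genome-survey experiment: an i.i.d. background
genome at a target GC (default 0.5), planted SSR loci, and uniform
paired-end reads (2 × 100 nt default geometry; fragment length normal
with configurable mean/sd; 50/50 haplotype sampling; i.i.d.
substitution errors with qualities encoding the error rate, Q40 cap).
Everything is deterministic under its seed.

Planting details that make validation exact: the background is
*sterilized* (chance tracts meeting the thresholds are broken by point
changes) so planted loci are the only loci; each insert is wrapped in
guard bases or designed flanks whose boundary bases cannot extend the
tract periodicity, so the scanner's maximal tracts coincide exactly
with the truth table.  The standard validation panel
(`default_het_hom_specs`) plants 10 heterozygous (two-unit allele gap)
and 10 homozygous tri- and tetranucleotide loci at 8 base units, each
between 20 nt rejection-sampled primer-admissible flank sites — the
loci are PAL-compatible by construction.  That choice is deliberate:
whether a random flank happens to admit a primer in the default Tm
window is a property of primer design, not of the pre-screen under
validation.

What the simulations do **not** model, and hence what passing tests do
not show about real data: indel sequencing errors (which would confound
length-based polymorphism calls), PCR stutter, position-dependent
quality profiles, GC-biased or otherwise non-uniform coverage, adapter
contamination, chloroplast/organellar contamination, and genome-wide
repeat families outside the planted loci.  Validation problem sizes are
chosen at desk scale — a 100 kb diploid at 30× for the pipeline
round-trip, 50–500 kb at 20–40× for genome-size recovery — as the
package's own standard test conditions.

## Marker-panel statistics

The packaged 46-marker table uses a small motif-string grammar:
`(UNIT)n` components, adjacency for compound repeats
(`(TC)10(AGCG)5`), and a `,(m)` suffix for a broken continuation of the
previous unit (`(ATC)7,(8)`).  Markers classify by their *longest* unit
(compound rule), the unique simple rule consistent with the panel's
printed 30/4/6/6 tri/tetra/penta/hexa partition.  Heterozygous
cross-species calls — including out-of-range ones — count as
polymorphism evidence, since two distinct alleles demonstrate
polymorphism regardless of size range.  Panel means are computed over
all rows including the one zero-heterozygosity marker.  Observed
heterozygosity from a genotype matrix is heterozygous over non-missing
individuals per locus.

Two documented discrepancies are reported as computed rather than
patched: the panel's allele-count column averages 4.91 (the source
abstract rounds differently to 4.8), and the 2×2 polymorphism-enrichment
comparison (37/82 randomly picked vs 9/13 pre-screened loci polymorphic)
gives Pearson χ² ≈ 2.61, p ≈ 0.11 — not significant by any standard 2×2
test, contrary to the originally reported significance.  The chi-square
operation defaults to Pearson without continuity correction, with Yates
and Fisher-exact variants selectable.

## Known limitations

Exact-match primer location (no mismatch or 3'-anchored model);
detection limited to perfect tracts (no imperfect-repeat alignment
scoring); single-copy screening is read-based and conservative under
sequencing errors; no assembly, no repeat-family classification, no
multi-individual genotype calling, and no Hardy–Weinberg or F-statistic
machinery — the panel module stops at the summary statistics above.
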