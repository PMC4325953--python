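# Methods

## Problem and scope

Chromosome-specific SSR markers must satisfy two conditions that ordinary
SSR markers do not: their flanking context must be unique on their own
chromosome (otherwise one primer pair amplifies several loci), and absent
from every other chromosome in the comparison set (otherwise the marker
cannot distinguish homologous chromosomes in a polyploid). `ssrkit`
implements detection, standardization, screening and primer design as a
single reproducible pipeline, validated end-to-end on synthetic genomes
with planted ground truth rather than on any particular assembly.

## Coordinates and formats

Internally every interval is 0-based half-open; every emitted file (TSV,
GFF3, truth tables) is 1-based inclusive. FASTA input is validated to the
alphabet {A, C, G, T, N}; N is retained in sequences, terminates repeat
runs, and never seeds or matches in alignment. Assemblies contain gap
characters, and treating them as wildcards would manufacture repeats and
alignments that do not exist.

## Motif standardization

A motif class is the orbit of a primitive motif (one that is not a
repetition of a shorter unit) under cyclic rotation and reverse
complement; its canonical name is the lexicographically smallest orbit
member. Primitivity is what makes the class counts per motif length —
2, 4, 10, 33, 102, 350 for lengths 1–6 — well defined: (AT)₂ is an AT
dinucleotide repeat, not a tetranucleotide one. The orbit of a primitive
k-mer has exactly k rotations, and the reverse-complement copy either
coincides with that rotation set or doubles it, so orbit size always
divides 2k. The test suite re-derives all counts by brute-force orbit
closure, independent of the canonicalization code.

## Detection

**Perfect mode** (the default everywhere): for each period p ≤ 6 the
scanner finds maximal stretches where s[i] = s[i+p]; each stretch is a
maximal tandem run, attributed to the primitive period of its leading
unit. Thresholds are ≥ 15 bp total length and ≥ 3 complete units; a
partial trailing unit counts toward length (`tail_bases`) but not toward
the unit count, and `unit_count = floor(length / period)`.

**Fixed-penalty mode**: every 3-unit perfect run seeds a greedy two-sided
extension against the periodic expectation anchored at the seed's frame;
a matching base scores +1, a mismatch −5, extension stops when the running
score falls 10 below its maximum (or at N or the sequence end), and the
record is trimmed to the maximum-score extent on each side. A record is
kept when score = matches − 5·mismatches ≥ 15. The penalty, x-drop and
minimum score are exposed on `SearchParams`; the defaults were chosen so
that a single interior mismatch (net −6 against +2·period recovered
context) is tolerated in long runs while double mismatches end a record,
and they are deliberately conservative because no published parameterization
of this search mode exists to pin them against. Imperfect records take the
motif of their seed, not of a majority vote over units.

**Overlap resolution** (both modes): candidates are ranked by score
(length, in perfect mode), then smaller start, then shorter period, and
selected greedily without overlap. The rule is stated explicitly because
any maximal-run definition makes, e.g., a mononucleotide run inside a
dinucleotide run ambiguous; this resolution is deterministic and is shared
verbatim by the independent regex oracle so that equivalence testing is
exact.

## Summary statistics

Densities divide counts by length in Mb with Mb = 10⁶ bases (this choice
reproduces 200,744 / 1,532 = 131.03 SSR/Mb); spacing is 1000/density in
kb. N-containing stretches count toward chromosome length, as densities
over assembled length do. Report rounding is half-up to 2 decimals;
internal values are never rounded. The mean repeat number of a period
class is the arithmetic mean of complete-unit counts.

## Specificity screening

Windows are tract plus up to 200 bp of flank per side, truncated (and
flagged) at chromosome ends. The search is ungapped seed-and-extend:
exact 12-mer seeds, +1 match / −2 mismatch, x-drop 20, one extension per
diagonal segment, best hit per target pair. Significance uses the
Karlin–Altschul expectation E = K·m·n·e^(−λS) with λ = 1.28 and K = 0.46,
the standard ungapped constants for +1/−2 scoring, m the query window
length and n the summed length of the current target set (the same-
chromosome windows, or the other-chromosome windows, per comparison
context). E-values are computed and compared in log10 space, since a
full-window identity at 430 bp gives E ≈ 10⁻²³⁰.

Seeds lying entirely within the repeat tract are suppressed on both query
and target sides: thousands of same-motif SSRs would otherwise seed
pairwise alignments whose only similarity is the repeat itself, and
specificity would collapse genome-wide. Alignments seeded in the flanks
may still extend through the tract. Window composition with or without the
tract is a flag (`include_tract`), defaulting to inclusion.

Within-chromosome repetition clusters windows by single linkage over hit
pairs at the threshold; a uniSSR is a singleton, the "repetitions" of a
repetitive SSR is its cluster size, and the per-chromosome statistics
report the mean over clusters of size ≥ 2 and the maximum. Cross-
chromosome screening then labels each SSR exhaustively and mutually
exclusively: `repetitive_within` (cluster size ≥ 2 on its own chromosome),
else `shared_across` (any hit at the threshold on another chromosome),
else `chromosome_specific`. Specific SSRs are by construction a subset of
uniSSRs. The default threshold is E ≤ 10⁻¹⁰⁰ for ~400 bp of flank; the
sensitivity range 10⁻¹⁰…10⁻¹⁵⁰ is exposed as `--e-threshold`, and the
specific count is monotonically non-decreasing as the threshold tightens.

Marker-to-chromosome assignment reuses the same search with whole
chromosomes as targets; a marker is assigned only when the best hit passes
the threshold and beats the runner-up chromosome by 10 orders of magnitude
in E-value (configurable), otherwise it is reported ambiguous — homologous
chromosomes typically produce two near-equal hits.

## Primer design

A transparent constraint filter with a deviation penalty replaces a full
thermodynamic design engine: every placement of a 17–27 bp forward primer
in the 5′ flank and reverse primer in the 3′ flank whose product covers
the tract and lies in 125–250 bp is enumerated; hard constraints are GC
20–80 %, nearest-neighbor Tm within 60 ± 3 °C, and no homopolymer run ≥ 5
(which also keeps primers out of the repeat tract). The returned pair
minimizes |len−20| + 0.5·|GC−50| + 1.0·|Tm−60| summed over both primers,
with ties broken by leftmost forward start then smallest product, so
output is deterministic. The ±3 °C window is a design choice: a hard
target of exactly 60 °C would reject every candidate. Tm uses the unified
nearest-neighbor table at 50 mM monovalent salt and 0.25 µM oligo, pinned
so results are reproducible to 0.01 °C; the test suite checks it against a
hand computation from the frozen thermodynamic table.
Self-complementarity, 3′-end stability and mispriming screens are out of
scope.

## Synthetic genomes and what passing tests show

The background model is i.i.d. bases at a configurable GC (default 35 %,
an AT-rich plant-like composition); plants are perfect or deliberately
mismatched tracts at fixed loci; duplicate blocks copy a window
(flank + tract + flank) to another locus at a chosen identity, with
mutations confined to flank bases so the copied SSR remains a perfect
repeat and the planted truth stays exact. Rejection resampling is local:
background within one flank width of a plant is redrawn until the scanner
reports exactly the planted tract there (for mismatched plants: nothing
extending outside the tract), so detection recall and precision on plants
are 100 % by construction. Background SSRs elsewhere are allowed, recorded
in the truth table post hoc by the independent regex scanner, and carry no
asserted specificity label.

The benchmark conditions used by tests and examples are three 12 kb
chromosomes, nine planted SSRs covering all three labels, and duplicate
identities of 95–100 % — sizes chosen so the exhaustive alignment oracle
remains feasible and the full suite runs in minutes on one core. An i.i.d.
background has no transposon families, GC isochores or compound repeats,
so passing these tests demonstrates correctness of the operations and
label logic, not performance on real repeat landscapes, where the
fraction of chromosome-specific SSRs will be far lower and single-linkage
clusters far larger.

## Numerical and degenerate-input choices

Empty sequences yield empty results, not errors; empty target sets yield
no hits; a window missing an entire flank yields no primer pair. Division
by zero (densities of zero-length sequences, frequencies of empty totals,
fold ratios against zero) raises. The E-value of a hit can underflow a
float for very long identities; all comparisons use log10(E) so thresholds
behave correctly at any score. Determinism is a contract throughout:
identical inputs, parameters and seeds give byte-identical outputs, with
provenance headers (version, parameters, input digests — no timestamps)
in every emitted table. FASTA has no comment syntax, so sequence outputs
carry no provenance header.

## Known limitations

Compound and interrupted SSRs are not merged into composite loci; motifs
longer than 6 bp are out of scope; the similarity search is ungapped, so
an indel between two otherwise identical flanks splits an alignment into
two diagonal segments and can understate similarity near the threshold;
the class counts and screening logic assume a fully resolved alphabet
(IUPAC ambiguity codes other than N are rejected at input).
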