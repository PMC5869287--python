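# Methods

This note records the models behind `haplodiag`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical conventions that matter for reproducing its outputs.

## Coverage model and the mode statistic

Short reads from a diploid genome sequenced to total depth *D* split evenly
between haplotypes. A contig carrying one haplotype of a separated region
therefore attracts ~*D*/2; a collapsed consensus contig attracts ~*D* (reads
from both alleles map to it, the divergent allele with a few mismatches).

**Mode coverage** summarises a contig's per-base depth histogram as the
center of the best-supported 3-wide window: among windows [d−1, d+1] for
centers d = 4, 5, 6, … (the lowest window covers depths 3–5), the center of
the window containing the most bases. Depths below 3 are never counted; a
contig whose bases all sit below 3× has no mode and is classed OTHER.
Windows slide by one center rather than tiling disjointly — the sliding
reading is the less lossy of the two readings consistent with the rule's
definition, and is disclosed here. Tie-break: tied windows prefer the one
whose *center bin* holds more bases, then the smaller center. The extra
first key is needed because a contig of exactly uniform depth d ties the
windows centered d−1, d, d+1; preferring the heavier center bin makes the
statistic report d itself, while pathological fully-symmetric ties still
resolve deterministically to the smaller center.

**Classes** are closed intervals: SEPARATED = [c−w, c+w], COLLAPSED =
[2c−w, 2c+w], defaults c = 18, w = 6 (matching a ~36× library). With
w < c/2 the windows cannot overlap; the implementation tests SEPARATED
first regardless. AUTO estimation sets c to the span-weighted modal mode
across contigs and w = round(c/3) — a generalisation for libraries at other
depths; FIXED reproduces the reference behaviour.

**Genome size.** With fraction *h* of assembled bases in the SEPARATED
class, those bases represent each genomic position twice, so
haploid_fraction = h/2 + (1 − h) and G = S × haploid_fraction. *h* uses the
total assembly span as denominator; undefined-mode contigs can only dilute
*h*, never enter the numerator.

Depth counts the aligned mate spans of concordant BEST_ONE pairs (pileup
convention), not the inferred fragment gap.

## Mapping

The internal mapper is substitution-only, by design: the synthetic data is
substitution-only (below), and real-data users bring SAM/BAM/PAF from a
production aligner, which `ingest_alignments` normalises (SAM POS → 0-based;
secondary records count toward multiplicity; supplementary records are
dropped; PAF is ingested as single-end).

Candidates come from exact k-mer seeds (default k = 13, seeds every k bases
plus one flush with the read end, both strands), verified end-to-end by
mismatch count. Seeds occurring more than 64 times in the reference are
treated as repeat noise and skipped. Three modes:

- `BEST_ONE` — single minimum-mismatch concordant placement per pair, ties
  broken by a seeded RNG (the depth substrate).
- `BEST_K` (preset `best4`) — up to 4 best placements; at the truncation
  boundary the tie group is shuffled with the seeded RNG before the cut,
  mirroring how a capped aligner samples equals (the paired-contig
  substrate). "Mapped exactly twice" is operationalised as exactly two
  reported concordant placements under this mode.
- `ALL_EXACT` — every zero-mismatch placement, uncapped. Here the seed
  scheme is lossless (an exact occurrence shares every seed), so output
  equals brute-force substring search; the test suite asserts this
  equivalence against an independent string-search oracle.

Concordance requires both mates on one contig, FR orientation, and fragment
length within bounds (default 50–1200 bp). Default mismatch tolerance is 18
per 150-bp mate (12%): haplotype counterparts at the heterozygosity levels
of interest diverge ~5–10%, and the PC statistic depends on reads from one
haplotype also placing on the other. The choice trades specificity for
counterpart sensitivity and is configurable.

k = 13 balances seed sensitivity at ~7% divergence (12 seeds per 150-bp
mate; the chance that all seeds are broken is <1%) against index size and
random-hit rate (4^13 ≈ 6.7e7 ≫ the genome sizes the package targets).

## Paired contigs

A read pair contributes to the counterpart count of contigs (A, B) iff it
has exactly two concordant placements, one on each. Same-contig doubles are
tallied separately (internal repeats) and never feed PCs. Detection keeps
pairs with shared count ≥ threshold: absolute 10 000 by default (the
fidelity setting for gigabase-scale data), or `density_per_kb ×
min(span_A, span_B)/1000` — the density option (default suggestion
4.5 pairs/kb) exists solely so megabase-scale synthetic genomes exercise
detection; it is not derivable from the reference analysis.

Intra-PC similarity is anchor-based, not full dynamic programming: k-mers
(k = 21) unique in both contigs, longest colinear chain per strand (the
better strand wins), thinned to non-overlapping anchors, merged into blocks
while consecutive anchor gaps stay ≤ 500 bp. Identity = matched columns /
aligned columns, counting anchors plus gap-free comparison of equal-length
inter-anchor gaps; unequal gaps contribute nothing aligned. On
substitution-only data this estimator tracks true divergence to within a
percentage point (asserted in tests); with indels it under-reports
alignment, which is the accepted cost of avoiding quadratic alignment.

Walk extraction is a disclosed heuristic (the underlying notion is
qualitative): an edge is TILING when each contig extends ≥ 5 kb beyond the
alignment footprint on exactly one side and the sides oppose in the aligned
frame; walks are vertex-disjoint simple paths grown greedily from the
heaviest TILING edge, extending each end toward the heaviest incident
TILING edge. Reported walk span is the summed span of member contigs.

## Ortholog duplication

Hits are grouped per gene; the crosstab bins instance counts 1, 2, 3, 4,
5–8 (counts above 8 join the last bin, which does not occur in the
reference data) against: genes touching / confined to each coverage class,
and instance-level class totals. The association test builds the 2×2
[exactly-2 vs other] × [all-instances-on-SEPARATED vs not] and computes a
two-sided Fisher exact p by summing hypergeometric probabilities ≤ the
observed table's, in exact integer arithmetic (ties are decided exactly,
not by float comparison; scipy's implementation serves as an independent
cross-check in the tests). Sidedness is a package choice — two-sided —
immaterial at the effect sizes of interest. Odds ratios apply a 0.5
continuity correction when a cell is zero; a degenerate margin returns
p = 1 with a warning.

Missing-gene triage (genes on exactly one contig of a PC) applies, in
precedence order: COVERAGE_ELEVATED if locus mean depth ≥ 1.5× the contig
mode; CONTIG_END if the locus lies outside the partner-alignment footprint
within 10 kb of its boundary; FRAGMENTARY if the partner carries a partial
hit covering < 50% of the gene; else CLEAN_LOSS. The three thresholds are
package inventions encoding checks that are qualitative in the reference
analysis, and are configurable.

## Chromosomal quotient

Contigs are hard-masked (masked bases become unindexable), tiled into
1 000-bp spans from position 0 (a terminal tile survives if ≥ 500 bp), and
female/male ALL_EXACT alignment counts are assigned to the span containing
the alignment *start* — start-assignment keeps counts additive across
tiles. CQ = female/male is reported when the span is not fully masked and
male count ≥ `min_male` (default 10); the floor guards 0/0 and low-count
artifacts and is settable to 1 to reproduce an unguarded quotient.
Male-specific means CQ < 0.01. Swapping the sexed read sets maps CQ → 1/CQ
on every span reporting under both orderings.

## Expression

RPKM = count × 1e9 / (length × total mapped reads), per isoform, no gene
consolidation, at most one placement per read. The denominator is reads
mapped to the transcript set, not total sequenced — the package's
resolution of an ambiguous convention, disclosed here. Expressed: RPKM ≥ 1.
Highly expressed: ≥ multiplier × mean RPKM of expressed isoforms
(multiplier 2; a mean of 32 puts the threshold at 64). RPKM values are used
unrounded throughout. Family verdicts: ABSENT (no member expressed),
NOMINAL (best member below twice the expressed threshold — "RPKM ≈ 1"
territory), EXPRESSED otherwise; the NOMINAL band is a package invention
encoding the barely-detected case.

## Host subtraction

Stage 1 removes single-end reads with ≥ 1 end-to-end placement on the
transcript set; stage 2 maps survivors to the genome. Mismatch tolerance
defaults to 2 per 150-bp read — stringency for subtraction is otherwise
unspecified, and 2 keeps error-free host reads removable while foreign
random sequence survives. Counts are exact integers and conserve the input;
"downstream workload" is reported as the remaining fraction (never
wall-clock). Stage fractions count unique reads, not alignment events.
Taxon assignment ingests a BLAST tabular file (the search itself is out of
scope): best hit per query by bitscore, then lower e-value, then
lexicographic subject.

## Synthetic data generator

What it emulates: a diploid genome whose haplotype B derives from a uniform
random haplotype A by per-locus substitution, with ~5.7% genome-wide SNV
heterozygosity concentrated so a configurable fraction of 10-kb loci
(default 0.8) exceeds the 2% separation threshold; an assembler that emits
both haplotype segments for each maximal run of separated loci (named
`c{chrom}r{run}a/b` and recorded as truth counterpart pairs) and haplotype
A verbatim for collapsed runs; paired 2×150 reads at total depth 36 over
the haploid span (so ~18 per haplotype), fragment 350 ± 30 bp — 350 rather
than the 270 of the emulated library so mates never overlap; 270 is
configurable for fidelity runs; allele-specific gene loss (a lost allele's
interval is overwritten with unrelated sequence); a male-limited locus
(a unique span present on one haplotype, locus-aligned, replacing rather
than inserting sequence so coordinates stay aligned); and long-tailed
transcript abundance with a zero-inflated set for silent families.

Key conventions:

- **Substitutions only.** Both haplotypes keep identical coordinates, so
  every truth table is positional; indel realism is deliberately excluded.
- **Rate calibration.** Low-divergence loci draw rates in (0.1, 0.75) ×
  separation threshold; high loci draw around the value that makes the
  genome-wide mean equal the heterozygosity target, then are rescaled so it
  does exactly; the only sampling noise left is binomial per base. An
  unreachable combination (e.g. a target too low to keep separated loci
  above the threshold) raises rather than silently degrading.
- **Realized classification.** The emulated assembler classifies loci by
  *realized* divergence, so a gene loss that pushes a low-divergence locus
  over the threshold separates it — as a real assembler would. Reported SNV
  heterozygosity excludes loss and M-locus spans (it is a substitution
  measure; structural overwrites are tracked separately).
- **Expression calibration.** Abundances are exp(σZ) with σ chosen by a
  deterministic grid search so the expected mean RPKM of expressed
  transcripts matches the target; counts are multinomial. The target is
  attainable only down to ~1e9/ΣL (all-expressed uniform profile) and up to
  the long-tail limit of the grid; out-of-range targets warn and use the
  closest attainable value.
- **Sex.** FEMALE read sets reject fragments overlapping the M-locus on its
  haplotype; MALE and unsexed sets sample everything.

What it does **not** emulate — and hence what passing tests do not show
about real data: indels and structural variants (beyond gene-loss
overwrites), assembler chimerism and consensus error, GC and
fragment-length bias, base-quality structure, repeat landscapes (real
repeat masks must be supplied for CQ on real data), and sequencing of a
mixed or passaged cell population.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at 1 Mb haploid scale
(36× depth, ~120 k pairs, ~46 contigs) for parameter recovery, 200–600 kb
for sex and triage recovery, and 10 k reads for subtraction — sizes chosen
so each property has comfortable statistical margin while the whole suite
runs in well under a minute on one core. Recovery margins at those sizes:
contig-class accuracy ≥ 95% (observed 100%), separated fraction within
±0.05 (observed exact to two decimals), genome size within ±5% (observed
<1%), PC detection exact against truth.

All randomness flows from explicit integer seeds; the pipeline derives one
child seed per stage from the master seed and a fixed stage index, so
disabling a stage never perturbs another and reruns are bit-reproducible
(reports exclude timestamps for this reason). Exact rational arithmetic is
used where tie semantics matter (Fisher p); everything else is float64.

## Known limitations

- The mapper's seed-and-verify heuristic can miss a counterpart placement
  when local divergence is extreme (>12%); PC counts are then conservative.
- Anchor-based identity is undefined (reported 0) for contig pairs without
  shared unique k-mers, and under-reports aligned span in repeat-rich
  sequence.
- Walks depend on a greedy, vertex-disjoint heuristic; alternative walk
  decompositions can exist.
- AUTO coverage classes need a clear modal depth; skewed or shallow
  libraries should use FIXED with known centers.
- The CQ contrast between genome-wide and M-locus span fractions is
  meaningful only directionally on synthetic data; absolute fractions
  depend on the real repeat landscape and read sets.
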