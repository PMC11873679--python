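# Methods

## Anchors and coordinates

Genes are anchored at the transcription start site (TSS) and the translation
start (ATG). GFF3 coordinates are 1-based inclusive and are preserved on gene
records; all window arithmetic is 0-based half-open internally; user-facing
positions are signed offsets in bp with the anchor base at offset 0 and
windows covering the half-open interval `[lower, upper)` (default
⟨−1000, 1000⟩).

Species differ in how their annotations expose the anchors, so a species
profile selects the rule set:

- **TSS** (`tss_rule=five_prime_utr`): the 5′-most coordinate of the 5′-most
  `five_prime_UTR` feature of the representative transcript (minimum start on
  `+`, maximum end on `−`). Annotations without usable 5′UTRs
  (`tss_rule=none`) restrict analyses to the ATG anchor.
- **ATG**: either the `start_codon` feature (both the `start_codon` and
  `start codon` spellings are accepted; 5′-most if several), the CDS min/max
  boundary per strand (`cds_minmax`, for annotations that carry only CDS
  features), or the 5′ end of the CDS segment whose feature ID ends in `.1`
  (`cds_dot1`), falling back to `cds_minmax` with a warning when no such
  segment exists.

When a gene has several transcripts, the representative transcript is the one
carrying the features the active rules need, ties broken by transcript ID
ascending — a deterministic choice where annotation conventions give no
canonical one. Genes without a resolvable ATG (non-coding genes,
pseudogenes) are excluded as `noStartCodonFound`. Genes with an ATG but no
5′UTR are *retained* for ATG-anchored analyses and logged as
`noFivePrimeUtrFound`; they are dropped (from numerator and denominator) only
in TSS-anchored profiles. Genes missing from the TPM table are excluded as
`noTpmDataFound`. The log's hard-exclusion list therefore satisfies
`n_valid + |excluded| = n_total`, while retained TSS-less genes are reported
separately (and appear in the TSV under the same literal reason string).

Windows at contig edges are clipped, not discarded: the gene remains in all
denominators, and truncation flags are recorded. For minus-strand genes the
contig slice is reverse-complemented before return, so every window reads
5′→3′ on the coding strand; a strand-symmetry test asserts that mirroring the
entire fixture (reverse-complement every contig, flip strands and
coordinates) reproduces byte-identical windows.

## Expression selection

TPM tables arrive precomputed; the only normalisation applied is arithmetic
replicate averaging (NA = missing replicate; a stage value is the mean of the
replicates present). Composite stages (e.g. early pollen = mean of UNM and
BCP; late pollen = mean of TCP and MPG) are element-wise means of member
columns.

The "P-th percentile" of a stage is a **cumulative-transcript prefix**: genes
are ranked by TPM (descending for `highest`), and the selection is the
shortest prefix whose TPM sum reaches P% of the stage's total TPM, including
the boundary gene that crosses the threshold. This is deliberately not a
per-gene TPM quantile: it selects the genes that jointly account for P% of
the stage's transcript mass, which is the quantity that makes narrow
expression programs (late pollen stages) visibly smaller than broad ones.
Ties are broken by gene ID ascending, so selections are invariant to input
row order. Zero-TPM genes belong to the universe (the reported denominator)
but can never enter a `highest` prefix; `lowest` ranks ascending and applies
the same prefix rule. A stage with zero total TPM yields an empty selection
with a warning rather than an error.

## Motif model and scanning

Motif families are one or more IUPAC strings compiled position-by-position to
character classes (`W → [AT]`, `N → [ACGT]`, …), with the reverse complement
of each variant compiled alongside via the degenerate-complement table
(R↔Y, K↔M, B↔V, D↔H; W, S, N self-complementary). Scanning is
**overlap-permitting** (a lookahead pattern reports every start position):
non-overlapping regex semantics would materially undercount runs of short
motifs such as `AAAG`. Each occurrence is recorded at the signed offset of
its middle, `start + ⌊(len−1)/2⌋` — left-of-center for even lengths, a fixed
documented convention chosen so histograms are deterministic. A start
position matched by both orientations of the same variant (degenerate
palindromes like `CANNTG`) counts once, attributed to the forward strand, to
avoid double-counting; distinct variants hitting the same start each count.
Non-ACGT bases in the genome (assembly-gap `N` runs) never satisfy any motif
position, including motif `N` — conservative handling of gaps. Matching is
case-insensitive over A/C/G/T.

Offsets are tallied into buckets of width `b` (default 30 bp): bucket `k`
covers `[k·b, (k+1)·b)` and is labelled by its left edge; offsets outside the
window interval are discarded, so bucket totals conserve match counts.

## Profiles, units and export

A profile series is computed per (stage selection, motif, anchor):
`mode=genes` counts each gene at most once per bucket, `mode=motifs` counts
every occurrence. Percentages divide by a **constant** denominator — the
number of selected genes that carry the anchor — so clipped contig-edge
windows do not create position-dependent denominators; the count of genes
dropped for lacking the anchor is reported with each series. The `all` stage
is the same computation over every valid TPM-matched gene regardless of
expression.

XLSX workbooks carry one sheet per series plus a long-format aggregate sheet
(series, bucket, count, percent, n_selected); TSV mirrors exist for both
exporters. Workbook timestamps are pinned to a fixed epoch so repeated runs
produce identical payloads. Gene-list export takes an offset range, widens it
to the enclosing buckets, and emits the union of genes with a match in those
buckets along with their TPM in every stage of the expression matrix. Plots
draw one curve per series at bucket left edges, with a settable y-axis
maximum; mixing percent and count series in one plot is an error.

## Synthetic data generator

The generator emulates the data model the pipeline consumes: multi-contig
genomes of uniform-random bases (GC fraction configurable, 0.5 by default so
background match rates have a closed form), genes laid out in independent
slots (1100 bp flanks, 5′UTR length uniform on a configurable range, 300 bp
CDS opening with a literal ATG), strands drawn per gene, optional fractions
of non-coding genes and UTR-less genes to exercise the validation log, and
sparse lognormal TPMs per stage (a stage expresses `n_expressed` genes,
log-mean 2.0, log-σ 1.0, the rest zero). A narrow stage (few expressed
genes) therefore yields a much smaller 90th-percentile selection than a
broad one, reproducing the qualitative structure of real developmental
series where late male-gametophyte stages express far fewer genes than
leaves or seedlings.

Planting replaces bases (never inserts, so coordinates stay fixed) at an
exact middle-adjusted offset from TSS or ATG in a stated fraction of the
genes selected in a stage; stage selection inside the generator uses its own
small cumulative-prefix routine, independent of the library's selection code.
Degenerate positions are realized with the seeded generator; overlapping
plants are re-drawn a bounded number of times and incompatible overlaps are a
hard error. Every planted instance is recorded in a truth table. One integer
seed drives named substreams (layout, sequence, TPM, planting), so identical
seeds give byte-identical FASTA/GFF3/TSV outputs.

The closed-form background model gives the expected matches per start
position as, per variant, `P(forward) + P(reverse) − P(both at same start)`
under independent bases — the subtraction mirrors the scanner's palindrome
dedup rule. What the fixtures do **not** emulate: real base composition
(isochores, codon usage, CpG structure), realistic 5′UTR length
distributions, introns, overlapping genes or alternative transcripts. Tests
passing on fixtures therefore establish the correctness of the mechanics
(anchoring, orientation, counting, selection, export), not biological claims
about any real genome.

## Problem sizes and numerical choices

The test suite and the acceptance script run on fixtures of 20–150 genes
(~0.4 Mb of sequence) and 100–200 kb of background sequence for rate
calibration, sizes at which every check is exact or has comfortably small
sampling error; the scanner itself streams gene windows one at a time via
random-access FASTA slicing, so large assemblies never require whole-genome
in-memory scans. Percentile thresholds subtract a `1e-9` relative guard so
`P=100` is immune to floating-point accumulation; all sorting uses explicit
(value, gene ID) keys; background-rate comparisons use three binomial
standard errors, a deliberate approximation that ignores the mild variance
inflation from self-overlapping motifs.

## Known limitations

- One representative transcript per gene; isoform-level 5′UTR variation is
  not profiled.
- The percent unit in `mode=motifs` still divides by the number of selected
  genes (occurrences per 100 genes), which can exceed 100 for dense motifs.
- GFF3 files are taken as-is (malformed lines are skipped and counted); no
  annotation repair or normalisation is attempted.
- Stage names in intermediate-FASTA headers must not contain spaces, commas
  or colons.
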