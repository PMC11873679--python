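# golem-profiler

Positional profiling of cis-regulatory DNA motifs around gene anchors in
annotated genomes.

Short cis-regulatory elements (CREs) such as the TATA-box or the pollen
LAT52/POLLEN1 motif act at characteristic distances from the transcription
start site (TSS) or the translation start (ATG). This package answers the
question a promoter biologist actually asks: *among the genes most (or least)
transcribed in a given tissue or developmental stage, what fraction carries a
motif at each position around the TSS or ATG, and how does that compare with
the genome-wide background?*

Given a genome (FASTA), its annotation (GFF3) and a gene × stage TPM table,
the pipeline:

1. anchors each protein-coding gene at its TSS (5′ end of the annotated
   5′UTR) and ATG (first base of the start codon), with species-profile rules
   for annotations that lack `start_codon` features (CDS min/max per strand,
   or the `CDS…​.1` segment), and writes a validation log
   (`noStartCodonFound`, `noFivePrimeUtrFound`, `noTpmDataFound`);
2. selects genes per stage by the cumulative-transcript percentile — the
   *smallest* set of top-expressed genes whose summed TPM reaches P% of the
   stage total (default P = 90) — or by top/bottom N, plus a genome-wide
   `all` baseline;
3. scans IUPAC motif families (forward and reverse complement, all
   overlapping occurrences) in oriented windows around the anchor, records
   each occurrence at the signed offset of its middle
   (`start + ⌊(len−1)/2⌋`), and tallies offsets into fixed-width buckets
   (default 30 bp) over a user interval (default ⟨−1000, 1000⟩ bp);
4. exports per-stage profile series — percent of genes with the motif per
   bucket, or raw motif counts — as XLSX/TSV, per-bucket gene lists with
   cross-stage TPMs, PNG plots, and a FASTA-compatible intermediate file with
   anchors and TPMs in the headers.

A built-in catalogue covers 16 plant promoter elements (TATA-box `TATAWA`,
POLLEN1_LeLAT52 `AGAAA`, MEF2 `CTAWWWWTAG`, DOF core `AAAG`, E-box `CANNTG`,
the TC element family `TCTTCT/TTTCTT/TTCTTC`, …); arbitrary degenerate motifs
can be supplied as `NAME=VARIANT1,VARIANT2`.

A deterministic synthetic-data generator (`golem.fixtures` / `golem
fixtures`) builds multi-contig genomes with genes on both strands, variable
or absent 5′UTRs, non-coding genes, sparse stage-dependent TPM models and
motifs planted at exact offsets, together with a truth table — so the whole
pipeline is testable without downloading any reference data.

## Worked example

Generate a 40-gene synthetic dataset in which the MEF2 motif (`CTAWWWWTAG`)
is planted 80 bp upstream of the TSS in 60% of the genes selected (90th
percentile) in a narrow "late" stage, then profile it:

```sh
golem fixtures --n-genes 40 --seed 1 --stage late:8 --stage leaf:30 \
      --plant "CTAWWWWTAG:TSS:-80:late:0.6" --out demo

golem run --genome demo/genome.fa --gff3 demo/annotation.gff3 \
      --tpm demo/tpm.tsv --motif MEF2 --anchor TSS \
      --interval -1000:1000 --bucket 30 --stages late,leaf,all \
      --percentile 90 --mode genes --unit percent --out demo/out
```

which prints

```
validated 40/40 genes (0 excluded, 0 without TSS)
stage late: selected 6/40 genes (highest, percentile=90.0)
stage leaf: selected 21/40 genes (highest, percentile=90.0)
```

and writes `demo/out/profiles.tsv`, whose bucket ⟨−90, −60) row reads

```
late|MEF2|TSS   -90   4   66.666667   6
leaf|MEF2|TSS   -90   3   14.285714   21
all|MEF2|TSS    -90   4   10.0        40
```

Read: 4 of the 6 late-selected genes (66.7%) carry MEF2 with its middle in
the bucket covering −80 bp — the planted signal — against a 10% genome-wide
baseline; the broad "leaf" selection sits near background, as it should,
because planting targeted late-selected genes only. `validation_log.tsv`
itemizes excluded genes; `genes.fa` is the intermediate FASTA whose headers
carry `tss=… atg=… strand=… tpm=stage:value,…` per valid gene.

The same analysis is available as a library (`parse_annotation`,
`select_percentile`, `compile_motif`, `compute_profile`, `export_series`) for
use in notebooks and pipelines; a YAML config file can replace all CLI flags
(`golem run --config run.yaml`).

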