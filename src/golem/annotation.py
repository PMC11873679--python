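"""Genome annotation parsing and anchor-window extraction.

Parses a genome (FASTA) together with its annotation (GFF3), determines the
two anchors used throughout the pipeline — the transcription start site (TSS,
5' end of the annotated 5'UTR) and the translation start (ATG, first base of
the start codon on the coding strand) — and extracts oriented sequence
windows around either anchor.  Genes that cannot be anchored are recorded in
a validation log under one of three literal reasons: ``noStartCodonFound``
(no resolvable ATG, e.g. non-protein-coding genes), ``noFivePrimeUtrFound``
(no annotated 5'UTR; the gene is retained for ATG-anchored analyses) and
``noTpmDataFound`` (no row in the expression table).

Coordinate conventions: GFF3 coordinates are 1-based inclusive and are kept
as such on :class:`GeneRecord`; all window arithmetic is done 0-based
half-open internally; user-facing offsets are signed base pairs with the
anchor base at offset 0, windows covering ``[lower, upper)``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SpeciesProfile",
    "GeneRecord",
    "ValidationLog",
    "WindowSpec",
    "Window",
    "AnchorUnavailableError",
    "WindowOutOfContigError",
    "ContigNotFoundError",
    "parse_annotation",
    "extract_window",
    "attach_windows",
    "match_tpm",
    "write_intermediate",
    "read_intermediate",
]

NO_START_CODON = "noStartCodonFound"
NO_FIVE_PRIME_UTR = "noFivePrimeUtrFound"
NO_TPM_DATA = "noTpmDataFound"

START_CODON_TYPES = ("start_codon", "start codon")


class AnchorUnavailableError(ValueError):
    """Requested anchor (TSS or ATG) is not defined for the gene."""


class WindowOutOfContigError(ValueError):
    """Requested window lies entirely outside the contig."""


class ContigNotFoundError(KeyError):
    """GFF3 references a contig absent from the FASTA."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Which GFF3 features define the TSS and ATG anchors for a species.

    ``tss_rule``: ``"five_prime_utr"`` (TSS = 5' end of the 5'UTR) or
    ``"none"`` (no TSS annotation; analyses are ATG-anchored only).
    ``atg_rule``: ``"start_codon_feature"`` (use the start_codon feature),
    ``"cds_minmax"`` (5'-most CDS boundary per strand) or ``"cds_dot1"``
    (the CDS segment whose ID ends in ``.1``, falling back to cds_minmax).
    ``id_attribute``: GFF3 attribute key carrying the gene identifier.
    """

    name: str = "default"
    tss_rule: str = "five_prime_utr"
    atg_rule: str = "start_codon_feature"
    id_attribute: str = "ID"

    def __post_init__(self) -> None:
        if self.tss_rule not in ("five_prime_utr", "none"):
            raise ValueError(f"unknown tss_rule: {self.tss_rule!r}")
        if self.atg_rule not in ("start_codon_feature", "cds_minmax", "cds_dot1"):
            raise ValueError(f"unknown atg_rule: {self.atg_rule!r}")


@dataclass
class GeneRecord:
    """One validated protein-coding gene with anchors and optional windows.

    ``tss`` and ``atg`` are 1-based genomic coordinates on ``contig``; ``atg``
    is the first base of the start codon on the coding strand.  ``window_tss``
    and ``window_atg`` are filled by :func:`attach_windows` and read 5'→3' on
    the coding strand.
    """

    gene_id: str
    contig: str
    strand: str
    atg: int
    tss: int | None = None
    window_tss: "Window | None" = None
    window_atg: "Window | None" = None
    tpm: dict[str, float] | None = None

    def anchor_coord(self, anchor: str) -> int | None:
        return self.tss if anchor == "TSS" else self.atg


@dataclass
class ValidationLog:
    """Per-gene exclusion reasons plus summary counts.

    ``excluded`` holds hard exclusions (the gene yields no record);
    ``tss_missing`` holds genes retained for ATG-anchored analyses but
    lacking a 5'UTR — written to the TSV with reason ``noFivePrimeUtrFound``.
    Invariant: ``n_valid + len({id for id, _ in excluded}) == n_total``.
    """

    excluded: list[tuple[str, str]] = field(default_factory=list)
    tss_missing: list[str] = field(default_factory=list)
    n_valid: int = 0
    n_total: int = 0
    n_malformed_lines: int = 0
    n_warnings: int = 0

    def exclude(self, gene_id: str, reason: str) -> None:
        self.excluded.append((gene_id, reason))

    def summary(self) -> str:
        return (
            f"# n_total={self.n_total}\tn_valid={self.n_valid}\t"
            f"n_excluded={len({g for g, _ in self.excluded})}\t"
            f"n_tss_missing={len(self.tss_missing)}\t"
            f"n_malformed_lines={self.n_malformed_lines}"
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\treason\n")
            for gid, reason in self.excluded:
                fh.write(f"{gid}\t{reason}\n")
            for gid in self.tss_missing:
                fh.write(f"{gid}\t{NO_FIVE_PRIME_UTR}\n")
            fh.write(self.summary() + "\n")


@dataclass(frozen=True)
class WindowSpec:
    """Anchored genomic interval ``[lower, upper)`` in signed bp, with bucket size."""

    anchor: str = "TSS"
    lower: int = -1000
    upper: int = 1000
    bucket_size: int = 30

    def __post_init__(self) -> None:
        if self.anchor not in ("TSS", "ATG"):
            raise ValueError(f"anchor must be 'TSS' or 'ATG', got {self.anchor!r}")
        if self.lower >= self.upper:
            raise ValueError("window lower bound must be < upper bound")
        if self.bucket_size < 1:
            raise ValueError("bucket size must be >= 1")

    def bucket_edges(self) -> list[int]:
        b = self.bucket_size
        k0 = math.floor(self.lower / b)
        k1 = math.floor((self.upper - 1) / b)
        return [k * b for k in range(k0, k1 + 1)]


@dataclass
class Window:
    """Oriented (coding-strand) sequence over signed offsets ``[lo, lo+len)``."""

    gene_id: str
    anchor: str
    seq: str
    lo: int
    truncated_left: bool = False
    truncated_right: bool = False

    def index_to_offset(self, i: int) -> int:
        if not 0 <= i < len(self.seq):
            raise IndexError(f"index {i} outside window of length {len(self.seq)}")
        return self.lo + i

    def offset_to_index(self, offset: int) -> int:
        i = offset - self.lo
        if not 0 <= i < len(self.seq):
            raise IndexError(f"offset {offset} outside window [{self.lo}, {self.lo + len(self.seq)})")
        return i


# ---------------------------------------------------------------------------
# genome access helpers (pyfaidx.Fasta or plain mapping contig -> sequence)

def _contig_seq_length(genome, contig: str) -> int:
    try:
        return len(genome[contig])
    except KeyError as exc:
        raise ContigNotFoundError(f"contig {contig!r} not found in genome FASTA") from exc


def _contig_slice(genome, contig: str, start: int, end: int) -> str:
    """0-based half-open forward-strand slice of a contig."""
    try:
        seg = genome[contig][start:end]
    except KeyError as exc:
        raise ContigNotFoundError(f"contig {contig!r} not found in genome FASTA") from exc
    return str(seg).upper()


def open_genome(fasta) -> Mapping[str, object]:
    """Return a random-access genome store from a path or pass through a mapping."""
    if isinstance(fasta, (str, Path)):
        import pyfaidx

        return pyfaidx.Fasta(str(fasta))
    return fasta  # mapping or already-open pyfaidx.Fasta


# ---------------------------------------------------------------------------
# GFF3 parsing

def _filter_gff3(text: str) -> tuple[str, int]:
    """Drop malformed GFF3 lines, returning cleaned text and a skip count."""
    kept: list[str] = []
    skipped = 0
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            kept.append(line)
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            skipped += 1
            continue
        try:
            int(cols[3]), int(cols[4])
        except ValueError:
            skipped += 1
            continue
        kept.append(line)
    return "\n".join(kept) + "\n", skipped


def _load_gff3_text(gff3) -> str:
    if isinstance(gff3, Path) or (isinstance(gff3, str) and "\n" not in gff3 and os.path.exists(gff3)):
        return Path(gff3).read_text()
    if isinstance(gff3, str):
        return gff3
    raise TypeError("gff3 must be a path or GFF3 text")


def _five_prime_coord(feature, strand: str, use_end: bool) -> int:
    return feature.end if use_end else feature.start


def _resolve_atg(db, transcript, strand: str, atg_rule: str, log: ValidationLog) -> int | None:
    if atg_rule == "start_codon_feature":
        codons = list(db.children(transcript, featuretype=START_CODON_TYPES))
        if not codons:
            return None
        # 5'-most start codon; first base on the coding strand
        if strand == "+":
            return min(f.start for f in codons)
        return max(f.end for f in codons)

    cds = list(db.children(transcript, featuretype="CDS"))
    if not cds:
        return None
    if atg_rule == "cds_dot1":
        dot1 = [f for f in cds if f.id and f.id.endswith(".1")]
        if dot1:
            cds = dot1
        else:
            log.n_warnings += 1  # fall back to cds_minmax
    if strand == "+":
        return min(f.start for f in cds)
    return max(f.end for f in cds)


def _resolve_tss(db, transcript, strand: str) -> int | None:
    utrs = list(db.children(transcript, featuretype="five_prime_UTR"))
    if not utrs:
        return None
    if strand == "+":
        return min(f.start for f in utrs)
    return max(f.end for f in utrs)


def _pick_transcript(db, gene, profile: SpeciesProfile):
    """Deterministic representative transcript: prefer one carrying the needed
    features, break ties by transcript ID (ascending)."""
    transcripts = sorted(
        (
            t
            for t in db.children(gene, level=1)
            if t.featuretype.endswith("RNA") or t.featuretype == "transcript"
        ),
        key=lambda t: t.id or "",
    )
    if not transcripts:
        return gene  # features (e.g. bare CDS) hang directly off the gene
    need_sc = profile.atg_rule == "start_codon_feature"

    def score(t) -> tuple[int, int]:
        if need_sc:
            has_atg = bool(list(db.children(t, featuretype=START_CODON_TYPES)))
        else:
            has_atg = bool(list(db.children(t, featuretype="CDS")))
        has_utr = bool(list(db.children(t, featuretype="five_prime_UTR")))
        return (int(has_atg), int(has_utr and profile.tss_rule == "five_prime_utr"))

    # max returns the first maximal element in iteration order; transcripts is
    # ID-sorted, so ties resolve to the lexicographically first transcript.
    return max(transcripts, key=score)


def parse_annotation(gff3, fasta, profile: SpeciesProfile) -> tuple[list[GeneRecord], ValidationLog]:
    """Parse GFF3 + FASTA into anchored gene records and a validation log.

    ``gff3`` may be a path or raw GFF3 text; ``fasta`` a path or a mapping
    ``contig -> sequence``.  One record is emitted per protein-coding gene
    with a resolvable ATG under the profile's ``atg_rule``; genes without one
    are excluded as ``noStartCodonFound``.  Under ``tss_rule='five_prime_utr'``
    genes lacking a 5'UTR are retained with ``tss=None`` and logged as
    ``noFivePrimeUtrFound``.
    """
    genome = open_genome(fasta)
    text, skipped = _filter_gff3(_load_gff3_text(gff3))
    log = ValidationLog(n_malformed_lines=skipped, n_warnings=skipped)
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return [], log
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by="start"):
        log.n_total += 1
        gid = gene.attributes.get(profile.id_attribute, [gene.id])[0]
        _contig_seq_length(genome, gene.seqid)  # hard error on unresolvable contig
        strand = gene.strand
        if strand not in ("+", "-"):
            log.exclude(gid, NO_START_CODON)
            continue
        transcript = _pick_transcript(db, gene, profile)
        atg = _resolve_atg(db, transcript, strand, profile.atg_rule, log)
        if atg is None:
            log.exclude(gid, NO_START_CODON)
            continue
        tss: int | None = None
        if profile.tss_rule == "five_prime_utr":
            tss = _resolve_tss(db, transcript, strand)
            if tss is not None:
                bad = (strand == "+" and tss > atg) or (strand == "-" and tss < atg)
                if bad:
                    tss = None
                    log.n_warnings += 1
            if tss is None:
                log.tss_missing.append(gid)
        records.append(GeneRecord(gene_id=gid, contig=gene.seqid, strand=strand, atg=atg, tss=tss))
        log.n_valid += 1
    return records, log


# ---------------------------------------------------------------------------
# window extraction

def extract_window(record: GeneRecord, genome, spec: WindowSpec) -> Window:
    """Extract the coding-strand sequence over offsets ``[lower, upper)``.

    Offset 0 is the anchor base; for minus-strand genes the contig slice is
    reverse-complemented so the returned string reads 5'→3' on the coding
    strand.  Windows are clipped at contig edges (truncation flags set); a
    window entirely off-contig raises :class:`WindowOutOfContigError`.
    """
    coord = record.anchor_coord(spec.anchor)
    if coord is None:
        raise AnchorUnavailableError(
            f"anchor {spec.anchor} unavailable for gene {record.gene_id}"
        )
    clen = _contig_seq_length(genome, record.contig)
    a = coord - 1  # 0-based anchor position
    if record.strand == "+":
        gstart, gend = a + spec.lower, a + spec.upper
    else:
        gstart, gend = a - spec.upper + 1, a - spec.lower + 1
    cstart, cend = max(0, gstart), min(clen, gend)
    if cstart >= cend:
        raise WindowOutOfContigError(
            f"window [{spec.lower},{spec.upper}) around {spec.anchor} of "
            f"{record.gene_id} lies outside contig {record.contig}"
        )
    seq = _contig_slice(genome, record.contig, cstart, cend)
    if record.strand == "+":
        lo = cstart - a
        trunc_left, trunc_right = cstart > gstart, cend < gend
    else:
        seq = str(Seq(seq).reverse_complement())
        lo = a - (cend - 1)
        trunc_left, trunc_right = cend < gend, cstart > gstart
    return Window(
        gene_id=record.gene_id,
        anchor=spec.anchor,
        seq=seq,
        lo=lo,
        truncated_left=trunc_left,
        truncated_right=trunc_right,
    )


def attach_windows(records: Iterable[GeneRecord], genome, spec: WindowSpec) -> None:
    """Populate ``window_tss`` / ``window_atg`` for the spec's anchor in place."""
    for rec in records:
        if rec.anchor_coord(spec.anchor) is None:
            continue
        win = extract_window(rec, genome, spec)
        if spec.anchor == "TSS":
            rec.window_tss = win
        else:
            rec.window_atg = win


# ---------------------------------------------------------------------------
# TPM matching and the FASTA-compatible intermediate file

def match_tpm(records: Sequence[GeneRecord], expression, log: ValidationLog) -> list[GeneRecord]:
    """Keep records with a TPM row; exclude the rest as ``noTpmDataFound``.

    Matched records get their per-stage TPM dict filled in.
    """
    known = set(expression.gene_ids)
    kept: list[GeneRecord] = []
    for rec in records:
        if rec.gene_id not in known:
            log.exclude(rec.gene_id, NO_TPM_DATA)
            if rec.gene_id in log.tss_missing:
                log.tss_missing.remove(rec.gene_id)
            log.n_valid -= 1
            continue
        rec.tpm = expression.gene_tpm(rec.gene_id)
        kept.append(rec)
    return kept


def _format_tpm(tpm: dict[str, float]) -> str:
    return ",".join(f"{stage}:{value!r}" for stage, value in tpm.items())


def write_intermediate(
    records: Sequence[GeneRecord],
    expression,
    path: str | os.PathLike,
    genome=None,
    spec: WindowSpec | None = None,
    log: ValidationLog | None = None,
) -> list[GeneRecord]:
    """Write one FASTA entry per valid, TPM-matched gene.

    Header: ``>gene_id tss=<int|NA> atg=<int> strand=<+|-> tpm=<stage>:<v>,...
    contig=<name>``.  The sequence is the oriented ATG window (extracted with
    ``spec`` if windows are not already attached).  Genes without a TPM row
    are excluded and logged as ``noTpmDataFound``.
    """
    log = log if log is not None else ValidationLog(n_valid=len(records), n_total=len(records))
    spec = spec or WindowSpec(anchor="ATG")
    kept = match_tpm(records, expression, log)
    entries = []
    for rec in kept:
        win = rec.window_atg
        if win is None:
            if genome is None:
                raise ValueError("windows not attached and no genome provided")
            win = extract_window(rec, genome, spec)
        tss_str = "NA" if rec.tss is None else str(rec.tss)
        desc = (
            f"tss={tss_str} atg={rec.atg} strand={rec.strand} "
            f"tpm={_format_tpm(rec.tpm or {})} contig={rec.contig}"
        )
        entries.append(SeqRecord(Seq(win.seq), id=rec.gene_id, description=desc))
    SeqIO.write(entries, str(path), "fasta")
    return kept


def read_intermediate(path: str | os.PathLike) -> list[GeneRecord]:
    """Read the intermediate FASTA back into gene records (windows as raw seq)."""
    out: list[GeneRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        fields = dict(tok.split("=", 1) for tok in entry.description.split()[1:])
        tpm: dict[str, float] = {}
        if fields.get("tpm"):
            for pair in fields["tpm"].split(","):
                stage, value = pair.split(":")
                tpm[stage] = float(value)
        tss = None if fields["tss"] == "NA" else int(fields["tss"])
        rec = GeneRecord(
            gene_id=entry.id,
            contig=fields.get("contig", ""),
            strand=fields["strand"],
            atg=int(fields["atg"]),
            tss=tss,
            tpm=tpm,
        )
        rec.window_atg = Window(gene_id=entry.id, anchor="ATG", seq=str(entry.seq), lo=0)
        out.append(rec)
    return out
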