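"""Deterministic synthetic genomes, annotations and TPM tables.

The generator builds a multi-contig genome of uniform-random bases (GC knob
provided) laid out as independent gene slots: upstream flank, optional 5'UTR
of bounded-uniform length, a CDS opening with a literal ATG, downstream
flank.  Genes land on both strands; a configurable fraction are non-coding
(gene + ncRNA features only) to exercise the validation log.  Per-stage TPMs
follow a sparse lognormal model — a stage expresses ``n_expressed`` genes and
leaves the rest at zero — which reproduces the qualitative structure of real
developmental series where late gametophyte stages express far fewer genes
than broad sporophyte tissues.

Motifs are *planted* by replacing bases (never inserting, so coordinates stay
fixed) at an exact middle-adjusted offset from TSS or ATG in a chosen
fraction of the genes selected in a stage, and every planted instance is
recorded in a truth table.  Stage-selected genes are determined by a small
self-contained cumulative-percentile routine so the generator stays
independent of the selection code it is used to test.

One integer seed drives everything through named numpy substreams; the same
seed yields byte-identical FASTA/GFF3/TSV outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .motifs import IUPAC, MotifPattern, reverse_complement

__all__ = [
    "StageModel",
    "PlantSpec",
    "FixtureSpec",
    "Fixture",
    "FixtureError",
    "generate",
    "make_background_rate",
    "percentile_prefix",
    "mirror_fixture",
    "random_sequence",
]


class FixtureError(RuntimeError):
    """Unsatisfiable fixture request (e.g. incompatible planting overlap)."""


@dataclass(frozen=True)
class StageModel:
    """Sparse lognormal TPM model for one stage."""

    n_expressed: int
    log_mean: float = 2.0
    log_sigma: float = 1.0


@dataclass(frozen=True)
class PlantSpec:
    """Plant ``motif`` at a middle-adjusted ``offset`` from ``anchor`` in a
    ``fraction`` of the genes selected in ``stage``."""

    motif: str  # IUPAC string
    anchor: str  # TSS | ATG
    offset: int
    stage: str
    fraction: float
    name: str = ""

    @property
    def motif_name(self) -> str:
        return self.name or self.motif


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int = 50
    n_contigs: int = 2
    strand_fraction: float = 0.5  # probability of the minus strand
    utr_length: tuple[int, int] = (20, 300)
    utr_absent_fraction: float = 0.0
    noncoding_fraction: float = 0.0
    planted: tuple[PlantSpec, ...] = ()
    tpm_model: dict[str, StageModel] = field(default_factory=dict)
    seed: int = 0
    gc: float = 0.5
    flank: int = 1100
    cds_length: int = 300
    spacer: int = 60
    replicates: int = 1
    selection_percentile: float = 90.0


def percentile_prefix(tpm: dict[str, float], percentile: float) -> set[str]:
    """Independent cumulative-transcript percentile selection (oracle form).

    Shortest prefix of genes ranked by (TPM desc, ID asc) whose summed TPM
    reaches ``percentile`` percent of the total.
    """
    total = sum(tpm.values())
    if total <= 0:
        return set()
    order = sorted(tpm, key=lambda g: (-tpm[g], g))
    target = percentile / 100.0 * total - 1e-9 * total
    out: set[str] = set()
    cum = 0.0
    for g in order:
        out.add(g)
        cum += tpm[g]
        if cum >= target:
            break
    return out


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


@dataclass
class Fixture:
    """In-memory fixture plus writers for the on-disk dialects."""

    spec: FixtureSpec
    genome: dict[str, str]
    gff3: str
    tpm: pd.DataFrame  # index gene_id, columns stages (or stage replicates)
    truth: pd.DataFrame  # gene_id, motif, anchor, offset, orientation, stage
    genes: dict[str, dict]  # gene_id -> {contig, strand, tss, atg, utr, coding}
    expressed: dict[str, set[str]]
    selected: dict[str, set[str]]
    replicate_map: dict[str, list[str]] | None = None

    @property
    def fasta_text(self) -> str:
        lines = []
        for contig in self.genome:
            lines.append(f">{contig}")
            seq = self.genome[contig]
            lines.extend(seq[i : i + 80] for i in range(0, len(seq), 80))
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "annotation.gff3",
            "tpm": outdir / "tpm.tsv",
            "truth": outdir / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["gff3"].write_text(self.gff3)
        self.tpm.to_csv(paths["tpm"], sep="\t", index_label="gene_id")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _realize(variant: str, fixed: dict[int, str], start: int, rng: np.random.Generator) -> str:
    """Draw a concrete ACGT realization of an IUPAC variant, honoring bases
    already fixed at overlapping positions; redraw a bounded number of times
    before declaring the overlap incompatible."""
    for _ in range(10):
        out = []
        ok = True
        for j, ch in enumerate(variant):
            classes = IUPAC[ch]
            pos = start + j
            if pos in fixed:
                if fixed[pos] in classes:
                    out.append(fixed[pos])
                else:
                    ok = False
                    break
            else:
                out.append(classes[rng.integers(len(classes))])
        if ok:
            return "".join(out)
    raise FixtureError(
        f"cannot plant {variant!r} at {start}: incompatible overlap with fixed bases"
    )


def generate(spec: FixtureSpec) -> Fixture:
    """Generate (FASTA, GFF3, TPM table, truth table) per the fixture spec."""
    if not 0 <= spec.strand_fraction <= 1:
        raise ValueError("strand_fraction must be in [0, 1]")
    for p in spec.planted:
        if not 0 <= p.fraction <= 1:
            raise ValueError("plant fraction must be in [0, 1]")

    rng_layout = np.random.default_rng([spec.seed, 1])
    rng_seq = np.random.default_rng([spec.seed, 2])
    rng_tpm = np.random.default_rng([spec.seed, 3])
    rng_plant = np.random.default_rng([spec.seed, 4])

    F, C = spec.flank, spec.cds_length
    gene_ids = [f"g{str(i + 1).zfill(4)}" for i in range(spec.n_genes)]

    # per-gene layout
    meta: dict[str, dict] = {}
    for i, gid in enumerate(gene_ids):
        coding = rng_layout.random() >= spec.noncoding_fraction
        utr = 0
        if rng_layout.random() >= spec.utr_absent_fraction:
            utr = int(rng_layout.integers(spec.utr_length[0], spec.utr_length[1] + 1))
        strand = "-" if rng_layout.random() < spec.strand_fraction else "+"
        meta[gid] = {
            "contig": f"chr{(i % spec.n_contigs) + 1}",
            "strand": strand,
            "utr": utr,
            "coding": coding,
            "slot_len": F + utr + C + F,
        }

    # TPM table (+ replicate columns when requested)
    coding_ids = [g for g in gene_ids if meta[g]["coding"]]
    base_tpm = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"), columns=list(spec.tpm_model))
    expressed: dict[str, set[str]] = {}
    for stage, model in spec.tpm_model.items():
        n = min(model.n_expressed, len(coding_ids))
        chosen = sorted(rng_tpm.choice(coding_ids, size=n, replace=False))
        expressed[stage] = set(chosen)
        base_tpm.loc[chosen, stage] = rng_tpm.lognormal(model.log_mean, model.log_sigma, size=n)
    replicate_map = None
    tpm_out = base_tpm
    if spec.replicates > 1:
        cols = {}
        replicate_map = {}
        for stage in base_tpm.columns:
            reps = [f"{stage}_r{r + 1}" for r in range(spec.replicates)]
            replicate_map[stage] = reps
            noise = rng_tpm.lognormal(0.0, 0.05, size=(len(base_tpm), spec.replicates))
            # keep the replicate mean equal to the base value
            noise = noise / noise.mean(axis=1, keepdims=True)
            for r, col in enumerate(reps):
                cols[col] = base_tpm[stage].to_numpy() * noise[:, r]
        tpm_out = pd.DataFrame(cols, index=base_tpm.index)

    selected = {
        stage: percentile_prefix(
            {g: float(v) for g, v in base_tpm[stage].items() if v > 0 or g in expressed[stage]},
            spec.selection_percentile,
        )
        for stage in base_tpm.columns
    }

    # planting plan: gene -> fixed bases in slot (coding-strand) coordinates
    fixed: dict[str, dict[int, str]] = {g: {} for g in gene_ids}
    for gid in coding_ids:
        u = meta[gid]["utr"]
        for j, b in enumerate("ATG"):
            fixed[gid][F + u + j] = b

    truth_rows = []
    for plant in spec.planted:
        k = len(plant.motif)
        mid = (k - 1) // 2
        pool = []
        for gid in sorted(selected.get(plant.stage, set())):
            m = meta[gid]
            if not m["coding"]:
                continue
            if plant.anchor == "TSS" and m["utr"] == 0:
                continue
            anchor_idx = F if plant.anchor == "TSS" else F + m["utr"]
            start = anchor_idx + plant.offset - mid
            if 0 <= start and start + k <= m["slot_len"]:
                pool.append((gid, start))
        count = int(round(plant.fraction * len(pool)))
        if count:
            idx = sorted(rng_plant.choice(len(pool), size=count, replace=False))
        else:
            idx = []
        for i in idx:
            gid, start = pool[i]
            bases = _realize(plant.motif, fixed[gid], start, rng_plant)
            for j, b in enumerate(bases):
                fixed[gid][start + j] = b
            truth_rows.append(
                {
                    "gene_id": gid,
                    "motif": plant.motif_name,
                    "anchor": plant.anchor,
                    "offset": plant.offset,
                    "orientation": "forward",
                    "stage": plant.stage,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "motif", "anchor", "offset", "orientation", "stage"]
    )

    # sequence assembly and GFF3 emission
    contig_parts: dict[str, list[str]] = {f"chr{c + 1}": [] for c in range(spec.n_contigs)}
    contig_pos: dict[str, int] = {c: 0 for c in contig_parts}
    gff_lines = ["##gff-version 3"]
    for gid in gene_ids:
        m = meta[gid]
        contig, strand, u, S = m["contig"], m["strand"], m["utr"], m["slot_len"]
        slot = random_sequence(rng_seq, S, spec.gc)
        for pos, b in fixed[gid].items():
            slot[pos] = b
        spacer = random_sequence(rng_seq, spec.spacer, spec.gc)
        p = contig_pos[contig]

        def span(a: int, b_: int) -> tuple[int, int]:
            """slot-coding [a, b) -> genomic 1-based inclusive (start, end)."""
            if strand == "+":
                return p + a + 1, p + b_
            return p + S - b_ + 1, p + S - a

        if strand == "-":
            slot_out = str(Seq("".join(slot)).reverse_complement())
        else:
            slot_out = "".join(slot)
        contig_parts[contig].append(slot_out)
        contig_parts[contig].append("".join(spacer))
        contig_pos[contig] += S + spec.spacer

        body_a = F if u > 0 else F + u
        body_b = F + u + C
        gs, ge = span(body_a, body_b)
        if m["coding"]:
            tid = f"{gid}.t1"
            gff_lines.append(
                f"{contig}\tsynth\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gid}"
            )
            gff_lines.append(
                f"{contig}\tsynth\tmRNA\t{gs}\t{ge}\t.\t{strand}\t.\tID={tid};Parent={gid}"
            )
            if u > 0:
                us, ue = span(F, F + u)
                gff_lines.append(
                    f"{contig}\tsynth\tfive_prime_UTR\t{us}\t{ue}\t.\t{strand}\t.\t"
                    f"ID={tid}.utr5;Parent={tid}"
                )
            cs, ce = span(F + u, F + u + C)
            gff_lines.append(
                f"{contig}\tsynth\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\tID={tid}.cds.1;Parent={tid}"
            )
            ss, se = span(F + u, F + u + 3)
            gff_lines.append(
                f"{contig}\tsynth\tstart_codon\t{ss}\t{se}\t.\t{strand}\t0\t"
                f"ID={tid}.sc;Parent={tid}"
            )
            # genomic anchor coordinates (1-based, first base on coding strand)
            m["tss"] = (p + F + 1 if strand == "+" else p + S - F) if u > 0 else None
            m["atg"] = p + F + u + 1 if strand == "+" else p + S - (F + u)
        else:
            tid = f"{gid}.t1"
            gff_lines.append(
                f"{contig}\tsynth\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gid}"
            )
            gff_lines.append(
                f"{contig}\tsynth\tncRNA\t{gs}\t{ge}\t.\t{strand}\t.\tID={tid};Parent={gid}"
            )
            m["tss"] = None
            m["atg"] = None

    genome = {c: "".join(parts) for c, parts in contig_parts.items()}
    return Fixture(
        spec=spec,
        genome=genome,
        gff3="\n".join(gff_lines) + "\n",
        tpm=tpm_out,
        truth=truth,
        genes=meta,
        expressed=expressed,
        selected=selected,
        replicate_map=replicate_map,
    )


def make_background_rate(motif: MotifPattern, gc: float = 0.5) -> float:
    """Expected matches per start position under an independent-base model.

    For each variant, forward and reverse-complement match probabilities are
    the products of per-position class probabilities; the same-start
    both-orientation overlap (degenerate palindromes) is subtracted so the
    rate matches the scanner's dedup rule.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}

    def class_prob(bases: set[str]) -> float:
        return sum(p[b] for b in bases)

    total = 0.0
    for v in motif.variants:
        fwd = [set(IUPAC[c]) for c in v]
        rev = [set(IUPAC[c]) for c in reverse_complement(v)]
        p_f = math.prod(class_prob(c) for c in fwd)
        p_r = math.prod(class_prob(c) for c in rev)
        p_both = math.prod(class_prob(cf & cr) for cf, cr in zip(fwd, rev))
        total += p_f + p_r - p_both
    return total


def mirror_fixture(genome: dict[str, str], gff3: str) -> tuple[dict[str, str], str]:
    """Reverse-complement every contig and flip all features/strands.

    Oriented anchor windows extracted from the mirrored fixture must be
    byte-identical to the originals (strand-symmetry invariant).
    """
    genome2 = {c: str(Seq(s).reverse_complement()) for c, s in genome.items()}
    lines = []
    for line in gff3.splitlines():
        if not line.strip() or line.startswith("#"):
            lines.append(line)
            continue
        cols = line.split("\t")
        L = len(genome[cols[0]])
        start, end = int(cols[3]), int(cols[4])
        cols[3], cols[4] = str(L - end + 1), str(L - start + 1)
        cols[6] = {"+": "-", "-": "+"}.get(cols[6], cols[6])
        lines.append("\t".join(cols))
    return genome2, "\n".join(lines) + "\n"
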