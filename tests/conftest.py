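"""Shared fixtures: a tiny hand-traced annotation and an independent
brute-force motif-scan oracle used to cross-check the regex scanner."""

from __future__ import annotations

import numpy as np
import pytest

# independent IUPAC tables (deliberately duplicated from the package so the
# oracle cannot inherit a bug from the code under test)
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def oracle_revcomp(motif: str) -> str:
    return "".join(ORACLE_COMPLEMENT[c] for c in reversed(motif))


def oracle_scan(seq: str, lo: int, variants) -> list[tuple[int, str, int]]:
    """Position-by-position sliding matcher over both orientations.

    Returns sorted (middle-adjusted offset, orientation, variant index)
    triples, deduplicating same-variant same-start double-orientation hits
    in favor of 'forward'.
    """
    seq = seq.upper()
    out = []
    for vi, v in enumerate(variants):
        k = len(v)
        rc = oracle_revcomp(v)
        for s in range(len(seq) - k + 1):
            kmer = seq[s : s + k]
            fwd = all(b in ORACLE_IUPAC[c] for b, c in zip(kmer, v))
            rev = all(b in ORACLE_IUPAC[c] for b, c in zip(kmer, rc))
            if fwd or rev:
                out.append((lo + s + (k - 1) // 2, "forward" if fwd else "reverse", vi))
    return sorted(out)


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


def random_motif(rng: np.random.Generator, max_len: int = 8) -> str:
    k = int(rng.integers(3, max_len + 1))
    letters = list(ORACLE_IUPAC)
    # bias toward concrete bases so matches actually occur
    probs = np.array([3.0] * 4 + [1.0] * 11)
    probs /= probs.sum()
    return "".join(rng.choice(letters, size=k, p=probs))


# ---------------------------------------------------------------------------
# hand-traced three-gene annotation on one 900 bp contig:
#   geneA: '+', five_prime_UTR 101-150, start_codon/CDS from 151
#   geneB: '-', CDS-only 501-560 (ATG at 560 under cds_minmax)
#   geneC: non-coding (gene + ncRNA), 701-800

THREE_GENE_GFF = "\n".join(
    [
        "##gff-version 3",
        "c1\ttest\tgene\t101\t450\t.\t+\t.\tID=geneA",
        "c1\ttest\tmRNA\t101\t450\t.\t+\t.\tID=geneA.1;Parent=geneA",
        "c1\ttest\tfive_prime_UTR\t101\t150\t.\t+\t.\tID=geneA.1.utr;Parent=geneA.1",
        "c1\ttest\tCDS\t151\t450\t.\t+\t0\tID=geneA.1.cds.1;Parent=geneA.1",
        "c1\ttest\tstart_codon\t151\t153\t.\t+\t0\tID=geneA.1.sc;Parent=geneA.1",
        "c1\ttest\tgene\t501\t560\t.\t-\t.\tID=geneB",
        "c1\ttest\tmRNA\t501\t560\t.\t-\t.\tID=geneB.1;Parent=geneB",
        "c1\ttest\tCDS\t501\t560\t.\t-\t0\tID=geneB.1.cds.1;Parent=geneB.1",
        "c1\ttest\tgene\t701\t800\t.\t+\t.\tID=geneC",
        "c1\ttest\tncRNA\t701\t800\t.\t+\t.\tID=geneC.1;Parent=geneC",
    ]
) + "\n"


@pytest.fixture(scope="session")
def tiny_genome() -> dict[str, str]:
    rng = np.random.default_rng(20240101)
    seq = list(random_dna(rng, 900))
    seq[150:153] = "ATG"  # geneA start codon, 1-based 151-153
    seq[557:560] = "CAT"  # geneB '-' start codon, coding ATG at 1-based 560
    return {"c1": "".join(seq)}


@pytest.fixture(scope="session")
def three_gene_gff() -> str:
    return THREE_GENE_GFF
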