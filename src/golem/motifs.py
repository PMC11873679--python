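"""IUPAC motif compilation and overlap-permitting window scanning.

A motif family is one or more IUPAC degenerate strings (e.g. the TC element
family TCTTCT / TTTCTT / TTCTTC).  Each variant is compiled to a forward and
a reverse-complement character-class pattern; scanning records *every*
occurrence, including overlapping ones, and reports the signed offset of the
motif middle (``start + floor((len-1)/2)``, left-of-center for even lengths)
relative to the window anchor.  A degenerate palindrome matching in both
orientations at the same start is reported once, as a forward match.

Non-ACGT bases in the genome (assembly-gap ``N`` runs and other ambiguity
letters) never satisfy any motif position, including motif ``N``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "IUPAC",
    "IUPAC_COMPLEMENT",
    "BUILTIN_MOTIFS",
    "MotifPattern",
    "MatchPosition",
    "reverse_complement",
    "compile_motif",
    "builtin_motif",
    "parse_motif_spec",
    "scan_window",
    "bucketize",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Built-in catalogue of plant promoter cis-regulatory elements.
BUILTIN_MOTIFS: dict[str, tuple[str, ...]] = {
    "TATA-box": ("TATAWA",),
    "pollen_Q-element": ("AGGTCA",),
    "POLLEN1_LeLAT52": ("AGAAA",),
    "CAAT-box": ("CCAATT",),
    "GTGA_motif": ("GTGA",),
    "ABRE": ("ACGTG",),
    "ARR10_core": ("GATY",),
    "E-box": ("CANNTG",),
    "G-box": ("CACGTG",),
    "GCC-box": ("GCCGCC",),
    "BR_response": ("CGTGYG",),
    "DOF_core": ("AAAG",),
    "DRE/CRT": ("CCGAC",),
    "I-box": ("GATAAG",),
    "TC_element": ("TCTTCT", "TTTCTT", "TTCTTC"),
    "MEF2": ("CTAWWWWTAG",),
}


def reverse_complement(seq: str) -> str:
    """Reverse complement extended over the full IUPAC alphabet."""
    comp = []
    for i, ch in enumerate(seq.upper()):
        try:
            comp.append(IUPAC_COMPLEMENT[ch])
        except KeyError:
            raise ValueError(f"invalid IUPAC character {ch!r} at position {i}") from None
    return "".join(reversed(comp))


def _class_pattern(variant: str) -> re.Pattern:
    """Compile one IUPAC variant to an overlap-permitting lookahead regex."""
    parts = []
    for ch in variant:
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class MotifPattern:
    """A named motif family compiled to forward and reverse-complement forms."""

    name: str
    variants: tuple[str, ...]
    compiled_forward: tuple[re.Pattern, ...]
    compiled_reverse: tuple[re.Pattern, ...]

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True, order=True)
class MatchPosition:
    """One motif occurrence at a middle-adjusted signed offset from the anchor."""

    gene_id: str
    anchor: str
    offset: int
    orientation: str
    variant_index: int


def compile_motif(name: str, variants) -> MotifPattern:
    """Compile IUPAC variants into a scannable :class:`MotifPattern`.

    Matching is case-insensitive over A/C/G/T (windows are uppercased before
    scanning); every other letter in the scanned sequence fails every
    position.
    """
    if isinstance(variants, str):
        variants = (variants,)
    variants = tuple(v.upper() for v in variants)
    if not variants:
        raise ValueError(f"motif {name!r} has no variants")
    for v in variants:
        if not v:
            raise ValueError(f"motif {name!r} has an empty variant")
        reverse_complement(v)  # validates the alphabet
    fwd = tuple(_class_pattern(v) for v in variants)
    rev = tuple(_class_pattern(reverse_complement(v)) for v in variants)
    return MotifPattern(name=name, variants=variants, compiled_forward=fwd, compiled_reverse=rev)


def builtin_motif(name: str) -> MotifPattern:
    return compile_motif(name, BUILTIN_MOTIFS[name])


def parse_motif_spec(spec: str) -> MotifPattern:
    """Parse ``NAME=VAR1,VAR2`` (or a built-in catalogue name) into a pattern."""
    if "=" in spec:
        name, _, rhs = spec.partition("=")
        return compile_motif(name.strip(), tuple(v.strip() for v in rhs.split(",") if v.strip()))
    return builtin_motif(spec.strip())


def scan_window(window, motif: MotifPattern) -> list[MatchPosition]:
    """Report every occurrence of the motif family in an oriented window.

    Overlapping occurrences are all counted.  The reported offset is the
    signed offset of ``start + floor((len-1)/2)``.  For a given variant, a
    start position matched by both orientations counts once (forward wins);
    distinct variants hitting the same start each count.
    """
    seq = window.seq.upper()
    out: list[MatchPosition] = []
    for vi, variant in enumerate(motif.variants):
        mid = (len(variant) - 1) // 2
        fstarts = {m.start() for m in motif.compiled_forward[vi].finditer(seq)}
        rstarts = {m.start() for m in motif.compiled_reverse[vi].finditer(seq)}
        for s in fstarts | rstarts:
            out.append(
                MatchPosition(
                    gene_id=window.gene_id,
                    anchor=window.anchor,
                    offset=window.lo + s + mid,
                    orientation="forward" if s in fstarts else "reverse",
                    variant_index=vi,
                )
            )
    out.sort()
    return out


def bucketize(matches, spec) -> dict[int, int]:
    """Tally middle-adjusted offsets into fixed-width buckets over ``[L, U)``.

    Bucket ``k`` is labeled by its left edge ``k*b`` and covers
    ``[k*b, (k+1)*b)``; offsets outside the window interval are discarded, so
    the histogram total equals the number of retained matches.
    """
    hist = {edge: 0 for edge in spec.bucket_edges()}
    b = spec.bucket_size
    for m in matches:
        off = m.offset if hasattr(m, "offset") else int(m)
        if spec.lower <= off < spec.upper:
            hist[math.floor(off / b) * b] += 1
    return hist
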