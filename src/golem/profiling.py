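"""Per-stage motif positional profiles, XLSX/TSV export and plotting.

A :class:`ProfileSeries` is the bucketized distribution of motif positions
relative to an anchor (TSS or ATG) over one gene selection.  ``mode='genes'``
counts each gene at most once per bucket (how many genes carry the motif
there); ``mode='motifs'`` counts every occurrence.  Percentages use a
constant denominator: the number of selected genes that carry the requested
anchor (genes lacking the anchor are dropped from numerator and denominator
alike, and the drop is reported).  Clipped contig-edge windows do not shrink
per-bucket denominators.
"""

from __future__ import annotations

import datetime
import math
import os
import re
import warnings
from dataclasses import dataclass, field

from openpyxl import Workbook, load_workbook

from .annotation import GeneRecord, WindowSpec, extract_window
from .expression import ExpressionMatrix, StageSelection
from .motifs import MotifPattern, bucketize, scan_window

__all__ = [
    "ProfileSeries",
    "compute_profile",
    "export_series",
    "export_series_tsv",
    "export_gene_list",
    "export_gene_list_tsv",
    "render_plot",
]

# fixed workbook timestamps so identical runs give identical payloads
_EPOCH = datetime.datetime(2000, 1, 1)


@dataclass
class ProfileSeries:
    """Bucketized motif distribution for one (stage, motif, anchor) series."""

    stage: str
    anchor: str
    spec: WindowSpec
    motif: str
    mode: str  # genes | motifs
    unit: str  # percent | count
    counts: dict[int, int] = field(default_factory=dict)
    per_bucket_genes: dict[int, set[str]] = field(default_factory=dict)
    n_selected: int = 0  # denominator: selected genes carrying the anchor
    n_universe: int = 0
    n_dropped_no_anchor: int = 0

    @property
    def label(self) -> str:
        return f"{self.stage}|{self.motif}|{self.anchor}"

    @property
    def values(self) -> dict[int, float]:
        if self.unit == "count":
            return {b: float(c) for b, c in self.counts.items()}
        if self.n_selected == 0:
            return {b: 0.0 for b in self.counts}
        return {b: 100.0 * c / self.n_selected for b, c in self.counts.items()}

    def percent(self, bucket: int) -> float:
        if self.n_selected == 0:
            return 0.0
        return 100.0 * self.counts[bucket] / self.n_selected

    @property
    def total_matches(self) -> int:
        return sum(self.counts.values())


def compute_profile(
    records,
    selection: StageSelection,
    motif: MotifPattern,
    spec: WindowSpec,
    mode: str = "genes",
    unit: str = "percent",
    genome=None,
) -> ProfileSeries:
    """Scan each selected gene's anchored window once and bucketize the hits.

    ``records`` is a mapping ``gene_id -> GeneRecord`` (or an iterable of
    records).  Windows are taken from the records if already attached for the
    spec's anchor, otherwise extracted from ``genome``.  Selected genes
    lacking the anchor are dropped from both the numerator and the percent
    denominator; the count of drops is reported on the series.
    """
    if mode not in ("genes", "motifs"):
        raise ValueError(f"mode must be 'genes' or 'motifs', got {mode!r}")
    if unit not in ("percent", "count"):
        raise ValueError(f"unit must be 'percent' or 'count', got {unit!r}")
    if not isinstance(records, dict):
        records = {r.gene_id: r for r in records}

    series = ProfileSeries(
        stage=selection.stage,
        anchor=spec.anchor,
        spec=spec,
        motif=motif.name,
        mode=mode,
        unit=unit,
        counts={b: 0 for b in spec.bucket_edges()},
        per_bucket_genes={b: set() for b in spec.bucket_edges()},
        n_universe=selection.n_universe,
    )
    if not selection.selected:
        warnings.warn(f"empty selection for stage {selection.stage!r}; all-zero series")
        return series

    b = spec.bucket_size
    n_with_anchor = 0
    for gene_id in sorted(selection.selected):
        rec: GeneRecord | None = records.get(gene_id)
        if rec is None or rec.anchor_coord(spec.anchor) is None:
            series.n_dropped_no_anchor += 1
            continue
        n_with_anchor += 1
        window = rec.window_tss if spec.anchor == "TSS" else rec.window_atg
        if window is None:
            if genome is None:
                raise ValueError(
                    f"gene {gene_id}: no attached {spec.anchor} window and no genome given"
                )
            window = extract_window(rec, genome, spec)
        matches = scan_window(window, motif)
        if mode == "motifs":
            hist = bucketize(matches, spec)
            for bucket, c in hist.items():
                series.counts[bucket] += c
        buckets_hit = set()
        for m in matches:
            if spec.lower <= m.offset < spec.upper:
                buckets_hit.add(math.floor(m.offset / b) * b)
        for bucket in buckets_hit:
            series.per_bucket_genes[bucket].add(gene_id)
    if mode == "genes":
        series.counts = {bk: len(gs) for bk, gs in series.per_bucket_genes.items()}
    series.n_selected = n_with_anchor
    return series


# ---------------------------------------------------------------------------
# XLSX / TSV export

_SHEET_BAD = re.compile(r"[\\/*?:\[\]]")


def _sheet_name(label: str, used: set[str]) -> str:
    base = _SHEET_BAD.sub("_", label)[:28] or "series"
    name, i = base, 1
    while name in used:
        name = f"{base}~{i}"
        i += 1
    used.add(name)
    return name


def _series_rows(series: ProfileSeries):
    for bucket in sorted(series.counts):
        yield bucket, series.counts[bucket], round(series.percent(bucket), 6), series.n_selected


def export_series(series_list, path: str | os.PathLike) -> None:
    """Write one sheet per series plus a long-format ``aggregate`` sheet."""
    wb = Workbook()
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    agg = wb.active
    agg.title = "aggregate"
    agg.append(["series", "bucket", "count", "percent", "n_selected"])
    if not series_list:
        warnings.warn("no series to export; writing empty aggregate sheet")
    used: set[str] = {"aggregate"}
    for series in series_list:
        ws = wb.create_sheet(_sheet_name(series.label, used))
        ws.append(["bucket", "count", "percent", "n_selected"])
        for row in _series_rows(series):
            ws.append(list(row))
            agg.append([series.label, *row])
    wb.save(str(path))


def export_series_tsv(series_list, path: str | os.PathLike) -> None:
    """Long-format TSV mirror of the aggregate sheet."""
    with open(path, "w") as fh:
        fh.write("series\tbucket\tcount\tpercent\tn_selected\n")
        for series in series_list:
            for bucket, count, percent, n_sel in _series_rows(series):
                fh.write(f"{series.label}\t{bucket}\t{count}\t{percent!r}\t{n_sel}\n")


def read_series_xlsx(path: str | os.PathLike) -> list[dict]:
    """Read back the aggregate sheet (for round-trip checks and pipelines)."""
    wb = load_workbook(str(path), read_only=True)
    ws = wb["aggregate"]
    rows = ws.iter_rows(values_only=True)
    header = next(rows)
    return [dict(zip(header, row)) for row in rows if row[0] is not None]


def _enclosing_buckets(series: ProfileSeries, lo: int, hi: int) -> list[int]:
    spec = series.spec
    if hi < spec.lower or lo >= spec.upper:
        raise ValueError(
            f"range [{lo},{hi}] outside window [{spec.lower},{spec.upper})"
        )
    if lo > hi:
        raise ValueError("gene-list range lower bound must be <= upper bound")
    b = spec.bucket_size
    lo_b = math.floor(lo / b) * b
    hi_b = math.floor(hi / b) * b
    return [bk for bk in sorted(series.counts) if lo_b <= bk <= hi_b]


def _gene_list_rows(series: ProfileSeries, bucket_range, expression: ExpressionMatrix):
    lo, hi = bucket_range
    genes: set[str] = set()
    for bk in _enclosing_buckets(series, lo, hi):
        genes |= series.per_bucket_genes.get(bk, set())
    header = ["gene_id", *expression.stages]
    rows = []
    for g in sorted(genes):
        tpm = expression.gene_tpm(g) if g in set(expression.gene_ids) else {}
        rows.append([g, *[tpm.get(s) for s in expression.stages]])
    return header, rows


def export_gene_list(
    series: ProfileSeries,
    bucket_range,
    expression: ExpressionMatrix,
    path: str | os.PathLike,
) -> list[str]:
    """Export genes with a motif in buckets intersecting ``[lo, hi]`` as XLSX.

    Each row carries the gene ID plus its TPM in *every* stage of the
    expression matrix, so exported lists can be inspected across tissues.
    Returns the exported gene IDs.
    """
    header, rows = _gene_list_rows(series, bucket_range, expression)
    wb = Workbook()
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    ws = wb.active
    ws.title = "genes"
    ws.append(header)
    for row in rows:
        ws.append(row)
    wb.save(str(path))
    return [r[0] for r in rows]


def export_gene_list_tsv(series, bucket_range, expression, path) -> list[str]:
    header, rows = _gene_list_rows(series, bucket_range, expression)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
    return [r[0] for r in rows]


# ---------------------------------------------------------------------------
# plotting

def render_plot(series_list, path: str | os.PathLike, style: dict | None = None) -> None:
    """Render one curve per series (x = bucket left edge) to a PNG file.

    ``style`` keys: ``colors`` (list), ``linewidth``, ``ymax`` (y-axis
    maximum, e.g. 45 for a 45% axis), ``figsize``, ``title``.  All series
    must share a unit.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not series_list:
        raise ValueError("no series to plot")
    units = {s.unit for s in series_list}
    if len(units) > 1:
        raise ValueError(f"mixed units across series: {sorted(units)}")
    style = style or {}
    fig, ax = plt.subplots(figsize=style.get("figsize", (8, 4.5)))
    colors = style.get("colors")
    for i, series in enumerate(series_list):
        xs = sorted(series.values)
        ys = [series.values[x] for x in xs]
        kwargs = {"linewidth": style.get("linewidth", 1.5), "label": series.stage}
        if colors:
            kwargs["color"] = colors[i % len(colors)]
        ax.plot(xs, ys, **kwargs)
    unit = next(iter(units))
    anchor = series_list[0].anchor
    ax.set_xlabel(f"position relative to {anchor} (bp)")
    ax.set_ylabel("% of genes with motif" if unit == "percent" else "motif count")
    if style.get("ymax") is not None:
        ax.set_ylim(0, style["ymax"])
    if style.get("title"):
        ax.set_title(style["title"])
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path), format="png", dpi=style.get("dpi", 100))
    plt.close(fig)
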