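"""TPM expression tables and expression-based gene selection.

Gene selection follows the cumulative-transcript reading of "percentile": the
P-th percentile in a stage is the *smallest* set of top-expressed genes whose
summed TPM reaches P% of the stage's total TPM — a prefix of the
expression-ranked gene list, not a per-gene TPM quantile.  The gene that
carries the cumulative sum across the threshold is included.  Ties are broken
by gene ID (ascending) so selections are reproducible regardless of input row
order.  Zero-TPM genes belong to the universe (the denominator reported
alongside every selection) but can never enter a "highest" prefix.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "StageSelection",
    "load_expression",
    "derive_composite_stage",
    "select_percentile",
    "select_top_n",
    "select_all",
]


@dataclass
class ExpressionMatrix:
    """Gene × stage TPM values after replicate averaging.

    Wraps a pandas DataFrame indexed by gene ID with one column per stage.
    Missing values (all replicates NA) are kept as NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if len(set(self.df.columns)) != len(self.df.columns):
            raise ValueError("stage names must be unique")
        if (self.df.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative TPM value in expression table")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def stages(self) -> list[str]:
        return list(self.df.columns)

    def gene_tpm(self, gene_id: str) -> dict[str, float]:
        return {s: float(v) for s, v in self.df.loc[gene_id].items()}

    def stage_values(self, stage: str) -> pd.Series:
        if stage not in self.df.columns:
            raise KeyError(f"unknown stage: {stage!r}")
        return self.df[stage]


@dataclass
class StageSelection:
    """A set of genes chosen in one stage, with its selection provenance."""

    stage: str
    mode: str  # percentile | top_n | bottom_n | all
    parameter: float | int | None
    selected: set[str] = field(default_factory=set)
    n_universe: int = 0

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def load_expression(table, replicate_map: dict[str, list[str]] | None = None) -> ExpressionMatrix:
    """Load a TSV/CSV TPM table (first column = gene ID) and average replicates.

    ``replicate_map`` maps a stage name to its replicate column names; stage
    value is the arithmetic mean of the replicates present (NA = missing
    replicate; all-NA leaves the stage value missing).  Without a map, every
    column is its own stage.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        if df.index.name is None and not np.issubdtype(df.index.dtype, np.object_):
            df = df.set_index(df.columns[0])
    else:
        path = Path(table)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df = df.astype(float)
    if replicate_map:
        out = {}
        for stage, cols in replicate_map.items():
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise KeyError(f"replicate columns not in table: {missing}")
            out[stage] = df[cols].mean(axis=1, skipna=True)
        df = pd.DataFrame(out, index=df.index)
    return ExpressionMatrix(df)


def derive_composite_stage(matrix: ExpressionMatrix, new_stage: str, members: list[str]) -> ExpressionMatrix:
    """Append a composite stage = element-wise mean of member stage columns."""
    if new_stage in matrix.df.columns:
        raise ValueError(f"stage {new_stage!r} already exists")
    for m in members:
        if m not in matrix.df.columns:
            raise KeyError(f"unknown member stage: {m!r}")
    df = matrix.df.copy()
    df[new_stage] = df[list(members)].mean(axis=1, skipna=True)
    return ExpressionMatrix(df)


def _ranked(values: pd.Series, direction: str) -> list[str]:
    sign = -1.0 if direction == "highest" else 1.0
    return sorted(values.index, key=lambda g: (sign * values[g], g))


def select_percentile(
    matrix: ExpressionMatrix,
    stage: str,
    percentile: float,
    direction: str = "highest",
) -> StageSelection:
    """Shortest expression-ranked prefix whose TPM sum reaches P% of the total.

    The universe is the set of genes with a non-missing TPM in the stage;
    ``direction='lowest'`` ranks ascending and applies the same prefix rule.
    A stage with zero total TPM yields an empty selection with a warning.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    if direction not in ("highest", "lowest"):
        raise ValueError(f"direction must be 'highest' or 'lowest', got {direction!r}")
    values = matrix.stage_values(stage).dropna()
    sel = StageSelection(stage=stage, mode="percentile", parameter=percentile, n_universe=len(values))
    total = float(values.sum())
    if total == 0.0:
        warnings.warn(f"stage {stage!r} has zero total TPM; empty selection")
        return sel
    order = _ranked(values, direction)
    target = (percentile / 100.0) * total - 1e-9 * total  # guard float roundoff at P=100
    cum = 0.0
    chosen: list[str] = []
    for g in order:
        chosen.append(g)
        cum += float(values[g])
        if cum >= target:
            break
    sel.selected = set(chosen)
    return sel


def select_top_n(
    matrix: ExpressionMatrix,
    stage: str,
    n: int,
    direction: str = "highest",
) -> StageSelection:
    """Exactly ``min(n, |universe|)`` genes ranked by TPM with gene-ID tie-break."""
    if n < 1:
        raise ValueError("n must be >= 1")
    values = matrix.stage_values(stage).dropna()
    order = _ranked(values, direction)
    if n > len(order):
        warnings.warn(f"n={n} exceeds universe of {len(order)} genes in stage {stage!r}")
    mode = "top_n" if direction == "highest" else "bottom_n"
    return StageSelection(
        stage=stage,
        mode=mode,
        parameter=n,
        selected=set(order[:n]),
        n_universe=len(order),
    )


def select_all(matrix: ExpressionMatrix, stage: str | None = None) -> StageSelection:
    """Genome-wide baseline: every gene in the universe, regardless of TPM."""
    if stage is not None:
        values = matrix.stage_values(stage).dropna()
        universe = set(values.index)
    else:
        universe = set(matrix.gene_ids)
    return StageSelection(
        stage=stage or "all",
        mode="all",
        parameter=None,
        selected=universe,
        n_universe=len(universe),
    )
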