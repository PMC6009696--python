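"""Per-chromosome deregulation summaries over a gene-level expression table.

The table is a pandas DataFrame with one row per gene and columns
``gene_id``, ``chromosome``, ``fpkm_<condition>`` for each condition and
``log2fc_<condition>`` for each non-reference condition (fold change against
the reference).  The summaries follow the RNA-seq downstream arithmetic of
the study design:

* transcribing genes: FPKM strictly > 1.0 (in the reference condition by
  default);
* deregulated genes: |log2 fold change| >= 2.0 (boundary inclusive), split
  into up and down;
* percent deregulation per chromosome: 100 x deregulated / transcribing;
* enrichment per chromosome: 100 x deregulated(chromosome) / deregulated
  (all chromosomes), per direction — sums to 100% over chromosomes;
* fold-change magnitude histograms and up/down overlap counts between two
  condition comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OverlapCounts",
    "transcribing_genes",
    "call_deregulated",
    "percent_deregulation",
    "enrichment",
    "fold_change_bins",
    "overlap",
    "deregulation_summary",
]

DEFAULT_FPKM_MIN = 1.0
DEFAULT_LOG2FC_MIN = 2.0


@dataclass(frozen=True)
class OverlapCounts:
    """Up- (or down-) regulated gene overlap between two comparisons."""

    total_a: int
    total_b: int
    unique_a: int
    unique_b: int
    common: int

    def __post_init__(self):
        if self.total_a != self.unique_a + self.common:
            raise ValueError("total_a != unique_a + common")
        if self.total_b != self.unique_b + self.common:
            raise ValueError("total_b != unique_b + common")

    @classmethod
    def from_totals(cls, total_a: int, total_b: int,
                    unique_a: int, unique_b: int) -> "OverlapCounts":
        """Recover the common count from totals and unique counts.

        Both sides must agree: total_a − unique_a == total_b − unique_b.
        """
        common_a = total_a - unique_a
        common_b = total_b - unique_b
        if common_a != common_b:
            raise ValueError(
                f"inconsistent overlap: {common_a} (from a) != {common_b} (from b)"
            )
        return cls(total_a, total_b, unique_a, unique_b, common_a)


def _check_chromosome(table: pd.DataFrame, chromosome: str):
    if chromosome not in set(table["chromosome"]):
        raise KeyError(f"chromosome {chromosome!r} not in table")


def transcribing_genes(table: pd.DataFrame, chromosome: str,
                       fpkm_min: float = DEFAULT_FPKM_MIN,
                       condition: str | None = None,
                       any_condition: bool = False) -> int:
    """Count transcribing genes (FPKM strictly > ``fpkm_min``) on a chromosome.

    By default the filter is evaluated in a single anchor ``condition`` (the
    first fpkm column when not given, conventionally the reference);
    ``any_condition=True`` instead keeps genes exceeding the threshold in at
    least one condition.
    """
    _check_chromosome(table, chromosome)
    sub = table[table["chromosome"] == chromosome]
    fpkm_cols = [c for c in table.columns if c.startswith("fpkm_")]
    if not fpkm_cols:
        raise ValueError("table has no fpkm_<condition> columns")
    if any_condition:
        keep = (sub[fpkm_cols] > fpkm_min).any(axis=1)
    else:
        col = f"fpkm_{condition}" if condition is not None else fpkm_cols[0]
        if col not in table.columns:
            raise KeyError(f"no column {col!r} in table")
        keep = sub[col] > fpkm_min
    return int(keep.sum())


def call_deregulated(table: pd.DataFrame, condition: str,
                     log2fc_min: float = DEFAULT_LOG2FC_MIN) -> pd.Series:
    """Classify every gene as ``up`` / ``down`` / ``none`` for a condition.

    ``up`` if log2fc >= log2fc_min, ``down`` if log2fc <= −log2fc_min
    (both boundaries inclusive).  Genes with a missing fold change are
    dropped with a warning.  Returns a Series indexed by gene_id.
    """
    col = f"log2fc_{condition}"
    if col not in table.columns:
        raise KeyError(f"no fold-change column {col!r} in table")
    fc = pd.Series(table[col].values, index=table["gene_id"].values, name=condition)
    missing = fc.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes lack a fold change for "
                      f"{condition!r} and were skipped", stacklevel=2)
        fc = fc[~missing]
    calls = pd.Series("none", index=fc.index, name=condition)
    calls[fc >= log2fc_min] = "up"
    calls[fc <= -log2fc_min] = "down"
    return calls


def _dereg_mask(table: pd.DataFrame, conditions, log2fc_min) -> pd.DataFrame:
    """Per-gene up/down indicator, pooled over conditions (union)."""
    if isinstance(conditions, str):
        conditions = [conditions]
    up = np.zeros(len(table), dtype=bool)
    down = np.zeros(len(table), dtype=bool)
    for cond in conditions:
        col = f"log2fc_{cond}"
        if col not in table.columns:
            raise KeyError(f"no fold-change column {col!r} in table")
        fc = table[col]
        up |= (fc >= log2fc_min).fillna(False).values
        down |= (fc <= -log2fc_min).fillna(False).values
    return pd.DataFrame({"chromosome": table["chromosome"].values,
                         "up": up, "down": down})


def percent_deregulation(table: pd.DataFrame, conditions,
                         log2fc_min: float = DEFAULT_LOG2FC_MIN,
                         fpkm_min: float = DEFAULT_FPKM_MIN,
                         transcribing_condition: str | None = None,
                         any_condition: bool = False) -> pd.Series:
    """Percent of transcribing genes deregulated, per chromosome.

    100 x (up + down) / transcribing.  ``conditions`` may be one condition
    (per-matrix mode) or several (a gene deregulated in any of them counts
    once — pooled mode).  Chromosomes with zero transcribing genes get NaN
    (undefined, not 0).
    """
    marks = _dereg_mask(table, conditions, log2fc_min)
    dereg = marks.groupby("chromosome").apply(
        lambda g: int((g["up"] | g["down"]).sum()), include_groups=False
    )
    out = {}
    for chrom in dict.fromkeys(table["chromosome"]):
        t = transcribing_genes(table, chrom, fpkm_min=fpkm_min,
                               condition=transcribing_condition,
                               any_condition=any_condition)
        out[chrom] = 100.0 * dereg.get(chrom, 0) / t if t > 0 else np.nan
    return pd.Series(out, name="percent_deregulation")


def enrichment(table: pd.DataFrame, condition: str, direction: str,
               log2fc_min: float = DEFAULT_LOG2FC_MIN) -> pd.Series:
    """Per-chromosome share of all deregulated genes, in percent.

    100 x deregulated(chromosome, direction) / deregulated(direction); sums
    to 100 over chromosomes.  Raises when no gene is deregulated in the
    requested direction.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    marks = _dereg_mask(table, condition, log2fc_min)
    per_chrom = marks.groupby("chromosome")[direction].sum()
    per_chrom = per_chrom.reindex(dict.fromkeys(table["chromosome"]), fill_value=0)
    total = int(per_chrom.sum())
    if total == 0:
        raise ValueError(f"no genes {direction}-regulated in {condition!r}")
    return (100.0 * per_chrom / total).rename(f"enrichment_{direction}")


def fold_change_bins(table: pd.DataFrame, condition: str, direction: str,
                     edges, log2fc_min: float = DEFAULT_LOG2FC_MIN) -> np.ndarray:
    """Histogram of |log2fc| for one direction's deregulated genes.

    ``edges`` are increasing bin edges on the |log2fc| scale (the last may
    be ``inf``); bins are left-closed.  With ``edges[0] == log2fc_min`` and
    an infinite last edge, the counts total the direction's call count.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    calls = call_deregulated(table, condition, log2fc_min=log2fc_min)
    col = f"log2fc_{condition}"
    fc = pd.Series(table[col].values, index=table["gene_id"].values)
    mag = fc.reindex(calls.index)[calls == direction].abs().values
    counts = np.zeros(edges.size - 1, dtype=int)
    for i in range(edges.size - 1):
        hi = edges[i + 1]
        in_bin = (mag >= edges[i]) & (mag < hi) if np.isfinite(hi) else mag >= edges[i]
        counts[i] = int(np.sum(in_bin))
    return counts


def overlap(calls_a: pd.Series, calls_b: pd.Series, direction: str) -> OverlapCounts:
    """Overlap of one direction's calls between two comparisons.

    Both call Series must cover the same gene universe (same index set).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if set(calls_a.index) != set(calls_b.index):
        raise ValueError("call series cover different gene universes")
    set_a = set(calls_a.index[calls_a == direction])
    set_b = set(calls_b.index[calls_b == direction])
    common = len(set_a & set_b)
    return OverlapCounts(
        total_a=len(set_a), total_b=len(set_b),
        unique_a=len(set_a) - common, unique_b=len(set_b) - common,
        common=common,
    )


def deregulation_summary(table: pd.DataFrame, condition: str,
                         log2fc_min: float = DEFAULT_LOG2FC_MIN,
                         fpkm_min: float = DEFAULT_FPKM_MIN,
                         transcribing_condition: str | None = None) -> pd.DataFrame:
    """Per-chromosome summary: transcribing, up, down, percent deregulation
    and up/down enrichment, as one DataFrame (chromosome index)."""
    marks = _dereg_mask(table, condition, log2fc_min)
    grouped = marks.groupby("chromosome")[["up", "down"]].sum()
    chroms = list(dict.fromkeys(table["chromosome"]))
    grouped = grouped.reindex(chroms, fill_value=0)
    out = pd.DataFrame(index=pd.Index(chroms, name="chromosome"))
    out["transcribing"] = [
        transcribing_genes(table, c, fpkm_min=fpkm_min,
                           condition=transcribing_condition) for c in chroms
    ]
    out["up"] = grouped["up"].astype(int)
    out["down"] = grouped["down"].astype(int)
    out["percent_deregulation"] = percent_deregulation(
        table, condition, log2fc_min=log2fc_min, fpkm_min=fpkm_min,
        transcribing_condition=transcribing_condition,
    ).reindex(chroms)
    for direction in ("up", "down"):
        total = int(out[direction].sum())
        col = f"enrichment_{direction}"
        out[col] = 100.0 * out[direction] / total if total > 0 else np.nan
    return out
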