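"""γH2A gene classification and expression meta-analysis.

Replication fork stalling sites are marked by S139-phosphorylated histone H2A
(γH2A). Genes with a γH2A ChIP-seq peak of at least 2-fold enrichment within
1 kb upstream of their CDS start are classed as γH2A genes; comparing their
expression against the remaining genes across RNA-seq datasets (log2 counts
normalised for CDS length, each dataset centred to a median of 9) shows
whether stalled-fork genes sit in a distinct expression regime.

Coordinates are 0-based half-open throughout (BED native; GFF3 converted on
read by :mod:`stimcnv.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError

__all__ = [
    "GenomicInterval",
    "PeakCall",
    "GeneModel",
    "upstream_window",
    "classify_gh2a",
    "normalize_expression",
    "ecdf_compare",
    "EcdfComparison",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise InputError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakCall:
    """One ChIP-seq peak with its fold enrichment over input."""

    interval: GenomicInterval
    fold_enrichment: float

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise InputError("fold_enrichment must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its CDS interval; strand must be defined."""

    gene_id: str
    cds: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if self.cds.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")


def upstream_window(gene: GeneModel, size: int = 1000) -> GenomicInterval:
    """The ``size``-bp window upstream of the CDS start, strand-aware.

    Plus strand: [start − size, start); minus strand: [end, end + size);
    clamped at position 0.
    """
    if size <= 0:
        raise DomainError("size must be > 0")
    cds = gene.cds
    if cds.strand == "+":
        start = max(cds.start - size, 0)
        end = cds.start
    elif cds.strand == "-":
        start = cds.end
        end = cds.end + size
    else:  # GeneModel validation prevents this, but upstream_window is public
        raise DomainError(f"gene {gene.gene_id}: strand '.' has no upstream side")
    if start >= end:
        raise DomainError(
            f"gene {gene.gene_id}: upstream window is empty (CDS at chromosome start)"
        )
    return GenomicInterval(cds.chrom, start, end, cds.strand)


def classify_gh2a(
    peaks: Iterable[PeakCall],
    genes: Sequence[GeneModel],
    min_fold: float = 2.0,
    window: int = 1000,
) -> pd.DataFrame:
    """Partition genes into γH2A / non-γH2A.

    A gene is γH2A iff at least one peak with fold enrichment >= ``min_fold``
    overlaps its upstream window by >= 1 bp on the same chromosome. Peaks on
    chromosomes absent from the gene annotation are ignored with a logged
    warning. Returns a DataFrame (gene_id, is_gh2a) covering every gene
    exactly once.
    """
    chroms = {g.cds.chrom for g in genes}
    kept: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for p in peaks:
        if p.interval.chrom not in chroms:
            logger.warning(
                "ignoring peak on unknown chromosome %r (%d-%d)",
                p.interval.chrom,
                p.interval.start,
                p.interval.end,
            )
            continue
        if p.fold_enrichment >= min_fold:
            kept[p.interval.chrom].append((p.interval.start, p.interval.end))
    rows = []
    for g in genes:
        win = upstream_window(g, window)
        hit = any(s < win.end and win.start < e for s, e in kept[win.chrom])
        rows.append((g.gene_id, hit))
    return pd.DataFrame(rows, columns=["gene_id", "is_gh2a"])


def normalize_expression(
    table: pd.DataFrame,
    target_median: float = 9.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Log2, CDS-length-normalised expression centred to a target median.

    ``table`` needs columns gene_id, dataset, count, cds_length. Each value
    is log2((count + pseudocount) / cds_length_kb); each dataset is then
    shifted by a single additive constant so its median equals
    ``target_median`` exactly (median of an even-length dataset is the
    midpoint of the central pair, so the shifted median is exact up to one
    floating-point rounding). Returns the table with a ``value`` column.
    """
    required = {"gene_id", "dataset", "count", "cds_length"}
    if not required.issubset(table.columns):
        raise InputError(f"expression table needs columns {sorted(required)}")
    if len(table) == 0:
        raise DomainError("empty expression table")
    if (table["cds_length"] <= 0).any():
        raise DomainError("cds_length must be > 0")
    if (table["count"] < 0).any():
        raise DomainError("counts must be >= 0")
    if pseudocount == 0 and (table["count"] == 0).all():
        raise DomainError("all-zero counts with pseudocount 0 are degenerate")
    out = table.copy()
    length_kb = out["cds_length"] / 1000.0
    out["value"] = np.log2((out["count"] + pseudocount) / length_kb)
    # a single additive constant per dataset; iterate the correction so the
    # median is exact even when it is the fp midpoint of a central pair
    for _ in range(5):
        resid = out.groupby("dataset")["value"].transform("median") - target_median
        if (resid == 0).all():
            break
        out["value"] -= resid
    return out


@dataclass
class EcdfComparison:
    """ECDFs and summary statistics for γH2A vs non-γH2A expression."""

    ecdfs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]  # (dataset, set) -> (x, F)
    set_means: pd.DataFrame  # dataset, set, mean, n
    median_difference: float  # pooled: median(γH2A) − median(non-γH2A)
    per_dataset_median_difference: pd.Series


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    return x, np.arange(1, len(x) + 1) / len(x)


def ecdf_compare(expr: pd.DataFrame, gh2a_genes: Iterable[str]) -> EcdfComparison:
    """Cumulative expression distributions for γH2A vs non-γH2A gene sets.

    ``expr`` is a normalised expression table (see
    :func:`normalize_expression`) with a ``value`` column. Emits per-dataset
    ECDFs, per-dataset set means (the tidy table a downstream nested ANOVA
    consumes), and the median expression difference γH2A − non-γH2A.
    """
    if "value" not in expr.columns:
        raise InputError("expression table must carry a 'value' column (normalised)")
    gh2a = set(gh2a_genes)
    if not gh2a:
        raise DomainError("γH2A gene set is empty")
    labels = np.where(expr["gene_id"].isin(gh2a), "gh2a", "non_gh2a")
    if (labels == "non_gh2a").all():
        raise DomainError("no expression rows for the γH2A gene set")
    if (labels == "gh2a").all():
        raise DomainError("no expression rows outside the γH2A gene set")
    tab = expr.assign(gene_set=labels)
    ecdfs = {}
    mean_rows = []
    med_diffs = {}
    for (dataset, gene_set), grp in tab.groupby(["dataset", "gene_set"]):
        ecdfs[(dataset, gene_set)] = _ecdf(grp["value"].to_numpy())
        mean_rows.append((dataset, gene_set, float(grp["value"].mean()), len(grp)))
    for dataset, grp in tab.groupby("dataset"):
        g = grp[grp["gene_set"] == "gh2a"]["value"]
        n = grp[grp["gene_set"] == "non_gh2a"]["value"]
        if len(g) and len(n):
            med_diffs[dataset] = float(g.median() - n.median())
    pooled_g = tab[tab["gene_set"] == "gh2a"]["value"].median()
    pooled_n = tab[tab["gene_set"] == "non_gh2a"]["value"].median()
    return EcdfComparison(
        ecdfs=ecdfs,
        set_means=pd.DataFrame(mean_rows, columns=["dataset", "gene_set", "mean", "n"]),
        median_difference=float(pooled_g - pooled_n),
        per_dataset_median_difference=pd.Series(med_diffs, name="median_difference"),
    )
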