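"""Differential-expression filtering and gene-set overlap statistics.

Consumes a differential-expression results table (the model fit itself is
upstream, e.g. DESeq2) and applies the standard filters: genes with too few
reads across all samples are removed before multiple-testing adjustment,
then significance and effect-size cutoffs select the differential set.
Two gene sets over a common universe are compared by intersection size,
Jaccard similarity and a one-sided hypergeometric enrichment test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "OverlapResult", "de_filter", "overlap_stats", "translate_ids"]


@dataclass(frozen=True)
class GeneSet:
    """A set of gene identifiers within a finite universe."""

    genes: frozenset
    universe_size: int

    def __post_init__(self):
        if len(self.genes) > self.universe_size:
            raise ValueError("gene set larger than its universe")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    n_common: int
    jaccard: float
    enrichment_p: float


_REQUIRED = {"gene_id", "lfc"}


def de_filter(
    table: pd.DataFrame,
    padj_cutoff: float = 0.05,
    lfc_cutoff: float = 0.5,
    min_total_reads: int = 10,
    lfc_base: str = "log2",
) -> GeneSet:
    """Select differentially expressed genes from a results table.

    Expected columns: ``gene_id``, ``lfc`` (log fold change), and either
    ``pvalue`` (raw; Benjamini-Hochberg adjustment is re-applied after the
    read filter) or ``padj`` (pre-adjusted), plus ``total_reads`` when the
    low-count filter is active.  Genes pass with
    ``|lfc| > lfc_cutoff`` and adjusted p < ``padj_cutoff``.

    ``lfc_base`` records the base of the fold-change column ("log2" or
    "log10"); it does not rescale the cutoff — callers supplying a log10
    table should pass the matching cutoff.
    """
    if padj_cutoff <= 0 or lfc_cutoff < 0:
        raise ValueError("cutoffs must be positive")
    if lfc_base not in ("log2", "log10"):
        raise ValueError(f"unknown lfc_base {lfc_base!r}")
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if "pvalue" not in table.columns and "padj" not in table.columns:
        raise ValueError("DE table needs a 'pvalue' or 'padj' column")

    universe_size = len(table)
    if len(table) == 0:
        return GeneSet(frozenset(), 0)

    work = table.copy()
    if min_total_reads > 0:
        if "total_reads" not in work.columns:
            raise ValueError("read filter requested but 'total_reads' column missing")
        work = work[work["total_reads"] >= min_total_reads]
    if len(work) == 0:
        return GeneSet(frozenset(), universe_size)

    if "pvalue" in work.columns:
        ok = work["pvalue"].notna()
        padj = pd.Series(np.nan, index=work.index)
        if ok.any():
            padj.loc[ok] = multipletests(work.loc[ok, "pvalue"], method="fdr_bh")[1]
    else:
        padj = work["padj"]

    keep = (padj < padj_cutoff) & (work["lfc"].abs() > lfc_cutoff)
    genes = frozenset(work.loc[keep.fillna(False), "gene_id"])
    logger.info("de_filter: %d of %d genes pass", len(genes), universe_size)
    return GeneSet(genes, universe_size)


def overlap_stats(a: GeneSet | set, b: GeneSet | set, universe_size: int | None = None) -> OverlapResult:
    """Intersection count, Jaccard index and hypergeometric enrichment p.

    The enrichment p-value is the upper tail P(X >= observed overlap) of the
    hypergeometric distribution drawing |B| genes from a universe containing
    |A| marked genes.
    """
    set_a = a.genes if isinstance(a, GeneSet) else frozenset(a)
    set_b = b.genes if isinstance(b, GeneSet) else frozenset(b)
    if universe_size is None:
        sizes = {x.universe_size for x in (a, b) if isinstance(x, GeneSet)}
        if len(sizes) != 1:
            raise ValueError("universe_size required when gene sets disagree")
        universe_size = sizes.pop()
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("gene set exceeds the universe")

    n_common = len(set_a & set_b)
    union = len(set_a | set_b)
    jaccard = n_common / union if union else 0.0
    p = float(hypergeom.sf(n_common - 1, universe_size, len(set_a), len(set_b)))
    return OverlapResult(n_common=n_common, jaccard=jaccard, enrichment_p=min(p, 1.0))


def translate_ids(genes, mapping: pd.DataFrame) -> frozenset:
    """Translate identifiers through a two-column mapping table
    (``from_id``, ``to_id``); unmapped genes are dropped with a logged count."""
    lut = mapping.set_index(mapping.columns[0])[mapping.columns[1]]
    genes = list(genes)
    mapped = [lut[g] for g in genes if g in lut.index]
    dropped = len(genes) - len(mapped)
    if dropped:
        logger.info("translate_ids: %d identifiers unmapped and dropped", dropped)
    return frozenset(mapped)
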