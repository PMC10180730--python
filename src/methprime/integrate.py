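"""Methylome-transcriptome integration: DMR-DEG linkage and shared DMRs.

A DMR is linked to a called DEG when the DMR midpoint lies within a window
(default 25 kb) of the gene's TSS. A link is "canonical" when methylation
and expression move in opposite directions (hypomethylation with
upregulation or hypermethylation with downregulation), the textbook
negative methylation-expression association at regulatory regions.
Shared DMRs between two comparisons are >= 1 bp interval overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datasets import GeneAnnotation
from .regulatory import midpoint

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["dmr", "gene_id", "distance", "dmr_direction", "deg_direction", "canonical"]


def classify_canonical(delta_me_sign: float, log2fc_sign: float) -> bool:
    """True iff methylation and expression change in opposite directions."""
    return float(np.sign(delta_me_sign)) * float(np.sign(log2fc_sign)) == -1.0


def link_dmrs_degs(dmrs: pd.DataFrame, degs: pd.DataFrame,
                   annotation: GeneAnnotation, window: int = 25_000,
                   anchor: str = "tss") -> pd.DataFrame:
    """Link every (DMR, called DEG) pair within `window` of the gene anchor.

    `degs` is a called-DEG frame with gene_id and log2fc. `anchor` is "tss"
    (distance from DMR midpoint to the gene TSS) or "body" (distance to the
    nearest gene-body edge, 0 when the midpoint falls inside the gene).
    Genes missing from the annotation are logged and skipped.
    """
    if anchor not in ("tss", "body"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if not len(dmrs) or not len(degs):
        return pd.DataFrame(columns=LINK_COLUMNS)
    genes = annotation.genes.set_index("gene_id")
    tss = annotation.tss
    records = []
    for deg in degs.itertuples(index=False):
        if deg.gene_id not in genes.index:
            logger.warning("DEG gene %s missing from annotation; skipped", deg.gene_id)
            continue
        gene = genes.loc[deg.gene_id]
        for dmr in dmrs.itertuples(index=False):
            if dmr.chrom != gene["chrom"]:
                continue
            mid = midpoint(dmr.start, dmr.end)
            if anchor == "tss":
                dist = abs(mid - int(tss.loc[deg.gene_id]))
            else:
                if gene["start"] <= mid < gene["end"]:
                    dist = 0
                else:
                    dist = min(abs(mid - int(gene["start"])), abs(mid - (int(gene["end"]) - 1)))
            if dist > window:
                continue
            canonical = classify_canonical(dmr.delta_me, deg.log2fc)
            records.append(
                {
                    "dmr": dmr.name,
                    "gene_id": deg.gene_id,
                    "distance": int(dist),
                    "dmr_direction": dmr.direction,
                    "deg_direction": "up" if deg.log2fc > 0 else "down",
                    "canonical": canonical,
                }
            )
    return pd.DataFrame(records, columns=LINK_COLUMNS)


def summarize_links(links: pd.DataFrame) -> dict:
    """Link counts both as pairs and as unique DMRs linked."""
    if not len(links):
        return {
            "n_links": 0,
            "n_canonical_links": 0,
            "n_dmrs_linked": 0,
            "n_dmrs_canonical": 0,
        }
    return {
        "n_links": int(len(links)),
        "n_canonical_links": int(links["canonical"].sum()),
        "n_dmrs_linked": int(links["dmr"].nunique()),
        "n_dmrs_canonical": int(links.loc[links["canonical"], "dmr"].nunique()),
    }


@dataclass
class SharedDmrResult:
    """Venn-style decomposition of two DMR sets by interval overlap."""

    pairs: pd.DataFrame  # name_a, name_b of every overlapping pair
    shared_a: int  # DMRs in A overlapping any DMR in B
    shared_b: int
    only_a: int
    only_b: int


def shared_dmrs(dmrs_a: pd.DataFrame, dmrs_b: pd.DataFrame) -> SharedDmrResult:
    """DMRs shared between two comparisons (>= 1 bp interval overlap).

    The overlap relation is symmetric; per-side shared counts may differ
    because one DMR can absorb several from the other set.
    """
    trees: dict[str, IntervalTree] = {}
    for row in dmrs_b.itertuples(index=False):
        tree = trees.setdefault(row.chrom, IntervalTree())
        if row.end > row.start:
            tree.addi(int(row.start), int(row.end), row.name)
    pairs = []
    shared_a_names = set()
    shared_b_names = set()
    for row in dmrs_a.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(row.start), int(row.end))):
            pairs.append({"name_a": row.name, "name_b": hit.data})
            shared_a_names.add(row.name)
            shared_b_names.add(hit.data)
    pairs_df = pd.DataFrame(pairs, columns=["name_a", "name_b"])
    return SharedDmrResult(
        pairs=pairs_df,
        shared_a=len(shared_a_names),
        shared_b=len(shared_b_names),
        only_a=len(dmrs_a) - len(shared_a_names),
        only_b=len(dmrs_b) - len(shared_b_names),
    )
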