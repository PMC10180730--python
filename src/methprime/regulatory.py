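"""cCRE classification and DMR overlap tables.

Elements carry signal flags (promoter-like, enhancer-like, CTCF) and are
assigned one category by distance from the element midpoint to the nearest
annotated TSS: PLS (promoter-like, within 200 bp of a TSS),
other-H3K4me3 (promoter-like, farther), pELS / dELS (enhancer-like,
within / beyond 2 kb), CTCF-only. Boundary distances (exactly 200 / 2000
bp) resolve to the proximal class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datasets import CCRE_CATEGORIES, CcreCatalog, GeneAnnotation, MethprimeError

PLS_TSS_DISTANCE = 200
ELS_TSS_DISTANCE = 2000


class UnclassifiableElementError(MethprimeError):
    """Element carries no signal flag and cannot be categorized."""


def midpoint(start: int, end: int) -> int:
    """Anchor coordinate of an interval: the lower-median position."""
    return (int(start) + int(end) - 1) // 2


def _nearest_tss_distance(chrom: str, anchor: int, annotation: GeneAnnotation) -> float:
    index = annotation.tss_index()
    if chrom not in index:
        return float("inf")
    positions = index[chrom][0]
    i = int(np.searchsorted(positions, anchor))
    best = float("inf")
    for j in (i - 1, i):
        if 0 <= j < len(positions):
            best = min(best, abs(int(positions[j]) - anchor))
    return best


def classify_ccre(chrom: str, start: int, end: int,
                  promoter_like: bool, enhancer_like: bool, ctcf: bool,
                  annotation: GeneAnnotation) -> str:
    """Assign the ENCODE-registry category for one element."""
    if not (promoter_like or enhancer_like or ctcf):
        raise UnclassifiableElementError(
            f"element {chrom}:{start}-{end} has no signal flags"
        )
    dist = _nearest_tss_distance(chrom, midpoint(start, end), annotation)
    if promoter_like:
        return "PLS" if dist <= PLS_TSS_DISTANCE else "other-H3K4me3"
    if enhancer_like:
        return "pELS" if dist <= ELS_TSS_DISTANCE else "dELS"
    return "CTCF-only"


def classify_catalog(catalog: CcreCatalog, annotation: GeneAnnotation) -> pd.Series:
    """Category per element, recomputed from coordinates and flags."""
    cats = [
        classify_ccre(row.chrom, row.start, row.end,
                      bool(row.promoter_like), bool(row.enhancer_like), bool(row.ctcf),
                      annotation)
        for row in catalog.elements.itertuples(index=False)
    ]
    return pd.Series(cats, index=catalog.elements.index, name="category")


def _interval_trees(frame: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in frame.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row in sub.itertuples(index=True):
            if row.end > row.start:
                tree.addi(int(row.start), int(row.end), row.Index)
        trees[chrom] = tree
    return trees


def overlap_dmrs_ccres(dmrs: pd.DataFrame, catalog: CcreCatalog) -> dict:
    """Count DMRs overlapping cCREs, per category and in total.

    A DMR touching elements of several categories counts once per category
    but only once in the overlapped total (>= 1 bp overlap). Returns a dict
    with a per-category table and overlapped count/percent of all DMRs.
    """
    trees = _interval_trees(catalog.elements) if len(catalog) else {}
    per_category = {cat: 0 for cat in CCRE_CATEGORIES}
    n_overlapped = 0
    for dmr in dmrs.itertuples(index=False):
        tree = trees.get(dmr.chrom)
        if tree is None:
            continue
        hits = tree.overlap(int(dmr.start), int(dmr.end))
        if not hits:
            continue
        n_overlapped += 1
        cats = {catalog.elements.loc[h.data, "category"] for h in hits}
        for cat in cats:
            per_category[cat] += 1
    total = len(dmrs)
    table = pd.DataFrame(
        {
            "category": list(CCRE_CATEGORIES),
            "count": [per_category[c] for c in CCRE_CATEGORIES],
        }
    )
    denom = n_overlapped if n_overlapped else np.nan
    table["percent_of_overlapped"] = 100.0 * table["count"] / denom
    return {
        "table": table,
        "n_dmrs": total,
        "n_overlapped": n_overlapped,
        "percent_overlapped": (100.0 * n_overlapped / total) if total else float("nan"),
    }


def overlap_dmrs_genes(dmrs: pd.DataFrame, annotation: GeneAnnotation) -> dict:
    """Label each DMR genic (>= 1 bp overlap with a gene body) or intergenic."""
    trees = _interval_trees(annotation.genes) if len(annotation) else {}
    genic = np.zeros(len(dmrs), dtype=bool)
    for i, dmr in enumerate(dmrs.itertuples(index=False)):
        tree = trees.get(dmr.chrom)
        if tree is not None and tree.overlaps(int(dmr.start), int(dmr.end)):
            genic[i] = True
    n = len(dmrs)
    n_genic = int(genic.sum())
    return {
        "labels": pd.Series(np.where(genic, "genic", "intergenic")),
        "n_dmrs": n,
        "n_genic": n_genic,
        "n_intergenic": n - n_genic,
        "percent_genic": (100.0 * n_genic / n) if n else float("nan"),
        "percent_intergenic": (100.0 * (n - n_genic) / n) if n else float("nan"),
    }
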