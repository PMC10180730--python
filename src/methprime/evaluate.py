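"""Recovery metrics against a simulated truth manifest."""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datasets import MethylationDataset


def dmr_recovery(called: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Interval-level recall/precision of called DMRs vs planted regions.

    A planted region is recovered when any called DMR overlaps it (>= 1 bp);
    a called DMR is a true positive when it overlaps any planted region.
    """
    trees: dict[str, IntervalTree] = {}
    for row in truth.itertuples(index=False):
        tree = trees.setdefault(row.chrom, IntervalTree())
        tree.addi(int(row.start), int(row.end), row.name)
    recovered: set[str] = set()
    n_tp = 0
    for row in called.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = tree.overlap(int(row.start), int(row.end)) if tree else set()
        if hits:
            n_tp += 1
            recovered |= {h.data for h in hits}
    return {
        "n_called": int(len(called)),
        "n_true": int(len(truth)),
        "n_recovered": len(recovered),
        "recall": len(recovered) / len(truth) if len(truth) else float("nan"),
        "precision": n_tp / len(called) if len(called) else float("nan"),
    }


def realized_delta_me(dataset: MethylationDataset, truth: pd.DataFrame,
                      treatment: str, control: str) -> np.ndarray:
    """Realized group methylation difference per planted region.

    Measured directly from the emitted counts (mean over member CpGs of the
    per-sample-fraction group means), so it estimates the planted effect
    without the selection bias of conditioning on a significance call.
    """
    ti = dataset.sample_indices(treatment)
    ci = dataset.sample_indices(control)
    cov = dataset.coverage
    with np.errstate(invalid="ignore"):
        frac = np.where(cov > 0, dataset.meth / np.maximum(cov, 1), np.nan)
    site_delta = np.nanmean(frac[:, ti], axis=1) - np.nanmean(frac[:, ci], axis=1)
    chrom = dataset.sites["chrom"].to_numpy()
    pos = dataset.sites["pos"].to_numpy()
    out = []
    for row in truth.itertuples(index=False):
        mask = (chrom == row.chrom) & (pos >= row.start) & (pos < row.end)
        out.append(float(np.nanmean(site_delta[mask])) if mask.any() else np.nan)
    return np.array(out)


def deg_recovery(called: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Gene-level recall and observed false discovery of called DEGs."""
    called_ids = set(called["gene_id"])
    true_ids = set(truth["gene_id"])
    n_tp = len(called_ids & true_ids)
    return {
        "n_called": len(called_ids),
        "n_true": len(true_ids),
        "recall": n_tp / len(true_ids) if true_ids else float("nan"),
        "observed_fdr": (len(called_ids) - n_tp) / len(called_ids)
        if called_ids
        else float("nan"),
    }
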