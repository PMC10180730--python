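"""In-memory containers for methylation, expression and annotation data.

All genomic coordinates are 0-based, half-open internally. File readers and
writers convert at the boundary (bismark coverage files and GTF are 1-based
inclusive on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CCRE_CATEGORIES = ("PLS", "other-H3K4me3", "pELS", "dELS", "CTCF-only")


class MethprimeError(Exception):
    """Base class for package errors."""


class ConfigurationError(MethprimeError):
    """Invalid configuration or design (e.g. a missing group label)."""


class PlacementError(MethprimeError):
    """Simulated features cannot be placed under the given configuration."""


@dataclass
class MethylationDataset:
    """Per-CpG methylated/unmethylated counts for a set of samples.

    Parameters
    ----------
    sites : DataFrame with columns ``chrom`` (str) and ``pos`` (int, 0-based
        CpG start), sorted by (chrom, pos), one row per measured CpG.
    meth, unmeth : int arrays of shape (n_sites, n_samples) holding
        methylated and unmethylated read counts.
    samples : column order of `meth`/`unmeth`.
    design : DataFrame indexed by sample with columns ``group`` and
        (optionally) ``age``.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    unmeth: np.ndarray
    samples: list[str]
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.unmeth = np.asarray(self.unmeth, dtype=np.int64)
        n_sites = len(self.sites)
        if self.meth.shape != (n_sites, len(self.samples)):
            raise ValueError(
                f"meth shape {self.meth.shape} does not match "
                f"{n_sites} sites x {len(self.samples)} samples"
            )
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth and unmeth shapes differ")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise ValueError("negative counts")
        missing = set(self.samples) - set(self.design.index)
        if missing:
            raise ConfigurationError(f"samples missing from design: {sorted(missing)}")
        # positions strictly increasing within each chromosome
        for _, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError("CpG positions not strictly increasing within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def sample_indices(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to `group`."""
        members = self.design.index[self.design["group"] == group]
        idx = [self.samples.index(s) for s in members if s in self.samples]
        if not idx:
            raise ConfigurationError(f"no samples for group {group!r}")
        return np.array(idx, dtype=int)

    def groups(self) -> list[str]:
        present = self.design.loc[self.samples, "group"]
        return list(pd.unique(present))

    def subset_samples(self, samples: list[str]) -> "MethylationDataset":
        idx = [self.samples.index(s) for s in samples]
        return MethylationDataset(
            sites=self.sites.reset_index(drop=True),
            meth=self.meth[:, idx],
            unmeth=self.unmeth[:, idx],
            samples=list(samples),
            design=self.design.loc[samples],
        )


@dataclass
class ExpressionDataset:
    """Gene-level RNA-seq counts (genes x samples) with a group design."""

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ConfigurationError(f"samples missing from design: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def group_columns(self, group: str) -> list[str]:
        members = [s for s in self.counts.columns if self.design.loc[s, "group"] == group]
        if not members:
            raise ConfigurationError(f"no samples for group {group!r}")
        return members

    def subset_samples(self, samples: list[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.counts[list(samples)], self.design.loc[samples])


@dataclass
class GeneAnnotation:
    """Gene models with strand, supporting nearest-TSS queries.

    `genes` columns: gene_id, chrom, start, end, strand (0-based half-open).
    TSS is the 5' end: start for '+' genes, end-1 for '-' genes.
    """

    genes: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) and self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        self._tss_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    @property
    def tss(self) -> pd.Series:
        """TSS coordinate per gene (indexed by gene_id)."""
        if not len(self.genes):
            return pd.Series(dtype=np.int64)
        pos = np.where(
            self.genes["strand"].to_numpy() == "+",
            self.genes["start"].to_numpy(),
            self.genes["end"].to_numpy() - 1,
        )
        return pd.Series(pos, index=self.genes["gene_id"].to_numpy(), dtype=np.int64)

    def tss_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted TSS positions, gene ids, strands)."""
        if self._tss_index is None:
            index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            if len(self.genes):
                tss = self.tss
                frame = self.genes.assign(tss=tss.to_numpy())
                for chrom, sub in frame.groupby("chrom", sort=False):
                    sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
                    index[chrom] = (
                        sub["tss"].to_numpy(np.int64),
                        sub["gene_id"].to_numpy(object),
                        sub["strand"].to_numpy(object),
                    )
            self._tss_index = index
        return self._tss_index

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CcreCatalog:
    """Candidate cis-regulatory elements with signal flags and category.

    `elements` columns: chrom, start, end, name, category, promoter_like,
    enhancer_like, ctcf. Categories follow the ENCODE registry scheme:
    PLS, other-H3K4me3, pELS, dELS, CTCF-only.
    """

    elements: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.elements):
            bad = set(self.elements["category"]) - set(CCRE_CATEGORIES)
            if bad:
                raise ValueError(f"unknown cCRE categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.elements)


def empty_dmr_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "name", "n_dmcs", "delta_me", "direction", "p_value"]
    )
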