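"""Readers and writers for the plain-text formats the pipeline touches.

Formats: bismark-coverage TSV (per-sample CpG counts), design TSV,
GTF-lite gene annotation, BED6+ (cCREs with signal flags / DMR tables),
genes x samples counts TSV. Disk coordinates follow each format's
convention (coverage and GTF 1-based inclusive, BED 0-based half-open);
in memory everything is 0-based half-open.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CcreCatalog, ExpressionDataset, GeneAnnotation, MethylationDataset

COVERAGE_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_meth", "count_unmeth"]


# ---------------------------------------------------------------- coverage

def read_coverage_file(path: str | os.PathLike) -> pd.DataFrame:
    """Read one bismark-style coverage file into a 0-based frame.

    Columns on disk: chrom, start (1-based), end (1-based inclusive),
    methylation percent, methylated count, unmethylated count.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=COVERAGE_COLUMNS,
        dtype={"chrom": str},
    )
    if df.isna().any().any():
        raise ValueError(f"malformed coverage file: {path}")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64) - 1,
            "meth": df["count_meth"].astype(np.int64),
            "unmeth": df["count_unmeth"].astype(np.int64),
        }
    )
    return out


def write_coverage_file(path: str | os.PathLike, sites: pd.DataFrame,
                        meth: np.ndarray, unmeth: np.ndarray) -> None:
    """Write one sample's counts as a bismark-style coverage file."""
    cov = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "start": sites["pos"].to_numpy() + 1,
            "end": sites["pos"].to_numpy() + 1,
            "meth_pct": np.round(pct, 6),
            "count_meth": meth,
            "count_unmeth": unmeth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    """Design TSV with columns sample, group and optionally age."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in design.columns or "group" not in design.columns:
        raise ValueError(f"design file {path} needs 'sample' and 'group' columns")
    if design["sample"].duplicated().any():
        raise ValueError(f"duplicate samples in design file {path}")
    return design.set_index("sample")


def write_design(path: str | os.PathLike, design: pd.DataFrame) -> None:
    design.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_methylation_dataset(coverage_dir: str | os.PathLike,
                             design: pd.DataFrame,
                             suffix: str = ".cov") -> MethylationDataset:
    """Assemble a MethylationDataset from per-sample coverage files.

    Each sample in `design` must have a file ``<sample><suffix>`` in
    `coverage_dir`. Sites absent from a sample get zero counts there.
    """
    coverage_dir = Path(coverage_dir)
    per_sample: dict[str, pd.DataFrame] = {}
    for sample in design.index:
        path = coverage_dir / f"{sample}{suffix}"
        if not path.exists():
            raise FileNotFoundError(f"no coverage file for sample {sample!r}: {path}")
        per_sample[sample] = read_coverage_file(path)

    keys = pd.concat(
        [df[["chrom", "pos"]] for df in per_sample.values()], ignore_index=True
    ).drop_duplicates()
    sites = keys.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    site_order = pd.MultiIndex.from_frame(sites)

    samples = list(design.index)
    meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
    unmeth = np.zeros_like(meth)
    for j, sample in enumerate(samples):
        df = per_sample[sample].set_index(["chrom", "pos"])
        aligned = df.reindex(site_order)
        meth[:, j] = aligned["meth"].fillna(0).to_numpy(np.int64)
        unmeth[:, j] = aligned["unmeth"].fillna(0).to_numpy(np.int64)
    return MethylationDataset(sites=sites, meth=meth, unmeth=unmeth,
                              samples=samples, design=design)


# ---------------------------------------------------------------- GTF-lite

def write_gtf(path: str | os.PathLike, annotation: GeneAnnotation) -> None:
    """Write gene models as GTF-lite (one 'gene' feature line per gene)."""
    with open(path, "w") as fh:
        for chrom, size in sorted(annotation.chrom_sizes.items()):
            fh.write(f"#!chrom {chrom} length {size}\n")
        for row in annotation.genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\tmethprime\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str | os.PathLike) -> GeneAnnotation:
    """Read gene models from GTF-lite (gene features only)."""
    records = []
    chrom_sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if len(parts) == 4 and parts[0] == "#!chrom":
                    chrom_sizes[parts[1]] = int(parts[3])
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno} in {path}")
            if fields[2] != "gene":
                continue
            attrs = fields[8]
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(" ", 1)[1].strip().strip('"')
            if gene_id is None:
                raise ValueError(f"GTF line {lineno} in {path} lacks gene_id")
            records.append(
                {
                    "gene_id": gene_id,
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                }
            )
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------- BED6+

def write_ccre_bed(path: str | os.PathLike, catalog: CcreCatalog) -> None:
    """BED6 + category + signal flags (promoter_like, enhancer_like, ctcf)."""
    el = catalog.elements
    out = pd.DataFrame(
        {
            "chrom": el["chrom"],
            "start": el["start"],
            "end": el["end"],
            "name": el["name"],
            "score": 0,
            "strand": ".",
            "category": el["category"],
            "promoter_like": el["promoter_like"].astype(int),
            "enhancer_like": el["enhancer_like"].astype(int),
            "ctcf": el["ctcf"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_ccre_bed(path: str | os.PathLike) -> CcreCatalog:
    names = ["chrom", "start", "end", "name", "score", "strand",
             "category", "promoter_like", "enhancer_like", "ctcf"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    elements = df[["chrom", "start", "end", "name", "category"]].copy()
    for flag in ("promoter_like", "enhancer_like", "ctcf"):
        elements[flag] = df[flag].astype(bool)
    return CcreCatalog(elements=elements)


def write_dmr_bed(path: str | os.PathLike, dmrs: pd.DataFrame) -> None:
    """DMR table as BED6+ (score = -log10 p; extras: delta_me, n_dmcs, direction)."""
    with np.errstate(divide="ignore"):
        score = np.where(
            dmrs["p_value"].to_numpy(float) > 0,
            -np.log10(dmrs["p_value"].to_numpy(float)),
            np.inf,
        ) if len(dmrs) else np.array([])
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["name"],
            "score": np.round(np.clip(score, 0, 1000), 4),
            "strand": ".",
            "delta_me": np.round(dmrs["delta_me"].to_numpy(float), 6),
            "n_dmcs": dmrs["n_dmcs"],
            "direction": dmrs["direction"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_dmr_bed(path: str | os.PathLike) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand",
             "delta_me", "n_dmcs", "direction"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    df["p_value"] = np.power(10.0, -df["score"].to_numpy(float))
    return df[["chrom", "start", "end", "name", "n_dmcs", "delta_me", "direction", "p_value"]]


# ---------------------------------------------------------------- counts

def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return counts


def write_counts(path: str | os.PathLike, counts: pd.DataFrame) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression_dataset(counts_path: str | os.PathLike,
                            design: pd.DataFrame) -> ExpressionDataset:
    counts = read_counts(counts_path)
    cols = [c for c in counts.columns if c in design.index]
    return ExpressionDataset(counts[cols], design.loc[cols])
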