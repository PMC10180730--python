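"""Synthetic study generator: annotation, cCREs, RRBS counts, RNA-seq counts.

The generator emulates the data structure of a two-group (treatment vs
control) RRBS + RNA-seq comparison in mouse liver at desk scale: one 10 Mb
chromosome, 20,000 CpGs and 200 genes stand in for a genome-wide ~2M-CpG
methylome. CpGs are emitted in MspI-fragment-like clusters (3-12 CpGs
within 100-600 bp, with a promoter-proximal excess), matching RRBS's
fragment-based coverage and guaranteeing multi-CpG windows for planted
DMRs. Baseline methylation is bimodal: TSS-proximal CpGs (<= 2 kb) are
lowly methylated (Beta(1,10)), distal CpGs highly methylated (Beta(10,1)),
so regulatory regions are hypomethylated as in real somatic methylomes.

Planted DMRs shift the treatment-group methylation of whole CpG fragments
by a signed delta-me; their baselines are drawn direction-compatibly so the
planted effect is realized without clipping (clipping of user-forced
extremes is counted and warned). Planted DEGs multiply the treatment-group
expression mean by 2**log2FC. Per-sample coverage is negative-binomial
truncated at >= 1 read; methylated counts are beta-binomial (binomial when
the overdispersion rho is 0, the default, matching the binomial
within-group model of the DMC caller). Every output artifact draws from
its own RNG stream derived from the master seed by a fixed label, so
adding an artifact never perturbs existing ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .datasets import (
    CcreCatalog,
    ExpressionDataset,
    GeneAnnotation,
    MethylationDataset,
    PlacementError,
)
from .regulatory import classify_ccre

# fixed per-artifact RNG stream labels (order must never change)
_STREAMS = {"annotation": 1, "ccre": 2, "rrbs": 3, "rnaseq": 4, "background": 5}

PROXIMAL_TSS_WINDOW = 5_000  # planted-DMR proximal/distal split
PROMOTER_WINDOW = 2_000  # low-methylation baseline window around TSS


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Scale defaults are a desk-scale stand-in for a genome-wide RRBS study
    (which covers on the order of 2M CpGs per sample); effect-size defaults
    are anchored to the observed study conditions: 5 samples per group,
    71% of treatment-effect DMRs hypomethylated, mean |delta-me| 0.18, and
    84% of DMRs distal (> 5 kb) to any TSS; planted DEGs have
    |log2FC| >= 1.
    """

    n_chroms: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 200
    n_cpgs: int = 20_000
    n_samples_per_group: int = 5
    n_planted_dmrs: int = 200
    hypo_fraction: float = 0.71
    mean_abs_delta_me: float = 0.18
    dmr_distal_fraction: float = 0.84
    n_planted_degs: int = 30
    deg_lfc_magnitude: float = 2.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.1
    meth_overdispersion: float = 0.0
    nb_dispersion: float = 0.05
    n_ccres: int = 500
    seed: int = 0
    treatment: str = "AME"
    control: str = "Con"
    age: str = "d0"

    def __post_init__(self) -> None:
        for name in ("hypo_fraction", "dmr_distal_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.meth_overdispersion < 1.0):
            raise ValueError("meth_overdispersion must be in [0, 1)")
        if not (0.0 < self.mean_abs_delta_me < 1.0):
            raise ValueError("mean_abs_delta_me must be in (0, 1)")
        for name in ("n_chroms", "chrom_length", "n_samples_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_cpgs", "n_planted_dmrs", "n_planted_degs", "n_ccres"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0 or self.nb_dispersion <= 0:
            raise ValueError("coverage and dispersion parameters must be positive")
        if self.deg_lfc_magnitude < 0:
            raise ValueError("deg_lfc_magnitude must be non-negative")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass
class TruthSet:
    """Ground truth manifest for planted effects."""

    planted_dmrs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["name", "chrom", "start", "end", "delta_me", "direction", "n_cpgs"]
        )
    )
    planted_degs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "true_log2fc"])
    )
    null_region_ids: list[str] = field(default_factory=list)

    def validate(self, chrom_sizes: dict[str, int]) -> None:
        dmrs = self.planted_dmrs.sort_values(["chrom", "start"])
        prev_end: dict[str, int] = {}
        for row in dmrs.itertuples(index=False):
            if row.start < 0 or row.end > chrom_sizes.get(row.chrom, 0):
                raise ValueError(f"planted DMR {row.name} outside chromosome bounds")
            if row.chrom in prev_end and row.start < prev_end[row.chrom]:
                raise ValueError("planted DMR intervals overlap")
            prev_end[row.chrom] = row.end
            expected = "hypo" if row.delta_me < 0 else "hyper"
            if row.direction != expected:
                raise ValueError(f"direction of {row.name} disagrees with delta_me sign")

    def to_json(self) -> str:
        payload = {
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
            "planted_degs": self.planted_degs.to_dict(orient="records"),
            "null_region_ids": list(self.null_region_ids),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        payload = json.loads(text)
        return cls(
            planted_dmrs=pd.DataFrame(
                payload["planted_dmrs"],
                columns=["name", "chrom", "start", "end", "delta_me", "direction", "n_cpgs"],
            ),
            planted_degs=pd.DataFrame(
                payload["planted_degs"], columns=["gene_id", "true_log2fc"]
            ),
            null_region_ids=payload["null_region_ids"],
        )


def _rng(config: SimConfig, label: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[label]])


# ------------------------------------------------------------- annotation

def generate_annotation(config: SimConfig) -> GeneAnnotation:
    """Place non-overlapping gene models with uniform strands.

    Gene lengths are uniform on [2, 20] kb; starts come from a uniform
    partition of the free space per chromosome. Raises PlacementError if
    the genes cannot fit.
    """
    rng = _rng(config, "annotation")
    chroms = config.chrom_names()
    if config.n_genes == 0:
        return GeneAnnotation(
            genes=pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"]),
            chrom_sizes=config.chrom_sizes(),
        )
    assignment = rng.integers(0, len(chroms), size=config.n_genes)
    records = []
    gene_no = 0
    for ci, chrom in enumerate(chroms):
        n_here = int((assignment == ci).sum())
        if n_here == 0:
            continue
        lengths = rng.integers(2_000, 20_001, size=n_here)
        free = config.chrom_length - int(lengths.sum())
        if free <= n_here:
            raise PlacementError(
                f"cannot place {n_here} genes of total length {lengths.sum()} "
                f"on {chrom} (length {config.chrom_length})"
            )
        offsets = np.sort(rng.choice(free, size=n_here, replace=False))
        starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.choice(["+", "-"], size=n_here)
        for k in range(n_here):
            gene_no += 1
            records.append(
                {
                    "gene_id": f"G{gene_no:05d}",
                    "chrom": chrom,
                    "start": int(starts[k]),
                    "end": int(starts[k] + lengths[k]),
                    "strand": strands[k],
                }
            )
    genes = pd.DataFrame(records).sort_values(["chrom", "start"], kind="mergesort")
    return GeneAnnotation(genes=genes.reset_index(drop=True), chrom_sizes=config.chrom_sizes())


# ------------------------------------------------------------------ cCREs

def generate_ccre_catalog(annotation: GeneAnnotation, config: SimConfig) -> CcreCatalog:
    """Emit a cCRE catalog whose categories match its own geometry.

    Signal mix: ~30% promoter-like (half hugging a TSS, half farther),
    ~55% enhancer-like (split across the 2 kb proximal/distal boundary),
    ~15% CTCF-only. Categories are assigned by re-classification from
    coordinates and flags, so the catalog is self-consistent by
    construction.
    """
    rng = _rng(config, "ccre")
    if config.n_ccres == 0:
        return CcreCatalog(
            elements=pd.DataFrame(
                columns=["chrom", "start", "end", "name", "category",
                         "promoter_like", "enhancer_like", "ctcf"]
            )
        )
    tss = annotation.tss
    tss_frame = annotation.genes.assign(tss=tss.to_numpy()) if len(annotation) else None
    if tss_frame is None or not len(tss_frame):
        raise PlacementError("cannot place promoter-class cCREs without genes")
    chroms = config.chrom_names()
    records = []
    kinds = rng.choice(
        ["promoter", "enhancer", "ctcf"], size=config.n_ccres, p=[0.30, 0.55, 0.15]
    )
    for i, kind in enumerate(kinds):
        width = int(rng.integers(150, 351))
        if kind in ("promoter", "enhancer"):
            gene = tss_frame.iloc[int(rng.integers(0, len(tss_frame)))]
            chrom, anchor = gene["chrom"], int(gene["tss"])
            if kind == "promoter":
                # half near the TSS (PLS), half 0.3-5 kb away (other-H3K4me3)
                offset = (
                    int(rng.integers(-150, 151))
                    if rng.random() < 0.5
                    else int(rng.choice([-1, 1]) * rng.integers(300, 5_001))
                )
            else:
                # split across the 2 kb pELS/dELS boundary
                offset = (
                    int(rng.choice([-1, 1]) * rng.integers(0, 1_800))
                    if rng.random() < 0.5
                    else int(rng.choice([-1, 1]) * rng.integers(2_500, 100_001))
                )
            mid = anchor + offset
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            mid = int(rng.integers(0, config.chrom_length))
        start = max(0, mid - width // 2)
        end = min(config.chrom_length, start + width)
        flags = {
            "promoter_like": kind == "promoter",
            "enhancer_like": kind == "enhancer",
            "ctcf": kind == "ctcf",
        }
        category = classify_ccre(chrom, start, end, annotation=annotation, **flags)
        records.append(
            {"chrom": chrom, "start": start, "end": end, "name": f"ccre_{i + 1}",
             "category": category, **flags}
        )
    elements = pd.DataFrame(records).sort_values(["chrom", "start"], kind="mergesort")
    return CcreCatalog(elements=elements.reset_index(drop=True))


# ------------------------------------------------------------------- RRBS

def _generate_fragments(config: SimConfig, annotation: GeneAnnotation,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Disjoint MspI-fragment-like CpG clusters totalling n_cpgs CpGs.

    Returns a frame with one row per CpG: chrom, pos, fragment id. ~30% of
    fragments sit within 2 kb of a TSS (RRBS promoter bias).
    """
    tss_by_chrom = {c: v[0] for c, v in annotation.tss_index().items()}
    chroms = config.chrom_names()
    frag_records: list[tuple[str, int, np.ndarray]] = []
    frag_no = 0
    kept: list[tuple[str, int, np.ndarray]] = []

    def _dedupe() -> int:
        """Keep a maximal disjoint subset of fragments; return CpG total."""
        nonlocal kept
        frag_records.sort(key=lambda r: (r[0], int(r[2][0])))
        kept = []
        last_end: dict[str, int] = {}
        n = 0
        for chrom, fid, pos in frag_records:
            if chrom in last_end and int(pos[0]) <= last_end[chrom]:
                continue
            kept.append((chrom, fid, pos))
            last_end[chrom] = int(pos[-1]) + 1
            n += len(pos)
        return n

    guard = 0
    count = 0
    while count < config.n_cpgs:
        guard += 1
        if guard > 500:
            raise PlacementError("cannot place requested number of CpGs")
        batch = max(64, (config.n_cpgs - count) // 4)
        for _ in range(batch):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            proximal = rng.random() < 0.30 and len(tss_by_chrom.get(chrom, [])) > 0
            if proximal:
                tss = int(rng.choice(tss_by_chrom[chrom]))
                center = tss + int(rng.integers(-PROMOTER_WINDOW, PROMOTER_WINDOW + 1))
            else:
                center = int(rng.integers(0, config.chrom_length))
            k = int(min(3 + rng.poisson(3), 12))
            span = int(rng.integers(100, 601))
            offsets = np.sort(rng.choice(span, size=min(k, span // 2), replace=False))
            pos = np.clip(center - span // 2 + offsets, 0, config.chrom_length - 2)
            pos = np.unique(pos)
            if len(pos) < 3:
                continue
            frag_no += 1
            frag_records.append((chrom, frag_no, pos))
        count = _dedupe()

    rows = []
    count = 0
    for chrom, fid, pos in kept:
        if count >= config.n_cpgs:
            break
        take = pos[: config.n_cpgs - count]
        for p in take:
            rows.append((chrom, int(p), fid))
        count += len(take)
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "fragment"])
    return frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _truncated_nb(rng: np.random.Generator, mean: float, dispersion: float,
                  size: tuple[int, ...]) -> np.ndarray:
    """NB(mean, dispersion) draws truncated at >= 1 (var = mu + d*mu^2)."""
    n_param = 1.0 / dispersion
    p_param = n_param / (n_param + mean)
    draws = rng.negative_binomial(n_param, p_param, size=size)
    for _ in range(8):
        zeros = draws == 0
        if not zeros.any():
            break
        draws[zeros] = rng.negative_binomial(n_param, p_param, size=int(zeros.sum()))
    return np.maximum(draws, 1)


def _fragment_tss_distance(frame: pd.DataFrame, annotation: GeneAnnotation) -> pd.Series:
    """Min distance of each fragment's span to any TSS (inf if none)."""
    index = {c: v[0] for c, v in annotation.tss_index().items()}
    out = {}
    for (chrom, fid), sub in frame.groupby(["chrom", "fragment"], sort=False):
        lo, hi = int(sub["pos"].min()), int(sub["pos"].max())
        positions = index.get(chrom)
        if positions is None or not len(positions):
            out[fid] = float("inf")
            continue
        i = int(np.searchsorted(positions, lo))
        best = float("inf")
        for j in (i - 1, i, int(np.searchsorted(positions, hi)) - 1,
                  int(np.searchsorted(positions, hi))):
            if 0 <= j < len(positions):
                t = int(positions[j])
                d = 0 if lo <= t <= hi else min(abs(t - lo), abs(t - hi))
                best = min(best, d)
        out[fid] = best
    return pd.Series(out)


def simulate_rrbs(annotation: GeneAnnotation, config: SimConfig,
                  fragments: pd.DataFrame | None = None
                  ) -> tuple[MethylationDataset, TruthSet]:
    """Simulate per-sample CpG counts with planted DMRs.

    Returns the dataset (2 x n_samples_per_group samples) and the truth
    manifest of planted regions. Passing `fragments` (a frame from a prior
    run's CpG layout) reuses the measured-site universe, as when one assay
    covers several comparisons.
    """
    rng = _rng(config, "rrbs")
    frame = _generate_fragments(config, annotation, rng) if fragments is None else fragments
    n_sites = len(frame)

    # baseline methylation: low near TSS, high distal
    tss_dist = np.full(n_sites, np.inf)
    index = {c: v[0] for c, v in annotation.tss_index().items()}
    for chrom, sub in frame.groupby("chrom", sort=False):
        positions = index.get(chrom)
        if positions is None or not len(positions):
            continue
        pos = sub["pos"].to_numpy()
        i = np.searchsorted(positions, pos)
        left = np.abs(pos - positions[np.clip(i - 1, 0, len(positions) - 1)])
        right = np.abs(pos - positions[np.clip(i, 0, len(positions) - 1)])
        tss_dist[sub.index] = np.minimum(left, right)
    proximal = tss_dist <= PROMOTER_WINDOW
    pi = np.where(
        proximal,
        rng.beta(1, 10, size=n_sites),
        rng.beta(10, 1, size=n_sites),
    )

    # choose planted fragments
    truth = TruthSet()
    delta_site = np.zeros(n_sites)
    frag_sizes = frame.groupby("fragment")["pos"].count()
    frag_dist = _fragment_tss_distance(frame, annotation)
    frag_span = frame.groupby("fragment")["pos"].agg(lambda s: s.max() - s.min())
    eligible = frag_sizes.index[(frag_sizes >= 3) & (frag_span >= 50)]
    planted_ids: list[int] = []
    if config.n_planted_dmrs > 0:
        distal_pool = [f for f in eligible if frag_dist.loc[f] > PROXIMAL_TSS_WINDOW]
        proximal_pool = [f for f in eligible if frag_dist.loc[f] <= PROXIMAL_TSS_WINDOW]
        n_distal = int(round(config.n_planted_dmrs * config.dmr_distal_fraction))
        n_proximal = config.n_planted_dmrs - n_distal
        if n_distal > len(distal_pool) or n_proximal > len(proximal_pool):
            raise PlacementError(
                f"not enough eligible CpG fragments to plant {config.n_planted_dmrs} DMRs "
                f"({len(distal_pool)} distal / {len(proximal_pool)} proximal available)"
            )
        planted_ids = list(rng.choice(distal_pool, size=n_distal, replace=False)) + list(
            rng.choice(proximal_pool, size=n_proximal, replace=False)
        )
        n_hypo = int(round(config.n_planted_dmrs * config.hypo_fraction))
        signs = np.array([-1.0] * n_hypo + [1.0] * (config.n_planted_dmrs - n_hypo))
        rng.shuffle(signs)
        lo = max(0.02, config.mean_abs_delta_me - 0.12)
        hi = min(config.mean_abs_delta_me + (config.mean_abs_delta_me - lo), 0.9)
        magnitudes = np.clip(
            rng.normal(config.mean_abs_delta_me, 0.04, size=config.n_planted_dmrs), lo, hi
        )
        records = []
        for k, fid in enumerate(planted_ids):
            members = frame.index[frame["fragment"] == fid]
            signed = float(signs[k] * magnitudes[k])
            # direction-compatible baseline so the shift stays inside [0, 1]
            if signed < 0:
                base = rng.uniform(abs(signed) + 0.05, 0.97, size=len(members))
            else:
                base = rng.uniform(0.03, 0.95 - signed, size=len(members))
            pi[members] = base
            delta_site[members] = signed
            sub = frame.loc[members]
            records.append(
                {
                    "name": f"planted_{k + 1}",
                    "chrom": sub["chrom"].iloc[0],
                    "start": int(sub["pos"].min()),
                    "end": int(sub["pos"].max()) + 2,
                    "delta_me": signed,
                    "direction": "hypo" if signed < 0 else "hyper",
                    "n_cpgs": int(len(members)),
                }
            )
        truth.planted_dmrs = pd.DataFrame(records)
    truth.null_region_ids = [
        f"fragment_{f}" for f in frag_sizes.index if f not in set(planted_ids)
    ]
    truth.validate(config.chrom_sizes())

    # sample counts
    n_per = config.n_samples_per_group
    samples = [f"{config.control}_{config.age}_{i + 1}" for i in range(n_per)] + [
        f"{config.treatment}_{config.age}_{i + 1}" for i in range(n_per)
    ]
    is_treatment = np.array([False] * n_per + [True] * n_per)
    coverage = _truncated_nb(
        rng, config.coverage_mean, config.coverage_dispersion, (n_sites, len(samples))
    )
    pi_treat = pi + delta_site
    n_clipped = int(((pi_treat < 0) | (pi_treat > 1)).sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} CpG methylation levels clipped to [0, 1] after delta-me shift",
            RuntimeWarning,
            stacklevel=2,
        )
    pi_treat = np.clip(pi_treat, 0.0, 1.0)
    meth = np.zeros_like(coverage)
    rho = config.meth_overdispersion
    for j, treat in enumerate(is_treatment):
        level = pi_treat if treat else pi
        if rho == 0:
            meth[:, j] = rng.binomial(coverage[:, j], level)
        else:
            a = level * (1 - rho) / rho
            b = (1 - level) * (1 - rho) / rho
            p = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
            meth[:, j] = rng.binomial(coverage[:, j], p)
    unmeth = coverage - meth

    design = pd.DataFrame(
        {
            "group": np.where(is_treatment, config.treatment, config.control),
            "age": config.age,
        },
        index=pd.Index(samples, name="sample"),
    )
    dataset = MethylationDataset(
        sites=frame[["chrom", "pos"]].reset_index(drop=True),
        meth=meth,
        unmeth=unmeth,
        samples=samples,
        design=design,
    )
    return dataset, truth


# ---------------------------------------------------------------- RNA-seq

def simulate_rnaseq(annotation: GeneAnnotation, config: SimConfig
                    ) -> tuple[ExpressionDataset, TruthSet]:
    """Simulate gene-level NB counts with planted DEGs.

    Base means are log-normal (median ~100 counts); planted DEGs multiply
    the treatment mean by 2**(+/- deg_lfc_magnitude) with random sign;
    per-sample size factors are log-normal with geometric mean 1.
    """
    rng = _rng(config, "rnaseq")
    genes = list(annotation.genes["gene_id"])
    if config.n_planted_degs > len(genes):
        raise PlacementError(
            f"cannot plant {config.n_planted_degs} DEGs among {len(genes)} genes"
        )
    n_genes = len(genes)
    n_per = config.n_samples_per_group
    samples = [f"{config.control}_{config.age}_{i + 1}" for i in range(n_per)] + [
        f"{config.treatment}_{config.age}_{i + 1}" for i in range(n_per)
    ]
    is_treatment = np.array([False] * n_per + [True] * n_per)

    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    lfc = np.zeros(n_genes)
    truth = TruthSet()
    if config.n_planted_degs > 0:
        planted_idx = rng.choice(n_genes, size=config.n_planted_degs, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_planted_degs)
        lfc[planted_idx] = signs * config.deg_lfc_magnitude
        truth.planted_degs = pd.DataFrame(
            {
                "gene_id": [genes[i] for i in planted_idx],
                "true_log2fc": lfc[planted_idx],
            }
        ).sort_values("gene_id").reset_index(drop=True)

    size_f = rng.lognormal(mean=0.0, sigma=0.15, size=len(samples))
    size_f /= np.exp(np.mean(np.log(size_f)))

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    n_param = 1.0 / config.nb_dispersion
    for j, treat in enumerate(is_treatment):
        mu = base_mean * size_f[j] * np.where(treat, 2.0 ** lfc, 1.0)
        p_param = n_param / (n_param + mu)
        counts[:, j] = rng.negative_binomial(n_param, p_param)

    design = pd.DataFrame(
        {
            "group": np.where(is_treatment, config.treatment, config.control),
            "age": config.age,
        },
        index=pd.Index(samples, name="sample"),
    )
    dataset = ExpressionDataset(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        design=design,
    )
    return dataset, truth


# ----------------------------------------------------------------- driver

@dataclass
class SimulatedStudy:
    """One simulated two-group comparison plus shared annotation artifacts."""

    config: SimConfig
    annotation: GeneAnnotation
    ccres: CcreCatalog
    methylation: MethylationDataset
    expression: ExpressionDataset
    truth: TruthSet


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run all generators for one comparison under one master seed."""
    annotation = generate_annotation(config)
    ccres = generate_ccre_catalog(annotation, config) if config.n_genes else CcreCatalog(
        elements=pd.DataFrame(
            columns=["chrom", "start", "end", "name", "category",
                     "promoter_like", "enhancer_like", "ctcf"]
        )
    )
    methylation, truth_m = simulate_rrbs(annotation, config)
    expression, truth_e = simulate_rnaseq(annotation, config)
    truth = TruthSet(
        planted_dmrs=truth_m.planted_dmrs,
        planted_degs=truth_e.planted_degs,
        null_region_ids=truth_m.null_region_ids,
    )
    return SimulatedStudy(
        config=config, annotation=annotation, ccres=ccres,
        methylation=methylation, expression=expression, truth=truth)


@dataclass
class TwoAgeStudy:
    """Two comparisons (e.g. birth and weaning) over one shared genome.

    Both ages share the gene annotation, cCRE catalog and measured-CpG
    layout; methylation and expression counts, planted effects and group
    labels are drawn independently per age.
    """

    config_a: SimConfig
    config_b: SimConfig
    annotation: GeneAnnotation
    ccres: CcreCatalog
    methylation: dict[str, MethylationDataset]
    expression: dict[str, ExpressionDataset]
    truth: dict[str, TruthSet]


def simulate_two_age_study(config_a: SimConfig, config_b: SimConfig) -> TwoAgeStudy:
    """Simulate the same cohort design at two ages over one genome.

    The annotation, cCREs and CpG site universe come from `config_a`;
    `config_b` must agree on the genome-scale fields and carry a different
    age label (and typically its own seed, hypo_fraction etc.).
    """
    if config_a.age == config_b.age:
        raise ValueError("the two configs must use different age labels")
    for name in ("n_chroms", "chrom_length", "n_genes", "n_cpgs"):
        if getattr(config_a, name) != getattr(config_b, name):
            raise ValueError(f"configs disagree on {name}")
    annotation = generate_annotation(config_a)
    ccres = generate_ccre_catalog(annotation, config_a)
    fragments = _generate_fragments(config_a, annotation, _rng(config_a, "rrbs"))
    meth: dict[str, MethylationDataset] = {}
    expr: dict[str, ExpressionDataset] = {}
    truth: dict[str, TruthSet] = {}
    for config in (config_a, config_b):
        m, tm = simulate_rrbs(annotation, config, fragments=fragments)
        e, te = simulate_rnaseq(annotation, config)
        meth[config.age] = m
        expr[config.age] = e
        truth[config.age] = TruthSet(
            planted_dmrs=tm.planted_dmrs,
            planted_degs=te.planted_degs,
            null_region_ids=tm.null_region_ids,
        )
    return TwoAgeStudy(config_a=config_a, config_b=config_b, annotation=annotation,
                       ccres=ccres, methylation=meth, expression=expr, truth=truth)


def write_two_age_study(study: TwoAgeStudy, outdir: str | Path) -> None:
    """Write a two-age study: one coverage dir, one design, merged counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    designs = []
    counts = []
    for age, ds in study.methylation.items():
        for j, sample in enumerate(ds.samples):
            mio.write_coverage_file(covdir / f"{sample}.cov", ds.sites,
                                    ds.meth[:, j], ds.unmeth[:, j])
        designs.append(ds.design)
        counts.append(study.expression[age].counts)
        (outdir / f"truth_{age}.json").write_text(study.truth[age].to_json() + "\n")
    mio.write_design(outdir / "design.tsv", pd.concat(designs))
    mio.write_counts(outdir / "counts.tsv", pd.concat(counts, axis=1))
    mio.write_gtf(outdir / "genes.gtf", study.annotation)
    mio.write_ccre_bed(outdir / "ccres.bed", study.ccres)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write all artifacts of a simulated study as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    ds = study.methylation
    for j, sample in enumerate(ds.samples):
        mio.write_coverage_file(covdir / f"{sample}.cov", ds.sites, ds.meth[:, j], ds.unmeth[:, j])
    mio.write_gtf(outdir / "genes.gtf", study.annotation)
    mio.write_ccre_bed(outdir / "ccres.bed", study.ccres)
    mio.write_counts(outdir / "counts.tsv", study.expression.counts)
    design = ds.design
    mio.write_design(outdir / "design.tsv", design)
    (outdir / "truth.json").write_text(study.truth.to_json() + "\n")
    (outdir / "sim_config.json").write_text(
        json.dumps(asdict(study.config), indent=2, sort_keys=True) + "\n"
    )
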