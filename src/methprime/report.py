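"""Pipeline orchestration and the study-style summary report.

`run_pipeline` reads all inputs named in a PipelineConfig, runs per-age
group comparisons (differential methylation, gene / cCRE annotation,
TSS-distance enrichment against a sampled CpG background, differential
expression, DMR-DEG linkage), intersects DMR sets across two ages when
present, and writes a machine-readable JSON report plus TSV tables.
All printed percentages are round-half-up to one decimal with their
denominators carried alongside.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .datasets import ConfigurationError
from .expression import DifferentialExpression
from .integrate import link_dmrs_degs, shared_dmrs, summarize_links
from .methylation import DifferentialMethylation
from .regulatory import overlap_dmrs_ccres, overlap_dmrs_genes
from .tss_enrichment import assign_regions, bin_distances, compare_to_background, sample_background

logger = logging.getLogger(__name__)


def percent(count: int, total: int) -> float | None:
    """Percentage rounded half-up to one decimal; None (NA) when total is 0."""
    if total == 0:
        return None
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Paths, thresholds and the master seed for a full pipeline run."""

    coverage_dir: str = ""
    counts: str = ""
    design: str = ""
    genes: str = ""
    ccres: str = ""
    treatment: str = "AME"
    control: str = "Con"
    alpha: float = 0.001
    min_delta: float = 0.10
    min_coverage: int = 10
    max_gap: int = 250
    min_dmcs: int = 1
    fdr: float = 0.05
    min_abs_lfc: float = 1.0
    link_window: int = 25_000
    background_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1) or not (0 <= self.min_delta <= 1):
            raise ValueError("alpha must be in (0,1], min_delta in [0,1]")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0,1]")
        if not (0 < self.background_fraction <= 1):
            raise ValueError("background_fraction must be in (0,1]")
        if min(self.min_coverage, self.max_gap, self.min_dmcs, self.link_window) < 0:
            raise ValueError("count thresholds must be non-negative")
        if self.min_abs_lfc < 0:
            raise ValueError("min_abs_lfc must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ------------------------------------------------------------- report schema

_COMPARISON_SCHEMA = {
    "age": str,
    "treatment": str,
    "control": str,
    "n_testable_sites": int,
    "n_dmcs": int,
    "n_dmrs": int,
    "hypo_fraction": (float, type(None)),
    "hypo_binomial_p": (float, type(None)),
    "mean_abs_delta_me": (float, type(None)),
    "genic": dict,
    "ccre": (dict, type(None)),
    "tss_bins": list,
    "tss_chi2": list,
    "expression": (dict, type(None)),
    "links": (dict, type(None)),
}

REPORT_SCHEMA = {
    "config": dict,
    "comparisons": list,
    "shared_dmrs": (dict, type(None)),
}


def validate_report(report: dict) -> None:
    """Structural validation of the report JSON (types and required keys)."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}")
    for comp in report["comparisons"]:
        for key, typ in _COMPARISON_SCHEMA.items():
            if key not in comp:
                raise ValueError(f"comparison missing key {key!r}")
            if not isinstance(comp[key], typ):
                raise ValueError(f"comparison key {key!r} has type {type(comp[key]).__name__}")
        for row in comp["tss_bins"]:
            if not {"orientation", "bin", "count"} <= set(row):
                raise ValueError("tss_bins rows need orientation/bin/count")
            if row["count"] < 0:
                raise ValueError("negative count in tss_bins")
        if comp["n_dmcs"] < 0 or comp["n_dmrs"] < 0:
            raise ValueError("negative counts in comparison")


@dataclass
class SummaryReport:
    """Machine-readable pipeline summary (one entry per comparison)."""

    config: dict
    comparisons: list[dict] = field(default_factory=list)
    shared: dict | None = None

    def to_dict(self) -> dict:
        return {"config": self.config, "comparisons": self.comparisons,
                "shared_dmrs": self.shared}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _float_or_none(x) -> float | None:
    try:
        f = float(x)
    except (TypeError, ValueError):
        return None
    return None if f != f else f


def _run_comparison(age: str, meth_dataset, expr_dataset, annotation, ccres,
                    config: PipelineConfig) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    t0 = time.monotonic()
    model = DifferentialMethylation(meth_dataset, treatment=config.treatment,
                                    control=config.control)
    res = model.fit(alpha=config.alpha, min_delta=config.min_delta,
                    min_coverage=config.min_coverage, max_gap=config.max_gap,
                    min_dmcs=config.min_dmcs)
    dmrs = res.dmrs
    logger.info("[%s] %d DMCs -> %d DMRs (%.1fs)", age, len(res.dmcs), len(dmrs),
                time.monotonic() - t0)

    genic = overlap_dmrs_genes(dmrs, annotation)
    entry: dict = {
        "age": age,
        "treatment": config.treatment,
        "control": config.control,
        "n_testable_sites": res.n_testable,
        "n_dmcs": int(len(res.dmcs)),
        "n_dmrs": int(len(dmrs)),
        "hypo_fraction": _float_or_none(res.hypo_fraction),
        "hypo_binomial_p": _float_or_none(res.hypo_hyper_pvalue),
        "mean_abs_delta_me": _float_or_none(res.mean_abs_delta_me),
        "genic": {
            "n_genic": genic["n_genic"],
            "n_intergenic": genic["n_intergenic"],
            "n_dmrs": genic["n_dmrs"],
            "percent_genic": percent(genic["n_genic"], genic["n_dmrs"]),
            "percent_intergenic": percent(genic["n_intergenic"], genic["n_dmrs"]),
        },
    }

    if ccres is not None:
        cc = overlap_dmrs_ccres(dmrs, ccres)
        entry["ccre"] = {
            "n_dmrs": cc["n_dmrs"],
            "n_overlapped": cc["n_overlapped"],
            "percent_overlapped": percent(cc["n_overlapped"], cc["n_dmrs"]),
            "categories": [
                {
                    "category": row.category,
                    "count": int(row.count),
                    "percent_of_overlapped": percent(int(row.count), cc["n_overlapped"]),
                }
                for row in cc["table"].itertuples(index=False)
            ],
        }
    else:
        entry["ccre"] = None
        logger.info("[%s] no cCRE catalog given; overlap stage skipped", age)

    assignments = assign_regions(dmrs, annotation)
    background = sample_background(meth_dataset, fraction=config.background_fraction,
                                   seed=config.seed)
    back_assign = assign_regions(background.as_regions(), annotation)
    bins = bin_distances(assignments)
    chi2 = compare_to_background(assignments, back_assign)
    entry["tss_bins"] = [
        {"orientation": r.orientation, "bin": r.bin, "count": int(r.count),
         "percent": percent(int(r.count), len(assignments))}
        for r in bins.itertuples(index=False)
    ]
    entry["tss_chi2"] = [
        {"bin": r.bin, "k_fore": int(r.k_fore), "n_fore": int(r.n_fore),
         "k_back": int(r.k_back), "n_back": int(r.n_back),
         "chi2": _float_or_none(r.chi2), "p_value": _float_or_none(r.p_value),
         "direction": r.direction}
        for r in chi2.itertuples(index=False)
    ]

    degs = pd.DataFrame()
    if expr_dataset is not None and len(expr_dataset.counts):
        de_model = DifferentialExpression(expr_dataset, treatment=config.treatment,
                                          control=config.control)
        de_res = de_model.fit(fdr_threshold=config.fdr, min_abs_lfc=config.min_abs_lfc)
        degs = de_res.called
        entry["expression"] = {
            "n_tested": int(len(de_res.table)),
            "n_degs": int(len(degs)),
            "n_up": de_res.n_up,
            "n_down": de_res.n_down,
        }
        links = link_dmrs_degs(dmrs, degs, annotation, window=config.link_window)
        entry["links"] = summarize_links(links) | {"window": config.link_window}
    else:
        entry["expression"] = None
        entry["links"] = None
        logger.info("[%s] no counts given; expression stage skipped", age)
    return entry, dmrs, degs


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> SummaryReport:
    """Run the full pipeline described by `config`.

    Deterministic under a fixed seed. When `outdir` is given, writes
    report.json plus per-comparison DMR BED and DEG TSV tables.
    """
    design = mio.read_design(config.design)
    annotation = mio.read_gtf(config.genes)
    ccres = mio.read_ccre_bed(config.ccres) if config.ccres else None
    counts = mio.read_counts(config.counts) if config.counts else None

    ages = list(pd.unique(design["age"])) if "age" in design.columns else [""]
    report = SummaryReport(config=asdict(config))
    dmr_sets: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, pd.DataFrame] = {}
    for age in ages:
        sub_design = design[design["age"] == age] if age else design
        meth = mio.read_methylation_dataset(config.coverage_dir, sub_design)
        expr = None
        if counts is not None:
            cols = [c for c in counts.columns if c in sub_design.index]
            if cols:
                from .datasets import ExpressionDataset

                expr = ExpressionDataset(counts[cols], sub_design.loc[cols])
        entry, dmrs, degs = _run_comparison(age or "all", meth, expr, annotation,
                                            ccres, config)
        report.comparisons.append(entry)
        dmr_sets[age or "all"] = dmrs
        deg_sets[age or "all"] = degs

    if len(dmr_sets) == 2:
        (age_a, dmrs_a), (age_b, dmrs_b) = dmr_sets.items()
        venn = shared_dmrs(dmrs_a, dmrs_b)
        report.shared = {
            "age_a": age_a,
            "age_b": age_b,
            "shared_a": venn.shared_a,
            "shared_b": venn.shared_b,
            "only_a": venn.only_a,
            "only_b": venn.only_b,
        }
    else:
        report.shared = None
        if len(dmr_sets) > 2:
            logger.info("more than two ages present; shared-DMR Venn skipped")

    validate_report(report.to_dict())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json() + "\n")
        for age, dmrs in dmr_sets.items():
            mio.write_dmr_bed(outdir / f"dmrs_{age}.bed", dmrs)
        for age, degs in deg_sets.items():
            if len(degs):
                degs.to_csv(outdir / f"degs_{age}.tsv", sep="\t", index=False)
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a report dict."""
    lines = []
    for comp in report["comparisons"]:
        lines.append(f"comparison {comp['treatment']} vs {comp['control']}"
                     + (f" ({comp['age']})" if comp["age"] else ""))
        lines.append(f"  DMCs {comp['n_dmcs']}  DMRs {comp['n_dmrs']}"
                     f"  (testable sites {comp['n_testable_sites']})")
        if comp["hypo_fraction"] is not None:
            lines.append(
                f"  hypomethylated {100 * comp['hypo_fraction']:.0f}%"
                f" (binomial p = {comp['hypo_binomial_p']:.3g});"
                f" mean |delta_me| {comp['mean_abs_delta_me']:.2f}"
            )
        g = comp["genic"]
        lines.append(f"  genic {g['n_genic']} ({g['percent_genic']}%) /"
                     f" intergenic {g['n_intergenic']} ({g['percent_intergenic']}%)")
        if comp["ccre"]:
            c = comp["ccre"]
            lines.append(f"  cCRE-overlapped {c['n_overlapped']} of {c['n_dmrs']}"
                         f" ({c['percent_overlapped']}%)")
            for row in c["categories"]:
                lines.append(f"    {row['category']:<14} {row['count']:>6}"
                             f"  {row['percent_of_overlapped']}%")
        for row in comp["tss_chi2"]:
            if row["chi2"] is not None:
                lines.append(
                    f"  TSS bin {row['bin']:<10} {row['direction']:<9}"
                    f" chi2 = {row['chi2']:.1f} (p = {row['p_value']:.3g})"
                )
        if comp["expression"]:
            e = comp["expression"]
            lines.append(f"  DEGs {e['n_degs']} ({e['n_up']} up / {e['n_down']} down)"
                         f" of {e['n_tested']} tested")
        if comp["links"]:
            l = comp["links"]
            lines.append(f"  DMR-DEG links within {l['window']} bp: {l['n_links']}"
                         f" ({l['n_canonical_links']} canonical;"
                         f" {l['n_dmrs_linked']} unique DMRs)")
    if report.get("shared_dmrs"):
        s = report["shared_dmrs"]
        lines.append(
            f"shared DMRs {s['age_a']} vs {s['age_b']}: "
            f"{s['shared_a']}/{s['shared_b']} shared, {s['only_a']}/{s['only_b']} unique"
        )
    return "\n".join(lines)
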