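"""Differential methylation: DMC calling, DMR aggregation, imbalance tests.

The per-site test is a two-sided Fisher exact test on the 2x2 table of
methylated/unmethylated counts pooled within each group. Delta-me is the
difference in average methylation between groups: the unweighted mean over
treatment samples of per-sample methylation fractions minus the same mean
over control samples (a pooled-count variant is available). A DMC requires
p < alpha, |delta_me| >= min_delta and a pooled per-group coverage minimum;
DMCs are aggregated into DMRs as maximal same-direction runs with bounded
inter-CpG gaps.

Sign convention (repo-wide): delta_me = treatment mean - control mean;
direction "hypo" means loss of methylation in the treatment group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ConfigurationError, MethylationDataset, empty_dmr_table

DMC_COLUMNS = ["chrom", "pos", "delta_me", "p_value",
               "mean_treatment", "mean_control", "cov_treatment", "cov_control"]


def compute_delta_me(site_counts: pd.DataFrame, design: pd.DataFrame,
                     treatment: str, control: str,
                     method: str = "mean_of_fractions") -> float:
    """Delta-me at one CpG: treatment group mean minus control group mean.

    Parameters
    ----------
    site_counts : frame indexed by sample with columns ``meth``/``unmeth``.
    design : frame indexed by sample with a ``group`` column.
    method : "mean_of_fractions" (default; unweighted mean of per-sample
        methylation fractions over covered samples) or "pooled"
        (fraction of pooled counts).

    Returns NaN (site untestable) if either group has no covered sample.
    """
    out = {}
    for label in (treatment, control):
        members = design.index[design["group"] == label]
        sub = site_counts.loc[site_counts.index.intersection(members)]
        m = sub["meth"].to_numpy(float)
        u = sub["unmeth"].to_numpy(float)
        cov = m + u
        covered = cov > 0
        if not covered.any():
            return float("nan")
        if method == "mean_of_fractions":
            out[label] = float(np.mean(m[covered] / cov[covered]))
        elif method == "pooled":
            out[label] = float(m.sum() / cov.sum())
        else:
            raise ValueError(f"unknown delta_me method {method!r}")
    return out[treatment] - out[control]


def test_dmc(meth_treatment: int, unmeth_treatment: int,
             meth_control: int, unmeth_control: int) -> float:
    """Two-sided Fisher exact p for one CpG's pooled 2x2 count table.

    Returns NaN if either group has zero total counts (untestable site).
    """
    if meth_treatment + unmeth_treatment == 0 or meth_control + unmeth_control == 0:
        return float("nan")
    table = [[meth_treatment, unmeth_treatment], [meth_control, unmeth_control]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _group_stats(dataset: MethylationDataset, treatment: str, control: str,
                 delta_method: str = "mean_of_fractions"):
    """Vectorized per-site group means, pooled counts and delta-me."""
    ti = dataset.sample_indices(treatment)
    ci = dataset.sample_indices(control)
    out = {}
    for label, idx in (("treatment", ti), ("control", ci)):
        m = dataset.meth[:, idx].astype(float)
        u = dataset.unmeth[:, idx].astype(float)
        cov = m + u
        n_cov = (cov > 0).sum(axis=1)
        if delta_method == "mean_of_fractions":
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(cov > 0, m / np.maximum(cov, 1), np.nan)
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(np.where(np.isnan(frac), np.nan, frac), axis=1)
            mean[n_cov == 0] = np.nan
        elif delta_method == "pooled":
            pooled_cov = cov.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = np.where(pooled_cov > 0, m.sum(axis=1) / np.maximum(pooled_cov, 1), np.nan)
        else:
            raise ValueError(f"unknown delta_me method {delta_method!r}")
        out[label] = {
            "mean": mean,
            "meth": m.sum(axis=1).astype(np.int64),
            "unmeth": u.sum(axis=1).astype(np.int64),
        }
    return out


def call_dmcs(dataset: MethylationDataset, treatment: str, control: str,
              alpha: float = 0.001, min_delta: float = 0.10,
              min_coverage: int = 10,
              delta_method: str = "mean_of_fractions") -> pd.DataFrame:
    """Call differentially methylated cytosines between two groups.

    Emits exactly the sites with Fisher p < `alpha`, |delta_me| >=
    `min_delta`, and pooled coverage >= `min_coverage` in each group,
    sorted by position. The Fisher test is only evaluated at sites passing
    the coverage and delta gates (the emitted set is identical).
    """
    groups = set(dataset.design.loc[dataset.samples, "group"])
    for label in (treatment, control):
        if label not in groups:
            raise ConfigurationError(f"group {label!r} absent from design")

    st = _group_stats(dataset, treatment, control, delta_method)
    t, c = st["treatment"], st["control"]
    cov_t = t["meth"] + t["unmeth"]
    cov_c = c["meth"] + c["unmeth"]
    delta = t["mean"] - c["mean"]

    candidate = (
        (cov_t >= min_coverage)
        & (cov_c >= min_coverage)
        & ~np.isnan(delta)
        & (np.abs(delta) >= min_delta)
    )
    idx = np.nonzero(candidate)[0]
    pvals = np.array(
        [test_dmc(t["meth"][i], t["unmeth"][i], c["meth"][i], c["unmeth"][i]) for i in idx]
    )
    keep = idx[~np.isnan(pvals) & (pvals < alpha)] if len(idx) else idx
    pkeep = pvals[~np.isnan(pvals) & (pvals < alpha)] if len(idx) else np.array([])

    dmcs = pd.DataFrame(
        {
            "chrom": dataset.sites["chrom"].to_numpy()[keep],
            "pos": dataset.sites["pos"].to_numpy()[keep],
            "delta_me": delta[keep],
            "p_value": pkeep,
            "mean_treatment": t["mean"][keep],
            "mean_control": c["mean"][keep],
            "cov_treatment": cov_t[keep],
            "cov_control": cov_c[keep],
        }
    )
    return dmcs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def count_testable_sites(dataset: MethylationDataset, treatment: str, control: str,
                         min_coverage: int = 10) -> int:
    """Number of sites passing the pooled per-group coverage gate."""
    st = _group_stats(dataset, treatment, control)
    cov_t = st["treatment"]["meth"] + st["treatment"]["unmeth"]
    cov_c = st["control"]["meth"] + st["control"]["unmeth"]
    return int(((cov_t >= min_coverage) & (cov_c >= min_coverage)).sum())


def aggregate_dmrs(dmcs: pd.DataFrame, max_gap: int = 250, min_dmcs: int = 1) -> pd.DataFrame:
    """Aggregate DMCs into DMRs.

    Maximal runs of same-chromosome, same-direction DMCs with inter-CpG gap
    <= `max_gap` become one DMR spanning the first to last member CpG.
    DMR delta_me is the unweighted mean of member delta_me; p_value is the
    minimum member p (for reporting). Runs with fewer than `min_dmcs`
    members are dropped.
    """
    if not len(dmcs):
        return empty_dmr_table()
    dmcs = dmcs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    chroms = dmcs["chrom"].to_numpy()
    pos = dmcs["pos"].to_numpy()
    sign = np.sign(dmcs["delta_me"].to_numpy())

    new_run = np.ones(len(dmcs), dtype=bool)
    if len(dmcs) > 1:
        same_chrom = chroms[1:] == chroms[:-1]
        close = (pos[1:] - pos[:-1]) <= max_gap
        same_sign = sign[1:] == sign[:-1]
        new_run[1:] = ~(same_chrom & close & same_sign)
    run_id = np.cumsum(new_run) - 1

    records = []
    grouped = dmcs.assign(_run=run_id).groupby("_run", sort=True)
    for rid, sub in grouped:
        if len(sub) < min_dmcs:
            continue
        first, last = int(sub["pos"].iloc[0]), int(sub["pos"].iloc[-1])
        delta = float(sub["delta_me"].mean())
        records.append(
            {
                "chrom": sub["chrom"].iloc[0],
                "start": first,
                # single-CpG DMRs span the CpG dinucleotide
                "end": max(last + 1, first + 2),
                "name": f"dmr_{len(records) + 1}",
                "n_dmcs": len(sub),
                "delta_me": delta,
                "direction": "hypo" if delta < 0 else "hyper",
                "p_value": float(sub["p_value"].min()),
            }
        )
    if not records:
        return empty_dmr_table()
    return pd.DataFrame(records)


def hypo_hyper_test(dmrs: pd.DataFrame) -> tuple[float, float]:
    """Fraction of hypomethylated DMRs and two-sided exact binomial p vs 0.5."""
    if not len(dmrs):
        raise ValueError("hypo_hyper_test requires at least one DMR")
    n = len(dmrs)
    k_hypo = int((dmrs["delta_me"].to_numpy() < 0).sum())
    p = stats.binomtest(k_hypo, n, 0.5, alternative="two-sided").pvalue
    return k_hypo / n, float(p)


# ------------------------------------------------------------ model object

@dataclass
class DifferentialMethylationResults:
    """Results of a two-group differential methylation fit."""

    dmcs: pd.DataFrame
    dmrs: pd.DataFrame
    treatment: str
    control: str
    params: dict = field(default_factory=dict)
    n_testable: int = 0

    @property
    def n_dmrs(self) -> int:
        return len(self.dmrs)

    @property
    def hypo_fraction(self) -> float:
        if not len(self.dmrs):
            return float("nan")
        return hypo_hyper_test(self.dmrs)[0]

    @property
    def hypo_hyper_pvalue(self) -> float:
        if not len(self.dmrs):
            return float("nan")
        return hypo_hyper_test(self.dmrs)[1]

    @property
    def mean_abs_delta_me(self) -> float:
        if not len(self.dmrs):
            return float("nan")
        return float(np.abs(self.dmrs["delta_me"]).mean())

    def summary(self) -> str:
        lines = [
            "Differential methylation " + f"({self.treatment} vs {self.control})",
            "=" * 46,
            f"testable CpG sites     {self.n_testable}",
            f"DMCs                   {len(self.dmcs)}",
            f"DMRs                   {self.n_dmrs}",
        ]
        if len(self.dmrs):
            frac, p = hypo_hyper_test(self.dmrs)
            lines += [
                f"hypomethylated         {frac:.1%} (binomial p = {p:.3g})",
                f"mean |delta_me|        {self.mean_abs_delta_me:.3f}",
            ]
        for key, value in self.params.items():
            lines.append(f"{key:<22} {value}")
        return "\n".join(lines)


class DifferentialMethylation:
    """Two-group differential methylation model over an RRBS dataset.

    Examples
    --------
    >>> model = DifferentialMethylation(dataset, treatment="AME", control="Con")
    >>> res = model.fit(alpha=0.001, min_delta=0.10)
    >>> print(res.summary())
    """

    def __init__(self, dataset: MethylationDataset,
                 treatment: str | None = None, control: str | None = None):
        groups = dataset.groups()
        if treatment is None or control is None:
            if len(groups) != 2:
                raise ConfigurationError(
                    "treatment/control must be given unless the design has exactly two groups"
                )
            treatment = treatment or groups[0]
            control = control or [g for g in groups if g != treatment][0]
        self.dataset = dataset
        self.treatment = treatment
        self.control = control

    def fit(self, alpha: float = 0.001, min_delta: float = 0.10,
            min_coverage: int = 10, max_gap: int = 250, min_dmcs: int = 1,
            delta_method: str = "mean_of_fractions") -> DifferentialMethylationResults:
        dmcs = call_dmcs(self.dataset, self.treatment, self.control,
                         alpha=alpha, min_delta=min_delta,
                         min_coverage=min_coverage, delta_method=delta_method)
        dmrs = aggregate_dmrs(dmcs, max_gap=max_gap, min_dmcs=min_dmcs)
        n_testable = count_testable_sites(self.dataset, self.treatment,
                                          self.control, min_coverage)
        params = dict(alpha=alpha, min_delta=min_delta, min_coverage=min_coverage,
                      max_gap=max_gap, min_dmcs=min_dmcs, delta_method=delta_method)
        return DifferentialMethylationResults(
            dmcs=dmcs, dmrs=dmrs, treatment=self.treatment, control=self.control,
            params=params, n_testable=n_testable)
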