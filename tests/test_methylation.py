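"""DMC/DMR calling: hand-checked examples, oracle equivalence, symmetries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methprime.datasets import ConfigurationError
from methprime.methylation import (
    DifferentialMethylation,
    aggregate_dmrs,
    call_dmcs,
    compute_delta_me,
    hypo_hyper_test,
    test_dmc as fisher_dmc_test,
)

from conftest import make_methylation_dataset


def _site(meths, unmeths, groups):
    samples = [f"s{i}" for i in range(len(meths))]
    counts = pd.DataFrame({"meth": meths, "unmeth": unmeths},
                          index=pd.Index(samples, name="sample"))
    design = pd.DataFrame({"group": groups}, index=counts.index)
    return counts, design


class TestDeltaMe:
    @pytest.mark.parametrize(
        "t_fracs, c_fracs, expected",
        [
            ([0.8, 0.8], [0.8, 0.8], 0.0),
            ([1.0, 1.0], [0.0, 0.0], 1.0),
            ([0.6, 0.8, 0.7], [0.5, 0.5, 0.5], 0.2),
        ],
    )
    def test_hand_examples(self, t_fracs, c_fracs, expected):
        fracs = list(t_fracs) + list(c_fracs)
        meths = [round(f * 10) for f in fracs]
        unmeths = [10 - m for m in meths]
        groups = ["T"] * len(t_fracs) + ["C"] * len(c_fracs)
        counts, design = _site(meths, unmeths, groups)
        assert compute_delta_me(counts, design, "T", "C") == pytest.approx(expected)

    def test_uncovered_group_is_untestable(self):
        counts, design = _site([0, 5], [0, 5], ["T", "C"])
        assert math.isnan(compute_delta_me(counts, design, "T", "C"))

    def test_pooled_variant_weights_by_coverage(self):
        # T: 9/10 and 0/90 -> pooled 9/100 = 0.09, mean-of-fractions 0.45
        counts, design = _site([9, 0, 5, 5], [1, 90, 5, 5], ["T", "T", "C", "C"])
        pooled = compute_delta_me(counts, design, "T", "C", method="pooled")
        meanfrac = compute_delta_me(counts, design, "T", "C")
        assert pooled == pytest.approx(0.09 - 0.5)
        assert meanfrac == pytest.approx(0.45 - 0.5)


class TestFisher:
    def test_identical_groups_p_one(self):
        assert fisher_dmc_test(10, 10, 10, 10) == pytest.approx(1.0)

    def test_extreme_table_exact_value(self):
        # 2 / C(20, 10): only the two most extreme tables are as extreme
        assert fisher_dmc_test(10, 0, 0, 10) == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_degenerate_group_untestable(self):
        assert math.isnan(fisher_dmc_test(0, 0, 5, 5))

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p = fisher_dmc_test(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration.

    Conditional on all margins, P(A = k) is hypergeometric; the two-sided p
    sums the probabilities of tables no more likely than the observed one.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def pmf(k: int) -> float:
        return (
            math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
        )

    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestCallDmcs:
    def test_gates_are_conjunctive(self):
        # site 0: strong effect -> emitted; site 1: tiny delta w/ huge
        # coverage (significant p) -> gated out; site 2: low coverage.
        rows = [
            ("chr1", 100, [20, 20, 0, 0], [0, 0, 20, 20]),
            ("chr1", 200, [540, 540, 460, 460], [460, 460, 540, 540]),
            ("chr1", 300, [3, 3, 0, 0], [0, 0, 3, 3]),
        ]
        ds = make_methylation_dataset(rows, ["t1", "t2", "c1", "c2"],
                                      ["T", "T", "C", "C"])
        dmcs = call_dmcs(ds, "T", "C", alpha=0.001, min_delta=0.10, min_coverage=10)
        assert list(dmcs["pos"]) == [100]
        assert dmcs["delta_me"].iloc[0] == pytest.approx(1.0)

    def test_missing_group_raises(self):
        rows = [("chr1", 100, [5, 5], [5, 5])]
        ds = make_methylation_dataset(rows, ["a", "b"], ["T", "T"])
        with pytest.raises(ConfigurationError):
            call_dmcs(ds, "T", "C")

    def test_monotone_in_thresholds(self, small_study):
        ds = small_study.methylation
        base = len(call_dmcs(ds, "AME", "Con", alpha=1e-3, min_delta=0.10))
        assert len(call_dmcs(ds, "AME", "Con", alpha=1e-4, min_delta=0.10)) <= base
        assert len(call_dmcs(ds, "AME", "Con", alpha=1e-3, min_delta=0.20)) <= base

    def test_antisymmetric_under_group_swap(self, small_study):
        ds = small_study.methylation
        fwd = call_dmcs(ds, "AME", "Con")
        rev = call_dmcs(ds, "Con", "AME")
        assert list(fwd["pos"]) == list(rev["pos"])
        np.testing.assert_allclose(fwd["delta_me"], -rev["delta_me"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-9)
        d_fwd = aggregate_dmrs(fwd)
        d_rev = aggregate_dmrs(rev)
        assert (
            d_fwd["direction"].map({"hypo": "hyper", "hyper": "hypo"}).tolist()
            == d_rev["direction"].tolist()
        )


def _dmc_frame(entries):
    return pd.DataFrame(
        [
            {"chrom": chrom, "pos": pos, "delta_me": delta, "p_value": 1e-5,
             "mean_treatment": 0.5 + delta, "mean_control": 0.5,
             "cov_treatment": 50, "cov_control": 50}
            for chrom, pos, delta in entries
        ]
    )


class TestAggregateDmrs:
    def test_single_run(self):
        dmrs = aggregate_dmrs(_dmc_frame([("chr1", 100, 0.3), ("chr1", 200, 0.3),
                                          ("chr1", 300, 0.3)]), max_gap=250)
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert (row["start"], row["end"], row["n_dmcs"]) == (100, 301, 3)
        assert row["direction"] == "hyper"

    def test_direction_break_splits(self):
        dmrs = aggregate_dmrs(_dmc_frame([("chr1", 100, 0.3), ("chr1", 200, -0.3)]))
        assert len(dmrs) == 2
        assert list(dmrs["direction"]) == ["hyper", "hypo"]

    def test_gap_rule(self):
        dmrs = aggregate_dmrs(
            _dmc_frame([("chr1", 100, 0.3), ("chr1", 400, 0.3), ("chr1", 700, 0.3)]),
            max_gap=250,
        )
        assert len(dmrs) == 3
        # single-DMC DMRs span the CpG dinucleotide
        assert list(dmrs["end"] - dmrs["start"]) == [2, 2, 2]

    def test_chromosome_break_splits(self):
        dmrs = aggregate_dmrs(_dmc_frame([("chr1", 100, 0.3), ("chr2", 150, 0.3)]))
        assert len(dmrs) == 2

    def test_min_dmcs_filter(self):
        frame = _dmc_frame([("chr1", 100, 0.3), ("chr1", 150, 0.3), ("chr1", 900, 0.3)])
        dmrs = aggregate_dmrs(frame, max_gap=250, min_dmcs=2)
        assert len(dmrs) == 1 and dmrs["n_dmcs"].iloc[0] == 2

    def test_empty_input(self):
        assert aggregate_dmrs(_dmc_frame([])).empty


class TestHypoHyper:
    def test_balanced_is_symmetric(self):
        dmrs = aggregate_dmrs(_dmc_frame(
            [("chr1", i * 1000, 0.3 if i % 2 else -0.3) for i in range(10)]
        ))
        frac, p = hypo_hyper_test(dmrs)
        assert frac == pytest.approx(0.5)
        assert p == pytest.approx(1.0)

    def test_all_hypo_exact_p(self):
        dmrs = aggregate_dmrs(_dmc_frame([("chr1", i * 1000, -0.3) for i in range(6)]))
        frac, p = hypo_hyper_test(dmrs)
        assert frac == 1.0
        assert p == pytest.approx(2 * 0.5**6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hypo_hyper_test(pd.DataFrame(columns=["delta_me"]))


def test_model_fit_summary(small_study):
    res = DifferentialMethylation(small_study.methylation).fit()
    text = res.summary()
    assert "DMRs" in text and str(res.n_dmrs) in text
    assert res.n_testable > 0
    # every emitted DMC obeys the gates
    assert (res.dmcs["p_value"] < res.params["alpha"]).all()
    assert (res.dmcs["delta_me"].abs() >= res.params["min_delta"]).all()
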