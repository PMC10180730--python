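"""Nearest-TSS assignment, distance binning, background sampling, chi-square."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from methprime.datasets import GeneAnnotation
from methprime.regulatory import midpoint
from methprime.tss_enrichment import (
    NONE_LABEL,
    assign_regions,
    bin_distances,
    chisq_bin_test,
    compare_to_background,
    distance_bin,
    nearest_tss,
    sample_background,
)


def _annotation(rows):
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(genes=genes, chrom_sizes={"chr1": 10_000_000})


class TestNearestTss:
    def test_midpoint_at_tss_distance_zero(self):
        ann = _annotation([("g1", "chr1", 100_000, 105_000, "+")])
        gene, dist, orient = nearest_tss("chr1", 100_000, 100_001, ann)
        assert (gene, dist, orient) == ("g1", 0, "downstream")
        assert distance_bin(dist) == "0-5 kb"

    def test_upstream_of_plus_gene(self):
        ann = _annotation([("g1", "chr1", 100_000, 105_000, "+")])
        gene, dist, orient = nearest_tss("chr1", 90_000, 90_001, ann)
        assert gene == "g1" and dist == -10_000 and orient == "upstream"
        assert distance_bin(dist) == "5-50 kb"

    def test_upstream_of_minus_gene(self):
        # minus-strand TSS at end-1; a region right of it is upstream
        ann = _annotation([("g1", "chr1", 100_000, 105_000, "-")])
        gene, dist, orient = nearest_tss("chr1", 110_000, 110_001, ann)
        assert gene == "g1" and dist == -(110_000 - 104_999) and orient == "upstream"

    def test_nearest_of_two(self):
        ann = _annotation(
            [("near", "chr1", 103_000, 108_000, "+"), ("far", "chr1", 96_000 - 5_000, 96_000 + 1, "-")]
        )
        gene, dist, _ = nearest_tss("chr1", 100_000, 100_001, ann)
        assert gene == "near" and abs(dist) == 3_000

    def test_equidistant_tie_prefers_upstream(self):
        # region upstream of "up" (+, TSS right) but downstream of "down"
        # (+, TSS left): the upstream assignment wins the tie
        ann = _annotation(
            [("up", "chr1", 104_000, 109_000, "+"), ("down", "chr1", 96_000, 99_000, "+")]
        )
        gene, dist, orient = nearest_tss("chr1", 100_000, 100_001, ann)
        assert gene == "up" and orient == "upstream" and dist == -4_000
        # when both candidates are upstream, the lower TSS coordinate wins
        ann2 = _annotation(
            [("right", "chr1", 104_000, 109_000, "+"), ("left", "chr1", 91_000, 96_001, "-")]
        )
        gene2, dist2, orient2 = nearest_tss("chr1", 100_000, 100_001, ann2)
        assert gene2 == "left" and orient2 == "upstream" and dist2 == -4_000

    def test_none_beyond_window(self):
        ann = _annotation([("g1", "chr1", 5_000_000, 5_010_000, "+")])
        assert nearest_tss("chr1", 0, 2, ann, max_distance=1_000_000) is None
        assert nearest_tss("chr2", 0, 2, ann) is None

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(40):
            start = int(rng.integers(0, 2_000_000))
            rows.append((f"g{i}", "chr1", start, start + 1_000, rng.choice(["+", "-"])))
        ann = _annotation(rows)
        tss = ann.tss
        for _ in range(200):
            s = int(rng.integers(0, 2_100_000))
            hit = nearest_tss("chr1", s, s + 100, ann)
            mid = midpoint(s, s + 100)
            brute = min(abs(int(t) - mid) for t in tss)
            if brute > 1_000_000:
                assert hit is None
            else:
                assert abs(hit[1]) == brute


class TestBinning:
    @pytest.mark.parametrize(
        "dist, label",
        [(0, "0-5 kb"), (4_999, "0-5 kb"), (5_000, "5-50 kb"), (49_999, "5-50 kb"),
         (50_000, "50-500 kb"), (499_999, "50-500 kb"), (500_000, ">500 kb"),
         (1_000_000, ">500 kb")],
    )
    def test_edges(self, dist, label):
        assert distance_bin(dist) == label

    def test_all_proximal(self):
        ann = _annotation([("g1", "chr1", 100_000, 105_000, "+")])
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [99_000, 101_000], "end": [99_001, 101_001],
             "name": ["a", "b"]}
        )
        summary = bin_distances(assign_regions(regions, ann))
        prox = summary[summary["bin"] == "0-5 kb"]["count"].sum()
        assert prox == 2
        assert summary[summary["bin"] == "0-5 kb"]["percent"].sum() == pytest.approx(100.0)

    def test_empty_region_list(self):
        ann = _annotation([("g1", "chr1", 100_000, 105_000, "+")])
        summary = bin_distances(assign_regions(regions=pd.DataFrame(
            columns=["chrom", "start", "end", "name"]), annotation=ann))
        assert (summary["count"] == 0).all()

    def test_bins_partition_regions(self, small_study):
        from methprime.methylation import DifferentialMethylation

        res = DifferentialMethylation(small_study.methylation, "AME", "Con").fit()
        assignments = assign_regions(res.dmrs, small_study.annotation)
        summary = bin_distances(assignments)
        assert summary["count"].sum() == len(assignments) == len(res.dmrs)
        counts = assignments["bin"].value_counts()
        for row in summary.itertuples(index=False):
            if row.orientation == "none":
                assert row.count == counts.get(NONE_LABEL, 0)


class TestBackground:
    def test_full_fraction_returns_everything(self, small_study):
        bg = sample_background(small_study.methylation, fraction=1.0, seed=0)
        assert len(bg) == small_study.methylation.n_sites

    def test_exact_count_and_determinism(self, small_study):
        ds = small_study.methylation
        bg1 = sample_background(ds, fraction=0.02, seed=4)
        bg2 = sample_background(ds, fraction=0.02, seed=4)
        assert len(bg1) == int(np.floor(0.02 * ds.n_sites))
        pd.testing.assert_frame_equal(bg1.positions, bg2.positions)
        assert len(sample_background(ds, 0.02, seed=5).positions.merge(bg1.positions)) < len(bg1)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_bad_fraction_raises(self, small_study, fraction):
        with pytest.raises(ValueError):
            sample_background(small_study.methylation, fraction=fraction)

    def test_inclusion_frequencies_uniform(self, small_study):
        """1,000 seeded draws at 2%: per-site inclusion matches Binomial(1000, 0.02).

        Under exact uniformity ~0.02% of sites still fall outside a 4-SE
        band, so the check bounds the exceedance count by the 99.9% envelope
        of its null distribution rather than demanding zero.
        """
        ds = small_study.methylation
        n = ds.n_sites
        hits = np.zeros(n)
        key = pd.MultiIndex.from_frame(ds.sites)
        for seed in range(1_000):
            bg = sample_background(ds, fraction=0.02, seed=seed)
            idx = key.get_indexer(pd.MultiIndex.from_frame(bg.positions))
            hits[idx] += 1
        freq = hits / 1_000
        se = np.sqrt(0.02 * 0.98 / 1_000)
        n_outside = int(((freq < 0.02 - 4 * se) | (freq > 0.02 + 4 * se)).sum())
        p_out = stats.binom.sf(np.floor((0.02 + 4 * se) * 1_000), 1_000, 0.02) + \
            stats.binom.cdf(np.ceil((0.02 - 4 * se) * 1_000) - 1, 1_000, 0.02)
        envelope = stats.binom.ppf(0.999, n, p_out)
        assert n_outside <= envelope
        assert freq.mean() == pytest.approx(
            len(sample_background(ds, 0.02, 0)) / n, rel=1e-9)


class TestChisq:
    def test_equal_proportions_zero(self):
        res = chisq_bin_test(100, 10, 1_000, 100)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_flagged(self):
        res = chisq_bin_test(10, 0, 100, 0)
        assert res.undefined and np.isnan(res.chi2)

    def test_depletion_direction(self):
        res = chisq_bin_test(100, 5, 1_000, 300)
        assert res.direction == "depleted"
        assert chisq_bin_test(100, 50, 1_000, 300).direction == "enriched"

    @given(
        n1=st.integers(2, 500), k1=st.integers(0, 500),
        n2=st.integers(2, 500), k2=st.integers(0, 500),
    )
    def test_equals_squared_two_proportion_z(self, n1, k1, n2, k2):
        k1, k2 = min(k1, n1), min(k2, n2)
        res = chisq_bin_test(n1, k1, n2, k2)
        if res.undefined:
            return
        p1, p2 = k1 / n1, k2 / n2
        pool = (k1 + k2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert res.chi2 == pytest.approx(z**2, rel=1e-9, abs=1e-9)

    def test_matches_scipy_contingency(self):
        table = [[647, 5879 - 647], [31405, 120788 - 31405]]
        expected = stats.chi2_contingency(table, correction=False)
        res = chisq_bin_test(5879, 647, 120788, 31405)
        assert res.chi2 == pytest.approx(expected.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(expected.pvalue, rel=1e-9)

    def test_compare_to_background_table(self, small_study):
        from methprime.methylation import DifferentialMethylation

        res = DifferentialMethylation(small_study.methylation, "AME", "Con").fit()
        fore = assign_regions(res.dmrs, small_study.annotation)
        bg = sample_background(small_study.methylation, 0.25, seed=1)
        back = assign_regions(bg.as_regions(), small_study.annotation)
        table = compare_to_background(fore, back)
        assert set(table["bin"]) == {"0-5 kb", "5-50 kb", "50-500 kb", ">500 kb"}
        assert (table["k_fore"] <= table["n_fore"]).all()
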