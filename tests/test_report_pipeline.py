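"""Pipeline orchestration, report schema, percent arithmetic, CLI."""

import json

import pytest
import yaml
from click.testing import CliRunner

from methprime.cli import main as cli_main
from methprime.report import (
    PipelineConfig,
    percent,
    render_report,
    run_pipeline,
    validate_report,
)
from methprime.simulate import SimConfig, simulate_two_age_study, write_two_age_study

from conftest import SMALL


class TestPercent:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(11_478, 49_143, 23.4), (11_940, 56_796, 21.0), (0, 10, 0.0),
         (1, 3, 33.3), (1, 8, 12.5), (25, 1000, 2.5), (5, 200, 2.5)],
    )
    def test_round_half_up_one_decimal(self, count, total, expected):
        assert percent(count, total) == expected

    def test_half_values_round_up(self):
        assert percent(45, 1000) == 4.5
        assert percent(1845, 10000) == 18.5  # .45 exactly -> up at 1 decimal
        assert percent(15, 10000) == 0.2  # 0.15 -> 0.2, not banker's 0.1

    def test_zero_total_is_na(self):
        assert percent(5, 0) is None


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(coverage_dir="cov", design="design.tsv", genes="g.gtf",
                             alpha=0.005, seed=42)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0.0}, {"fdr": 1.5}, {"background_fraction": 0.0},
                   {"min_coverage": -1}, {"min_abs_lfc": -0.5}]
    )
    def test_bad_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A written two-age synthetic study shared by the pipeline tests."""
    outdir = tmp_path_factory.mktemp("study")
    base = dict(SMALL)
    cfg_a = SimConfig(seed=41, age="d0", **base)
    cfg_b = SimConfig(seed=42, age="d21", hypo_fraction=0.48, **base)
    write_two_age_study(simulate_two_age_study(cfg_a, cfg_b), outdir)
    return outdir


def _pipeline_config(study_dir, **overrides) -> PipelineConfig:
    defaults = dict(
        coverage_dir=str(study_dir / "coverage"),
        counts=str(study_dir / "counts.tsv"),
        design=str(study_dir / "design.tsv"),
        genes=str(study_dir / "genes.gtf"),
        ccres=str(study_dir / "ccres.bed"),
        seed=3,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


class TestRunPipeline:
    def test_deterministic_report_json(self, study_dir, tmp_path):
        cfg = _pipeline_config(study_dir)
        r1 = run_pipeline(cfg, outdir=tmp_path / "a")
        r2 = run_pipeline(cfg, outdir=tmp_path / "b")
        assert (tmp_path / "a" / "report.json").read_bytes() == \
            (tmp_path / "b" / "report.json").read_bytes()
        validate_report(r1.to_dict())
        assert r1.to_json() == r2.to_json()

    def test_report_sections_populated(self, study_dir):
        report = run_pipeline(_pipeline_config(study_dir)).to_dict()
        assert len(report["comparisons"]) == 2
        for comp in report["comparisons"]:
            assert comp["n_dmrs"] > 0
            assert comp["ccre"] is not None
            assert 0 <= comp["ccre"]["percent_overlapped"] <= 100
            g = comp["genic"]
            assert g["percent_genic"] + g["percent_intergenic"] == pytest.approx(100.0, abs=0.1)
            assert sum(r["count"] for r in comp["tss_bins"]) == comp["n_dmrs"]
            assert comp["expression"] is not None
        assert report["shared_dmrs"] is not None
        text = render_report(report)
        assert "shared DMRs" in text and "DMRs" in text

    def test_missing_ccres_marks_stage_skipped(self, study_dir):
        report = run_pipeline(_pipeline_config(study_dir, ccres="")).to_dict()
        assert all(c["ccre"] is None for c in report["comparisons"])
        validate_report(report)

    def test_schema_rejects_malformed_report(self, study_dir):
        report = run_pipeline(_pipeline_config(study_dir, ccres="")).to_dict()
        del report["comparisons"][0]["n_dmrs"]
        with pytest.raises(ValueError):
            validate_report(report)
        with pytest.raises(ValueError):
            validate_report({"config": {}, "comparisons": "oops", "shared_dmrs": None})


class TestCli:
    def test_simulate_then_dmr_then_deg(self, tmp_path):
        runner = CliRunner()
        sim_cfg = dict(SMALL)
        sim_cfg.update(n_cpgs=1_500, n_genes=40, chrom_length=2_000_000,
                       n_planted_dmrs=10, n_ccres=50, n_planted_degs=5)
        cfg_path = tmp_path / "sim.yaml"
        cfg_path.write_text(yaml.safe_dump(sim_cfg))
        outdir = tmp_path / "study"
        result = runner.invoke(cli_main, ["simulate", "--config", str(cfg_path),
                                          "--outdir", str(outdir), "--seed", "8"])
        assert result.exit_code == 0, result.output
        assert (outdir / "truth.json").exists()

        dmr_out = tmp_path / "dmrs.bed"
        result = runner.invoke(cli_main, [
            "dmr", "--cov-dir", str(outdir / "coverage"),
            "--design", str(outdir / "design.tsv"), "-o", str(dmr_out)])
        assert result.exit_code == 0, result.output
        assert "DMRs" in result.output

        deg_out = tmp_path / "degs.tsv"
        result = runner.invoke(cli_main, [
            "deg", "--counts", str(outdir / "counts.tsv"),
            "--design", str(outdir / "design.tsv"), "-o", str(deg_out)])
        assert result.exit_code == 0, result.output

        links_out = tmp_path / "links.tsv"
        result = runner.invoke(cli_main, [
            "integrate", "--dmrs", str(dmr_out), "--degs", str(deg_out),
            "--genes", str(outdir / "genes.gtf"), "-o", str(links_out)])
        assert result.exit_code == 0, result.output
        assert json.loads(result.output.strip().splitlines()[-1])["n_links"] >= 0

    def test_run_and_report_verbs(self, study_dir, tmp_path):
        runner = CliRunner()
        cfg = _pipeline_config(study_dir)
        cfg_path = tmp_path / "pipeline.yaml"
        cfg.to_yaml(cfg_path)
        outdir = tmp_path / "out"
        result = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                          "--outdir", str(outdir)])
        assert result.exit_code == 0, result.output
        report_path = outdir / "report.json"
        assert report_path.exists()
        result = runner.invoke(cli_main, ["report", "--report", str(report_path)])
        assert result.exit_code == 0
        assert "comparison" in result.output
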