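"""Model/Results facade, config-driven pipeline and CLI."""

import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from gridcode.cli import main as cli_main
from gridcode.events import PartitionScheme
from gridcode.magnitude import Glm2Spec
from gridcode.model import HexadirectionalModel
from gridcode.pipeline import ConfigError, PipelineConfig, run_pipeline
from gridcode.simulate import SimSpec, simulate_session


@pytest.fixture(scope="module")
def fitted(default_session):
    model = HexadirectionalModel.from_simulation(default_session)
    return model, model.fit()


class TestModel:
    def test_results_schema_and_finiteness(self, fitted):
        _, res = fitted
        d = res.to_dict()
        for key in ("phi", "rayleigh_rbar", "rayleigh_p", "roi_mean_magnitude",
                    "fraction_stable"):
            assert np.isfinite(d[key]), key
        assert 0 <= d["phi"] < 60.0

    def test_summary_mentions_key_metrics(self, fitted):
        _, res = fitted
        s = res.summary()
        assert "grid orientation" in s
        assert "Rayleigh" in s
        assert "stability" in s.lower()

    def test_recovers_truth(self, fitted, default_session):
        from gridcode.stability import circular_distance

        _, res = fitted
        truth = default_session.truth.spec
        assert circular_distance(res.phi.phi, truth.phi_true, 6) < 3.0
        assert res.rayleigh.p_value < 1e-6      # coherent ROI
        assert res.magnitude.roi_mean > 0
        assert res.stability.fraction_stable > 0.5

    def test_run_count_mismatch_rejected(self, default_session):
        with pytest.raises(ValueError, match="runs"):
            HexadirectionalModel(default_session.bold_runs[:1],
                                 default_session.events)

    def test_from_files_round_trip(self, tmp_path, noiseless_session):
        spec = noiseless_session.truth.spec
        simulate_session(spec, tmp_path)
        bolds = sorted(str(p) for p in tmp_path.glob("run-*_bold.nii.gz"))
        model = HexadirectionalModel.from_files(
            bolds, tmp_path / "events.tsv", tr=spec.tr,
            roi_path=tmp_path / "roi_mask.nii.gz",
            scheme=PartitionScheme("half_runs"))
        res = model.fit()
        assert abs(res.phi.phi - spec.phi_true) < 1.0


def _write_session_and_config(tmp_path, spec=None):
    spec = spec or SimSpec(seed=5, grid_shape=(6, 6, 2), roi_fraction=0.3,
                           n_events_per_run=80, run_length=240.0)
    simulate_session(spec, tmp_path)
    cfg = {
        "bold": sorted(str(p) for p in tmp_path.glob("run-*_bold.nii.gz")),
        "events": str(tmp_path / "events.tsv"),
        "roi": str(tmp_path / "roi_mask.nii.gz"),
        "out_dir": str(tmp_path / "results"),
        "tr": spec.tr,
    }
    p = tmp_path / "cfg.json"
    p.write_text(json.dumps(cfg))
    return p, spec


class TestPipeline:
    def test_summary_written_and_finite(self, tmp_path):
        cfg_path, _ = _write_session_and_config(tmp_path)
        summary = run_pipeline(PipelineConfig.from_json(cfg_path))
        for key in ("phi", "rayleigh_rbar", "rayleigh_p", "roi_mean_magnitude"):
            assert np.isfinite(summary[key])
        out = Path(json.loads(cfg_path.read_text())["out_dir"])
        assert (out / "summary.json").exists()
        assert (out / "orientation_phi.nii.gz").exists()
        assert (out / "config.json").exists()

    def test_rerun_is_deterministic(self, tmp_path):
        cfg_path, _ = _write_session_and_config(tmp_path)
        s1 = run_pipeline(PipelineConfig.from_json(cfg_path))
        s2 = run_pipeline(PipelineConfig.from_json(cfg_path))
        assert s1["outputs"] == s2["outputs"]      # content hashes equal
        assert s1["phi"] == s2["phi"]

    def test_missing_mask_fails_before_compute(self, tmp_path):
        cfg_path, _ = _write_session_and_config(tmp_path)
        raw = json.loads(cfg_path.read_text())
        raw["roi"] = str(tmp_path / "nope.nii.gz")
        cfg_path.write_text(json.dumps(raw))
        with pytest.raises(ConfigError, match="does not exist"):
            cfg = PipelineConfig.from_json(cfg_path)
            cfg.validate()

    def test_unknown_key_rejected(self, tmp_path):
        cfg_path, _ = _write_session_and_config(tmp_path)
        raw = json.loads(cfg_path.read_text())
        raw["bogus_option"] = 1
        cfg_path.write_text(json.dumps(raw))
        with pytest.raises(ConfigError, match="unknown config keys"):
            PipelineConfig.from_json(cfg_path)

    def test_config_written_back_reproduces(self, tmp_path):
        cfg_path, _ = _write_session_and_config(tmp_path)
        s1 = run_pipeline(PipelineConfig.from_json(cfg_path))
        effective = Path(json.loads(cfg_path.read_text())["out_dir"]) / "config.json"
        s2 = run_pipeline(PipelineConfig.from_json(effective))
        assert s1["phi"] == s2["phi"]
        assert s1["roi_mean_magnitude"] == s2["roi_mean_magnitude"]


class TestCli:
    def test_simulate_then_estimate_smoke(self, tmp_path):
        runner = CliRunner()
        r1 = runner.invoke(cli_main, ["simulate", "--seed", "7",
                                      "--out", str(tmp_path / "d")])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(cli_main, ["estimate", "--config",
                                      str(tmp_path / "d" / "cfg.json")])
        assert r2.exit_code == 0, r2.output
        assert "phi" in r2.output

    def test_test_subcommand_overrides_method_and_threshold(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, ["simulate", "--seed", "7",
                                 "--out", str(tmp_path / "d")])
        r = runner.invoke(cli_main, ["test", "--config",
                                     str(tmp_path / "d" / "cfg.json"),
                                     "--method", "aligned", "--threshold", "20"])
        assert r.exit_code == 0, r.output
        assert "aligned_misaligned" in r.output
        written = json.loads((tmp_path / "d" / "results" / "config.json").read_text())
        assert written["glm2"]["method"] == "aligned_misaligned"
        assert written["glm2"]["align_threshold"] == 20.0

    def test_sweep_emits_requested_rows(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, ["simulate", "--seed", "7",
                                 "--out", str(tmp_path / "d")])
        out_tsv = tmp_path / "sweep.tsv"
        r = runner.invoke(cli_main, ["sweep", "--config",
                                     str(tmp_path / "d" / "cfg.json"),
                                     "--folds", "4,5,6,7,8",
                                     "--out", str(out_tsv)])
        assert r.exit_code == 0, r.output
        import pandas as pd

        table = pd.read_csv(out_tsv, sep="\t")
        assert len(table) == 5
        assert "best-fitting fold" in r.output

    def test_stability_subcommand(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, ["simulate", "--seed", "7",
                                 "--out", str(tmp_path / "d")])
        r = runner.invoke(cli_main, ["stability", "--config",
                                     str(tmp_path / "d" / "cfg.json")])
        assert r.exit_code == 0, r.output
        assert "stable voxels" in r.output

    def test_unknown_flag_usage_error(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["estimate", "--frobnicate"])
        assert r.exit_code == 2

    def test_missing_config_validation_error(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps({"bold": ["nope.nii"], "events": "nope.tsv",
                                   "out_dir": str(tmp_path), "tr": 1.5}))
        r = runner.invoke(cli_main, ["run", "--config", str(bad)])
        assert r.exit_code == 2
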