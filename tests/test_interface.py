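"""I/O round trips, config validation and the CLI workflow."""

import json

import numpy as np
import pydantic
import pytest
from click.testing import CliRunner

from cpcdosy import AcquisitionParams, DecayCurve, GroundTruth, RunConfig, simulate_decay
from cpcdosy.cli import main
from cpcdosy.io import (
    load_decay_table,
    load_titration_table,
    write_decay_table,
    write_titration_table,
)


class TestDecayTableIO:
    def test_write_read_round_trip(self, acq, ramp16, tmp_path):
        truth = GroundTruth(true_D_per_species={"H1 8.9 ppm": 4e-10}, noise_sd=0.01)
        curve = simulate_decay(truth, acq, ramp16, seed=3, species="H1 8.9 ppm")
        path = tmp_path / "decay.csv"
        write_decay_table(curve, path)
        back = load_decay_table(path)["H1 8.9 ppm"]
        assert np.allclose(back.gradient_strengths, curve.gradient_strengths)
        assert np.allclose(back.intensities, curve.intensities)

    def test_shuffled_rows_normalised(self, tmp_path):
        path = tmp_path / "decay.csv"
        path.write_text(
            "gradient_T_per_m,intensity,peak_label\n"
            "0.3,0.5,p\n0.1,0.9,p\n0.2,0.7,p\n"
        )
        curve = load_decay_table(path)["p"]
        assert list(curve.gradient_strengths) == [0.1, 0.2, 0.3]
        assert list(curve.intensities) == [0.9, 0.7, 0.5]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("gradient_T_per_m,peak_label\n0.1,p\n")
        with pytest.raises(ValueError, match="intensity"):
            load_decay_table(path)

    def test_duplicate_pairs_reported_with_rows(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "gradient_T_per_m,intensity,peak_label\n0.1,1.0,p\n0.1,0.9,p\n"
        )
        with pytest.raises(ValueError, match="row"):
            load_decay_table(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "nn.csv"
        path.write_text("gradient_T_per_m,intensity,peak_label\n0.1,oops,p\n")
        with pytest.raises(ValueError, match="intensity"):
            load_decay_table(path)


class TestRunConfig:
    def test_defaults_validate(self):
        cfg = RunConfig()
        acq = cfg.acquisition.to_params()
        assert isinstance(acq, AcquisitionParams)
        assert acq.little_delta == pytest.approx(1.5e-3)  # bipolar: 2 x 0.75 ms

    def test_unknown_keys_rejected_with_location(self):
        with pytest.raises(pydantic.ValidationError, match="typo_key"):
            RunConfig.model_validate({"thresholds": {"typo_key": 1}})

    def test_invalid_threshold_refused(self):
        with pytest.raises(pydantic.ValidationError):
            RunConfig.model_validate(
                {"thresholds": {"countable_plate_min": 300, "countable_plate_max": 30}}
            )

    def test_hash_stable_and_sensitive(self):
        a, b = RunConfig(), RunConfig()
        assert a.config_hash() == b.config_hash()
        c = RunConfig.model_validate({"seed": 99})
        assert c.config_hash() != a.config_hash()

    def test_monopolar_convention(self):
        cfg = RunConfig.model_validate({"acquisition": {"delta_convention": "monopolar"}})
        assert cfg.acquisition.to_params().little_delta == pytest.approx(0.75e-3)


class TestCli:
    def test_simulate_then_fit_recovers_truth(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "run"
        r1 = runner.invoke(
            main, ["--out", str(out), "simulate", "--d", "4.4e-10", "--noise-sd", "0.01"]
        )
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, ["--out", str(out), "fit", str(out / "decay.csv")])
        assert r2.exit_code == 0, r2.output
        report = json.loads((out / "fit_report.json").read_text())
        d_hat = report["cpc"]["D_m2_per_s"][0]
        assert d_hat == pytest.approx(4.4e-10, rel=0.05)
        assert report["cpc"]["expanded_uncertainty_pct_k2"] > 0
        # run log carries provenance for both stages
        lines = (out / "run_log.jsonl").read_text().strip().splitlines()
        assert len(lines) == 2
        assert all("config_hash" in json.loads(ln) for ln in lines)

    def test_rerun_same_seed_byte_identical(self, tmp_path):
        runner = CliRunner()
        texts = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            r = runner.invoke(main, ["--out", str(out), "simulate", "--seed", "12"])
            assert r.exit_code == 0, r.output
            texts.append((out / "decay.csv").read_bytes())
        assert texts[0] == texts[1]

    def test_bind_subcommand_recovers_ka(self, tmp_path):
        from cpcdosy import simulate_binding_titration

        hosts = np.logspace(-4.5, -1.5, 8)
        d = simulate_binding_titration(500.0, 5e-10, 0.8e-10, 1e-4, hosts)
        tit = tmp_path / "titration.csv"
        write_titration_table(hosts, d, tit)
        assert len(load_titration_table(tit)) == 8
        runner = CliRunner()
        r = runner.invoke(
            main,
            ["--out", str(tmp_path / "o"), "bind", str(tit), "--d-free", "5e-10",
             "--d-bound", "0.8e-10", "--guest-total", "1e-4"],
        )
        assert r.exit_code == 0, r.output
        result = json.loads((tmp_path / "o" / "binding.json").read_text())
        assert result["K_a_per_M"] == pytest.approx(500.0, rel=0.01)

    def test_invalid_config_refused_before_computation(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({"thresholds": {"activity_log10": 5, "bogus": 1}}))
        runner = CliRunner()
        r = runner.invoke(main, ["--config", str(cfg), "simulate"])
        assert r.exit_code != 0

    def test_panel_simulation_smoke(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "p"
        r = runner.invoke(main, ["--out", str(out), "panel", "--simulate-n", "40"])
        assert r.exit_code == 0, r.output
        report = json.loads((out / "panel_report.json").read_text())
        assert report["n_records"] == 40
        assert report["regressions"]["log_kill~cpc_free_conc"]["slope"] > 0


def test_decay_curve_csv_round_trip_multi_peak(tmp_path):
    acq = AcquisitionParams()
    g = np.linspace(0.05, 0.5, 8)
    curves = [
        DecayCurve(g, np.exp(-np.arange(8) * 0.2), "H1 8.9 ppm"),
        DecayCurve(g, np.exp(-np.arange(8) * 0.4), "H2 8.1 ppm"),
    ]
    path = tmp_path / "multi.csv"
    write_decay_table(curves, path)
    back = load_decay_table(path)
    assert set(back) == {"H1 8.9 ppm", "H2 8.1 ppm"}
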