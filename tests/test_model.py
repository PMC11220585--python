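"""End-to-end model fitting, reports, campaign scoring and the CLI."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from chromyield.chromdata import AnalyteSpec, write_ms, write_pda
from chromyield.cli import main as cli_main
from chromyield.config import RunConfig
from chromyield.model import (
    ReactionYieldModel,
    YieldResult,
    estimate_yield,
    run_campaign,
)
from chromyield.simulate import SimAnalyte, simulate_sample

BENZAMIDE = "NC(=O)c1ccccc1"


class TestFit:
    def test_noiseless_fit_recovers_truth(self, noiseless_sample, target_spec,
                                          config, epsilon_table):
        pda, traces, truth = noiseless_sample
        res = ReactionYieldModel(pda, list(traces), target_spec,
                                 config=config,
                                 epsilon_predictor=epsilon_table).fit()
        assert res.yield_fraction == pytest.approx(truth.true_yields["x"],
                                                   rel=0.01)
        assert res.flags == frozenset()
        assert res.n_components == 1
        assert res.lambda_red == pytest.approx(350.0, abs=2.0)

    def test_saturated_sample_flagged_with_half_injection(
            self, constants, gradient, config, epsilon_table):
        hot = SimAnalyte(label="x", conc=5e-3, log10_eps_water=4.4,
                         log10_eps_acn=4.4,
                         spectrum_bands=((350.0, 18.0, 1.0),),
                         retention=200.0, peak_sigma=2.0, mz=486.007,
                         smiles=BENZAMIDE)
        pda, traces, _ = simulate_sample([hot], constants=constants,
                                         gradient=gradient, seed=0)
        pred = _exact_predictor(hot)
        res = ReactionYieldModel(pda, traces,
                                 AnalyteSpec(smiles=BENZAMIDE,
                                             exact_mass=485.0),
                                 config=config,
                                 epsilon_predictor=pred).fit()
        assert "saturated" in res.flags
        assert res.suggested_injection_factor == 0.5

    def test_weak_sample_flagged_with_double_injection(
            self, constants, gradient, config):
        faint = SimAnalyte(label="x", conc=2e-5, log10_eps_water=2.9,
                           log10_eps_acn=2.9,
                           spectrum_bands=((350.0, 18.0, 1.0),),
                           retention=200.0, peak_sigma=3.0, mz=486.007,
                           smiles=BENZAMIDE)
        pda, traces, _ = simulate_sample([faint], constants=constants,
                                         gradient=gradient, seed=0,
                                         noise_sigma=0.0005,
                                         drift_amplitude=0.0)
        res = ReactionYieldModel(pda, traces,
                                 AnalyteSpec(smiles=BENZAMIDE,
                                             exact_mass=485.0),
                                 config=config,
                                 epsilon_predictor=_exact_predictor(faint)
                                 ).fit()
        assert "weak" in res.flags
        assert res.suggested_injection_factor == 2.0

    def test_overloaded_window_withholds_yield(self, constants, gradient,
                                               config):
        # four mutually distinct, strongly absorbing species all inside the
        # target's resolution window (target second-from-left so the window
        # spans every apex)
        retentions = (196.0, 190.0, 201.0, 206.0)
        analytes = [
            SimAnalyte(label=f"c{k}", conc=4e-3, log10_eps_water=4.0,
                       log10_eps_acn=4.0,
                       spectrum_bands=((260.0 + 70 * k, 14.0, 1.0),),
                       retention=retentions[k], peak_sigma=3.0,
                       mz=486.007 + 10 * k, smiles=BENZAMIDE)
            for k in range(4)]
        pda, traces, _ = simulate_sample(analytes, constants=constants,
                                         gradient=gradient, seed=0,
                                         noise_sigma=0.0005)
        res = ReactionYieldModel(pda, traces,
                                 AnalyteSpec(smiles=BENZAMIDE,
                                             exact_mass=485.0),
                                 config=config,
                                 epsilon_predictor=_exact_predictor(
                                     analytes[0])).fit()
        assert "overloaded" in res.flags
        assert res.yield_fraction is None

    def test_deterministic_reports(self, noiseless_sample, target_spec,
                                   config, epsilon_table):
        pda, traces, _ = noiseless_sample
        reports = []
        for _ in range(2):
            res = ReactionYieldModel(pda, list(traces), target_spec,
                                     config=config,
                                     epsilon_predictor=epsilon_table
                                     ).fit(seed=0)
            d = res.to_report()
            d.pop("timings")
            reports.append(json.dumps(d, sort_keys=True))
        assert reports[0] == reports[1]

    def test_config_digest_recorded(self, noiseless_sample, target_spec,
                                    config, epsilon_table):
        pda, traces, _ = noiseless_sample
        res = ReactionYieldModel(pda, list(traces), target_spec,
                                 config=config,
                                 epsilon_predictor=epsilon_table).fit()
        assert res.config_digest == config.digest()

    def test_report_roundtrip_and_summary(self, noiseless_sample, target_spec,
                                          config, epsilon_table):
        pda, traces, _ = noiseless_sample
        res = ReactionYieldModel(pda, list(traces), target_spec,
                                 config=config,
                                 epsilon_predictor=epsilon_table).fit()
        back = YieldResult.from_report(json.loads(res.to_json()))
        assert back.yield_fraction == res.yield_fraction
        assert back.flags == res.flags
        text = res.summary()
        assert "yield" in text and "MCR components" in text


def _exact_predictor(analyte):
    from chromyield.quantify import TablePredictor

    pred = TablePredictor()
    pred.add(analyte.smiles, "water", analyte.log10_eps_water,
             lambda_max=analyte.lambda_red)
    pred.add(analyte.smiles, "acetonitrile", analyte.log10_eps_acn,
             lambda_max=analyte.lambda_red)
    return pred


class TestEstimateYieldFromFiles:
    def test_file_round_trip(self, tmp_path, noiseless_sample, target_spec,
                             config, epsilon_table):
        pda, traces, truth = noiseless_sample
        pda_path = write_pda(pda, tmp_path / "s.npz")
        ms_path = write_ms(list(traces), tmp_path / "s_ms.npz")
        model = ReactionYieldModel.from_files(
            pda_path, ms_path, target_spec, config=config,
            epsilon_predictor=epsilon_table)
        res = model.fit()
        assert res.yield_fraction == pytest.approx(truth.true_yields["x"],
                                                   rel=0.01)


class TestRunCampaign:
    def test_unmatched_truth_row_scored_separately(self, noiseless_sample,
                                                   target_spec, config,
                                                   epsilon_table):
        pda, traces, _ = noiseless_sample

        @dataclasses.dataclass
        class S:
            sample_id: str
            pda: object
            ms_traces: tuple
            target_spec: object

        samples = [S("a", pda, tuple(traces), target_spec)]
        truth = pd.DataFrame([{"sample_id": "WRONG", "true_yield": 0.5}])
        table, stats = run_campaign(samples, config,
                                    epsilon_predictor=epsilon_table,
                                    truth_table=truth)
        assert stats["n_unmatched"] == 1
        assert stats["n_scored"] == 0

    def test_partial_failure_recorded_and_campaign_continues(
            self, noiseless_sample, target_spec, config, epsilon_table):
        pda, traces, _ = noiseless_sample

        @dataclasses.dataclass
        class S:
            sample_id: str
            pda: object
            ms_traces: tuple
            target_spec: object

        bad_spec = AnalyteSpec(smiles=BENZAMIDE, exact_mass=999.0)
        samples = [S("bad", pda, tuple(traces), bad_spec),
                   S("good", pda, tuple(traces), target_spec)]
        table, stats = run_campaign(samples, config,
                                    epsilon_predictor=epsilon_table)
        assert stats["n_failed"] == 1
        assert table.loc[table.sample_id == "bad", "error"].notna().all()
        assert table.loc[table.sample_id == "good", "yield_est"].notna().all()


class TestCli:
    def test_simulate_then_quantify(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "data"
        r = runner.invoke(cli_main, ["simulate", "--n-samples", "1",
                                     "--seed", "5", "--out", str(out_dir),
                                     "--noise-sigma", "0.001",
                                     "--overlap-fraction", "0.0"])
        assert r.exit_code == 0, r.output
        truth = pd.read_csv(out_dir / "truth.csv")
        report_path = tmp_path / "report.json"
        r = runner.invoke(cli_main, [
            "quantify", "--pda", str(out_dir / "sample_0000_pda.npz"),
            "--ms", str(out_dir / "sample_0000_ms.npz"),
            "--smiles", truth.loc[0, "smiles"],
            "--config", str(out_dir / "config.json"),
            "--out", str(report_path)])
        assert r.exit_code == 0, r.output
        report = json.loads(report_path.read_text())
        assert report["n_components"] >= 1
        assert report["config_digest"]
        # the emitted config references the campaign's epsilon table, so the
        # estimate should land near the simulated truth
        assert report["yield_fraction"] == pytest.approx(
            truth.loc[0, "true_yield"], rel=0.15)

    def test_campaign_command_scores_dataset(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "data"
        r = runner.invoke(cli_main, ["simulate", "--n-samples", "2",
                                     "--seed", "6", "--out", str(out_dir),
                                     "--overlap-fraction", "0.0"])
        assert r.exit_code == 0, r.output
        out_csv = tmp_path / "results.csv"
        r = runner.invoke(cli_main, ["campaign", "--dataset", str(out_dir),
                                     "--config", str(out_dir / "config.json"),
                                     "--out", str(out_csv)])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(out_csv)
        assert len(table) == 2
        assert "yield_est" in table.columns

    def test_quantify_exit_code_for_missing_product(self, tmp_path,
                                                    noiseless_sample):
        pda, traces, _ = noiseless_sample
        pda_path = write_pda(pda, tmp_path / "s.npz")
        ms_path = write_ms(list(traces), tmp_path / "s_ms.npz")
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "quantify", "--pda", str(pda_path), "--ms", str(ms_path),
            "--smiles", BENZAMIDE, "--exact-mass", "999.0"])
        assert r.exit_code == 3  # product mass not detected

    def test_inspect_dumps_summary(self, tmp_path, noiseless_sample):
        pda, _, _ = noiseless_sample
        pda_path = write_pda(pda, tmp_path / "s.npz")
        runner = CliRunner()
        r = runner.invoke(cli_main, ["inspect", "--pda", str(pda_path),
                                     "--wavelength", "350"])
        assert r.exit_code == 0, r.output
        info = json.loads(r.output)
        assert info["n_wavelengths"] == 601
        assert info["channel_apex_s"] == pytest.approx(200.0, abs=1.0)
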