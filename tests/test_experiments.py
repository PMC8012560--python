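"""Experiment drivers and the CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest

import netresil as nr
from netresil.experiments import (
    ExperimentConfig,
    run_study1,
    run_study2,
    run_study3,
    synthetic_study2_network,
)


@pytest.fixture(scope="module")
def study1_table():
    return run_study1(ExperimentConfig(study="study1", seed=1))


@pytest.fixture(scope="module")
def study2_table():
    cfg = ExperimentConfig(study="study2", seed=2, iterations=6000, burn_in=600)
    return run_study2(cfg)


class TestStudy1:

    def test_default_design_is_99_rows(self, study1_table):
        assert len(study1_table) == 99  # 3 densities x 3 targets x 11 constants

    def test_density1_cells_match_reference_values(self, study1_table):
        d1 = study1_table[study1_table.density == 1.0]
        cell = lambda t, c: d1[(d1.target == t) & (d1.multiplier == c)].iloc[0]  # noqa: E731
        expected = {
            ("edges", 2.0): (8.98, 6.47),
            ("edges", 0.5): (1.46, 0.77),
            ("thresholds", 0.5): (8.40, 1.08),
            ("thresholds", 2.0): (0.18, 2.26),
            ("both", 0.5): (4.5, 0.49),
            ("both", 2.0): (4.5, 0.23),
            ("both", 1.0): (4.5, 0.34),
        }
        for (t, c), (esa, sas) in expected.items():
            row = cell(t, c)
            assert row.esa == pytest.approx(esa, abs=5e-3)
            assert row.sas == pytest.approx(sas, abs=5e-3)

    def test_density1_both_rows_hold_esa(self, study1_table):
        both = study1_table[(study1_table.density == 1.0) & (study1_table.target == "both")]
        assert np.allclose(both.esa, 4.5, atol=1e-9)

    def test_exact_density1_rows_are_seed_independent(self, study1_table):
        other = run_study1(ExperimentConfig(study="study1", seed=99))
        a = study1_table[study1_table.density == 1.0].reset_index(drop=True)
        b = other[other.density == 1.0].reset_index(drop=True)
        assert np.allclose(a.esa, b.esa) and np.allclose(a.sas, b.sas)

    def test_trivial_grid_returns_per_density_baselines(self):
        t = run_study1(ExperimentConfig(study="study1", seed=1, grid=(1.0,)))
        assert len(t) == 9
        assert t.groupby("density").esa.nunique().le(1).all()

    def test_rows_carry_provenance(self, study1_table):
        assert {"config_hash", "run_seed", "version"} <= set(study1_table.columns)
        assert study1_table.config_hash.nunique() == 1

    def test_csv_output(self, tmp_path):
        cfg = ExperimentConfig(study="study1", seed=1, densities=(1.0,),
                               grid=(1.0,), out_dir=str(tmp_path))
        run_study1(cfg)
        assert (tmp_path / "study1.csv").exists()


class TestStudy2:

    def test_design_shape(self, study2_table):
        assert len(study2_table) == 66  # 2 conditions x 3 targets x 11 constants
        assert set(study2_table.condition) == {"strong_nodes", "weak_nodes"}

    def test_strong_condition_spans_wider_esa_range(self, study2_table):
        """Perturbing central nodes moves activity further than weak nodes."""
        rng = study2_table.groupby("condition").esa.agg(lambda s: s.max() - s.min())
        assert rng["strong_nodes"] > rng["weak_nodes"]

    def test_unperturbed_rows_agree_across_conditions(self, study2_table):
        base = study2_table[study2_table.multiplier == 1.0]
        spread = base.groupby("target").esa.agg(lambda s: s.max() - s.min())
        assert (spread < 1.0).all()  # same network, MC noise only

    def test_synthetic_network_is_heterogeneous(self):
        net = synthetic_study2_network(seed=0)
        strengths = nr.node_strength(net).strength
        assert net.n_nodes == 27 and strengths.std() > 0.1


class TestStudy3:
    def test_canonical_scenarios_and_signs(self):
        t = run_study3(ExperimentConfig(study="study3", seed=3))
        t = t.set_index("scenario")
        assert t.loc["baseline", "delta"] == 0.0
        assert t.loc["protective_present_risk_absent", "delta"] < 0
        assert t.loc["risk_present_protective_absent", "delta"] > 0
        assert (t.clip_count == 0).all()

    def test_rerun_is_bit_identical(self, tmp_path):
        cfg = ExperimentConfig(study="study3", seed=4, out_dir=str(tmp_path / "a"))
        run_study3(cfg)
        cfg2 = ExperimentConfig(study="study3", seed=4, out_dir=str(tmp_path / "b"))
        run_study3(cfg2)
        a = (tmp_path / "a" / "study3.csv").read_text()
        b = (tmp_path / "b" / "study3.csv").read_text()
        assert a == b

    def test_uncoupled_model_has_zero_deltas(self):
        _, model = nr.generate_hybrid_dataset(
            nr.HybridGeneratorSpec(
                n_symptoms=5, n_persons=10, seed=0, sf_coef=0.0,
                factors=(nr.FactorSpec("r", "risk"),
                         nr.FactorSpec("p", "protective")),
            )
        )
        t = run_study3(ExperimentConfig(study="study3"), model=model)
        assert np.allclose(t.delta, 0.0, atol=1e-8)


class TestCli:
    def test_metrics_command_exact(self, tmp_path, baseline9):
        from click.testing import CliRunner

        from netresil import io
        from netresil.cli import main

        io.write_network_json(baseline9, tmp_path / "net.json")
        result = CliRunner().invoke(
            main, ["metrics", "--network", str(tmp_path / "net.json")]
        )
        assert result.exit_code == 0
        payload = json.loads(result.output)
        assert payload["esa"] == pytest.approx(4.5, abs=1e-6)

    def test_study1_command_writes_csv(self, tmp_path):
        from click.testing import CliRunner

        from netresil.cli import main

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("densities: [1.0]\ngrid: [1.0]\n")
        result = CliRunner().invoke(
            main, ["study1", "--config", str(cfg), "--out", str(tmp_path), "--seed", "1"]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "study1.csv").exists()

    def test_estimate_command_roundtrip(self, tmp_path):
        from click.testing import CliRunner

        from netresil import io
        from netresil.cli import main

        truth = nr.make_network([-1.0, -1.0, -1.0], 1.0 - np.eye(3))
        nr.sample_ising_exact(truth, 800, seed=0).to_csv(tmp_path / "d.csv", index=False)
        result = CliRunner().invoke(
            main, ["estimate", "--data", str(tmp_path / "d.csv"),
                   "--out", str(tmp_path / "net.json")]
        )
        assert result.exit_code == 0, result.output
        est = io.read_network_json(tmp_path / "net.json")
        assert est.n_nodes == 3

    def test_missing_network_exits_nonzero(self, tmp_path):
        from click.testing import CliRunner

        from netresil.cli import main

        bad = tmp_path / "broken.json"
        bad.write_text("{not json")
        result = CliRunner().invoke(main, ["metrics", "--network", str(bad)])
        assert result.exit_code != 0


def test_plot_sweep_produces_figure(tmp_path):
    table = run_study1(ExperimentConfig(study="study1", densities=(1.0,), grid=(0.5, 1.0, 2.0)))
    from netresil.experiments import plot_sweep

    plot_sweep(table, tmp_path / "fig.png")
    assert (tmp_path / "fig.png").stat().st_size > 0
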