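import os

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from glycosync import (
    AnalysisParams,
    PopulationSynchrony,
    SimulationConfig,
    period_from_frequency_mHz,
    write_population,
)
from glycosync.cli import main


def test_period_conversion_and_validation():
    assert period_from_frequency_mHz(20.0) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        period_from_frequency_mHz(0.0)


def test_default_run_reproduces_epoch_sequence(default_results):
    labels = default_results.episodes["label"].tolist()
    assert labels[0] == "induction"
    assert "asynchronous" in labels
    assert "partial_sync" in labels
    assert labels[-1] == "decayed"
    # epochs appear in temporal order
    starts = default_results.episodes["t_start"].to_numpy()
    assert np.all(np.diff(starts) > 0)


def test_partial_sync_episode_properties(default_results):
    part = default_results.partial_sync_episodes()
    assert len(part) >= 1
    row = part.iloc[0]
    assert 0.40 < row["mean_R"] < 0.85
    assert row["t_end"] - row["t_start"] >= 100.0
    assert row["period_s"] == pytest.approx(1000.0 / row["mean_f_mHz"])


def test_summary_contains_key_sections(default_results):
    text = default_results.summary()
    for token in ("Epochs", "partial_sync", "clusters (by_density)", "chimera test"):
        assert token in text


def test_report_dict_round_trips_through_yaml(default_results):
    d = default_results.report_dict()
    assert d["n_cells"] == 232
    assert {"episodes", "clusters", "params", "simulation"} <= set(d)
    text = yaml.safe_dump(d)
    assert yaml.safe_load(text)["n_cells"] == 232


def test_save_writes_all_tables(default_results, tmp_path):
    out = tmp_path / "run"
    default_results.save(str(out))
    for name in (
        "filtered.tsv",
        "collective.tsv",
        "phases.tsv",
        "global.tsv",
        "episodes.tsv",
        "tessellation.tsv",
        "clusters.tsv",
        "cluster_sync.tsv",
        "chimera.tsv",
        "report.txt",
        "report.yaml",
    ):
        assert (out / name).exists(), name


def test_model_from_files_matches_simulation(tmp_path):
    cfg = SimulationConfig(seed=3, n_cells=20, duration_s=600.0)
    model_sim = PopulationSynchrony.from_simulation(
        cfg, params=AnalysisParams(cluster_modes=())
    )
    write_population(model_sim.population, tmp_path)
    model_files = PopulationSynchrony.from_files(
        str(tmp_path / "traces.tsv"),
        str(tmp_path / "positions.tsv"),
        geometry=cfg.geometry,
        params=AnalysisParams(cluster_modes=()),
    )
    a = model_sim.fit()
    b = model_files.fit()
    assert np.allclose(a.R, b.R, atol=1e-12)


def test_cli_simulate_validate_run(tmp_path):
    runner = CliRunner()
    sim_dir = tmp_path / "sim"
    cfg = SimulationConfig(seed=5, n_cells=24, duration_s=600.0)
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg.to_dict()))

    r = runner.invoke(main, ["simulate", "--config", str(cfg_path), "--out", str(sim_dir)])
    assert r.exit_code == 0, r.output
    assert (sim_dir / "traces.tsv").exists()
    assert (sim_dir / "simulation_config.yaml").exists()

    r = runner.invoke(
        main, ["validate", str(sim_dir / "traces.tsv"), str(sim_dir / "positions.tsv")]
    )
    assert r.exit_code == 0, r.output
    assert "24 cells" in r.output

    out_dir = tmp_path / "out"
    r = runner.invoke(
        main,
        [
            "run",
            "--traces", str(sim_dir / "traces.tsv"),
            "--positions", str(sim_dir / "positions.tsv"),
            "--geometry", '{"shape": "circle", "diameter_um": 169}',
            "--out", str(out_dir),
        ],
    )
    assert r.exit_code == 0, r.output
    assert (out_dir / "report.yaml").exists()
    assert "Epochs" in r.output


def test_cli_run_from_preset_seed_override(tmp_path):
    runner = CliRunner()
    out_dir = tmp_path / "out"
    cfg = SimulationConfig(seed=6, n_cells=20, duration_s=500.0)
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg.to_dict()))
    r = runner.invoke(
        main,
        ["run", "--sim-config", str(cfg_path), "--seed", "7", "--out", str(out_dir)],
    )
    assert r.exit_code == 0, r.output
    report = yaml.safe_load((out_dir / "report.yaml").read_text())
    assert report["simulation"]["seed"] == 7
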