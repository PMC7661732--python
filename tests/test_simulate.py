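import numpy as np
import pytest

from glycosync import Circle, SimulationConfig, simulate_population
from glycosync.config import Placement, dense_preset, sparse_preset
from glycosync.simulate import amplitude_envelope, place_cells, simulate_phases


SMALL = dict(n_cells=20, duration_s=400.0)


def test_determinism_same_seed_bit_identical():
    cfg = SimulationConfig(seed=7, **SMALL)
    a = simulate_population(cfg)
    b = simulate_population(cfg)
    assert np.array_equal(a.traces, b.traces)
    assert a.positions.equals(b.positions)


def test_different_seeds_differ():
    a = simulate_population(SimulationConfig(seed=1, **SMALL))
    b = simulate_population(SimulationConfig(seed=2, **SMALL))
    assert not np.array_equal(a.traces, b.traces)


def test_positions_inside_geometry_and_unique():
    cfg = SimulationConfig(seed=3, **SMALL)
    pop = simulate_population(cfg)
    geom = cfg.geometry
    assert np.all(geom.contains(pop.positions["x_um"], pop.positions["y_um"]))
    assert pop.positions["cell_id"].is_unique
    assert len(pop.positions) == cfg.n_cells


def test_clustered_placement_stays_inside_field():
    cfg = SimulationConfig(
        seed=4,
        n_cells=60,
        geometry=Circle(80.0),
        placement=Placement(mode="clustered", n_parents=5, spread_um=4.0),
        duration_s=100.0,
    )
    rng = np.random.default_rng(cfg.seed)
    pos = place_cells(cfg, rng)
    assert np.all(cfg.geometry.contains(pos["x_um"], pos["y_um"]))


def test_uncoupled_phase_slope_matches_natural_frequency():
    cfg = SimulationConfig(
        seed=5, n_cells=4, duration_s=600.0, coupling_strength=0.0, phase_noise_sd=0.0
    )
    rng = np.random.default_rng(cfg.seed)
    pos = place_cells(cfg, rng)
    theta, omega = simulate_phases(cfg, pos, rng, return_omega=True)
    slopes = (theta[:, -1] - theta[:, 0]) / (cfg.times[-1] - cfg.times[0])
    assert np.allclose(slopes, omega, rtol=1e-9)


def test_no_coupling_effect_before_ramp_onset():
    base = dict(n_cells=6, duration_s=200.0, phase_noise_sd=0.0, seed=6,
                coupling_ramp=(1000.0, 1200.0))
    weak = SimulationConfig(coupling_strength=0.0, **base)
    strong = SimulationConfig(coupling_strength=0.5, **base)
    rng_kwargs = {}
    rng1 = np.random.default_rng(6)
    pos = place_cells(weak, rng1)
    th_weak = simulate_phases(weak, pos, np.random.default_rng(42))
    th_strong = simulate_phases(strong, pos, np.random.default_rng(42))
    # the record ends before the ramp starts: coupling must not act
    assert np.allclose(th_weak, th_strong)


def test_amplitude_envelope_shape():
    t = np.array([0.0, 50.0, 100.0, 600.0, 1100.0, 1300.0])
    env = amplitude_envelope(t, 100.0, 1100.0, 200.0)
    assert env[0] == 0.0
    assert env[1] == pytest.approx(0.5)
    assert env[2] == env[3] == env[4] == pytest.approx(1.0)
    assert env[5] == pytest.approx(np.exp(-1.0))


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimulationConfig(n_cells=1)
    with pytest.raises(ValueError):
        SimulationConfig(sample_interval_s=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(coupling_ramp=(500.0, 400.0))
    with pytest.raises(ValueError):
        SimulationConfig(coupling_length_um=0.0)


def test_config_dict_round_trip():
    cfg = dense_preset(seed=9)
    assert SimulationConfig.from_dict(cfg.to_dict()) == cfg
    cfg = sparse_preset(seed=3)
    assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


def test_presets_match_study_conditions():
    sparse = sparse_preset()
    dense = dense_preset()
    assert sparse.n_cells == 232 and sparse.geometry == Circle(169.0)
    assert dense.n_cells == 251 and dense.geometry.side_um == 85.0
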