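"""Synthetic oscillating cell populations.

Generates per-cell fluorescence traces with the statistical structure the
downstream synchronisation analysis assumes: a population of noisy phase
oscillators (Sakaguchi-Kuramoto with distance-weighted coupling) rendered
into fluorescence-like signals with baseline drift, an amplitude envelope
and detection noise.  The generator is the stand-in for experimental
recordings, so everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig

_MAX_PLACEMENT_TRIES = 200


@dataclass
class Population:
    """A set of cell traces on one shared, uniform time grid.

    ``traces[i, k]`` is the fluorescence of cell ``i`` at time ``t[k]``;
    ``positions`` holds one row per cell (cell_id, x_um, y_um, optional
    area_um2) in the same order as the trace rows.
    """

    t: np.ndarray  # (T,) seconds
    traces: np.ndarray  # (N, T) fluorescence, arbitrary units
    positions: pd.DataFrame  # columns cell_id, x_um, y_um[, area_um2]

    def __post_init__(self):
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (cells x time) array")
        if self.traces.shape[0] != len(self.positions):
            raise ValueError("positions and traces disagree on cell count")
        if self.traces.shape[1] != len(self.t):
            raise ValueError("time grid and traces disagree on sample count")
        dt = np.diff(self.t)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def cell_ids(self) -> np.ndarray:
        return self.positions["cell_id"].to_numpy()

    @property
    def sample_interval_s(self) -> float:
        return float(self.t[1] - self.t[0])


def place_cells(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw cell positions inside the field of view.

    Uniform mode draws independent uniform points; clustered mode scatters
    cells around uniform parent points with Gaussian spread, mimicking the
    spatial clusters that form when cells sediment onto the coverslip.
    Returns a DataFrame with columns cell_id, x_um, y_um.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geom = config.geometry
    n = config.n_cells
    placement = config.placement

    if placement.mode == "uniform":
        pos = geom.sample(rng, n)
    else:
        parents = geom.sample(rng, placement.n_parents)
        which = rng.integers(0, placement.n_parents, size=n)
        pos = np.empty((n, 2))
        for i in range(n):
            for _ in range(_MAX_PLACEMENT_TRIES):
                p = parents[which[i]] + rng.normal(0.0, placement.spread_um, size=2)
                if geom.contains(p[0], p[1]):
                    pos[i] = p
                    break
            else:
                raise RuntimeError(
                    "could not place a cell inside the field of view; "
                    "geometry too small for the requested placement"
                )

    # duplicate centres would break the Voronoi tessellation downstream
    for _ in range(_MAX_PLACEMENT_TRIES):
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        dup = np.argwhere(d < 1e-9)
        if len(dup) == 0:
            break
        for i in np.unique(dup[:, 0]):
            pos[i] = geom.sample(rng, 1)[0]
    else:
        raise RuntimeError("geometry too small to place cells at distinct positions")

    return pd.DataFrame({"cell_id": np.arange(n), "x_um": pos[:, 0], "y_um": pos[:, 1]})


def _coupling_ramp(t: np.ndarray, t_on: float, t_full: float, k_full: float) -> np.ndarray:
    if t_full == t_on:
        return np.where(t >= t_on, k_full, 0.0)
    ramp = np.clip((t - t_on) / (t_full - t_on), 0.0, 1.0)
    return k_full * ramp


def simulate_phases(
    config: SimulationConfig,
    positions: pd.DataFrame,
    rng: np.random.Generator | None = None,
    return_omega: bool = False,
):
    """Integrate the phase model and return per-cell phase paths.

    The model is

        dtheta_i/dt = omega_i + K(t) * R_i * sin(Theta_i - theta_i + alpha) + xi_i(t)

    where (R_i, Theta_i) are the modulus and argument of the local field
    sum_j w_ij exp(i theta_j) with weights w_ij = exp(-r_ij / lambda)
    normalized to one over j != i, K(t) ramps linearly between t_on and
    t_full and then decays with the amplitude envelope's depletion tail
    (coupling is metabolite-mediated, so it dies with glycolytic activity),
    alpha is the Sakaguchi frustration and xi is white phase noise.
    Integration is fixed-step Euler-Maruyama with step sample_interval/4,
    subsampled back onto the sample grid.

    Returns ``theta`` with shape (n_cells, n_samples); with
    ``return_omega=True`` also the per-cell natural frequencies (rad/s).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    t_grid = config.times
    dt = config.sample_interval_s / 4.0
    n_sub = 4
    n_steps = (len(t_grid) - 1) * n_sub

    omega = rng.normal(
        2.0 * np.pi * config.natural_freq_mean_mHz * 1e-3,
        2.0 * np.pi * config.natural_freq_sd_mHz * 1e-3,
        size=n,
    )

    xy = positions[["x_um", "y_um"]].to_numpy()
    r = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    w = np.exp(-r / config.coupling_length_um)
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)

    theta0 = rng.uniform(-np.pi, np.pi, size=n)
    theta0 = theta0 + config.wave_gradient_rad_per_um * xy[:, 0]

    t_on, t_full = config.coupling_ramp
    t_sub = np.arange(n_steps) * dt
    k_of_t = _coupling_ramp(t_sub, t_on, t_full, config.coupling_strength)
    # Intercellular coupling is carried by metabolite exchange, so it wanes
    # together with glycolytic activity once the batch substrate runs out.
    _, t_plateau, decay_tau = config.amplitude_envelope
    k_of_t = k_of_t * np.exp(-np.clip(t_sub - t_plateau, 0.0, None) / decay_tau)
    noise_scale = config.phase_noise_sd * np.sqrt(dt)

    theta = np.empty((n, len(t_grid)))
    theta[:, 0] = theta0
    state = theta0.copy()
    alpha = config.frustration_alpha
    for step in range(n_steps):
        k = k_of_t[step]
        if k > 0.0:
            field = w @ np.exp(1j * state)
            r_loc = np.abs(field)
            th_loc = np.angle(field)
            drift = omega + k * r_loc * np.sin(th_loc - state + alpha)
        else:
            drift = omega
        state = state + drift * dt
        if config.phase_noise_sd > 0.0:
            state = state + noise_scale * rng.standard_normal(n)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(
                "non-finite phase during integration; check step size and rates"
            )
        if (step + 1) % n_sub == 0:
            theta[:, (step + 1) // n_sub] = state

    if return_omega:
        return theta, omega
    return theta


def amplitude_envelope(t: np.ndarray, t_rise: float, t_plateau: float, decay_tau: float) -> np.ndarray:
    """Rise-plateau-exponential-decay oscillation amplitude, max 1."""
    env = np.ones_like(t, dtype=float)
    if t_rise > 0:
        env = np.minimum(env, np.clip(t / t_rise, 0.0, 1.0))
    decay = np.exp(-np.clip(t - t_plateau, 0.0, None) / decay_tau)
    return env * decay


def render_traces(
    config: SimulationConfig,
    positions: pd.DataFrame,
    theta: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Turn phase paths into fluorescence traces.

    F_i(t) = baseline_i(t) + A(t) sin(theta_i(t)) + eps_i(t), with A the
    rise-plateau-decay envelope, a per-cell baseline level (10% cell-to-cell
    scatter) plus a shared linear drift, and Gaussian detection noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.times
    n = config.n_cells
    env = amplitude_envelope(t, *config.amplitude_envelope)
    level, slope = config.baseline_drift
    cell_level = level * (1.0 + 0.1 * rng.standard_normal(n))
    baseline = cell_level[:, None] + slope * t[None, :]
    traces = baseline + env[None, :] * np.sin(theta)
    if config.measurement_noise_sd > 0.0:
        traces = traces + config.measurement_noise_sd * rng.standard_normal(traces.shape)
    if not np.all(np.isfinite(traces)):
        raise FloatingPointError("non-finite fluorescence values")
    return traces


def simulate_population(config: SimulationConfig, return_truth: bool = False):
    """Generate a full synthetic population from one seed.

    The single ``config.seed`` drives placement, natural frequencies, phase
    noise and measurement noise through one generator stream, so an
    identical config reproduces the population bit for bit.  With
    ``return_truth=True`` also returns the ground-truth phase paths and
    natural frequencies (rad/s) for oracle tests.
    """
    rng = np.random.default_rng(config.seed)
    positions = place_cells(config, rng)
    theta, omega = simulate_phases(config, positions, rng, return_omega=True)
    traces = render_traces(config, positions, theta, rng)
    pop = Population(t=config.times, traces=traces, positions=positions)
    if return_truth:
        return pop, theta, omega
    return pop
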