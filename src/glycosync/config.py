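"""Configuration objects for the synthetic population generator.

The generator produces per-cell NADH-like fluorescence traces from a
Sakaguchi-Kuramoto phase model with distance-weighted coupling.  The default
configuration emulates a population of ~230 immobilized yeast cells in a
169-um circular field of view sampled every 2 s: natural oscillation
frequencies around 20 mHz (50-s periods), a coupling ramp that takes the
population from asynchrony into partial synchronisation, and an imposed
amplitude envelope that rises during induction and decays as the batch
nutrient is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

from .geometry import Circle, Geometry, Square, geometry_from_dict, geometry_to_dict


@dataclass(frozen=True)
class Placement:
    """Spatial placement of cells in the field of view.

    ``mode="uniform"`` draws independent uniform positions.  ``mode="clustered"``
    draws ``n_parents`` uniform parent points and scatters cells around a
    randomly chosen parent with isotropic Gaussian spread ``spread_um``,
    rejection-resampling offsets that fall outside the field.
    """

    mode: Literal["uniform", "clustered"] = "uniform"
    n_parents: int = 10
    spread_um: float = 5.0

    def to_dict(self) -> dict:
        if self.mode == "uniform":
            return {"mode": "uniform"}
        return {"mode": "clustered", "n_parents": self.n_parents, "spread_um": self.spread_um}

    @classmethod
    def from_dict(cls, d: dict) -> "Placement":
        return cls(**d)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic oscillating cell population.

    Attributes
    ----------
    n_cells : int
        Number of cells in the field of view (232 for the sparse preset,
        251 for the dense one).
    geometry : Circle | Square
        Field-of-view geometry; all cells are placed strictly inside it.
    placement : Placement
        Uniform or clustered spatial placement.
    sample_interval_s : float
        Sampling (time-binning) interval of the fluorescence record, seconds.
    duration_s : float
        Record length, seconds; t = 0 is oscillation onset.
    natural_freq_mean_mHz, natural_freq_sd_mHz : float
        Mean and spread of the per-cell natural oscillation frequencies.
        Glycolytic oscillation periods of 33-60 s correspond to 17-30 mHz.
    coupling_strength : float
        Kuramoto coupling rate K at full strength, 1/s.
    frustration_alpha : float
        Sakaguchi phase-lag (frustration) in radians.  A positive value makes
        the locked population run faster than the mean natural frequency,
        reproducing entrainment by phase advancement.
    coupling_length_um : float
        Decay length lambda of the exp(-r/lambda) coupling weights, standing
        in for diffusive exchange of the coupling metabolite.
    coupling_ramp : (t_on_s, t_full_s)
        K ramps linearly from 0 at t_on to its full value at t_full.
    phase_noise_sd : float
        White phase-noise intensity, rad / sqrt(s).
    amplitude_envelope : (t_rise_s, t_plateau_s, decay_tau_s)
        Oscillation amplitude rises linearly to 1 over t_rise, stays at 1
        until t_plateau, then decays exponentially with time constant
        decay_tau (batch glucose depletion; oscillation death at trace level).
    baseline_drift : (level, slope_per_s)
        Per-cell fluorescence baseline: a level (with 10% cell-to-cell
        variation) plus a linear drift.
    measurement_noise_sd : float
        Additive Gaussian detection noise on the fluorescence samples.
    wave_gradient_rad_per_um : float
        Optional travelling-wave mode: a fixed phase gradient added along the
        x-axis to the initial phases.
    seed : int
        Seed for all randomness; identical config => bit-identical output.
    """

    n_cells: int = 232
    geometry: Geometry = field(default_factory=lambda: Circle(169.0))
    placement: Placement = field(default_factory=Placement)
    sample_interval_s: float = 2.0
    duration_s: float = 1500.0
    natural_freq_mean_mHz: float = 20.0
    natural_freq_sd_mHz: float = 1.1
    coupling_strength: float = 0.04
    frustration_alpha: float = 0.5
    coupling_length_um: float = 200.0
    coupling_ramp: tuple[float, float] = (300.0, 500.0)
    phase_noise_sd: float = 0.125
    amplitude_envelope: tuple[float, float, float] = (100.0, 1100.0, 200.0)
    baseline_drift: tuple[float, float] = (100.0, -0.01)
    measurement_noise_sd: float = 0.05
    wave_gradient_rad_per_um: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")
        if self.natural_freq_sd_mHz < 0:
            raise ValueError("natural_freq_sd_mHz must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        t_on, t_full = self.coupling_ramp
        if t_full < t_on:
            raise ValueError("coupling_ramp must satisfy t_full >= t_on")
        if self.coupling_length_um <= 0:
            raise ValueError("coupling_length_um must be > 0")

    @property
    def times(self):
        import numpy as np

        n = int(round(self.duration_s / self.sample_interval_s)) + 1
        return np.arange(n) * self.sample_interval_s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = geometry_to_dict(self.geometry)
        d["placement"] = self.placement.to_dict()
        d["coupling_ramp"] = list(self.coupling_ramp)
        d["amplitude_envelope"] = list(self.amplitude_envelope)
        d["baseline_drift"] = list(self.baseline_drift)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = geometry_from_dict(d["geometry"])
        if "placement" in d:
            d["placement"] = Placement.from_dict(d["placement"])
        for key in ("coupling_ramp", "amplitude_envelope", "baseline_drift"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def sparse_preset(seed: int = 0) -> SimulationConfig:
    """232 cells in a 169-um circular field (sparse-population conditions)."""
    return SimulationConfig(n_cells=232, geometry=Circle(169.0), seed=seed)


def dense_preset(seed: int = 0) -> SimulationConfig:
    """251 cells in an 85 x 85 um^2 square field (denser-population conditions)."""
    return SimulationConfig(n_cells=251, geometry=Square(85.0), seed=seed)
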