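"""Model/results interface to the synchronisation analysis.

:class:`PopulationSynchrony` wraps a population of per-cell fluorescence
traces (experimental files or synthetic) together with the analysis
parameters; :meth:`PopulationSynchrony.fit` runs preprocessing, phase
reconstruction, synchrony metrics, spatial cluster analysis and the chimera
test, returning a :class:`SynchronyResults` carrying every intermediate
product, a text ``summary()`` and writers for the tabular outputs.

    >>> from glycosync import PopulationSynchrony, SimulationConfig
    >>> model = PopulationSynchrony.from_simulation(SimulationConfig(seed=1))
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as gio
from .chimera import DEFAULT_BAND_RAD, DEFAULT_SPREAD_FRACTION, ChimeraResult, chimera_test
from .config import SimulationConfig
from .geometry import Circle, Geometry, Square
from .phase import (
    DEFAULT_FREQ_BIN_MHZ,
    DEFAULT_FREQ_SMOOTH_S,
    DEFAULT_MIN_EPISODE_S,
    DEFAULT_PHASE_BIN_RAD,
    DEFAULT_R_BAND,
    PhaseSeries,
    SyncSummary,
    analyze_sync,
    wrap_phase,
)
from .preprocessing import (
    DEFAULT_BAND_MHZ,
    DEFAULT_BASELINE_WINDOW_S,
    FilteredPopulation,
    preprocess,
)
from .simulate import Population, simulate_population
from .spatial import (
    DEFAULT_R_MAX_UM,
    DEFAULT_RC_ABSOLUTE,
    DEFAULT_RC_MARGIN,
    ClusterSet,
    Tessellation,
    analyze_clusters,
    tessellate,
)


def period_from_frequency_mHz(f_mHz: float) -> float:
    """Oscillation period T = 1/f in seconds for a frequency in mHz."""
    if f_mHz <= 0:
        raise ValueError("frequency must be positive")
    return 1000.0 / f_mHz


@dataclass(frozen=True)
class AnalysisParams:
    """All tunable analysis parameters, at their standard values.

    baseline_window_s=200 (3-5 oscillation periods), band 14-40 mHz,
    40-s phase smoothing, 0.5-mHz frequency bins, 0.05*pi phase bins,
    partial-synchrony band 0.40 < R < 0.85, 6-um neighbour threshold,
    ~1 cluster per 10 preselected cells, cluster-synchrony margin +0.1
    (or absolute 0.75), chimera selection half-width pi/12.
    """

    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S
    band_mHz: tuple[float, float] = DEFAULT_BAND_MHZ
    freq_smooth_s: float = DEFAULT_FREQ_SMOOTH_S
    r_band: tuple[float, float] = DEFAULT_R_BAND
    min_episode_s: float = DEFAULT_MIN_EPISODE_S
    freq_bin_mHz: float = DEFAULT_FREQ_BIN_MHZ
    phase_bin_rad: float = DEFAULT_PHASE_BIN_RAD
    cluster_modes: tuple[str, ...] = ("by_density", "by_distance")
    r_max_um: float = DEFAULT_R_MAX_UM
    n_clusters: int | None = None
    rc_rule: str = "relative"
    rc_margin: float = DEFAULT_RC_MARGIN
    rc_absolute: float = DEFAULT_RC_ABSOLUTE
    chimera_band_rad: float = DEFAULT_BAND_RAD
    chimera_fraction: float = DEFAULT_SPREAD_FRACTION
    chimera_t_ref_s: float | None = None  # None => time of maximum R in the episode


class PopulationSynchrony:
    """Synchronisation model of an oscillating cell population.

    Parameters
    ----------
    population : Population
        Per-cell fluorescence traces plus positions on one time grid.
    geometry : Circle | Square, optional
        Field-of-view geometry for the spatial analysis.  If omitted, a
        bounding square around the positions is used and a note is kept in
        the results.
    params : AnalysisParams
        Analysis parameters (defaults reproduce the standard processing).
    """

    def __init__(
        self,
        population: Population,
        geometry: Geometry | None = None,
        params: AnalysisParams = AnalysisParams(),
    ):
        self.population = population
        if geometry is None:
            xy = population.positions[["x_um", "y_um"]].to_numpy()
            half = float(np.abs(xy).max()) * 1.05
            geometry = Square(2 * half)
        self.geometry = geometry
        self.params = params
        self.config: SimulationConfig | None = None

    @classmethod
    def from_files(
        cls,
        traces_path: str,
        positions_path: str,
        geometry: Geometry | None = None,
        params: AnalysisParams = AnalysisParams(),
    ) -> "PopulationSynchrony":
        pop = gio.read_population(traces_path, positions_path)
        return cls(pop, geometry=geometry, params=params)

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig, params: AnalysisParams = AnalysisParams()
    ) -> "PopulationSynchrony":
        pop = simulate_population(config)
        model = cls(pop, geometry=config.geometry, params=params)
        model.config = config
        return model

    def fit(self) -> "SynchronyResults":
        """Run the full analysis chain and return the results object."""
        p = self.params
        filtered = preprocess(self.population, p.baseline_window_s, p.band_mHz)
        phases, sync = analyze_sync(
            filtered,
            freq_smooth_s=p.freq_smooth_s,
            r_band=p.r_band,
            min_episode_s=p.min_episode_s,
            freq_bin_mHz=p.freq_bin_mHz,
            phase_bin_rad=p.phase_bin_rad,
        )
        tess = tessellate(self.population.positions, self.geometry)
        clusters = {
            mode: analyze_clusters(
                tess,
                self.population.positions,
                phases.phi_wrapped,
                filtered.t,
                sync.R,
                mode=mode,
                r_max_um=p.r_max_um,
                n_clusters=p.n_clusters,
                rule=p.rc_rule,
                margin=p.rc_margin,
                absolute_threshold=p.rc_absolute,
            )
            for mode in p.cluster_modes
        }
        chimera = self._run_chimera(sync)
        return SynchronyResults(
            model=self,
            filtered=filtered,
            phases=phases,
            sync=sync,
            tessellation=tess,
            clusters=clusters,
            chimera=chimera,
        )

    def _run_chimera(self, sync: SyncSummary) -> ChimeraResult | None:
        p = self.params
        episodes = sync.episodes
        partial = episodes[episodes["label"] == "partial_sync"]
        if partial.empty:
            return None
        row = partial.iloc[0]
        in_ep = (sync.t >= row["t_start"]) & (sync.t <= row["t_end"])
        if p.chimera_t_ref_s is not None:
            t_ref = p.chimera_t_ref_s
        else:
            t_ref = float(sync.t[in_ep][np.argmax(sync.R[in_ep])])
        try:
            return chimera_test(
                sync.delta_phi,
                sync.t,
                self.population.cell_ids,
                t_ref,
                float(row["t_end"]),
                band=p.chimera_band_rad,
                fraction=p.chimera_fraction,
            )
        except ValueError:
            return None


@dataclass
class SynchronyResults:
    """Everything the analysis produced, with summary and export helpers."""

    model: PopulationSynchrony
    filtered: FilteredPopulation
    phases: PhaseSeries
    sync: SyncSummary
    tessellation: Tessellation
    clusters: dict[str, ClusterSet]
    chimera: ChimeraResult | None

    # -- convenience accessors -------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.sync.t

    @property
    def R(self) -> np.ndarray:
        return self.sync.R

    @property
    def episodes(self) -> pd.DataFrame:
        return self.sync.episodes

    def partial_sync_episodes(self) -> pd.DataFrame:
        ep = self.sync.episodes
        return ep[ep["label"] == "partial_sync"].reset_index(drop=True)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable run report."""
        pop = self.model.population
        lines = []
        w = lines.append
        w("Population synchrony analysis")
        w("=" * 64)
        w(f"cells: {pop.n_cells}   samples: {len(self.t)}   "
          f"dt: {pop.sample_interval_s:g} s   span: {self.t[0]:g}-{self.t[-1]:g} s")
        w(f"geometry: {self.model.geometry}")
        w("")
        w("Epochs (period T = 1000 / mean frequency):")
        w(f"{'label':<14}{'t_start':>9}{'t_end':>9}{'mean R':>9}"
          f"{'f (mHz)':>10}{'T (s)':>8}{'skew':>8}")
        for _, row in self.sync.episodes.iterrows():
            w(
                f"{row['label']:<14}{row['t_start']:>9.0f}{row['t_end']:>9.0f}"
                f"{row['mean_R']:>9.2f}{row['mean_f_mHz']:>10.1f}"
                f"{row['period_s']:>8.1f}{row['freq_skewness']:>8.2f}"
            )
        w("")
        for mode, cs in self.clusters.items():
            n_ep = len(cs.sync_episodes)
            w(f"clusters ({mode}): {len(cs.labels)} with >= 2 members, "
              f"{n_ep} enhanced-synchrony episode(s)")
            if n_ep:
                pers = cs.sync_episodes["persistence_s"]
                w(f"  persistence: median {pers.median():.0f} s, max {pers.max():.0f} s")
        w("")
        if self.chimera is None:
            w("chimera test: not run (no partial-synchronisation episode)")
        else:
            c = self.chimera
            rb = (
                f"{c.rebroadening_time_s:.0f} s"
                if c.rebroadening_time_s is not None
                else "never"
            )
            w(
                f"chimera test: t_ref = {c.t_ref_s:.0f} s, "
                f"{len(c.selected_ids)}/{pop.n_cells} cells selected, "
                f"rebroadening after {rb} -> {c.verdict}"
            )
        return "\n".join(lines)

    def report_dict(self) -> dict:
        """Machine-readable summary (key-value) of the run."""
        out = {
            "n_cells": int(self.model.population.n_cells),
            "n_samples": int(len(self.t)),
            "sample_interval_s": float(self.model.population.sample_interval_s),
            "params": asdict(self.model.params),
            "episodes": self.sync.episodes.to_dict("records"),
            "clusters": {
                mode: {
                    "n_clusters": int(len(cs.labels)),
                    "sync_episodes": cs.sync_episodes.to_dict("records"),
                }
                for mode, cs in self.clusters.items()
            },
        }
        if self.model.config is not None:
            out["simulation"] = self.model.config.to_dict()
        if self.chimera is not None:
            out["chimera"] = {
                "t_ref_s": self.chimera.t_ref_s,
                "n_selected": int(len(self.chimera.selected_ids)),
                "rebroadening_time_s": self.chimera.rebroadening_time_s,
                "verdict": self.chimera.verdict,
            }
        return out

    # -- tabular export ---------------------------------------------------
    def save(self, out_dir: str) -> None:
        """Write all tabular outputs plus the run report under ``out_dir``."""
        os.makedirs(out_dir, exist_ok=True)
        pop = self.model.population
        ids = pop.cell_ids
        n, t_len = self.filtered.x.shape
        rep_ids = np.repeat(ids, t_len)
        tiled_t = np.tile(self.t, n)

        pd.DataFrame(
            {
                "cell_id": rep_ids,
                "t_s": tiled_t,
                "x": self.filtered.x.ravel(),
                "a_norm": self.filtered.a_norm.ravel(),
            }
        ).to_csv(os.path.join(out_dir, "filtered.tsv"), sep="\t", index=False)
        pd.DataFrame({"t_s": self.t, "X": self.filtered.collective}).to_csv(
            os.path.join(out_dir, "collective.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {
                "cell_id": rep_ids,
                "t_s": tiled_t,
                "phi_wrapped": self.phases.phi_wrapped.ravel(),
                "phi_unwrapped": self.phases.phi_unwrapped.ravel(),
                "f_inst_mHz": self.phases.f_inst_mHz.ravel(),
                "delta_phi": self.sync.delta_phi.ravel(),
                "R_rel": self.sync.R_rel.ravel(),
            }
        ).to_csv(os.path.join(out_dir, "phases.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {
                "t_s": self.t,
                "R": self.sync.R,
                "Phi": self.sync.Phi_wrapped,
                "mean_f_mHz": self.sync.mean_f_mHz,
            }
        ).to_csv(os.path.join(out_dir, "global.tsv"), sep="\t", index=False)
        self.sync.episodes.to_csv(
            os.path.join(out_dir, "episodes.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {
                "cell_id": ids,
                "S_um2": self.tessellation.S_um2,
                "sigma": self.tessellation.sigma,
            }
        ).to_csv(os.path.join(out_dir, "tessellation.tsv"), sep="\t", index=False)
        cluster_rows = []
        for mode, cs in self.clusters.items():
            for cid, lab in cs.assignments.items():
                cluster_rows.append({"cell_id": cid, "mode": mode, "cluster_label": lab})
        pd.DataFrame(cluster_rows).to_csv(
            os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False
        )
        sync_frames = []
        for mode, cs in self.clusters.items():
            df = cs.sync_episodes.copy()
            df.insert(0, "mode", mode)
            sync_frames.append(df)
        pd.concat(sync_frames, ignore_index=True).to_csv(
            os.path.join(out_dir, "cluster_sync.tsv"), sep="\t", index=False
        )
        if self.chimera is not None:
            c = self.chimera
            pd.DataFrame(
                {
                    "t_s": c.t,
                    "n_selected": len(c.selected_ids),
                    "circ_sd_selected": c.spread_selected,
                    "circ_sd_all": c.spread_all,
                }
            ).to_csv(os.path.join(out_dir, "chimera.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "report.txt"), "w") as fh:
            fh.write(self.summary() + "\n")
        import yaml

        with open(os.path.join(out_dir, "report.yaml"), "w") as fh:
            yaml.safe_dump(self.report_dict(), fh, sort_keys=False)

    # -- plotting ---------------------------------------------------------
    def plot_order_parameter(self, ax=None):
        """R(t) with the partial-synchrony band shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        ax.plot(self.t, self.R, lw=1, color="k")
        lo, hi = self.model.params.r_band
        ax.axhspan(lo, hi, color="tab:orange", alpha=0.15, label="partial synchrony")
        ax.set(xlabel="time (s)", ylabel="order parameter R", ylim=(0, 1))
        ax.legend(frameon=False)
        return ax

    def plot_phase_map(self, t_s: float, quantity: str = "phi", mask=None, ax=None, n_pixels: int = 512):
        """Spatial map of a per-cell quantity at one instant."""
        import matplotlib.pyplot as plt

        from .spatial import phase_map

        k = int(np.argmin(np.abs(self.t - t_s)))
        values = {
            "phi": self.phases.phi_wrapped[:, k],
            "delta_phi": wrap_phase(self.sync.delta_phi[:, k]),
            "R_i": self.sync.R_rel[:, k],
            "f": self.phases.f_inst_mHz[:, k],
            "a_norm": self.filtered.a_norm[:, k],
        }
        if quantity not in values:
            raise ValueError(f"unknown quantity {quantity!r}; one of {sorted(values)}")
        grid, extent = phase_map(
            values[quantity],
            self.model.population.positions,
            self.tessellation,
            self.model.geometry,
            mask=mask,
            n_pixels=n_pixels,
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        cmap = "twilight" if quantity in ("phi", "delta_phi") else "viridis"
        im = ax.imshow(grid, origin="lower", extent=extent, cmap=cmap)
        ax.set(xlabel="x (um)", ylabel="y (um)", title=f"{quantity} at t = {self.t[k]:.0f} s")
        plt.colorbar(im, ax=ax, shrink=0.8)
        return ax
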