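"""Phase reconstruction and global synchronisation metrics.

Per-cell phases come from the analytic signal (Hilbert transform) of the
filtered fluorescence; instantaneous frequencies from the smoothed,
unwrapped phase.  Population synchrony is quantified by the Kuramoto order
parameter

    R(t) = | (1/N) sum_i exp(i phi_i(t)) |,   Phi(t) = arg(...)

together with per-cell relative phases Delta phi_i = phi_i - Phi and the
relative order parameter R_i = |(exp(i phi_i) + exp(i Phi)) / 2|, which has
the closed form |cos(Delta phi_i / 2)|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.stats import skew

from .preprocessing import FilteredPopulation, walking_average

DEFAULT_FREQ_SMOOTH_S = 40.0
DEFAULT_R_BAND = (0.40, 0.85)
DEFAULT_MIN_EPISODE_S = 100.0
DEFAULT_FREQ_BIN_MHZ = 0.5
DEFAULT_PHASE_BIN_RAD = 0.05 * np.pi


@dataclass
class PhaseSeries:
    """Per-cell phases and instantaneous frequencies on the shared grid."""

    t: np.ndarray
    phi_wrapped: np.ndarray  # (N, T), in (-pi, pi]
    phi_unwrapped: np.ndarray  # (N, T), radians
    f_inst_mHz: np.ndarray  # (N, T)
    amplitude: np.ndarray  # |analytic signal|
    hilbert_pair: np.ndarray  # imaginary part of the analytic signal
    undefined_mask: np.ndarray  # cells with all-zero input (phase undefined)


def hilbert_phase(x: np.ndarray, t: np.ndarray) -> PhaseSeries:
    """Analytic-signal phase of each (zero-mean, bandlimited) trace.

    The analytic signal x + i*H[x] is computed in the frequency domain; the
    phase is the four-quadrant arctangent of (H[x], x), unwrapped by adding
    multiples of 2*pi wherever consecutive samples jump by more than pi.
    All-zero traces have no defined phase and are flagged.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    undefined = np.all(x == 0.0, axis=-1)
    analytic = hilbert(x, axis=-1)
    phi_wrapped = np.angle(analytic)
    phi_unwrapped = np.unwrap(phi_wrapped, axis=-1)
    f_inst = instantaneous_frequency(phi_unwrapped, t)
    return PhaseSeries(
        t=np.asarray(t, dtype=float),
        phi_wrapped=phi_wrapped,
        phi_unwrapped=phi_unwrapped,
        f_inst_mHz=f_inst,
        amplitude=np.abs(analytic),
        hilbert_pair=analytic.imag,
        undefined_mask=undefined,
    )


def instantaneous_frequency(
    phi_unwrapped: np.ndarray, t: np.ndarray, smooth_window_s: float = DEFAULT_FREQ_SMOOTH_S
) -> np.ndarray:
    """Instantaneous frequency in mHz from the unwrapped phase.

    The unwrapped phase is boxcar-smoothed over a centred window (default
    40 s) and differentiated by central finite differences (one-sided at the
    record edges); rad/s converts to mHz via 1000 / (2 pi).
    """
    phi = np.atleast_2d(np.asarray(phi_unwrapped, dtype=float))
    t = np.asarray(t, dtype=float)
    dt = float(t[1] - t[0])
    window_samples = int(round(smooth_window_s / dt)) | 1
    if window_samples < 3:
        raise ValueError("smoothing window must span at least 3 samples")
    smoothed = walking_average(phi, window_samples)
    dphi_dt = np.gradient(smoothed, dt, axis=-1)
    out = dphi_dt * 1000.0 / (2.0 * np.pi)
    return out if phi_unwrapped.ndim > 1 else out[0]


def order_parameter(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kuramoto order parameter R and macroscopic phase Phi.

    ``phi`` is (N,) for a snapshot or (N, T) for a time course; the mean
    unit phasor is taken over the cell axis.
    """
    phi = np.asarray(phi, dtype=float)
    z = np.exp(1j * phi).mean(axis=0)
    return np.abs(z), np.angle(z)


def unwrap_macroscopic_phase(Phi_wrapped: np.ndarray) -> np.ndarray:
    """Unwrap Phi with the same jump rule as cell phases, anchored so the
    first sample stays in (-pi, pi]."""
    return np.unwrap(np.asarray(Phi_wrapped, dtype=float))


def relative_phase(phi_unwrapped: np.ndarray, Phi_unwrapped: np.ndarray) -> np.ndarray:
    """Per-cell instantaneous phase shift Delta phi_i = phi_i - Phi (unwrapped)."""
    return np.atleast_2d(phi_unwrapped) - np.asarray(Phi_unwrapped)[None, :]


def relative_order_parameter(delta_phi: np.ndarray) -> np.ndarray:
    """Per-cell coherence with the population phase.

    |(exp(i phi_i) + exp(i Phi)) / 2| reduces to |cos(Delta phi_i / 2)|.
    """
    return np.abs(np.cos(np.asarray(delta_phi) / 2.0))


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Map any phase onto (-pi, pi]."""
    wrapped = np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def bin_frequencies(f_mHz: np.ndarray, bin_width_mHz: float = DEFAULT_FREQ_BIN_MHZ):
    """Histogram instantaneous frequencies into fixed bins anchored at 0 mHz.

    Bins are left-closed/right-open ([k*w, (k+1)*w)); edges extend to cover
    the data so counts always sum to the number of values.  For a (N, T)
    input one histogram per time sample is returned (bins x T).
    """
    f = np.atleast_2d(np.asarray(f_mHz, dtype=float))
    lo = np.floor(f.min() / bin_width_mHz) * bin_width_mHz
    hi = np.ceil((f.max() + 1e-12) / bin_width_mHz) * bin_width_mHz
    if hi <= lo:
        hi = lo + bin_width_mHz
    edges = np.arange(lo, hi + bin_width_mHz / 2, bin_width_mHz)
    idx = np.clip(np.floor((f - lo) / bin_width_mHz).astype(int), 0, len(edges) - 2)
    counts = np.zeros((len(edges) - 1, f.shape[1]), dtype=int)
    for k in range(f.shape[1]):
        counts[:, k] = np.bincount(idx[:, k], minlength=len(edges) - 1)
    return edges, counts


def bin_phases(phi: np.ndarray, bin_width_rad: float = DEFAULT_PHASE_BIN_RAD):
    """Histogram (wrapped) phases into fixed bins anchored at -pi.

    Values are wrapped onto (-pi, pi] first; bins are left-closed/right-open
    with +pi folded into the last bin, so counts sum to the number of cells.
    """
    phi = np.atleast_2d(wrap_phase(phi))
    n_bins = int(round(2.0 * np.pi / bin_width_rad))
    edges = -np.pi + bin_width_rad * np.arange(n_bins + 1)
    idx = np.clip(np.floor((phi + np.pi) / bin_width_rad).astype(int), 0, n_bins - 1)
    counts = np.zeros((n_bins, phi.shape[1]), dtype=int)
    for k in range(phi.shape[1]):
        counts[:, k] = np.bincount(idx[:, k], minlength=n_bins)
    return edges, counts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    out = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


@dataclass
class SyncSummary:
    """Population-level synchrony time series and distributions."""

    t: np.ndarray
    R: np.ndarray
    Phi_wrapped: np.ndarray
    Phi_unwrapped: np.ndarray
    delta_phi: np.ndarray  # (N, T), unwrapped phi_i - unwrapped Phi
    R_rel: np.ndarray  # (N, T), |cos(delta_phi/2)|
    freq_hist: tuple  # (edges_mHz, counts bins x T)
    phase_hist: tuple  # (edges_rad, counts) for phi_i
    dphi_hist: tuple  # (edges_rad, counts) for wrapped delta_phi
    episodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    mean_f_mHz: np.ndarray | None = None  # across-cell mean frequency per sample
    amp_env: np.ndarray | None = None  # population-mean oscillation amplitude


EPISODE_COLUMNS = [
    "label",
    "t_start",
    "t_end",
    "mean_R",
    "mean_f_mHz",
    "period_s",
    "freq_skewness",
]


def detect_episodes(
    t: np.ndarray,
    R: np.ndarray,
    f_inst_mHz: np.ndarray,
    amp_env: np.ndarray | None = None,
    r_band: tuple[float, float] = DEFAULT_R_BAND,
    min_duration_s: float = DEFAULT_MIN_EPISODE_S,
    induction_fraction: float = 0.5,
    decay_fraction: float = 0.25,
    edge_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Segment the record into induction / asynchronous / partial_sync / decayed.

    partial_sync: maximal intervals with r_band[0] < R < r_band[1] (strict)
    lasting at least ``min_duration_s`` — the duration guard discards short
    coincidental alignments.  induction: the initial interval where the
    population-mean oscillation amplitude is still below
    ``induction_fraction`` of its maximum (this boundary rule is a pipeline
    convention, not a measured property).  asynchronous: from induction end
    to the first partial_sync episode.  decayed: from where the amplitude
    has fallen below ``decay_fraction`` of its maximum for good.

    Each row reports the episode's mean R, pooled mean instantaneous
    frequency, the corresponding period T = 1000 / f (seconds), and the
    adjusted Fisher-Pearson skewness of the pooled frequencies.

    ``edge_mask`` marks samples corrupted by baseline/Hilbert edge
    transients (typically half a baseline window at either end); those
    samples are excluded from threshold crossings.
    """
    t = np.asarray(t, dtype=float)
    R = np.asarray(R, dtype=float)
    f = np.atleast_2d(np.asarray(f_inst_mHz, dtype=float))
    dt = float(t[1] - t[0])
    n = len(t)
    interior = np.ones(n, dtype=bool) if edge_mask is None else ~np.asarray(edge_mask)

    rows = []

    def add(label, i0, i1):
        # i1 exclusive
        if i1 <= i0:
            return
        sel = f[:, i0:i1].ravel()
        mean_f = float(np.mean(sel))
        rows.append(
            {
                "label": label,
                "t_start": t[i0],
                "t_end": t[i1 - 1],
                "mean_R": float(np.mean(R[i0:i1])),
                "mean_f_mHz": mean_f,
                "period_s": 1000.0 / mean_f if mean_f > 0 else np.nan,
                "freq_skewness": float(skew(sel, bias=False)),
            }
        )

    i_ind_end = 0
    i_decay = n
    if amp_env is not None and interior.any():
        amp_env = np.asarray(amp_env, dtype=float)
        peak = amp_env[interior].max()
        if peak > 0:
            above = (amp_env >= induction_fraction * peak) & interior
            i_ind_end = int(np.argmax(above)) if above.any() else n
            # decayed = trailing sub-threshold amplitude, judged on interior
            # samples only (edge transients inflate the envelope)
            last_interior = int(np.flatnonzero(interior)[-1])
            low = amp_env < decay_fraction * peak
            if low[last_interior]:
                i_peak = int(np.argmax(np.where(interior, amp_env, -np.inf)))
                idx = np.flatnonzero(~low[i_peak : last_interior + 1])
                i_decay = i_peak + (int(idx[-1]) + 1 if len(idx) else 0)

    in_band = (R > r_band[0]) & (R < r_band[1]) & interior
    min_samples = int(np.ceil(min_duration_s / dt))
    partial = [
        (max(i0, i_ind_end), min(i1, i_decay))
        for (i0, i1) in _runs(in_band)
        if (i1 - i0) >= min_samples
    ]
    partial = [(i0, i1) for (i0, i1) in partial if (i1 - i0) >= min_samples]

    if i_ind_end > 0:
        add("induction", 0, i_ind_end)
    first_partial = partial[0][0] if partial else i_decay
    add("asynchronous", i_ind_end, first_partial)
    for i0, i1 in partial:
        add("partial_sync", i0, i1)
    if i_decay < n:
        last_partial = partial[-1][1] if partial else i_decay
        add("decayed", max(i_decay, last_partial), n)

    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def analyze_sync(
    filtered: FilteredPopulation,
    freq_smooth_s: float = DEFAULT_FREQ_SMOOTH_S,
    r_band: tuple[float, float] = DEFAULT_R_BAND,
    min_episode_s: float = DEFAULT_MIN_EPISODE_S,
    freq_bin_mHz: float = DEFAULT_FREQ_BIN_MHZ,
    phase_bin_rad: float = DEFAULT_PHASE_BIN_RAD,
) -> tuple[PhaseSeries, SyncSummary]:
    """Full synchrony analysis of a preprocessed population."""
    phases = hilbert_phase(filtered.x, filtered.t)
    if freq_smooth_s != DEFAULT_FREQ_SMOOTH_S:
        phases.f_inst_mHz = instantaneous_frequency(
            phases.phi_unwrapped, filtered.t, freq_smooth_s
        )
    R, Phi_w = order_parameter(phases.phi_wrapped)
    Phi_u = unwrap_macroscopic_phase(Phi_w)
    dphi = relative_phase(phases.phi_unwrapped, Phi_u)
    # remove the arbitrary common 2*pi offset between each cell's unwrapping
    # origin and Phi's, so Delta phi starts in (-pi, pi]
    offset = 2.0 * np.pi * np.round((dphi[:, :1] - wrap_phase(dphi[:, :1])) / (2.0 * np.pi))
    dphi = dphi - offset
    r_rel = relative_order_parameter(dphi)

    amp_env = walking_average(
        phases.amplitude.mean(axis=0),
        int(round(freq_smooth_s / (filtered.t[1] - filtered.t[0]))) | 1,
    )
    episodes = detect_episodes(
        filtered.t,
        R,
        phases.f_inst_mHz,
        amp_env=amp_env,
        r_band=r_band,
        min_duration_s=min_episode_s,
        edge_mask=filtered.edge_mask,
    )
    summary = SyncSummary(
        t=filtered.t,
        R=R,
        Phi_wrapped=Phi_w,
        Phi_unwrapped=Phi_u,
        delta_phi=dphi,
        R_rel=r_rel,
        freq_hist=bin_frequencies(phases.f_inst_mHz, freq_bin_mHz),
        phase_hist=bin_phases(phases.phi_wrapped, phase_bin_rad),
        dphi_hist=bin_phases(dphi, phase_bin_rad),
        episodes=episodes,
        mean_f_mHz=phases.f_inst_mHz.mean(axis=0),
        amp_env=amp_env,
    )
    return phases, summary
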