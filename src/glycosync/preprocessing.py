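"""Baseline subtraction, bandpass filtering and amplitude normalization.

Raw single-cell fluorescence records carry slow drifts (photobleaching,
baseline shifts) on top of the 14-40 mHz glycolytic oscillation band.  The
pipeline removes a 200-s walking-average baseline, applies an ideal Fourier
bandpass, and rescales each cell by its own maximum oscillation amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .simulate import Population

DEFAULT_BASELINE_WINDOW_S = 200.0
DEFAULT_BAND_MHZ = (14.0, 40.0)


def walking_average(y: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average along the last axis.

    The window is symmetric and shrinks (is truncated) at the record edges,
    so the average is always taken over the samples actually available.
    """
    if window_samples < 1:
        raise ValueError("window must span at least one sample")
    y = np.asarray(y, dtype=float)
    num = uniform_filter1d(y, size=window_samples, axis=-1, mode="constant", cval=0.0)
    ones = np.ones(y.shape[-1])
    den = uniform_filter1d(ones, size=window_samples, mode="constant", cval=0.0)
    return num / den


def subtract_baseline(traces: np.ndarray, t: np.ndarray, window_s: float = DEFAULT_BASELINE_WINDOW_S) -> np.ndarray:
    """Remove the walking-average baseline (default 200-s window).

    200 s spans roughly 3-5 oscillation periods, so the moving average tracks
    the slow drift while leaving the oscillation band essentially untouched;
    the output oscillates around zero.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    dt = float(t[1] - t[0])
    window_samples = int(round(window_s / dt)) | 1  # odd => symmetric window
    if traces.shape[-1] < window_samples:
        raise ValueError(
            f"trace of {traces.shape[-1]} samples shorter than the "
            f"{window_samples}-sample baseline window"
        )
    return traces - walking_average(traces, window_samples)


def bandpass_filter(
    x: np.ndarray,
    t: np.ndarray,
    f_lo_mHz: float = DEFAULT_BAND_MHZ[0],
    f_hi_mHz: float = DEFAULT_BAND_MHZ[1],
) -> np.ndarray:
    """Ideal (brick-wall) Fourier bandpass.

    The discrete spectrum is computed, bins with |f| outside
    [f_lo, f_hi] are zeroed (band edges inclusive), and the signal is
    transformed back.  Conjugate symmetry is preserved automatically by
    operating on the real FFT.
    """
    if f_lo_mHz >= f_hi_mHz:
        raise ValueError("f_lo must be < f_hi")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dt = float(t[1] - t[0])
    nyquist_mHz = 500.0 / dt
    if f_hi_mHz >= nyquist_mHz:
        raise ValueError(f"upper band edge {f_hi_mHz} mHz at or above Nyquist {nyquist_mHz} mHz")
    n = x.shape[-1]
    freqs_mHz = np.fft.rfftfreq(n, d=dt) * 1000.0
    spectrum = np.fft.rfft(x, axis=-1)
    eps = 1e-9  # keep bins that sit exactly on a band edge
    mask = (freqs_mHz >= f_lo_mHz - eps) & (freqs_mHz <= f_hi_mHz + eps)
    spectrum[..., ~mask] = 0.0
    return np.fft.irfft(spectrum, n=n, axis=-1)


def normalize_amplitude(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell normalization by the maximum oscillation amplitude.

    Returns (a_norm, zero_mask): a_norm[i] = x[i] / max|x[i]| in [-1, 1];
    identically-zero traces are left at zero and flagged in zero_mask so
    downstream amplitude statistics can exclude them.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    peak = np.max(np.abs(x), axis=-1)
    zero_mask = peak == 0.0
    safe = np.where(zero_mask, 1.0, peak)
    return x / safe[:, None], zero_mask


def collective_signal(x: np.ndarray) -> np.ndarray:
    """Population-mean signal X(t): arithmetic mean over cells at each sample."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("no traces to average")
    return x.mean(axis=0)


@dataclass
class FilteredPopulation:
    """Preprocessed population: detrended, bandpassed, normalized traces."""

    t: np.ndarray
    x: np.ndarray  # (N, T) bandpassed signal x_i(t)
    x_detrended: np.ndarray  # baseline-subtracted, pre-filter
    a_norm: np.ndarray  # normalized amplitudes in [-1, 1]
    zero_mask: np.ndarray  # cells with identically-zero filtered signal
    collective: np.ndarray  # X(t)
    edge_window_s: float = field(default=DEFAULT_BASELINE_WINDOW_S / 2)

    @property
    def edge_mask(self) -> np.ndarray:
        """True on samples within half a baseline window of either edge
        (baseline and filter transients make these samples less reliable)."""
        return (self.t < self.t[0] + self.edge_window_s) | (
            self.t > self.t[-1] - self.edge_window_s
        )


def preprocess(
    pop: Population,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    band_mHz: tuple[float, float] = DEFAULT_BAND_MHZ,
) -> FilteredPopulation:
    """Run the full preprocessing chain on a population."""
    detrended = subtract_baseline(pop.traces, pop.t, baseline_window_s)
    x = bandpass_filter(detrended, pop.t, *band_mHz)
    a_norm, zero_mask = normalize_amplitude(x)
    return FilteredPopulation(
        t=pop.t,
        x=x,
        x_detrended=detrended,
        a_norm=a_norm,
        zero_mask=zero_mask,
        collective=collective_signal(x),
        edge_window_s=baseline_window_s / 2,
    )
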