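"""Chimera-state test.

A chimera is the coexistence of a persistently synchronized subpopulation
with a desynchronized one.  The test mirrors the tail-cut procedure: at a
reference time inside the partially synchronized episode, keep only the
cells whose relative phase lies within +/- pi/12 of the population phase
(the centre of the relative-phase distribution), then watch whether this
initially tight subpopulation stays tight (chimera candidate) or rebroadens
to the full population's spread within the episode (no chimera).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import circstd

from .phase import bin_phases, wrap_phase

DEFAULT_BAND_RAD = np.pi / 12.0
DEFAULT_SPREAD_FRACTION = 0.8

VERDICT_ABSENT = "chimera_absent"
VERDICT_CANDIDATE = "chimera_candidate"
VERDICT_INDETERMINATE = "indeterminate"


@dataclass
class ChimeraResult:
    t_ref_s: float
    band_rad: float
    selected_ids: np.ndarray
    t: np.ndarray  # times from t_ref onwards
    spread_selected: np.ndarray  # circular SD of selected cells' delta phi
    spread_all: np.ndarray  # circular SD of the full population
    rebroadening_time_s: float | None
    verdict: str


def select_synchronized(
    delta_phi_at_tref: np.ndarray, cell_ids: np.ndarray, band: float = DEFAULT_BAND_RAD
) -> np.ndarray:
    """Cells whose wrapped relative phase lies in the closed band [-band, band]."""
    dphi = wrap_phase(np.asarray(delta_phi_at_tref, dtype=float))
    # closed interval; the tiny slack keeps values exactly on the boundary
    # selected despite wrap-around rounding
    keep = np.abs(dphi) <= band + 1e-12
    if not keep.any():
        raise ValueError(
            "no cells inside the selection band at the reference time; "
            "choose a t_ref with higher synchrony"
        )
    return np.asarray(cell_ids)[keep]


def track_rebroadening(
    delta_phi: np.ndarray,
    t: np.ndarray,
    cell_ids: np.ndarray,
    selected_ids: np.ndarray,
    t_ref_s: float,
    episode_end_s: float,
    band: float = DEFAULT_BAND_RAD,
    fraction: float = DEFAULT_SPREAD_FRACTION,
) -> ChimeraResult:
    """Follow the selected subpopulation's phase spread after t_ref.

    The spread is the circular standard deviation of the wrapped relative
    phases.  The subpopulation has rebroadened once its spread first reaches
    ``fraction`` of the full population's spread at the same instant.  If
    that happens before the partially synchronized episode ends, the
    synchronized core did not persist and the verdict is chimera_absent;
    if the spread stays below the threshold through the episode the verdict
    is chimera_candidate.  A record that ends before either resolution is
    indeterminate.
    """
    t = np.asarray(t, dtype=float)
    k_ref = int(np.argmin(np.abs(t - t_ref_s)))
    sel = np.isin(np.asarray(cell_ids), np.asarray(selected_ids))
    if sel.sum() == 0:
        raise ValueError("selection is empty")
    dphi = wrap_phase(np.atleast_2d(np.asarray(delta_phi, dtype=float)))

    tt = t[k_ref:]
    spread_sel = circstd(dphi[sel, k_ref:], axis=0)
    spread_all = circstd(dphi[:, k_ref:], axis=0)

    crossed = spread_sel >= fraction * spread_all
    crossed[0] = False  # the selection is tight by construction at t_ref
    rebroadening_time = None
    if crossed.any():
        k = int(np.argmax(crossed))
        rebroadening_time = float(tt[k] - t_ref_s)

    if rebroadening_time is not None and (t_ref_s + rebroadening_time) <= episode_end_s:
        verdict = VERDICT_ABSENT
    elif rebroadening_time is None and t[-1] < episode_end_s:
        verdict = VERDICT_INDETERMINATE
    else:
        verdict = VERDICT_CANDIDATE

    return ChimeraResult(
        t_ref_s=float(t[k_ref]),
        band_rad=band,
        selected_ids=np.asarray(selected_ids),
        t=tt,
        spread_selected=spread_sel,
        spread_all=spread_all,
        rebroadening_time_s=rebroadening_time,
        verdict=verdict,
    )


def chimera_test(
    delta_phi: np.ndarray,
    t: np.ndarray,
    cell_ids: np.ndarray,
    t_ref_s: float,
    episode_end_s: float,
    band: float = DEFAULT_BAND_RAD,
    fraction: float = DEFAULT_SPREAD_FRACTION,
) -> ChimeraResult:
    """Select the synchronized core at t_ref and track its rebroadening."""
    t = np.asarray(t, dtype=float)
    k_ref = int(np.argmin(np.abs(t - t_ref_s)))
    dphi = np.atleast_2d(np.asarray(delta_phi, dtype=float))
    selected = select_synchronized(dphi[:, k_ref], cell_ids, band)
    return track_rebroadening(
        dphi, t, cell_ids, selected, t[k_ref], episode_end_s, band, fraction
    )


def phase_histogram_series(
    delta_phi: np.ndarray,
    t: np.ndarray,
    times_s,
    selected_mask: np.ndarray | None = None,
    bin_width_rad: float = 0.05 * np.pi,
):
    """Relative-phase histograms at requested times (full and selected sets).

    Off-grid times snap to the nearest sample (with a warning).  Returns a
    list of dicts with keys t_s, edges, counts_all and (if a selection is
    given) counts_selected.
    """
    import warnings

    t = np.asarray(t, dtype=float)
    dphi = np.atleast_2d(np.asarray(delta_phi, dtype=float))
    out = []
    for treq in np.atleast_1d(times_s):
        k = int(np.argmin(np.abs(t - treq)))
        if abs(t[k] - treq) > 1e-9:
            warnings.warn(f"requested time {treq} s snapped to sample at {t[k]} s")
        edges, counts = bin_phases(dphi[:, k : k + 1], bin_width_rad)
        entry = {"t_s": float(t[k]), "edges": edges, "counts_all": counts[:, 0]}
        if selected_mask is not None:
            _, c_sel = bin_phases(dphi[selected_mask, k : k + 1], bin_width_rad)
            entry["counts_selected"] = c_sel[:, 0]
        out.append(entry)
    return out
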