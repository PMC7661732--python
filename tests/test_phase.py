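import numpy as np
import pytest

from glycosync.phase import (
    bin_frequencies,
    bin_phases,
    detect_episodes,
    hilbert_phase,
    instantaneous_frequency,
    order_parameter,
    relative_order_parameter,
    wrap_phase,
)


def test_hilbert_phase_of_sinusoid_recovers_frequency():
    t = np.arange(0, 1500, 2.0)
    f = hilbert_phase(np.sin(2 * np.pi * 0.020 * t), t).f_inst_mHz[0]
    n = len(f)
    interior = f[int(0.1 * n) : int(0.9 * n)]
    assert len(interior) == 600
    assert np.all(np.abs(interior - 20.0) < 0.2)


def test_instantaneous_frequency_requires_enough_samples():
    t = np.arange(0, 6, 2.0)
    with pytest.raises(ValueError, match="at least 3 samples"):
        instantaneous_frequency(np.zeros(3), t, smooth_window_s=2.0)


def test_order_parameter_identities():
    R, _ = order_parameter(np.zeros(100))
    assert R == pytest.approx(1.0)
    R, _ = order_parameter(np.array([0.0, np.pi]))
    assert R == pytest.approx(0.0, abs=1e-15)
    R, _ = order_parameter(np.array([0.0, np.pi / 2]))
    assert R == pytest.approx(np.sqrt(2) / 2)


def test_order_parameter_time_axis():
    phi = np.array([[0.0, 0.0], [np.pi, 0.0]])
    R, Phi = order_parameter(phi)
    assert R == pytest.approx([0.0, 1.0], abs=1e-15)
    assert Phi[1] == pytest.approx(0.0)


def test_relative_order_parameter_closed_form():
    dphi = np.linspace(-3 * np.pi, 3 * np.pi, 10_001)
    expected = np.abs((np.exp(1j * dphi) + 1.0) / 2.0)
    assert np.allclose(relative_order_parameter(dphi), expected, rtol=1e-12, atol=1e-12)


def test_wrap_phase_range_and_boundary():
    assert wrap_phase(np.pi) == pytest.approx(np.pi)
    assert wrap_phase(-np.pi) == pytest.approx(np.pi)
    x = np.linspace(-20, 20, 1001)
    w = wrap_phase(x)
    assert np.all((w > -np.pi) & (w <= np.pi))
    assert np.allclose(np.exp(1j * w), np.exp(1j * x))


def test_bin_frequencies_anchored_and_conserving():
    f = np.array([[14.1, 14.6, 20.0, 39.9]]).T @ np.ones((1, 3))
    edges, counts = bin_frequencies(f, 0.5)
    assert np.allclose(edges % 0.5, 0.0)
    assert counts.sum(axis=0).tolist() == [4, 4, 4]
    # 14.1 and 14.6 land in adjacent bins
    k1 = np.searchsorted(edges, 14.1, side="right") - 1
    k2 = np.searchsorted(edges, 14.6, side="right") - 1
    assert k2 == k1 + 1


def test_bin_phases_forty_bins_and_boundary_fold():
    edges, counts = bin_phases(np.array([[np.pi], [-np.pi], [0.0]]), 0.05 * np.pi)
    assert len(edges) == 41  # 2*pi / 0.05*pi = 40 bins
    assert counts.sum() == 3
    assert counts[-1, 0] == 2  # both +pi values (after wrapping) in last bin
    assert counts[20, 0] == 1  # zero in the bin starting at 0


def make_episode_inputs():
    t = np.arange(0, 1500, 2.0)
    n = len(t)
    amp = np.clip(t / 100.0, 0, 1) * np.exp(-np.clip(t - 1100.0, 0, None) / 150.0)
    R = np.full(n, 0.1)
    R[(t >= 600) & (t < 1100)] = 0.6
    f = np.full((5, n), 20.0)
    edge = (t < 100) | (t > t[-1] - 100)
    return t, R, f, amp, edge


def test_detect_episodes_sequence_and_period_identity():
    t, R, f, amp, edge = make_episode_inputs()
    ep = detect_episodes(t, R, f, amp_env=amp, edge_mask=edge)
    assert ep["label"].tolist() == [
        "induction",
        "asynchronous",
        "partial_sync",
        "decayed",
    ]
    for _, row in ep.iterrows():
        assert row["period_s"] == pytest.approx(1000.0 / row["mean_f_mHz"])
    part = ep[ep["label"] == "partial_sync"].iloc[0]
    assert part["t_start"] == pytest.approx(600.0, abs=4.0)
    assert part["mean_R"] == pytest.approx(0.6)


def test_detect_episodes_min_duration_guard():
    t, R, f, amp, edge = make_episode_inputs()
    R = np.full(len(t), 0.1)
    R[(t >= 600) & (t < 650)] = 0.6  # only 50 s in band
    ep = detect_episodes(t, R, f, amp_env=amp, edge_mask=edge)
    assert "partial_sync" not in ep["label"].tolist()


def test_detect_episodes_edge_mask_suppresses_edge_artifacts():
    t, R, f, amp, edge = make_episode_inputs()
    # fake a filter transient: R pinned high at the very edges
    R[:10] = 0.99
    R[-10:] = 0.99
    ep = detect_episodes(t, R, f, amp_env=amp, edge_mask=edge)
    part = ep[ep["label"] == "partial_sync"]
    assert len(part) == 1
    assert part.iloc[0]["t_start"] == pytest.approx(600.0, abs=4.0)
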