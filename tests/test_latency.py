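"""Latency metrics: first-spike extraction, spontaneous events, jitter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblesim.config import rng_stream
from ensemblesim.dynamics import SimulationResult, StimProtocol
from ensemblesim.latency import (RiseTimeModel, apply_indicator_jitter,
                                 classify_early_late, default_sensors,
                                 detect_spontaneous_events, evoked_latency_table,
                                 first_spike_latencies, pair_latencies,
                                 spontaneous_latency)


def _raster(neurons, times, duration=10_000.0):
    return SimulationResult(spike_neurons=np.asarray(neurons, dtype=np.int64),
                            spike_times_ms=np.asarray(times, dtype=float),
                            duration_ms=duration, seed=0,
                            protocol=StimProtocol.empty())


def test_first_spike_latency_simple():
    members = np.array([1, 2, 3])
    res = _raster([1, 2, 1], [101.0, 103.5, 104.0])
    lat = first_spike_latencies(res, members, np.array([100.0]))
    assert lat[0, 0] == pytest.approx(1.0)     # first spike only
    assert lat[0, 1] == pytest.approx(3.5)
    assert np.isnan(lat[0, 2])                 # silent in window


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10**6))
def test_first_spike_latency_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_spikes = rng.integers(0, 150)
    neurons = rng.integers(0, 20, n_spikes)
    times = rng.uniform(0, 400, n_spikes)
    members = np.arange(20)
    pulses = np.sort(rng.uniform(0, 380, 4))
    lat = first_spike_latencies(_raster(neurons, times), members, pulses)
    for k, p in enumerate(pulses):
        for m in members:
            mine = [t - p for n, t in zip(neurons, times)
                    if n == m and p < t <= p + 10.0]
            if mine:
                assert lat[k, m] == pytest.approx(min(mine))
            else:
                assert np.isnan(lat[k, m])


def test_evoked_table_excludes_stimulated_and_pools():
    members = np.array([0, 1, 2])
    lat0 = np.array([[1.0, 2.0, np.nan], [1.0, 4.0, 3.0]])  # set 0 stimulates 0
    lat1 = np.array([[5.0, 2.0, 1.0]])                      # set 1 stimulates 1
    tab = evoked_latency_table({0: lat0, 1: lat1}, members,
                               {0: np.array([0]), 1: np.array([1])})
    by_id = tab.set_index("neuron_id")
    # neuron 0: only set 1 counts -> 5.0; neuron 1: only set 0 -> mean(2, 4)
    assert by_id.loc[0, "mean_latency_ms"] == pytest.approx(5.0)
    assert by_id.loc[1, "mean_latency_ms"] == pytest.approx(3.0)
    assert by_id.loc[2, "mean_latency_ms"] == pytest.approx(2.0)
    assert by_id.loc[2, "n_events"] == 2
    pl = pair_latencies(tab, [np.array([0, 1])])
    assert pl[0] == pytest.approx(8.0)


def test_spontaneous_event_detection_planted_volleys():
    rng = np.random.default_rng(3)
    members = np.arange(20)
    neurons, times = [], []
    planted = [1000.0, 2500.0, 4000.0, 7000.0, 9500.0]
    for t0 in planted:
        neurons.extend(members[:18])                     # 90% participate
        times.extend(t0 + rng.uniform(0, 8, 18))
    # background: sparse non-synchronous spikes
    neurons.extend(rng.integers(0, 20, 60))
    times.extend(rng.uniform(0, 10_000, 60))
    events = detect_spontaneous_events(_raster(neurons, times), members)
    assert len(events) == len(planted)
    got = sorted(ev["median_ms"] for ev in events)
    for t0, tm in zip(planted, got):
        assert abs(tm - t0) < 10.0
    assert detect_spontaneous_events(_raster([], []), members) == []


def test_spontaneous_latency_order_recovery():
    members = np.arange(10)
    offsets = np.linspace(-4.0, 4.0, 10)       # fixed firing order
    neurons, times = [], []
    for t0 in (1000.0, 3000.0, 5000.0):
        neurons.extend(members)
        times.extend(t0 + offsets)
    events = detect_spontaneous_events(_raster(neurons, times), members,
                                       window_ms=10.0, fraction=0.75)
    assert len(events) == 3
    tab = spontaneous_latency(events, members)
    lat = tab["mean_latency_ms"].to_numpy()
    assert np.all(np.diff(lat) > 0)            # exact order recovered
    # median-centering: at least half the offsets on each side of zero
    assert np.sum(lat <= 0) >= 5 and np.sum(lat >= 0) >= 5
    # all-synchronous volleys give zero latencies
    neurons2, times2 = [], []
    for t0 in (1000.0, 2000.0):
        neurons2.extend(members)
        times2.extend([t0] * 10)
    ev2 = detect_spontaneous_events(_raster(neurons2, times2), members)
    tab2 = spontaneous_latency(ev2, members)
    assert np.allclose(tab2["mean_latency_ms"], 0.0)
    with pytest.raises(ValueError):
        spontaneous_latency([], members)


def test_classify_early_late():
    tab = pd.DataFrame({"neuron_id": np.arange(12),
                        "mean_latency_ms": np.arange(12)[::-1] * 0.5,
                        "n_events": 10})
    early, late = classify_early_late(tab, 6, 5)
    assert set(early) == set(range(6, 12))     # smallest latencies
    assert set(late) == set(range(5))
    tab2 = tab.copy()
    assert np.mean(tab.set_index("neuron_id").loc[early, "mean_latency_ms"]) < \
        np.mean(tab.set_index("neuron_id").loc[late, "mean_latency_ms"])
    with pytest.raises(ValueError):
        classify_early_late(tab, 8, 8)


def test_rise_time_models():
    sensors = default_sensors()
    assert sensors["GCaMP8f"].sd_ms < sensors["GCaMP7f"].sd_ms
    assert sensors["GCaMP8f"].mean_ms < sensors["GCaMP7f"].mean_ms
    rng = np.random.default_rng(0)
    s = sensors["GCaMP7f"].sample(200_000, rng)
    assert np.all(s >= 0)
    assert s.mean() == pytest.approx(40.0, rel=0.02)
    assert s.std() == pytest.approx(20.0, rel=0.03)
    emp = RiseTimeModel.from_samples("custom", [3.0, 4.0, 5.0])
    draw = emp.sample(1000, rng)
    assert set(np.unique(draw)) <= {3.0, 4.0, 5.0}
    with pytest.raises(ValueError):
        RiseTimeModel.from_samples("bad", [])


def test_rise_time_file_round_trip(tmp_path):
    path = tmp_path / "rise.txt"
    np.savetxt(path, [5.0, 6.5, 7.25])
    m = RiseTimeModel.from_file("file-sensor", path)
    assert m.mean_ms == pytest.approx(np.mean([5.0, 6.5, 7.25]))


def test_jitter_shifts_means_and_preserves_rank_at_zero_sd():
    rng = rng_stream(0, "jitter-test")
    lat = np.array([[1.0, 2.0, np.nan], [1.5, 2.5, 3.0]] * 2000)
    fixed = RiseTimeModel("delta", mean_ms=7.0, sd_ms=0.0)
    out = apply_indicator_jitter(lat, fixed, rng)
    finite = np.isfinite(lat)
    assert np.allclose(out[finite], lat[finite] + 7.0)  # rank-preserving shift
    assert np.all(np.isnan(out[~finite]))
    noisy = RiseTimeModel("noisy", mean_ms=7.0, sd_ms=3.0)
    out2 = apply_indicator_jitter(lat, noisy, rng)
    # law of large numbers: corrupted mean = clean mean + model mean
    assert out2[finite].mean() == pytest.approx(lat[finite].mean() + 7.0,
                                                abs=0.15)
    # decreasing sd converges to the clean values plus the constant: the mean
    # absolute perturbation tracks the sensor sd
    for sd in (3.0, 0.3, 0.03):
        m = RiseTimeModel("s", mean_ms=7.0, sd_ms=sd)
        o = apply_indicator_jitter(lat, m, rng)
        mad = np.mean(np.abs(o[finite] - lat[finite] - 7.0))
        assert 0.5 * sd < mad < 1.5 * sd
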