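"""Spike-latency metrics and calcium-indicator corruption.

Ensembles activate in stages rather than simultaneously; a neuron's position
in that sequence predicts its pattern-completion ability.  Two latency
definitions are implemented:

* evoked   - time from pulse onset to the neuron's first spike, within the
  10 ms recall window; spikes later than the window are discarded and
  directly stimulated neurons are excluded from their own trials;
* spontaneous - signed offset of the neuron's spike from the median spike
  time of a spontaneously detected ensemble recall event (negative = early).

Calcium imaging blurs these estimates because fluorescence rise times are
variable.  ``RiseTimeModel`` provides per-sensor rise-time distributions as
configurable positively skewed (lognormal) parametric stand-ins - the fast
sensor (GCaMP8f-like) is quicker and narrower than the slower one
(GCaMP7f-like) - or as empirical samples loaded from a plain numeric column
file.  Jitter is applied by adding one independent rise-time draw to every
per-trial latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SimulationResult


# ------------------------------------------------------------------ evoked

def first_spike_latencies(result: SimulationResult, members: np.ndarray,
                          pulse_times: np.ndarray,
                          window_ms: float = 10.0) -> np.ndarray:
    """Per-pulse, per-member first-spike latency matrix (ms; NaN = no spike).

    Entry [k, m] is the time from pulse k's onset to member m's first spike
    inside (onset, onset + window]; members silent in the window get NaN.
    """
    members = np.asarray(members)
    pos = {int(nid): i for i, nid in enumerate(members)}
    sel = np.isin(result.spike_neurons, members)
    t = result.spike_times_ms[sel]
    nid = result.spike_neurons[sel]
    order = np.argsort(t, kind="stable")
    t, nid = t[order], nid[order]
    lat = np.full((len(pulse_times), len(members)), np.nan)
    for k, p in enumerate(np.asarray(pulse_times, dtype=float)):
        lo = np.searchsorted(t, p, side="right")
        hi = np.searchsorted(t, p + window_ms, side="right")
        for j in range(lo, hi):
            m = pos[int(nid[j])]
            if np.isnan(lat[k, m]):
                lat[k, m] = t[j] - p
    return lat


def evoked_latency_table(latency_matrices: dict[int, np.ndarray],
                         members: np.ndarray,
                         stimulated_sets: dict[int, np.ndarray]) -> pd.DataFrame:
    """Mean evoked latency per neuron, pooled over sets it was not stimulated in.

    ``latency_matrices`` maps set_id to an (n_pulses x n_members) matrix from
    :func:`first_spike_latencies`; ``stimulated_sets`` maps set_id to the ids
    stimulated in that set.  Returns (neuron_id, mean_latency_ms, n_events);
    neurons with no in-window spikes anywhere get NaN latency.
    """
    members = np.asarray(members)
    sums = np.zeros(len(members))
    counts = np.zeros(len(members), dtype=np.int64)
    for set_id, lat in latency_matrices.items():
        stim = np.asarray(stimulated_sets[set_id])
        allowed = ~np.isin(members, stim)
        finite = np.isfinite(lat) & allowed[None, :]
        sums += np.where(finite, lat, 0.0).sum(axis=0)
        counts += finite.sum(axis=0)
    mean = np.divide(sums, counts, out=np.full(len(members), np.nan),
                     where=counts > 0)
    return pd.DataFrame({"neuron_id": members, "mean_latency_ms": mean,
                         "n_events": counts})


def pair_latencies(neuron_latency: pd.DataFrame,
                   neuron_sets: list[np.ndarray]) -> np.ndarray:
    """Latency of a stimulated set = sum of its members' mean latencies."""
    lut = dict(zip(neuron_latency["neuron_id"].astype(int),
                   neuron_latency["mean_latency_ms"]))
    return np.array([sum(lut[int(n)] for n in s) for s in neuron_sets])


# ------------------------------------------------------------------ spontaneous

def detect_spontaneous_events(result: SimulationResult, members: np.ndarray,
                              window_ms: float = 10.0, fraction: float = 0.75,
                              min_gap_ms: float = 100.0) -> list[dict]:
    """Spontaneous ensemble recall events in a raster.

    An event is triggered when at least ``fraction`` of the members spike
    within a sliding window of ``window_ms``; successive events must be
    separated by ``min_gap_ms``.  Each event records the member spikes of its
    window and their median time.
    """
    members = np.asarray(members)
    need = int(np.ceil(fraction * len(members)))
    sel = np.isin(result.spike_neurons, members)
    t = result.spike_times_ms[sel]
    nid = result.spike_neurons[sel]
    order = np.argsort(t, kind="stable")
    t, nid = t[order], nid[order]
    events = []
    i, n = 0, len(t)
    last_event_t = -np.inf
    while i < n:
        if t[i] - last_event_t < min_gap_ms:
            i += 1
            continue
        hi = np.searchsorted(t, t[i] + window_ms, side="right")
        uniq = np.unique(nid[i:hi])
        if len(uniq) >= need:
            first = {}
            for j in range(i, hi):
                k = int(nid[j])
                if k not in first:
                    first[k] = t[j]
            times = np.array(sorted(first.values()))
            events.append(dict(onset_ms=float(t[i]),
                               median_ms=float(np.median(times)),
                               neuron_times=first))
            last_event_t = t[i]
            i = hi
        else:
            i += 1
    return events


def spontaneous_latency(events: list[dict], members: np.ndarray) -> pd.DataFrame:
    """Mean signed offset from the event median per neuron (negative = early)."""
    if not events:
        raise ValueError("no events supplied")
    members = np.asarray(members)
    sums = np.zeros(len(members))
    counts = np.zeros(len(members), dtype=np.int64)
    for ev in events:
        for idx, nid_ in enumerate(members):
            t_spk = ev["neuron_times"].get(int(nid_))
            if t_spk is not None:
                sums[idx] += t_spk - ev["median_ms"]
                counts[idx] += 1
    mean = np.divide(sums, counts, out=np.full(len(members), np.nan),
                     where=counts > 0)
    return pd.DataFrame({"neuron_id": members, "mean_latency_ms": mean,
                         "n_events": counts})


def classify_early_late(neuron_latency: pd.DataFrame, n_early: int,
                        n_late: int) -> tuple[np.ndarray, np.ndarray]:
    """Extreme-latency neuron sets: earliest ``n_early`` and latest ``n_late``.

    Sorting is by mean latency with neuron id as the deterministic
    tie-breaker; neurons with undefined latency are excluded first.
    """
    t = neuron_latency.dropna(subset=["mean_latency_ms"])
    if n_early + n_late > len(t):
        raise ValueError("not enough neurons with defined latency")
    t = t.sort_values(["mean_latency_ms", "neuron_id"], kind="stable")
    early = t["neuron_id"].to_numpy()[:n_early].astype(int)
    late = t["neuron_id"].to_numpy()[len(t) - n_late:].astype(int)
    return early, late


# ------------------------------------------------------------------ indicators

@dataclass
class RiseTimeModel:
    """Fluorescence rise-time distribution for one calcium sensor.

    Defaults are synthetic parametric stand-ins (lognormal, configurable mean
    and sd in ms); pass empirical 0-80% rise-time samples via
    :meth:`from_samples` or :meth:`from_file` to override.
    """

    sensor: str
    mean_ms: float
    sd_ms: float
    samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.samples is None and (self.mean_ms < 0 or self.sd_ms < 0):
            raise ValueError("mean and sd must be non-negative")

    @classmethod
    def from_samples(cls, sensor: str, samples) -> "RiseTimeModel":
        s = np.asarray(samples, dtype=float)
        if len(s) == 0:
            raise ValueError("empty rise-time sample source")
        if np.any(s < 0):
            raise ValueError("rise times must be non-negative")
        return cls(sensor=sensor, mean_ms=float(s.mean()), sd_ms=float(s.std()),
                   samples=s)

    @classmethod
    def from_file(cls, sensor: str, path: str | Path) -> "RiseTimeModel":
        return cls.from_samples(sensor, np.loadtxt(path, ndmin=1))

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.samples is not None:
            return rng.choice(self.samples, size=size, replace=True)
        if self.sd_ms == 0:
            return np.full(size, self.mean_ms)
        sigma2 = np.log(1.0 + (self.sd_ms / self.mean_ms) ** 2)
        mu = np.log(self.mean_ms) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def default_sensors() -> dict[str, RiseTimeModel]:
    """Stand-in fast (8f-like) and slow (7f-like) sensor models."""
    return {"GCaMP8f": RiseTimeModel("GCaMP8f", mean_ms=10.0, sd_ms=4.0),
            "GCaMP7f": RiseTimeModel("GCaMP7f", mean_ms=40.0, sd_ms=20.0)}


def apply_indicator_jitter(latencies: np.ndarray, model: RiseTimeModel,
                           rng: np.random.Generator) -> np.ndarray:
    """Add one independent rise-time draw to every finite per-trial latency."""
    lat = np.array(latencies, dtype=float, copy=True)
    finite = np.isfinite(lat)
    jit = model.sample(int(finite.sum()), rng)
    lat[finite] = lat[finite] + jit
    return lat


# ------------------------------------------------------------------ latency vs PCC

def latency_pcc_correlation(latency_matrices: dict[int, np.ndarray],
                            members: np.ndarray,
                            stimulated_sets: dict[int, np.ndarray],
                            neuron_sets: list[np.ndarray],
                            pcc: np.ndarray) -> float:
    """Pearson r between summed pair latency and PCC over stimulated sets."""
    tab = evoked_latency_table(latency_matrices, members, stimulated_sets)
    lat = pair_latencies(tab, neuron_sets)
    keep = np.isfinite(lat) & np.isfinite(pcc)
    if keep.sum() < 3:
        raise ValueError("need at least 3 sets with defined latency and PCC")
    return float(np.corrcoef(lat[keep], np.asarray(pcc)[keep])[0, 1])


def latency_pcc_curve(latency_matrices: dict[int, np.ndarray],
                      members: np.ndarray,
                      stimulated_sets: dict[int, np.ndarray],
                      neuron_sets: list[np.ndarray],
                      pcc: np.ndarray,
                      event_counts,
                      model: RiseTimeModel | None,
                      n_resamples: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Latency-PCC correlation as a function of the number of recall events.

    For each requested total event count, that many recall events are drawn
    (with replacement) from the pooled events of all stimulated sets,
    optionally corrupted with sensor rise-time jitter, aggregated to pair
    latencies, and correlated with PCC.  As the event count grows toward the
    full experiment the estimate converges to the all-events correlation.
    Returns (n_events, mean_r, sem_r, sensor).
    """
    pool = [(set_id, row) for set_id, lat in latency_matrices.items()
            for row in range(lat.shape[0])]
    if not pool:
        raise ValueError("no recall events available")
    pool_sets = np.array([p[0] for p in pool])
    pool_rows = np.array([p[1] for p in pool])
    rows = []
    for n_ev in event_counts:
        rs = []
        for _ in range(n_resamples):
            draw = rng.integers(0, len(pool), size=int(n_ev))
            sub: dict[int, np.ndarray] = {}
            for set_id in np.unique(pool_sets[draw]):
                ridx = pool_rows[draw[pool_sets[draw] == set_id]]
                sample = latency_matrices[set_id][ridx]
                if model is not None:
                    sample = apply_indicator_jitter(sample, model, rng)
                sub[int(set_id)] = sample
            try:
                rs.append(latency_pcc_correlation(sub, members, stimulated_sets,
                                                  neuron_sets, pcc))
            except ValueError:
                continue
        if rs:
            rows.append(dict(n_events=int(n_ev), mean_r=float(np.mean(rs)),
                             sem_r=float(np.std(rs) / np.sqrt(len(rs))),
                             sensor=model.sensor if model else "none"))
    return pd.DataFrame(rows)
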