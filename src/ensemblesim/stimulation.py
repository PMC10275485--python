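"""Optogenetic stimulation experiments on trained ensembles.

An ensemble is "trained" by scaling the synaptic weights between its members
(simulating the increased coupling/excitability of an imprinted ensemble)
until a probe experiment reaches the target ~5% recall rate, and by lowering
the excitatory background current to 75 pA to preserve baseline statistics.
Stimulation then delivers trains of eight 0.6 ms pulses at 20 or 30 Hz to
small sets of ensemble neurons.  Every pulse is one trial: the trial records
the mean ensemble membrane voltage over the 10 ms before the pulse (V_e) and
whether the pulse recalled the ensemble (>= 75% of members spiking within
10 ms of pulse onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import CELL_TYPES, rng_stream
from .dynamics import SimulationResult, StimProtocol, integrate, population_rates
from .ensembles import Ensemble
from .network import Connectome, circular_dpo


class TrainingError(RuntimeError):
    """Raised when weight titration cannot reach the target recall rate."""


# ------------------------------------------------------------------ recall

def recall_counts(result: SimulationResult, members: np.ndarray,
                  pulse_times: np.ndarray, window_ms: float = 10.0) -> np.ndarray:
    """Distinct ensemble members spiking in (pulse, pulse + window] per pulse."""
    members = np.asarray(members)
    member_set = np.zeros(int(result.spike_neurons.max() + 1) if len(result.spike_neurons) else 1,
                          dtype=bool)
    member_set[members[members < len(member_set)]] = True
    sel = member_set[result.spike_neurons] if len(result.spike_neurons) else np.zeros(0, bool)
    t = result.spike_times_ms[sel]
    nid = result.spike_neurons[sel]
    order = np.argsort(t, kind="stable")
    t, nid = t[order], nid[order]
    counts = np.zeros(len(pulse_times), dtype=np.int64)
    for k, p in enumerate(np.asarray(pulse_times, dtype=float)):
        lo = np.searchsorted(t, p, side="right")
        hi = np.searchsorted(t, p + window_ms, side="right")
        counts[k] = len(np.unique(nid[lo:hi]))
    return counts


def detect_recall(result: SimulationResult, members: np.ndarray, pulse_time: float,
                  window_ms: float = 10.0, fraction: float = 0.75) -> bool:
    """True iff >= ceil(fraction * ensemble size) members spike in the window."""
    need = int(np.ceil(fraction * len(members)))
    count = recall_counts(result, members, np.array([pulse_time]), window_ms)[0]
    return bool(count >= need)


# ------------------------------------------------------------------ training

@dataclass
class TrainedEnsembleContext:
    """A connectome view with trained (scaled) intra-ensemble weights.

    Only EXC->EXC synapses between ensemble members are scaled; every other
    weight is bit-identical to the base connectome.  The excitatory background
    current is overridden (75 pA by default) for all simulations in this
    context.
    """

    connectome: Connectome
    ensemble: Ensemble
    weight_scale: float
    probe_recall_rate: float = float("nan")
    background_pa: np.ndarray = field(default=None, repr=False)

    @classmethod
    def build(cls, connectome: Connectome, ensemble: Ensemble, weight_scale: float,
              probe_recall_rate: float = float("nan")) -> "TrainedEnsembleContext":
        if weight_scale < 1.0:
            raise ValueError("weight_scale must be >= 1")
        if ensemble.size == 0:
            raise ValueError("ensemble is empty")
        w = connectome.weights.tocoo(copy=True)
        in_ens = np.zeros(connectome.n_neurons, dtype=bool)
        in_ens[ensemble.members] = True
        sel = in_ens[w.row] & in_ens[w.col]
        data = w.data.copy()
        data[sel] *= weight_scale
        scaled = sp.csr_matrix((data, (w.row, w.col)), shape=w.shape)
        trained = connectome.copy_with_weights(scaled)
        cfg = connectome.config
        b_pa = np.empty(connectome.n_neurons)
        for code, name in enumerate(CELL_TYPES):
            mask = connectome.type_of == code
            if not mask.any():
                continue
            ct = cfg.network.cell_type(name)
            b_pa[mask] = (cfg.analysis.trained_background_pa if name == "EXC"
                          else ct.background_pa)
        return cls(connectome=trained, ensemble=ensemble, weight_scale=weight_scale,
                   probe_recall_rate=probe_recall_rate, background_pa=b_pa)


def _train_starts(n_trains: int, frequency_hz: float, n_pulses: int,
                  gap_ms: float, burn_in_ms: float) -> np.ndarray:
    period = 1000.0 / frequency_hz
    train_len = period * (n_pulses - 1) + period  # last pulse + one period margin
    return burn_in_ms + np.arange(n_trains) * (train_len + gap_ms)


def run_stimulation_experiment(context: TrainedEnsembleContext,
                               neuron_sets: list[np.ndarray],
                               n_pulses_per_set: int,
                               frequency_hz: float | None = None,
                               seed: int = 0,
                               burn_in_ms: float = 500.0,
                               inter_train_gap_ms: float | None = None,
                               return_latencies: bool = False,
                               stream: str = "stimulation") -> pd.DataFrame:
    """Stimulate each neuron set with trains of pulses; one row per pulse.

    Pulses are organized in trains of ``train_n_pulses`` (8); the simulation
    runs continuously across the trains of one set (no state reset), so the
    pre-pulse ensemble voltage V_e varies trial to trial.  Columns:
    set_id, train_idx, pulse_idx, t_ms, v_e_mv, recall, frequency_hz.
    """
    cfg = context.connectome.config
    proto = cfg.protocol
    ana = cfg.analysis
    freq = frequency_hz if frequency_hz is not None else proto.train_frequency_hz
    gap = inter_train_gap_ms if inter_train_gap_ms is not None else proto.inter_train_gap_ms
    per_train = proto.train_n_pulses
    if n_pulses_per_set % per_train:
        raise ValueError(f"n_pulses_per_set must be a multiple of {per_train}")
    n_trains = n_pulses_per_set // per_train
    members = context.ensemble.members
    need = int(np.ceil(ana.recall_fraction * len(members)))
    period = 1000.0 / freq

    frames = []
    latency_matrices: dict[int, np.ndarray] = {}
    for set_id, targets in enumerate(neuron_sets):
        targets = np.asarray(targets)
        if not np.isin(targets, members).all():
            raise ValueError("stimulated sets must be ensemble members")
        starts = _train_starts(n_trains, freq, per_train, gap, burn_in_ms)
        trains = [StimProtocol.pulse_train(targets, t0, per_train, freq,
                                           proto.pulse_width_ms) for t0 in starts]
        protocol = StimProtocol.concatenate(trains)
        pulses = protocol.pulse_onsets_ms
        windows = np.column_stack([pulses - ana.recall_window_ms, pulses])
        duration = starts[-1] + period * per_train + gap
        res = integrate(context.connectome, duration, seed=seed, protocol=protocol,
                        windows_ms=windows, window_ids=members,
                        background_pa=context.background_pa,
                        stream=f"{stream}/{set_id}")
        counts = recall_counts(res, members, pulses, ana.recall_window_ms)
        v_e = res.window_means.mean(axis=1)
        if return_latencies:
            from .latency import first_spike_latencies

            latency_matrices[set_id] = first_spike_latencies(
                res, members, pulses, ana.recall_window_ms)
        frames.append(pd.DataFrame({
            "set_id": set_id,
            "train_idx": np.repeat(np.arange(n_trains), per_train),
            "pulse_idx": np.tile(np.arange(per_train), n_trains),
            "t_ms": pulses,
            "v_e_mv": v_e,
            "recall": counts >= need,
            "frequency_hz": freq,
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["neuron_sets"] = [np.asarray(s) for s in neuron_sets]
    out.attrs["members"] = members
    if return_latencies:
        out.attrs["latencies"] = latency_matrices
    return out


def train_ensemble(connectome: Connectome, ensemble: Ensemble,
                   target_rate: float | None = None, seed: int = 0,
                   n_probe_pairs: int = 5, n_probe_pulses: int = 80,
                   fold_max: float = 20.0, tolerance: float = 0.005,
                   max_iter: int = 8,
                   probe_pairs: list | None = None) -> TrainedEnsembleContext:
    """Titrate the intra-ensemble weight fold-increase to the target recall.

    Bisection on the fold factor: at each candidate fold a probe experiment
    (random pairs, a reduced pulse budget) measures the mean recall rate.
    Returns the context at the first fold within ``tolerance`` of the target
    (or the best bracket midpoint after ``max_iter`` splits).  Because recall
    varies strongly from pair to pair, pass ``probe_pairs`` (e.g. a subset of
    the pairs the subsequent experiment will stimulate) to titrate against
    the same pair population that will be measured.
    """
    cfg = connectome.config
    target = target_rate if target_rate is not None else cfg.analysis.pcc_target_rate
    rng = rng_stream(seed, "training")
    if probe_pairs is not None:
        pairs = [np.asarray(p) for p in probe_pairs]
    else:
        pairs = [rng.choice(ensemble.members, size=2, replace=False)
                 for _ in range(n_probe_pairs)]

    def probe(fold: float) -> float:
        ctx = TrainedEnsembleContext.build(connectome, ensemble, fold)
        trials = run_stimulation_experiment(ctx, pairs, n_probe_pulses, seed=seed,
                                            stream=f"training-probe/{fold:.4f}")
        return float(trials["recall"].mean())

    lo, hi = 1.0, float(fold_max)
    r_lo = probe(lo)
    if r_lo >= target:
        return TrainedEnsembleContext.build(connectome, ensemble, lo, r_lo)
    r_hi = probe(hi)
    if r_hi < target:
        raise TrainingError(
            f"target recall {target:.3f} unreachable: rate {r_lo:.3f} at fold {lo}, "
            f"{r_hi:.3f} at fold {hi}")
    best = (abs(r_hi - target), hi, r_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = probe(mid)
        if abs(r_mid - target) < best[0]:
            best = (abs(r_mid - target), mid, r_mid)
        if abs(r_mid - target) <= tolerance:
            break
        if r_mid < target:
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    _, fold, rate = best
    return TrainedEnsembleContext.build(connectome, ensemble, fold, rate)


# ------------------------------------------------------------------ multi-neuron

def multi_neuron_recall_curve(context: TrainedEnsembleContext,
                              pools: dict[str, np.ndarray],
                              set_sizes=(2, 3, 4, 5),
                              n_sets: int = 10,
                              n_trials: int = 200,
                              frequencies=(20.0, 30.0),
                              seed: int = 0) -> pd.DataFrame:
    """Recall rate versus number of stimulated neurons, per pool and frequency.

    ``pools`` maps a label (e.g. "early", "random") to candidate neuron ids;
    each of the ``n_sets`` stimulated sets is drawn without replacement from
    its pool.  Returns one row per (pool, frequency, set size, set).
    """
    rng = rng_stream(seed, "multi-neuron")
    rows = []
    for label, pool in pools.items():
        pool = np.asarray(pool)
        for size in set_sizes:
            if size > len(pool):
                raise ValueError(f"pool {label!r} smaller than set size {size}")
            sets = [rng.choice(pool, size=size, replace=False) for _ in range(n_sets)]
            for freq in frequencies:
                trials = run_stimulation_experiment(
                    context, sets, n_trials, frequency_hz=freq, seed=seed,
                    stream=f"multi/{label}/{size}/{freq:g}")
                for sid, grp in trials.groupby("set_id"):
                    rows.append(dict(pool=label, set_size=size, frequency_hz=freq,
                                     set_idx=int(sid),
                                     recall_rate=float(grp["recall"].mean())))
    return pd.DataFrame(rows)


def odd_even_recall(trials: pd.DataFrame) -> pd.DataFrame:
    """Recall rate of odd- vs even-indexed pulses within trains, per frequency.

    Odd pulses (1st, 3rd, ... of each train; even ``pulse_idx``) include each
    train's first pulse and recover from any preceding recall for longer.
    """
    t = trials.copy()
    t["parity"] = np.where(t["pulse_idx"] % 2 == 0, "odd", "even")
    return (t.groupby(["frequency_hz", "parity"])["recall"]
            .mean().rename("recall_rate").reset_index())


# ------------------------------------------------------------------ network response

def network_response_experiment(context: TrainedEnsembleContext,
                                neuron_sets: list[np.ndarray],
                                n_periods: int = 50,
                                stim_ms: float = 400.0,
                                frequency_hz: float = 20.0,
                                seed: int = 0) -> dict:
    """Response of the rest of the network to repeated ensemble stimulation.

    Each neuron set is stimulated for ``n_periods`` periods of ``stim_ms`` at
    ``frequency_hz``; each period has a matched immediately-preceding baseline
    window.  Returns per-period recall rate, the change in the number of
    active non-ensemble excitatory neurons, per-inhibitory-type rate changes,
    and a histogram of non-ensemble spike probability vs dPO to the ensemble
    mean PO.
    """
    cfg = context.connectome.config
    ana = cfg.analysis
    members = context.ensemble.members
    need = int(np.ceil(ana.recall_fraction * len(members)))
    conn = context.connectome
    exc = conn.type_indices("EXC")
    non_ens_exc = np.setdiff1d(exc, members)
    dpo_to_ens = circular_dpo(conn.po[non_ens_exc], context.ensemble.mean_po_deg)
    n_pulses = int(round(stim_ms * frequency_hz / 1000.0))
    burn_in, gap = 500.0, 600.0
    period_rows, hist_acc = [], []
    edges = np.arange(0.0, 91.0, 10.0)
    for set_id, targets in enumerate(neuron_sets):
        starts = burn_in + np.arange(n_periods) * (2 * stim_ms + gap) + stim_ms
        trains = [StimProtocol.pulse_train(targets, t0, n_pulses, frequency_hz,
                                           cfg.protocol.pulse_width_ms)
                  for t0 in starts]
        protocol = StimProtocol.concatenate(trains)
        duration = starts[-1] + stim_ms + gap
        res = integrate(conn, duration, seed=seed, protocol=protocol,
                        background_pa=context.background_pa,
                        stream=f"network-response/{set_id}")
        counts = recall_counts(res, members, protocol.pulse_onsets_ms,
                               ana.recall_window_ms)
        recall_by_period = (counts >= need).reshape(n_periods, n_pulses).mean(axis=1)
        spk_t, spk_i = res.spike_times_ms, res.spike_neurons
        for pidx, t0 in enumerate(starts):
            base = (spk_t >= t0 - stim_ms) & (spk_t < t0)
            stim = (spk_t >= t0) & (spk_t < t0 + stim_ms)
            row = dict(set_id=set_id, period=pidx, n_stim=len(targets),
                       recall_rate=float(recall_by_period[pidx]))
            mask_ne = np.zeros(conn.n_neurons, dtype=bool)
            mask_ne[non_ens_exc] = True
            act_b = len(np.unique(spk_i[base & mask_ne[spk_i]]))
            act_s = len(np.unique(spk_i[stim & mask_ne[spk_i]]))
            row["active_exc_change"] = act_s - act_b
            for name in ("PV", "SOM", "VIP"):
                ids = conn.type_indices(name)
                m = np.zeros(conn.n_neurons, dtype=bool)
                m[ids] = True
                rb = np.sum(base & m[spk_i]) / (len(ids) * stim_ms * 1e-3)
                rs = np.sum(stim & m[spk_i]) / (len(ids) * stim_ms * 1e-3)
                row[f"{name}_rate_change"] = rs - rb
            period_rows.append(row)
            # spike probability vs dPO during this stim period
            fired = np.zeros(conn.n_neurons, dtype=bool)
            fired[np.unique(spk_i[stim])] = True
            hist_acc.append(fired[non_ens_exc])
    fired_mat = np.array(hist_acc)  # (periods*sets, n_non_ens)
    digit = np.digitize(dpo_to_ens, edges) - 1
    hist = pd.DataFrame({
        "dpo_bin_deg": edges[:-1] + 5.0,
        "spike_probability": [float(fired_mat[:, digit == b].mean()) if (digit == b).any()
                              else np.nan for b in range(len(edges) - 1)],
    })
    return dict(periods=pd.DataFrame(period_rows), dpo_histogram=hist)
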