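"""Conductance-based leaky integrate-and-fire dynamics.

Each neuron obeys

    C_m dV/dt = -g_L (V - V_L) - g_E (V - V_E) - g_I (V - V_I)
                - g_opsin (V - V_opsin) + B + g_L * eta(t)

with exponential synaptic conductances (tau_E = 5 ms, tau_I = 10 ms) that jump
by the synaptic weight W_ij when a presynaptic spike arrives after its
conduction delay, Poisson background events that jump g_E by 30 nS, a constant
background current B, and an Ornstein-Uhlenbeck voltage noise eta injected as
a leak-scaled current.  The opsin conductance is 150 nS inside stimulation
pulses targeting a neuron and zero otherwise, and depolarizes the membrane
toward V_opsin = 0 mV (the channelrhodopsin-2 reversal).  Threshold crossings
at -55 mV emit a spike, reset the membrane, and start a 2 ms refractory period
during which the voltage is clamped at the reset potential.

Integration is forward-Euler for the voltage and exact exponential decay for
the conductances and the noise process, at dt = 0.1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CELL_TYPES, ExperimentConfig, SimulationParams, rng_stream
from .network import Connectome, circular_dpo
from ._kernel import HAVE_NUMBA, run_chunk, run_chunk_numpy

_CHUNK_STEPS = 500


class IntegrationError(RuntimeError):
    """Raised when the membrane state becomes non-finite."""


# ------------------------------------------------------------------ protocol

@dataclass
class StimProtocol:
    """A schedule of optogenetic pulses.

    Each pulse has an onset time, a width, and a target set (an index into
    ``target_sets`` so that different trains can stimulate different neurons
    within one continuous simulation).  Pulses must not overlap.
    """

    pulse_onsets_ms: np.ndarray
    pulse_set: np.ndarray
    target_sets: list[np.ndarray]
    pulse_width_ms: float = 0.6

    def __post_init__(self):
        self.pulse_onsets_ms = np.asarray(self.pulse_onsets_ms, dtype=float)
        self.pulse_set = np.asarray(self.pulse_set, dtype=np.int64)
        self.target_sets = [np.asarray(s, dtype=np.int64) for s in self.target_sets]
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse width must be positive")
        if len(self.pulse_onsets_ms) != len(self.pulse_set):
            raise ValueError("pulse_onsets_ms and pulse_set must have equal length")
        if len(self.pulse_onsets_ms) > 1:
            on = self.pulse_onsets_ms
            if np.any(np.diff(on) < self.pulse_width_ms):
                raise ValueError("stimulation pulses overlap")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets_ms)

    @classmethod
    def empty(cls) -> "StimProtocol":
        return cls(np.zeros(0), np.zeros(0, dtype=int), [])

    @classmethod
    def pulse_train(cls, targets, start_ms: float, n_pulses: int, frequency_hz: float,
                    pulse_width_ms: float = 0.6) -> "StimProtocol":
        """A single train of ``n_pulses`` pulses at ``frequency_hz``."""
        period = 1000.0 / frequency_hz
        onsets = start_ms + period * np.arange(n_pulses)
        return cls(onsets, np.zeros(n_pulses, dtype=int), [np.asarray(targets)],
                   pulse_width_ms)

    @classmethod
    def concatenate(cls, protocols: list["StimProtocol"]) -> "StimProtocol":
        if not protocols:
            return cls.empty()
        width = protocols[0].pulse_width_ms
        onsets, setsidx, sets = [], [], []
        for p in protocols:
            offset = len(sets)
            onsets.append(p.pulse_onsets_ms)
            setsidx.append(p.pulse_set + offset)
            sets.extend(p.target_sets)
        return cls(np.concatenate(onsets), np.concatenate(setsidx), sets, width)


# ------------------------------------------------------------------ result

@dataclass
class SimulationResult:
    """Spike raster plus optional voltage recordings for one simulated run."""

    spike_neurons: np.ndarray
    spike_times_ms: np.ndarray
    duration_ms: float
    seed: int
    protocol: StimProtocol
    record_ids: np.ndarray | None = None
    voltages: np.ndarray | None = None      # (n_recorded, n_samples), mV
    record_dt_ms: float | None = None
    window_ids: np.ndarray | None = None
    window_means: np.ndarray | None = None  # (n_windows, len(window_ids)), mV
    windows_ms: np.ndarray | None = None
    final_state: dict = field(default_factory=dict, repr=False)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return np.sort(self.spike_times_ms[self.spike_neurons == neuron])

    def raster_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.spike_neurons, "t_ms": self.spike_times_ms})

    def save_raster_csv(self, path) -> None:
        self.raster_frame().to_csv(path, index=False)


# ------------------------------------------------------------------ integrator

def integrate(connectome: Connectome,
              duration_ms: float,
              seed: int,
              protocol: StimProtocol | None = None,
              record_ids=None,
              record_every: int = 10,
              windows_ms=None,
              window_ids=None,
              background_pa=None,
              noise: bool = True,
              poisson: bool = True,
              initial_state: dict | None = None,
              stream: str = "sim") -> SimulationResult:
    """Integrate the network for ``duration_ms`` and return spikes/voltages.

    ``windows_ms`` (an (n, 2) array of non-overlapping [start, end) intervals)
    requests per-neuron mean voltages of ``window_ids`` over each interval,
    accumulated on the fly so long experiments never store full traces.
    ``background_pa`` optionally overrides the per-neuron background current.
    ``initial_state`` (from a previous result's ``final_state``) resumes a
    simulation without resetting membrane variables.
    """
    cfg = connectome.config
    p = cfg.simulation
    n = connectome.n_neurons
    dt = p.dt_ms
    n_steps = int(round(duration_ms / dt))
    if n_steps <= 0:
        raise ValueError("duration must be positive")
    protocol = protocol or StimProtocol.empty()
    rng = rng_stream(seed, stream)

    # per-neuron constants
    v_leak = np.empty(n)
    b_pa = np.empty(n)
    poisson_p = np.empty(n)
    poisson_jump = np.empty(n)
    for code, name in enumerate(CELL_TYPES):
        ct = None
        for c in cfg.network.cell_types:
            if c.name == name:
                ct = c
        mask = connectome.type_of == code
        if ct is None:
            if np.any(mask):
                raise ValueError(f"connectome contains unconfigured type {name}")
            continue
        v_leak[mask] = ct.v_leak
        b_pa[mask] = ct.background_pa
        poisson_p[mask] = ct.poisson_rate_hz * dt * 1e-3
        poisson_jump[mask] = ct.poisson_jump_ns
    if background_pa is not None:
        b_pa = np.asarray(background_pa, dtype=float).copy()

    # synaptic propagation tables
    W = connectome.weights
    indptr, indices, wdata = W.indptr, W.indices, W.data
    delay_steps = np.maximum(1, np.round(connectome.delays.data / dt)).astype(np.int64)
    max_delay = int(delay_steps.max()) if len(delay_steps) else 1
    D = max_delay + 1
    pre_exc = connectome.is_excitatory
    buf_e = np.zeros((D, n))
    buf_i = np.zeros((D, n))

    # opsin schedule: map step -> pulse target-set id (-1 = off)
    active_set = np.full(n_steps, -1, dtype=np.int64)
    for onset, sid in zip(protocol.pulse_onsets_ms, protocol.pulse_set):
        a = int(np.floor(onset / dt))
        b = int(np.ceil((onset + protocol.pulse_width_ms) / dt))
        if a < n_steps:
            active_set[max(a, 0):min(b, n_steps)] = sid
    target_sets = protocol.target_sets

    # recording setup
    if record_ids is not None:
        record_ids = np.asarray(record_ids, dtype=np.int64)
        n_samples = (n_steps + record_every - 1) // record_every
        traces = np.empty((len(record_ids), n_samples))
    else:
        traces = None
    if windows_ms is not None:
        windows_ms = np.asarray(windows_ms, dtype=float).reshape(-1, 2)
        window_ids = np.asarray(window_ids, dtype=np.int64)
        win_of = np.full(n_steps, -1, dtype=np.int64)
        for wi, (a, b) in enumerate(windows_ms):
            ia, ib = int(np.floor(a / dt)), int(np.floor(b / dt))
            if np.any(win_of[max(ia, 0):min(ib, n_steps)] >= 0):
                raise ValueError("voltage-mean windows overlap")
            win_of[max(ia, 0):min(ib, n_steps)] = wi
        wsums = np.zeros((len(windows_ms), len(window_ids)))
        wcounts = np.zeros(len(windows_ms), dtype=np.int64)
    else:
        wsums = None

    # state
    if initial_state:
        v = initial_state["v"].copy()
        g_e = initial_state["g_e"].copy()
        g_i = initial_state["g_i"].copy()
        eta = initial_state["eta"].copy()
        refr_left = initial_state["refr_left"].copy()
    else:
        v = v_leak.copy()
        g_e = np.zeros(n)
        g_i = np.zeros(n)
        eta = np.zeros(n)
        refr_left = np.zeros(n, dtype=np.int64)

    decay_e = np.exp(-dt / p.tau_e_ms)
    decay_i = np.exp(-dt / p.tau_i_ms)
    noise_every = int(p.noise_update_steps)
    if noise_every < 1 or _CHUNK_STEPS % noise_every:
        raise ValueError("noise_update_steps must divide the kernel chunk size")
    noise_a = np.exp(-noise_every * dt / p.noise_tau_ms)
    noise_b = p.noise_sigma_mv * np.sqrt(1.0 - noise_a ** 2) if noise else 0.0
    refr_steps = int(round(p.refractory_ms / dt))
    inv_cm = dt / p.c_m_pf
    g_l = p.g_leak_ns

    # flatten ragged target sets for the kernel
    if target_sets:
        set_offsets = np.concatenate([[0], np.cumsum([len(s) for s in target_sets])]).astype(np.int64)
        set_data = np.concatenate(target_sets).astype(np.int64) if set_offsets[-1] else np.zeros(0, np.int64)
    else:
        set_offsets = np.zeros(1, dtype=np.int64)
        set_data = np.zeros(0, dtype=np.int64)
    indices64 = indices.astype(np.int64)
    kernel = run_chunk if HAVE_NUMBA else run_chunk_numpy
    rec_ids_arr = record_ids if record_ids is not None else np.zeros(0, dtype=np.int64)
    traces_arr = traces if traces is not None else np.zeros((0, 0))
    if wsums is None:
        win_of = np.full(n_steps, -1, dtype=np.int64)
        window_ids_arr = np.zeros(0, dtype=np.int64)
        wsums_arr = np.zeros((0, 0))
        wcounts = np.zeros(0, dtype=np.int64)
    else:
        window_ids_arr = window_ids
        wsums_arr = wsums

    spike_t_chunks: list[np.ndarray] = []
    spike_i_chunks: list[np.ndarray] = []
    cap = n * (_CHUNK_STEPS // max(refr_steps, 1) + 2)
    spike_step = np.empty(cap, dtype=np.int64)
    spike_id = np.empty(cap, dtype=np.int64)

    for t0 in range(0, n_steps, _CHUNK_STEPS):
        k = min(_CHUNK_STEPS, n_steps - t0)
        rows = (k + noise_every - 1) // noise_every
        if noise:
            noise_chunk = rng.standard_normal((rows, n), dtype=np.float32) * np.float32(noise_b)
        else:
            noise_chunk = np.zeros((rows, n), dtype=np.float32)
        if poisson and poisson_p.max() > 0:
            counts = rng.binomial(k, poisson_p)
            hits = np.flatnonzero(counts)
            if len(hits):
                ev_neuron = np.repeat(hits, counts[hits]).astype(np.int64)
                ev_step = rng.integers(0, k, size=len(ev_neuron)).astype(np.int64)
                order = np.argsort(ev_step, kind="stable")
                ev_step, ev_neuron = ev_step[order], ev_neuron[order]
            else:
                ev_step = np.zeros(0, dtype=np.int64)
                ev_neuron = np.zeros(0, dtype=np.int64)
        else:
            ev_step = np.zeros(0, dtype=np.int64)
            ev_neuron = np.zeros(0, dtype=np.int64)
        n_sp = kernel(
            t0, k, v, g_e, g_i, eta, refr_left,
            buf_e, buf_i,
            v_leak, b_pa, poisson_jump,
            noise_chunk, noise_a, noise_every,
            ev_step, ev_neuron,
            active_set[t0:t0 + k], set_offsets, set_data,
            indptr, indices64, wdata, delay_steps, pre_exc,
            decay_e, decay_i, g_l, inv_cm,
            p.v_exc_mv, p.v_inh_mv, p.v_threshold_mv, p.v_reset_mv, refr_steps,
            p.g_opsin_ns, p.v_opsin_mv,
            spike_step, spike_id,
            rec_ids_arr, record_every, traces_arr,
            win_of[t0:t0 + k], window_ids_arr, wsums_arr, wcounts,
        )
        if n_sp:
            spike_i_chunks.append(spike_id[:n_sp].copy())
            spike_t_chunks.append(spike_step[:n_sp] * dt)
        if not np.isfinite(v).all():
            raise IntegrationError(f"non-finite membrane state near step {t0 + k}")

    spikes_i = np.concatenate(spike_i_chunks) if spike_i_chunks else np.zeros(0, dtype=np.int64)
    spikes_t = np.concatenate(spike_t_chunks) if spike_t_chunks else np.zeros(0)
    result = SimulationResult(
        spike_neurons=spikes_i, spike_times_ms=spikes_t, duration_ms=duration_ms,
        seed=seed, protocol=protocol,
        record_ids=record_ids, voltages=traces,
        record_dt_ms=record_every * dt if traces is not None else None,
        window_ids=window_ids if wsums is not None else None,
        window_means=(wsums / np.maximum(wcounts, 1)[:, None]) if wsums is not None else None,
        windows_ms=windows_ms,
        final_state={"v": v, "g_e": g_e, "g_i": g_i, "eta": eta, "refr_left": refr_left},
    )
    return result


# ------------------------------------------------------------------ summaries

def population_rates(result: SimulationResult, type_of: np.ndarray,
                     window_ms: tuple[float, float],
                     exclude: np.ndarray | None = None) -> dict[str, float]:
    """Mean firing rate (spikes/s) per cell type inside ``window_ms``.

    ``exclude`` removes neurons (e.g. directly stimulated ones) from both the
    spike count and the population size.
    """
    a, b = window_ms
    if not (0 <= a < b <= result.duration_ms + 1e-9):
        raise ValueError("window outside simulated span")
    sel = (result.spike_times_ms >= a) & (result.spike_times_ms < b)
    neurons = result.spike_neurons[sel]
    excluded = np.zeros(len(type_of), dtype=bool)
    if exclude is not None and len(exclude):
        excluded[np.asarray(exclude)] = True
    rates = {}
    for code, name in enumerate(CELL_TYPES):
        members = (type_of == code) & ~excluded
        count = int(members.sum())
        if count == 0:
            continue
        n_spikes = int(np.sum(members[neurons]))
        rates[name] = n_spikes / (count * (b - a) * 1e-3)
    return rates


def resting_potential_report(result: SimulationResult, type_of: np.ndarray) -> dict[str, float]:
    """Mean baseline membrane potential (mV) per type over recorded neurons."""
    if result.voltages is None:
        raise ValueError("no recorded voltages in result")
    means = {}
    for code, name in enumerate(CELL_TYPES):
        rows = np.flatnonzero(type_of[result.record_ids] == code)
        if len(rows) == 0:
            continue
        vals = result.voltages[rows]
        means[name] = float(np.mean(vals))
    return means


def baseline_sigma(result: SimulationResult, neuron_rows=None) -> float:
    """Std of recorded baseline voltage fluctuations (mV), averaged per neuron."""
    if result.voltages is None:
        raise ValueError("no recorded voltages in result")
    vals = result.voltages if neuron_rows is None else result.voltages[neuron_rows]
    return float(np.mean(np.std(vals, axis=1)))


# ------------------------------------------------------------------ experiments

def _trial_protocol(target_sets, starts_ms, stim_ms, frequency_hz, width_ms):
    trains = [StimProtocol.pulse_train(s, t0, int(round(stim_ms * frequency_hz / 1000.0)),
                                       frequency_hz, width_ms)
              for s, t0 in zip(target_sets, starts_ms)]
    return StimProtocol.concatenate(trains)


def single_neuron_stim_experiment(connectome: Connectome,
                                  n_stim_values=range(6),
                                  n_trials: int = 20,
                                  seed: int = 0,
                                  stim_ms: float = 250.0,
                                  recovery_ms: float = 250.0,
                                  burn_in_ms: float = 500.0) -> pd.DataFrame:
    """Dose-response experiment: stimulate 0..5 random EXC neurons per trial.

    For each condition ``n_stim`` the network runs continuously through
    ``n_trials`` trains (250 ms at 30 Hz by default) separated by recovery
    gaps, with freshly drawn random excitatory targets every trial.  Returns a
    tidy table of per-trial mean rates per cell type; directly stimulated
    neurons are excluded from the excitatory population average.
    """
    cfg = connectome.config
    rng = rng_stream(seed, "dose-response")
    exc = connectome.type_indices("EXC")
    # all conditions interleaved in one continuous run, in shuffled order, so
    # slow network-state drift cannot masquerade as a condition effect
    conditions = np.repeat(list(n_stim_values), n_trials)
    rng.shuffle(conditions)
    starts = burn_in_ms + np.arange(len(conditions)) * (stim_ms + recovery_ms)
    sets = [rng.choice(exc, size=int(n), replace=False) for n in conditions]
    stim_trials = [(t0, s) for t0, s in zip(starts, sets) if len(s)]
    protocol = (_trial_protocol([s for _, s in stim_trials],
                                [t0 for t0, _ in stim_trials], stim_ms,
                                cfg.protocol.train_frequency_hz,
                                cfg.protocol.pulse_width_ms)
                if stim_trials else StimProtocol.empty())
    duration = starts[-1] + stim_ms + recovery_ms
    res = integrate(connectome, duration, seed=seed, protocol=protocol,
                    stream="dose-response")
    rows = []
    trial_counter: dict[int, int] = {}
    for n, t0, s in zip(conditions, starts, sets):
        rates = population_rates(res, connectome.type_of, (t0, t0 + stim_ms),
                                 exclude=s)
        trial = trial_counter.get(int(n), 0)
        trial_counter[int(n)] = trial + 1
        for name, rate in rates.items():
            rows.append(dict(n_stim=int(n), trial=trial, cell_type=name,
                             rate_hz=rate))
    return pd.DataFrame(rows)


def feature_suppression_experiment(connectome: Connectome,
                                   n_neurons: int = 35,
                                   n_trials: int = 3,
                                   seed: int = 0,
                                   stim_ms: float = 250.0,
                                   recovery_ms: float = 250.0,
                                   burn_in_ms: float = 500.0) -> pd.DataFrame:
    """Single-neuron stimulation: voltage change of other EXC neurons vs dPO.

    ``n_neurons`` random excitatory neurons are each stimulated for
    ``n_trials`` trains.  For every trial and every non-stimulated excitatory
    neuron the mean membrane voltage during stimulation minus the mean over a
    matched pre-stimulation baseline window is recorded together with the
    neuron's orientation difference to the stimulated neuron.
    """
    cfg = connectome.config
    rng = rng_stream(seed, "feature-suppression")
    exc = connectome.type_indices("EXC")
    stim_neurons = rng.choice(exc, size=n_neurons, replace=False)
    trial_len = 2 * stim_ms + recovery_ms  # baseline + stim + recovery
    sets, starts, windows = [], [], []
    for i, neuron in enumerate(np.repeat(stim_neurons, n_trials)):
        t0 = burn_in_ms + i * trial_len
        sets.append(np.array([neuron]))
        starts.append(t0 + stim_ms)            # stim begins after baseline window
        windows.append((t0, t0 + stim_ms))     # baseline
        windows.append((t0 + stim_ms, t0 + 2 * stim_ms))  # stimulation
    protocol = _trial_protocol(sets, starts, stim_ms,
                               cfg.protocol.train_frequency_hz,
                               cfg.protocol.pulse_width_ms)
    duration = burn_in_ms + len(sets) * trial_len
    res = integrate(connectome, duration, seed=seed, protocol=protocol,
                    windows_ms=np.array(windows), window_ids=exc,
                    stream="feature-suppression")
    rows = []
    exc_pos = {nid: k for k, nid in enumerate(exc)}
    for i, neuron in enumerate(np.repeat(stim_neurons, n_trials)):
        base = res.window_means[2 * i]
        stim = res.window_means[2 * i + 1]
        dv = stim - base
        dpo = circular_dpo(connectome.po[exc], connectome.po[neuron])
        keep = exc != neuron
        rows.append(pd.DataFrame({
            "stim_neuron": neuron, "trial": i % n_trials,
            "neuron_id": exc[keep], "dpo_deg": dpo[keep], "dv_mv": dv[keep],
        }))
    return pd.concat(rows, ignore_index=True)


def dose_response_slopes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-type linear regression of trial rate on number of stimulated neurons.

    Returns slope (spikes/s per stimulated neuron), intercept, and the F-test
    p-value of the slope for each cell type.
    """
    from scipy import stats

    out = []
    for name, grp in table.groupby("cell_type"):
        fit = stats.linregress(grp["n_stim"], grp["rate_hz"])
        out.append(dict(cell_type=name, slope=fit.slope, intercept=fit.intercept,
                        p_value=fit.pvalue, r=fit.rvalue))
    return pd.DataFrame(out).set_index("cell_type")


def feature_suppression_slope(table: pd.DataFrame) -> tuple[float, float]:
    """Slope (mV/degree) and p-value of the pooled dV vs dPO regression."""
    from scipy import stats

    fit = stats.linregress(table["dpo_deg"], table["dv_mv"])
    return float(fit.slope), float(fit.pvalue)
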