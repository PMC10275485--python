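"""Construction of the V1 L2/3 connectome.

The network is a directed, weighted graph over four cell classes (EXC, PV,
SOM, VIP).  Each neuron carries a preferred orientation (PO) drawn uniformly
from [0, 180) degrees.  For orientation-tuned projections both the connection
probability and the synaptic conductance scale with PO similarity through a
cosine profile of the folded orientation difference; weights are lognormal in
nS.  Excitatory synapses act after a fixed 1.5 ms conduction delay, inhibitory
synapses after a per-synapse delay drawn once from uniform[4, 6] ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
import yaml

from .config import (
    CELL_TYPES,
    ConfigError,
    ConnectivityRule,
    ExperimentConfig,
    SimulationParams,
    rng_stream,
)

_CHUNK = 256  # presynaptic rows sampled per block during construction


# ------------------------------------------------------------------ helpers

def circular_dpo(po_a, po_b):
    """Orientation difference in degrees, folded into [0, 90].

    Orientations live on a 180-degree circle, so dPO(179, 1) == 2.
    """
    d = np.abs(np.asarray(po_a, dtype=float) - np.asarray(po_b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def assign_cell_types(n_total: int, fractions: dict[str, float],
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Assign cell-type codes (index into CELL_TYPES) to ``n_total`` neurons.

    Counts follow largest-remainder rounding of ``fractions`` so they sum to
    ``n_total`` exactly.  Labels are laid out in contiguous blocks in the
    canonical type order; with POs assigned independently at random this is
    statistically equivalent to a shuffled layout and keeps indexing simple.
    """
    if n_total < 0:
        raise ConfigError("n_total must be non-negative")
    total_frac = sum(fractions.values())
    if abs(total_frac - 1.0) > 1e-6:
        raise ConfigError(f"cell-type fractions sum to {total_frac}, expected 1")
    names = [t for t in CELL_TYPES if t in fractions]
    raw = np.array([fractions[t] * n_total for t in names])
    counts = np.floor(raw).astype(int)
    remainder = n_total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    codes = np.concatenate([
        np.full(c, CELL_TYPES.index(t), dtype=np.int8) for t, c in zip(names, counts)
    ]) if n_total else np.zeros(0, dtype=np.int8)
    return codes


def assign_preferred_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform POs on [0, 180) degrees."""
    return rng.uniform(0.0, 180.0, size=n)


def _cosine_profile(dpo_deg, kappa):
    """(1 + kappa*cos(2 dPO)) / (1 + kappa): 1 at dPO=0, minimum at dPO=90."""
    return (1.0 + kappa * np.cos(2.0 * np.deg2rad(dpo_deg))) / (1.0 + kappa)


def connection_probability(rule: ConnectivityRule | None, dpo_deg,
                           probability_scale: float = 1.0):
    """Connection probability for a projection at orientation difference dPO.

    ``rule is None`` encodes a disallowed projection and yields 0 everywhere.
    """
    dpo_deg = np.asarray(dpo_deg, dtype=float)
    if rule is None:
        return np.zeros_like(dpo_deg)
    p = rule.p_base * _cosine_profile(dpo_deg, rule.kappa_p) * probability_scale
    return np.clip(p, 0.0, 1.0)


def sample_weight(rule: ConnectivityRule, dpo_deg, rng: np.random.Generator):
    """Sample synaptic weights (nS): lognormal scaled by the PO profile."""
    dpo_deg = np.asarray(dpo_deg, dtype=float)
    w = np.exp(rng.normal(rule.mu_log, rule.sigma_log, size=dpo_deg.shape))
    return w * _cosine_profile(dpo_deg, rule.kappa_w)


# ------------------------------------------------------------------ PSP

def psp_time_course(weight_ns: float, v_leak_mv: float, params: SimulationParams,
                    inhibitory: bool = False, duration_ms: float = 100.0):
    """Simulate one presynaptic spike onto a quiescent neuron at rest.

    Background current, noise, and Poisson drive are off; the membrane starts
    at its leak reversal and receives a single exponential conductance of
    initial amplitude ``weight_ns``.  Returns (times_ms, voltage_mv).
    """
    p = params
    n_steps = int(round(duration_ms / p.dt_ms))
    tau = p.tau_i_ms if inhibitory else p.tau_e_ms
    v_rev = p.v_inh_mv if inhibitory else p.v_exc_mv
    decay = np.exp(-p.dt_ms / tau)
    v = np.full(n_steps + 1, v_leak_mv)
    g = float(weight_ns)
    for k in range(n_steps):
        dv = (-p.g_leak_ns * (v[k] - v_leak_mv) - g * (v[k] - v_rev)) / p.c_m_pf
        v[k + 1] = v[k] + p.dt_ms * dv
        g *= decay
    return np.arange(n_steps + 1) * p.dt_ms, v


def weight_to_psp(weight_ns, v_leak_mv: float, params: SimulationParams | None = None,
                  inhibitory: bool = False):
    """Peak PSP amplitude (mV) evoked by a single spike of the given weight.

    Vectorized over ``weight_ns``; monotone increasing, 0 at weight 0.
    """
    p = params or SimulationParams()
    w = np.atleast_1d(np.asarray(weight_ns, dtype=float))
    if np.any(w < 0):
        raise ValueError("synaptic weights must be non-negative")
    n_steps = int(round(100.0 / p.dt_ms))
    tau = p.tau_i_ms if inhibitory else p.tau_e_ms
    v_rev = p.v_inh_mv if inhibitory else p.v_exc_mv
    decay = np.exp(-p.dt_ms / tau)
    v = np.full(w.shape, v_leak_mv)
    g = w.copy()
    peak = np.zeros(w.shape)
    for _ in range(n_steps):
        dv = (-p.g_leak_ns * (v - v_leak_mv) - g * (v - v_rev)) / p.c_m_pf
        v = v + p.dt_ms * dv
        g *= decay
        dev = np.abs(v - v_leak_mv)
        np.maximum(peak, dev, out=peak)
    return peak if np.ndim(weight_ns) else float(peak[0])


def psp_threshold_weight(epsp_mv: float, v_leak_mv: float,
                         params: SimulationParams | None = None) -> float:
    """Weight (nS) whose EPSP peak equals ``epsp_mv``, by bisection."""
    lo, hi = 0.0, 1.0
    while weight_to_psp(hi, v_leak_mv, params) < epsp_mv:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("EPSP target unreachable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if weight_to_psp(mid, v_leak_mv, params) < epsp_mv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ------------------------------------------------------------------ connectome

@dataclass
class Connectome:
    """The static network: cell types, POs, weighted synapses with delays.

    ``weights`` is CSR with ``weights[i, j]`` the conductance jump (nS) that a
    spike of neuron i causes in neuron j; ``delays`` shares its sparsity
    pattern and holds per-synapse delays in ms.
    """

    type_of: np.ndarray        # int8 codes into CELL_TYPES
    po: np.ndarray             # degrees in [0, 180)
    weights: sp.csr_matrix     # nS
    delays: sp.csr_matrix      # ms, same sparsity as weights
    seed: int
    config: ExperimentConfig

    @property
    def n_neurons(self) -> int:
        return len(self.type_of)

    def type_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.type_of == CELL_TYPES.index(name))

    @property
    def is_excitatory(self) -> np.ndarray:
        return self.type_of == CELL_TYPES.index("EXC")

    def copy_with_weights(self, weights: sp.csr_matrix) -> "Connectome":
        return Connectome(self.type_of, self.po, weights, self.delays,
                          self.seed, self.config)

    # ------------------------------------------------------------- io
    def to_hdf5(self, path: str | Path) -> None:
        w = self.weights.tocoo()
        d = self.delays.tocoo()
        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.attrs["n_neurons"] = self.n_neurons
            f.attrs["config_yaml"] = yaml.safe_dump(self.config.to_dict())
            f.create_dataset("type_of", data=self.type_of)
            f.create_dataset("po_deg", data=self.po)
            f.create_dataset("pre", data=w.row.astype(np.int32))
            f.create_dataset("post", data=w.col.astype(np.int32))
            f.create_dataset("weight_ns", data=w.data)
            f.create_dataset("delay_ms", data=d.data)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Connectome":
        with h5py.File(path, "r") as f:
            n = int(f.attrs["n_neurons"])
            cfg = ExperimentConfig.from_dict(yaml.safe_load(f.attrs["config_yaml"]))
            pre = f["pre"][:]
            post = f["post"][:]
            weights = sp.csr_matrix((f["weight_ns"][:], (pre, post)), shape=(n, n))
            delays = sp.csr_matrix((f["delay_ms"][:], (pre, post)), shape=(n, n))
            return cls(f["type_of"][:], f["po_deg"][:], weights, delays,
                       int(f.attrs["seed"]), cfg)

    def to_synapse_csv(self, path: str | Path) -> None:
        w = self.weights.tocoo()
        d = self.delays.tocoo()
        arr = np.column_stack([w.row, w.col, w.data, d.data])
        np.savetxt(path, arr, fmt=["%d", "%d", "%.6g", "%.4f"], delimiter=",",
                   header="pre,post,weight_ns,delay_ms", comments="")


def build_connectome(config: ExperimentConfig, seed: int) -> Connectome:
    """Sample a connectome from the configured wiring rules.

    Pure function of (config, seed): the same inputs always produce an
    identical network.  Self-synapses never occur; projections without a rule
    (SOM->SOM, PV->SOM, PV->VIP, ...) are absent by construction.
    """
    net = config.network
    rng = rng_stream(seed, "network")
    fractions = {ct.name: ct.count / net.n_neurons for ct in net.cell_types}
    type_of = assign_cell_types(net.n_neurons, fractions)
    po = assign_preferred_orientations(net.n_neurons, rng)

    blocks = {name: np.flatnonzero(type_of == CELL_TYPES.index(name))
              for name in CELL_TYPES}
    rows, cols, wdata, ddata = [], [], [], []
    p_sim = config.simulation
    n = net.n_neurons
    for rule in net.rules:
        pre_idx = blocks[rule.pre]
        post_idx = blocks[rule.post]
        if len(pre_idx) == 0 or len(post_idx) == 0:
            continue
        inhibitory = rule.pre != "EXC"
        if rule.endpoint_gain_sigma > 0:
            gain = np.exp(rng.normal(0.0, rule.endpoint_gain_sigma, size=net.n_neurons))
        else:
            gain = None
        rule_rows, rule_cols = [], []
        for start in range(0, len(pre_idx), _CHUNK):
            chunk = pre_idx[start:start + _CHUNK]
            dpo = circular_dpo(po[chunk][:, None], po[post_idx][None, :])
            p = connection_probability(rule, dpo, net.probability_scale)
            mask = rng.random(size=p.shape) < p
            if rule.pre == rule.post:
                self_cols = np.searchsorted(post_idx, chunk)
                mask[np.arange(len(chunk)), self_cols] = False
            r, c = np.nonzero(mask)
            if len(r) == 0:
                continue
            w = sample_weight(rule, dpo[r, c], rng)
            if gain is not None:
                w = w * gain[chunk[r]] * gain[post_idx[c]]
            if rule.w_max_ns > 0:
                np.minimum(w, rule.w_max_ns, out=w)
            if inhibitory:
                d = rng.uniform(p_sim.inh_delay_min_ms, p_sim.inh_delay_max_ms, size=len(r))
            else:
                d = np.full(len(r), p_sim.exc_delay_ms)
            rows.append(chunk[r])
            cols.append(post_idx[c])
            wdata.append(w)
            ddata.append(d)
            rule_rows.append(chunk[r])
            rule_cols.append(post_idx[c])
        # reciprocal over-representation: each sampled synapse recruits the
        # reverse synapse with probability reciprocity * PO profile
        if rule.reciprocity > 0 and rule.pre == rule.post and rule_rows:
            rr = np.concatenate(rule_rows)
            cc = np.concatenate(rule_cols)
            dpo_e = circular_dpo(po[rr], po[cc])
            prof = _cosine_profile(dpo_e, rule.kappa_p)
            cand = rng.random(len(rr)) < rule.reciprocity * prof
            rev_r, rev_c = cc[cand], rr[cand]
            existing = set(zip(rr.tolist(), cc.tolist()))
            keep_mask = np.array([(int(a), int(b)) not in existing
                                  for a, b in zip(rev_r, rev_c)], dtype=bool)
            # deduplicate repeated reverse candidates
            seen = set()
            for idx in np.flatnonzero(keep_mask):
                key = (int(rev_r[idx]), int(rev_c[idx]))
                if key in seen:
                    keep_mask[idx] = False
                else:
                    seen.add(key)
            rev_r, rev_c = rev_r[keep_mask], rev_c[keep_mask]
            if len(rev_r):
                w_rev = sample_weight(rule, circular_dpo(po[rev_r], po[rev_c]), rng)
                if gain is not None:
                    w_rev = w_rev * gain[rev_r] * gain[rev_c]
                if rule.w_max_ns > 0:
                    np.minimum(w_rev, rule.w_max_ns, out=w_rev)
                d_rev = (rng.uniform(p_sim.inh_delay_min_ms, p_sim.inh_delay_max_ms,
                                     size=len(rev_r))
                         if inhibitory else np.full(len(rev_r), p_sim.exc_delay_ms))
                rows.append(rev_r)
                cols.append(rev_c)
                wdata.append(w_rev)
                ddata.append(d_rev)

    if rows:
        row = np.concatenate(rows)
        col = np.concatenate(cols)
        weights = sp.csr_matrix((np.concatenate(wdata), (row, col)), shape=(n, n))
        delays = sp.csr_matrix((np.concatenate(ddata), (row, col)), shape=(n, n))
    else:
        weights = sp.csr_matrix((n, n))
        delays = sp.csr_matrix((n, n))
    return Connectome(type_of=type_of, po=po, weights=weights, delays=delays,
                      seed=seed, config=config)
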