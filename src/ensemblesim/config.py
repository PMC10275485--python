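"""Configuration objects, defaults, and seeded random-number streams.

Every tunable quantity of the model lives here rather than in code: cell-type
composition, per-projection connectivity rules, membrane/synapse constants,
stimulation protocol defaults, and the analysis thresholds.  Configurations
round-trip losslessly through YAML, and all randomness in the package is drawn
from named substreams of a single master seed so that each pipeline stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

CELL_TYPES = ("EXC", "PV", "SOM", "VIP")


def rng_stream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``.

    Substreams are derived with a SeedSequence spawn key built from a CRC32 of
    the stream name, so the same (seed, name) pair always yields the same
    stream and distinct names yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))


class ConfigError(ValueError):
    """Raised when a configuration file or dict violates the schema."""


@dataclass
class CellTypeParams:
    """Physiology of one cell class.

    ``v_leak`` is the leak reversal (mV), ``background_pa`` the constant
    background current (pA), ``poisson_rate_hz`` the rate of background
    excitatory conductance events and ``poisson_jump_ns`` their size (nS).
    """

    name: str
    count: int
    v_leak: float
    background_pa: float
    poisson_rate_hz: float
    poisson_jump_ns: float = 30.0

    def __post_init__(self):
        if self.name not in CELL_TYPES:
            raise ConfigError(f"unknown cell type {self.name!r}")
        if self.count < 0:
            raise ConfigError("cell count must be non-negative")
        if self.poisson_rate_hz < 0:
            raise ConfigError("poisson_rate_hz must be non-negative")


@dataclass
class ConnectivityRule:
    """Wiring rule for one directed projection (pre type -> post type).

    Connection probability follows a cosine profile of the orientation
    difference dPO (folded into [0, 90] deg)::

        p(dPO) = p_base * (1 + kappa_p * cos(2 dPO)) / (1 + kappa_p)

    so ``p_base`` is the probability at dPO = 0 and ``kappa_p = 0`` recovers
    orientation-independent wiring.  Synaptic weights are lognormal in nS,
    ``exp(Normal(mu_log, sigma_log))``, multiplied by the same cosine profile
    with ``kappa_w`` so similarly tuned neurons receive stronger synapses.
    ``endpoint_gain_sigma`` adds per-neuron lognormal coupling gains (drawn
    once per neuron, applied multiplicatively at both endpoints), modelling
    cell-to-cell variability in overall synaptic strength; it spreads the
    strong-connection degree distribution without changing mean coupling
    appreciably.  ``w_max_ns`` (if positive) caps sampled weights, bounding
    the largest single-synapse PSP as observed in slice recordings.
    ``reciprocity`` reproduces the over-representation of reciprocal pairs
    seen in slice: each sampled synapse i->j recruits the reverse synapse
    j->i with probability ``reciprocity`` times the PO profile, so
    similarly tuned pairs are preferentially bidirectional.  Reciprocation
    never creates new undirected pairs, so the pruned undirected graph used
    for ensemble detection is unaffected.
    """

    pre: str
    post: str
    p_base: float
    mu_log: float
    sigma_log: float
    kappa_p: float = 0.0
    kappa_w: float = 0.0
    endpoint_gain_sigma: float = 0.0
    w_max_ns: float = 0.0  # 0 = uncapped
    reciprocity: float = 0.0

    def __post_init__(self):
        for t in (self.pre, self.post):
            if t not in CELL_TYPES:
                raise ConfigError(f"unknown cell type {t!r} in connectivity rule")
        if not (0.0 <= self.p_base <= 1.0):
            raise ConfigError(f"p_base must be in [0,1], got {self.p_base}")
        if not (0.0 <= self.kappa_p <= 1.0) or not (0.0 <= self.kappa_w <= 1.0):
            raise ConfigError("kappa_p and kappa_w must be in [0,1]")
        if not np.isfinite(self.mu_log) or not np.isfinite(self.sigma_log):
            raise ConfigError("lognormal parameters must be finite")
        if self.sigma_log < 0:
            raise ConfigError("sigma_log must be non-negative")
        if self.endpoint_gain_sigma < 0:
            raise ConfigError("endpoint_gain_sigma must be non-negative")
        if self.w_max_ns < 0:
            raise ConfigError("w_max_ns must be non-negative")
        if not (0.0 <= self.reciprocity <= 1.0):
            raise ConfigError("reciprocity must be in [0,1]")


@dataclass
class SimulationParams:
    """Integrator and membrane constants (units in field names)."""

    dt_ms: float = 0.1
    c_m_pf: float = 200.0
    g_leak_ns: float = 10.0
    v_exc_mv: float = 0.0
    v_inh_mv: float = -80.0
    v_threshold_mv: float = -55.0
    v_reset_mv: float = -70.0
    refractory_ms: float = 2.0
    tau_e_ms: float = 5.0
    tau_i_ms: float = 10.0
    noise_sigma_mv: float = 4.0
    noise_tau_ms: float = 10.0
    noise_update_steps: int = 5
    g_opsin_ns: float = 150.0
    v_opsin_mv: float = 0.0
    exc_delay_ms: float = 1.5
    inh_delay_min_ms: float = 4.0
    inh_delay_max_ms: float = 6.0

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ConfigError("dt_ms must be positive")
        if self.tau_e_ms <= 0 or self.tau_i_ms <= 0:
            raise ConfigError("synaptic time constants must be positive")
        if self.refractory_ms < 0:
            raise ConfigError("refractory_ms must be non-negative")
        if self.inh_delay_min_ms > self.inh_delay_max_ms:
            raise ConfigError("inh_delay_min_ms must not exceed inh_delay_max_ms")


@dataclass
class ProtocolParams:
    """Defaults for optogenetic stimulation protocols."""

    pulse_width_ms: float = 0.6
    train_frequency_hz: float = 30.0
    train_n_pulses: int = 8
    stim_duration_ms: float = 250.0
    inter_train_gap_ms: float = 600.0

    def __post_init__(self):
        if self.pulse_width_ms <= 0:
            raise ConfigError("pulse_width_ms must be positive")
        if self.train_frequency_hz <= 0:
            raise ConfigError("train_frequency_hz must be positive")


@dataclass
class AnalysisParams:
    """Thresholds for ensemble detection, recall scoring, and PCC."""

    epsp_threshold_mv: float = 0.9
    target_median_size: int = 40
    kmeans_k_min: int = 30
    kmeans_k_max: int = 80
    kmeans_k_step: int = 5
    kmeans_n_init: int = 3
    po_std_threshold_rad: float = 0.25
    recall_fraction: float = 0.75
    recall_window_ms: float = 10.0
    pcc_target_rate: float = 0.05
    pcc_bin_width_mv: float = 5.0
    pcc_bin_step_mv: float = 1.6
    pcc_v_max_mv: float = -68.0
    pcc_min_trials_per_bin: int = 5
    r2_retention_threshold: float = 0.5
    trained_background_pa: float = 75.0
    spont_event_min_gap_ms: float = 100.0


@dataclass
class NetworkConfig:
    """Cell-type composition plus per-projection wiring rules.

    Projections absent from ``rules`` do not exist (e.g. SOM->SOM, PV->SOM,
    PV->VIP are disallowed by default, matching the wiring of mouse V1 L2/3).
    ``probability_scale`` multiplies every rule's connection probability; it is
    used by reduced-scale fixtures to preserve per-neuron in-degree.
    """

    cell_types: list[CellTypeParams]
    rules: list[ConnectivityRule]
    probability_scale: float = 1.0

    def __post_init__(self):
        seen = set()
        for r in self.rules:
            if (r.pre, r.post) in seen:
                raise ConfigError(f"duplicate rule for {r.pre}->{r.post}")
            seen.add((r.pre, r.post))
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cell type entry")

    @property
    def n_neurons(self) -> int:
        return sum(ct.count for ct in self.cell_types)

    def cell_type(self, name: str) -> CellTypeParams:
        for ct in self.cell_types:
            if ct.name == name:
                return ct
        raise ConfigError(f"no cell type named {name!r}")

    def rule(self, pre: str, post: str) -> ConnectivityRule | None:
        for r in self.rules:
            if r.pre == pre and r.post == post:
                return r
        return None


@dataclass
class ExperimentConfig:
    """Top-level configuration: one object drives every pipeline stage."""

    network: NetworkConfig
    simulation: SimulationParams = field(default_factory=SimulationParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    master_seed: int = 0

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        _check_keys(d, {"network", "simulation", "protocol", "analysis", "master_seed"},
                    required={"network"}, where="top level")
        net = dict(d["network"])
        _check_keys(net, {"cell_types", "rules", "probability_scale"},
                    required={"cell_types", "rules"}, where="network")
        cell_types = [_build(CellTypeParams, ct, "network.cell_types") for ct in net["cell_types"]]
        rules = [_build(ConnectivityRule, r, "network.rules") for r in net["rules"]]
        network = NetworkConfig(cell_types=cell_types, rules=rules,
                                probability_scale=float(net.get("probability_scale", 1.0)))
        return cls(
            network=network,
            simulation=_build(SimulationParams, d.get("simulation", {}), "simulation"),
            protocol=_build(ProtocolParams, d.get("protocol", {}), "protocol"),
            analysis=_build(AnalysisParams, d.get("analysis", {}), "analysis"),
            master_seed=int(d.get("master_seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


def _check_keys(d: dict, allowed: set, required: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"missing required key(s) {sorted(missing)} in {where}")


def _build(cls, d: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    required = {f.name for f in dataclasses.fields(cls)
                if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING}
    _check_keys(dict(d), names, required, where)
    return cls(**d)


# --------------------------------------------------------------------------
# Default model: mouse V1 L2/3, 4000 neurons.
#
# Membrane constants, cell counts, leak reversals, background currents, and
# Poisson drive follow published slice/in-vivo measurements for this circuit.
# Per-projection connection probabilities and lognormal weight parameters are
# calibrated stand-ins chosen so that (i) most EXC->EXC EPSPs are below 1 mV
# with a heavy right tail and ~80% below 0.9 mV, (ii) spontaneous per-type
# firing rates and resting potentials fall in the in-vivo bands, and (iii)
# single-neuron stimulation reproduces SOM sensitivity and feature
# suppression.  See docs/methods.md for the calibration procedure.
# --------------------------------------------------------------------------

DEFAULT_CELL_TYPES = [
    dict(name="EXC", count=3200, v_leak=-50.0, background_pa=100.0, poisson_rate_hz=0.08),
    dict(name="PV", count=330, v_leak=-55.0, background_pa=0.0, poisson_rate_hz=1.6),
    dict(name="SOM", count=330, v_leak=-65.0, background_pa=0.0, poisson_rate_hz=0.05),
    dict(name="VIP", count=140, v_leak=-65.0, background_pa=0.0, poisson_rate_hz=1.3),
]

DEFAULT_RULES = [
    # orientation-tuned recurrent excitation; weights heavy-tailed, mostly sub-mV EPSPs
    dict(pre="EXC", post="EXC", p_base=0.06, kappa_p=0.9, mu_log=-0.90, sigma_log=0.35, kappa_w=0.9, endpoint_gain_sigma=1.2, w_max_ns=5.1, reciprocity=0.4),
    # excitatory drive onto interneurons; E->PV tuned (like-to-like), E->SOM/VIP untuned
    dict(pre="EXC", post="PV", p_base=0.45, kappa_p=0.5, mu_log=1.30, sigma_log=0.8, kappa_w=0.9),
    dict(pre="EXC", post="SOM", p_base=0.28, mu_log=1.355, sigma_log=1.0),
    dict(pre="EXC", post="VIP", p_base=0.30, mu_log=0.00, sigma_log=0.6),
    # PV: dense perisomatic inhibition of EXC (tuned) and of other PV
    dict(pre="PV", post="EXC", p_base=0.60, kappa_p=0.5, mu_log=1.68, sigma_log=0.6, kappa_w=0.9),
    dict(pre="PV", post="PV", p_base=0.60, mu_log=-0.22, sigma_log=0.6),
    # SOM inhibits every other class, never itself; SOM->PV kept marginal
    dict(pre="SOM", post="EXC", p_base=0.30, mu_log=-0.91, sigma_log=0.6),
    dict(pre="SOM", post="PV", p_base=0.05, mu_log=-2.30, sigma_log=0.6),
    dict(pre="SOM", post="VIP", p_base=0.40, mu_log=-0.50, sigma_log=0.6),
    # VIP: canonical disinhibitory motif, targets SOM only
    dict(pre="VIP", post="SOM", p_base=0.40, mu_log=1.40, sigma_log=0.6),
]


def default_config(master_seed: int = 0) -> ExperimentConfig:
    """The full-scale (4000-neuron) model configuration."""
    return ExperimentConfig.from_dict(
        {
            "network": {"cell_types": DEFAULT_CELL_TYPES, "rules": DEFAULT_RULES},
            "master_seed": master_seed,
        }
    )
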