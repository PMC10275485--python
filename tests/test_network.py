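"""Network construction: composition, orientation tuning, weights, PSPs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ensemblesim as es
from ensemblesim.config import CELL_TYPES, ConfigError, ConnectivityRule, SimulationParams
from ensemblesim.network import (assign_cell_types, assign_preferred_orientations,
                                 circular_dpo, connection_probability,
                                 psp_threshold_weight, psp_time_course,
                                 sample_weight, weight_to_psp)

DEFAULT_FRACTIONS = {"EXC": 0.8, "PV": 0.0825, "SOM": 0.0825, "VIP": 0.035}


@pytest.mark.parametrize("n_total,expected", [
    (4000, {"EXC": 3200, "PV": 330, "SOM": 330, "VIP": 140}),
    (400, {"EXC": 320, "PV": 33, "SOM": 33, "VIP": 14}),
    (0, {"EXC": 0, "PV": 0, "SOM": 0, "VIP": 0}),
])
def test_cell_type_counts_match_rounded_targets(n_total, expected):
    codes = assign_cell_types(n_total, DEFAULT_FRACTIONS)
    assert len(codes) == n_total
    for name, count in expected.items():
        assert np.sum(codes == CELL_TYPES.index(name)) == count


def test_bad_fractions_rejected():
    with pytest.raises(ConfigError):
        assign_cell_types(100, {"EXC": 0.5, "PV": 0.2})


def test_preferred_orientations_uniform():
    rng = np.random.default_rng(5)
    po = assign_preferred_orientations(4000, rng)
    assert po.min() >= 0 and po.max() < 180
    # goodness of fit against uniform[0, 180)
    assert stats.kstest(po / 180.0, "uniform").pvalue > 0.01
    single = assign_preferred_orientations(1, rng)
    assert 0 <= single[0] < 180


def test_circular_dpo_wraps_at_180():
    assert circular_dpo(179.0, 1.0) == pytest.approx(2.0)
    assert circular_dpo(0.0, 90.0) == pytest.approx(90.0)
    assert circular_dpo(10.0, 10.0) == 0.0
    d = circular_dpo(np.arange(0, 180, 7.0), 91.0)
    assert np.all((d >= 0) & (d <= 90))


def test_connection_probability_monotone_and_disallowed():
    rule = ConnectivityRule("EXC", "EXC", p_base=0.2, mu_log=0.0, sigma_log=1.0,
                            kappa_p=0.7)
    dpo = np.linspace(0, 90, 50)
    p = connection_probability(rule, dpo)
    assert np.all(np.diff(p) <= 1e-12)            # monotone non-increasing
    assert p[0] > p[-1]
    flat = ConnectivityRule("SOM", "EXC", p_base=0.3, mu_log=0.0, sigma_log=1.0)
    assert np.ptp(connection_probability(flat, dpo)) == 0
    assert np.all(connection_probability(None, dpo) == 0)   # disallowed pair


def test_sample_weight_positive_skewed_and_po_scaled():
    rule = ConnectivityRule("EXC", "EXC", p_base=0.1, mu_log=-0.9,
                            sigma_log=0.8, kappa_w=0.6)
    rng = np.random.default_rng(2)
    w0 = sample_weight(rule, np.zeros(100_000), rng)
    w90 = sample_weight(rule, np.full(100_000, 90.0), rng)
    assert np.all(w0 > 0)
    assert stats.skew(w0) > 0
    assert w0.mean() > w90.mean()
    # log-weights are normal: straight line on a normal probability plot
    r = stats.probplot(np.log(w0), dist="norm")[1][2]
    assert r ** 2 > 0.95
    # degenerate lognormal collapses to the location's exponential
    degen = ConnectivityRule("EXC", "EXC", p_base=0.1, mu_log=0.5, sigma_log=0.0)
    wd = sample_weight(degen, np.zeros(10), rng)
    assert np.allclose(wd, np.exp(0.5))


def test_epsp_matches_linearized_closed_form():
    """Small-EPSP peak agrees with the fixed-driving-force analytic solution.

    With the synaptic driving force frozen at its resting value the membrane
    equation is linear and the PSP is a difference of exponentials; for a
    sub-mV EPSP the nonlinear correction is far below 1%.
    """
    p = SimulationParams()
    v_leak = -50.0
    w = 0.5  # nS -> EPSP ~0.4 mV
    tau_m = p.c_m_pf / p.g_leak_ns
    tau_e = p.tau_e_ms
    amp = w * (p.v_exc_mv - v_leak) / (p.c_m_pf * (1 / tau_e - 1 / tau_m))
    t_peak = np.log(tau_m / tau_e) * tau_e * tau_m / (tau_m - tau_e)
    analytic = amp * (np.exp(-t_peak / tau_m) - np.exp(-t_peak / tau_e))
    simulated = weight_to_psp(w, v_leak, p)
    assert simulated == pytest.approx(analytic, rel=0.01)


def test_psp_monotone_zero_and_threshold_inverse():
    p = SimulationParams()
    assert weight_to_psp(0.0, -50.0, p) == 0.0
    w = np.array([0.3, 0.6, 1.2, 2.4])
    psp = weight_to_psp(w, -50.0, p)
    assert np.all(np.diff(psp) > 0)
    w09 = psp_threshold_weight(0.9, -50.0, p)
    assert weight_to_psp(w09, -50.0, p) == pytest.approx(0.9, abs=1e-6)
    # IPSP: hyperpolarizing deflection reported as magnitude
    assert weight_to_psp(1.0, -60.0, p, inhibitory=True) > 0
    t, v = psp_time_course(1.0, -60.0, p, inhibitory=True)
    assert v.min() < -60.0


def test_connectome_invariants_and_determinism(tiny_config):
    net1 = es.build_connectome(tiny_config, seed=3)
    net2 = es.build_connectome(tiny_config, seed=3)
    assert np.array_equal(net1.po, net2.po)
    assert (net1.weights != net2.weights).nnz == 0
    assert (net1.delays != net2.delays).nnz == 0
    net3 = es.build_connectome(tiny_config, seed=4)
    assert (net1.weights != net3.weights).nnz > 0

    w = net1.weights.tocoo()
    assert np.all(w.data > 0)
    assert not np.any(w.row == w.col)          # no self-synapses
    # disallowed projections absent: SOM->SOM, PV->SOM, PV->VIP, VIP->{EXC,PV,VIP}
    t = net1.type_of
    for pre, post in [("SOM", "SOM"), ("PV", "SOM"), ("PV", "VIP"),
                      ("VIP", "EXC"), ("VIP", "PV"), ("VIP", "VIP")]:
        pre_c, post_c = CELL_TYPES.index(pre), CELL_TYPES.index(post)
        assert not np.any((t[w.row] == pre_c) & (t[w.col] == post_c)), f"{pre}->{post}"

    # delays: excitatory synapses fixed, inhibitory in [4, 6] ms
    d = net1.delays.tocoo()
    exc_pre = net1.is_excitatory[d.row]
    assert np.allclose(d.data[exc_pre], 1.5)
    assert np.all(d.data[~exc_pre] >= 4.0) and np.all(d.data[~exc_pre] <= 6.0)


def test_like_to_like_excitatory_wiring(tiny_net):
    """EXC pairs with similar POs are connected more often than orthogonal ones."""
    exc = tiny_net.type_indices("EXC")
    po = tiny_net.po[exc]
    sub = tiny_net.weights[exc][:, exc].toarray() > 0
    dpo = circular_dpo(po[:, None], po[None, :])
    off = ~np.eye(len(exc), dtype=bool)
    similar = (dpo < 15) & off
    dissimilar = (dpo > 75) & off
    assert sub[similar].mean() > sub[dissimilar].mean()


def test_hdf5_round_trip(tiny_net, tmp_path):
    path = tmp_path / "net.h5"
    tiny_net.to_hdf5(path)
    back = es.Connectome.from_hdf5(path)
    assert back.n_neurons == tiny_net.n_neurons
    assert np.array_equal(back.type_of, tiny_net.type_of)
    assert np.allclose(back.po, tiny_net.po)
    assert (back.weights != tiny_net.weights).nnz == 0
    assert (back.delays != tiny_net.delays).nnz == 0
    assert back.config.network.n_neurons == tiny_net.config.network.n_neurons
    csv = tmp_path / "synapses.csv"
    tiny_net.to_synapse_csv(csv)
    assert csv.read_text().startswith("pre,post,weight_ns,delay_ms")


@settings(max_examples=20, deadline=None)
@given(a=st.floats(0, 180, exclude_max=True), b=st.floats(0, 180, exclude_max=True))
def test_dpo_symmetric_bounded(a, b):
    d = circular_dpo(a, b)
    assert 0 <= d <= 90
    assert d == pytest.approx(circular_dpo(b, a))
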