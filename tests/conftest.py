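"""Shared fixtures.

Unit tests use a tiny (scale 0.1, ~400 neuron) network.  The acceptance tests
share two expensive session-scoped fixtures: the full 4000-neuron model and a
half-scale "desk" model with a detected, trained ensemble and its pair-
stimulation trial table, reused across the recall/PCC/graph/latency checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import ensemblesim as es


@pytest.fixture(scope="session")
def tiny_config():
    return es.scaled_config(None, 0.1)


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    return es.build_connectome(tiny_config, seed=42)


@pytest.fixture(scope="session")
def full_net():
    return es.build_connectome(es.default_config(0), seed=1)


@pytest.fixture(scope="session")
def desk():
    """Half-scale model with detected ensembles, a trained ensemble, and a
    24-pair x 400-pulse stimulation trial table (with per-trial latencies)."""
    cfg = es.scaled_config(None, 0.5)
    net = es.build_connectome(cfg, seed=7)
    from ensemblesim import ensembles as em

    und = em.prune_weak_connections(net)
    a = em.shared_neighbor_matrix(und)
    labels = em.kmeans_ensembles(a, 30, seed=1, n_init=2)
    ens_list = em.filter_orientation_selective(labels, net.type_indices("EXC"),
                                               net.po)
    sizes = np.array([e.size for e in ens_list])
    ens = ens_list[int(np.argmin(np.abs(sizes - 40)))]
    rng = np.random.default_rng(0)
    pairs = [rng.choice(ens.members, 2, replace=False) for _ in range(24)]
    ctx = es.train_ensemble(net, ens, seed=3, probe_pairs=pairs[:12],
                            n_probe_pulses=80, tolerance=0.004, max_iter=10)
    trials = es.run_stimulation_experiment(ctx, pairs, 400, seed=11,
                                           return_latencies=True)
    results = es.pair_results(trials, cfg.analysis)
    return dict(net=net, ensembles=ens_list, ensemble=ens, context=ctx,
                pairs=pairs, trials=trials, results=results)
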