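"""Spike latency as an imaging-friendly proxy for pattern completion.

During recall events ensemble members activate in a staged sequence; a
neuron's average first-spike latency predicts how capable it is.  This script
reuses the pipeline's trained ensemble, computes per-neuron evoked latencies
within recall events, sums them per stimulated pair, and correlates with PCC
(expected positive: early pairs have low PCC).  It then corrupts per-event
latencies with calcium-sensor rise-time jitter - a fast/narrow sensor
(GCaMP8f-like) versus a slow/broad one (GCaMP7f-like) - and prints the
latency-PCC correlation as a function of how many recall events were
observed: the fast sensor recovers the correlation with far fewer events.

Takes several minutes on one CPU.
"""

import numpy as np

import ensemblesim as es
from ensemblesim.latency import (default_sensors, latency_pcc_correlation,
                                 latency_pcc_curve)
from ensemblesim.pcc import pair_results

cfg = es.scaled_config(None, scale=0.5)
art = es.run_pipeline(cfg, "examples_output/graph", seed=7, n_pairs=20,
                      n_pulses=320)
trials = art["trials"]
ens = art["context"].ensemble
pairs = trials.attrs["neuron_sets"]
results = pair_results(trials, cfg.analysis)
pcc = np.array([r.pcc_mv for r in results])

lat_all = trials.attrs["latencies"]
lat = {sid: lat_all[sid][grp["recall"].to_numpy()]
       for sid, grp in trials.groupby("set_id") if grp["recall"].any()}
stim = {i: p for i, p in enumerate(pairs)}
r = latency_pcc_correlation(lat, ens.members, stim, pairs, pcc)
print(f"clean latency-PCC Pearson r = {r:.3f}")

rng = es.rng_stream(3, "example-jitter")
for name, model in [("no sensor", None)] + list(default_sensors().items()):
    curve = latency_pcc_curve(lat, ens.members, stim, pairs, pcc,
                              [25, 50, 100, 200], model, n_resamples=20,
                              rng=rng)
    vals = ", ".join(f"{int(row.n_events)} events: r={row.mean_r:.2f}"
                     for row in curve.itertuples())
    print(f"{name:10s} {vals}")
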