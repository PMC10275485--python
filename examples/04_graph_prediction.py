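"""Predict a pair's PCC from graph-theoretic connectivity features.

Reuses the pipeline to obtain a trained ensemble and its pair-stimulation
PCCs, computes the four pair features on the pruned intra-ensemble digraph
(degree = summed outgoing weight, closeness = summed inverse synaptic
distances, intersection/union of postsynaptic target sets), and fits a LASSO
regression with the penalty tuned by leave-one-out cross-validation.  The
printout shows each feature's correlation with PCC (all expected negative:
better-connected pairs complete the pattern at lower voltages), the model's
predicted-vs-actual Pearson r, and the algorithm-reliance of each feature
(fold-increase in model error when that feature is withheld).

Takes several minutes on one CPU.
"""

import numpy as np

import ensemblesim as es
from ensemblesim.graphs import features_table, fit_lasso_loocv, reliance_table
from ensemblesim.pcc import pair_results

cfg = es.scaled_config(None, scale=0.5)
art = es.run_pipeline(cfg, "examples_output/graph", seed=7, n_pairs=20,
                      n_pulses=320)
net, ens, pairs = art["connectome"], art["context"].ensemble, None
trials = art["trials"]
pairs = trials.attrs["neuron_sets"]
results = pair_results(trials, cfg.analysis)
pcc = np.array([r.pcc_mv for r in results])
keep = np.isfinite(pcc)
print(f"{int(keep.sum())} of {len(pairs)} pairs with a retained PCC fit")

graph = es.ensemble_subgraph(net, ens)
feats = features_table(graph, pairs)[keep].reset_index(drop=True)
for f in ("degree", "closeness", "intersection", "union"):
    print(f"  corr({f}, PCC) = {np.corrcoef(feats[f], pcc[keep])[0, 1]:+.2f}")
model = fit_lasso_loocv(feats, pcc[keep])
print(f"LASSO predicted-vs-actual Pearson r = {model.pearson_r:.3f} "
      f"(leave-one-out r = {model.pearson_r_loo:.3f})")
print("algorithm reliance (error fold-change when withheld):")
print(reliance_table(feats, pcc[keep]).round(3).to_string())
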