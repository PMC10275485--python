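"""Train an ensemble and measure pattern completion capability (PCC).

Detects an ensemble in a half-scale model, scales its internal weights until
random pairs of its members recall it on ~5% of stimulation pulses, then
stimulates 8 pairs with trains of 0.6 ms pulses at 30 Hz.  For each pair the
trials are binned by the ensemble's mean pre-pulse voltage V_e, the recall
rate is fit to a logistic of V_e, and the PCC is the voltage at which the
fitted curve reaches 5% recall.  Capable pairs (high overall recall) reach 5%
at voltages further below the -55 mV threshold, i.e. lower PCC - the printed
correlation between recall rate and PCC should be strongly negative.

Takes a few minutes on one CPU.
"""

import numpy as np

import ensemblesim as es
from ensemblesim.pcc import pair_results, results_frame, pcc_recall_correlation

cfg = es.scaled_config(None, scale=0.5)
net = es.build_connectome(cfg, seed=7)
ensembles, _ = es.detect_ensembles(net, seed=1, target_median_size=40,
                                   k_range=range(15, 51, 5))
ens = max(ensembles, key=lambda e: e.size)
print(f"training ensemble of {ens.size} neurons ...")

rng = np.random.default_rng(0)
pairs = [rng.choice(ens.members, 2, replace=False) for _ in range(8)]
ctx = es.train_ensemble(net, ens, seed=3, probe_pairs=pairs, n_probe_pulses=80)
print(f"weight fold-increase {ctx.weight_scale:.2f} -> probe recall "
      f"{ctx.probe_recall_rate:.3f}")

trials = es.run_stimulation_experiment(ctx, pairs, 240, seed=11)
print(f"overall recall rate over {len(trials)} pulses: "
      f"{trials['recall'].mean():.3f}")

results = pair_results(trials, cfg.analysis)
print(results_frame(results).round(3).to_string(index=False))
try:
    r, p = pcc_recall_correlation(results)
    print(f"Pearson r (PCC vs recall rate) = {r:.3f}  (p = {p:.2e})")
except ValueError as e:
    print(f"not enough retained pairs for the correlation: {e}")
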