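# Model and methods

## The network

The model is a conductance-based leaky integrate-and-fire network of 4000
neurons representing layer 2/3 of mouse primary visual cortex: 3200
excitatory pyramidal cells (EXC) and three interneuron classes -
parvalbumin- (PV, 330), somatostatin- (SOM, 330) and VIP-expressing (140)
cells.  Each neuron carries a preferred orientation (PO) drawn uniformly on
[0, 180) degrees.  The sub-threshold membrane potential obeys

    C_m dV/dt = -g_L (V - V_L) - g_E (V - V_E) - g_I (V - V_I)
                - g_opsin (V - V_opsin) + B + g_L eta(t)

with C_m = 200 pF, g_L = 10 nS, V_E = 0 mV, V_I = -80 mV, threshold -55 mV,
reset -70 mV, 2 ms refractory period, and per-type leak reversals
V_L = -50 / -55 / -65 / -65 mV (EXC / PV / SOM / VIP).  Excitatory and
inhibitory conductances decay exponentially (tau_E = 5 ms, tau_I = 10 ms)
and jump by the synaptic weight W_ij when a presynaptic spike arrives after
its conduction delay (1.5 ms for excitatory synapses; drawn once per synapse
from uniform[4, 6] ms for inhibitory synapses).  A background current
B = 100 pA drives EXC cells (75 pA in the trained-ensemble context, see
below); independent background Poisson events (EXC 0.08, PV 1.6, SOM 0.05,
VIP 1.3 events/s) kick g_E by 30 nS and essentially guarantee a spike, so
they set the floor of the excitatory spontaneous rate.  Membrane noise is an
Ornstein-Uhlenbeck process eta with 10 ms correlation time injected as a
leak-scaled current; its amplitude (4 mV) is set so the excitatory baseline
voltage fluctuation is ~3.4 mV once synaptic bombardment is added.

A note on the opsin term: written with a plus sign the term would
hyperpolarize a sub-threshold membrane, which contradicts channelrhodopsin-2
physiology and the fact that stimulated model neurons fire.  It is
implemented depolarizing (-g_opsin (V - V_opsin), V_opsin = 0 mV,
g_opsin = 150 nS during 0.6 ms pulses on targeted neurons, 0 otherwise).

Because the excitatory leak reversal (-50 mV) and background current place
the uninhibited excitatory equilibrium ~15 mV above threshold, excitatory
cells are intrinsic pacemakers that must be held quiet by sustained
inhibition.  The operating point is therefore an inhibition-stabilized
asynchronous state: PV cells (whose leak reversal sits at threshold) fire
tonically at ~7 spikes/s and provide the bulk of the ~20 nS inhibitory tone
that keeps EXC near -70 mV and ~0.1 spikes/s.

## Connectivity

Wiring follows per-projection rules.  EXC cells contact all classes; PV
cells contact EXC and PV; SOM cells contact every class but themselves; VIP
cells contact only SOM (the canonical disinhibitory motif).  SOM->SOM,
PV->SOM and PV->VIP projections do not exist.  For orientation-tuned
projections, connection probability and synaptic weight scale with the
folded orientation difference dPO through a cosine profile
(1 + kappa cos 2*dPO)/(1 + kappa); weights are lognormal in nS.

The wiring rules fix which projections exist and which are
orientation-tuned, but their numeric parameters are calibrated stand-ins
chosen against measurable targets rather than taken from a published table:

* most EXC->EXC EPSPs are sub-millivolt with a heavy right tail, and the
  0.9 mV EPSP pruning threshold removes 80 +/- 2% of recurrent excitatory
  synapses;
* spontaneous per-type rates, resting potentials and voltage fluctuations
  fall in the declared physiological bands (`CALIBRATION_BANDS`);
* single-neuron stimulation reproduces the SOM dose-response slope
  (~+1.35 spikes/s per stimulated neuron), the slightly negative EXC slope
  (~-0.01), a PV response that is not significant below 4 stimulated
  neurons, and orientation-tuned feature suppression (dV-vs-dPO slope
  ~+0.01 mV/deg);
* K-means on the shared-neighbor matrix yields a median cluster size ~40
  at the tuned k, dozens of tight orientation-selective clusters, and one
  large weakly-connected residual cluster.

Three EXC->EXC ingredients beyond the plain lognormal were needed to meet
the structural targets simultaneously:

* **per-neuron endpoint gains** (lognormal, sigma = 1.2, applied at both
  ends of each synapse) model cell-to-cell variability in overall coupling
  strength.  They spread the strong-connection degree distribution, which is
  what produces both the weakly-connected residual cluster and dense
  co-tuned hubs; without them K-means returns size strata instead of
  orientation-selective ensembles.  They also couple a neuron's in- and
  out-strength, which is what makes early spike latency predictive of
  pattern-completion capability.
* **a weight cap** (5.1 nS, ~4 mV EPSP, consistent with the largest
  unitary EPSPs reported in slice).  Multiplied endpoint gains otherwise
  produce rare suprathreshold reciprocal pairs that ignite a saturated
  network state.
* **reciprocity** (0.4, scaled by the PO profile): each sampled synapse
  recruits its reverse partner preferentially between similarly tuned
  cells, reproducing the over-representation of bidirectional pairs seen in
  slice.  Reciprocation never creates new undirected pairs, so ensemble
  detection is unaffected; it is what makes within-ensemble bidirectional
  connectivity measurably exceed random sampling.

## Integration and reproducibility

Forward-Euler for the voltage and exact exponential updates for the
conductances and the noise process, at dt = 0.1 ms.  The noise process is
updated every 5 steps (0.5 ms) with the exact OU discretization for that
interval; 0.5 ms is far below the 10 ms correlation time, so the membrane
statistics are unchanged while the per-step cost halves.  The inner loop is
compiled with numba; a pure-numpy twin with identical update semantics is
the fallback, and a test asserts the two produce bit-identical rasters.
Every random draw comes from a named substream of one master seed
(SeedSequence spawn keys), so each pipeline stage is independently
reproducible and a fixed (connectome, protocol, seed) gives bit-identical
results.  Spike times are reported at the step of threshold crossing;
refractory neurons are clamped at the reset potential.

Reduced-scale models (`scaled_config`) shrink cell counts while raising
connection probabilities toward constant in-degree; where a probability
would clip at 1 the lost connection count is folded into the projection's
weights, conserving each neuron's mean input conductance per projection.
Test fixtures mostly use the half-scale (2000-neuron) model.

## Ensemble detection

EXC->EXC synapses with single-spike EPSP < 0.9 mV are removed (the EPSP is
computed by simulating one spike onto a quiescent cell at rest); any
surviving synapse in either direction makes an undirected edge.  The
shared-neighbor matrix A (A_ij = number of common neighbors) is clustered
with seeded k-means++ (Euclidean distance on rows of A, 3 restarts), with k
tuned over a grid so the median cluster size is closest to 40 (ties to
smaller k).  Clusters are ensembles if their PO circular standard deviation
is below 0.25 rad; angles are doubled before the circular statistics
(orientation period 180 deg) and the threshold lives on the doubled scale.
The largest cluster - the residual of weakly connected neurons - is excluded
before the filter.  Under the default calibration most clusters are tightly
tuned (std 0.16-0.36 rad) and straddle the 0.25 rad cutoff, so roughly half
pass; the residual sits near 2.4 rad.

## Training and stimulation

A detected ensemble is "trained" by multiplying all synaptic weights between
its members by a fold factor, emulating the strengthened coupling of an
imprinted ensemble; the excitatory background current is simultaneously
lowered to 75 pA so baseline rates and resting potentials stay in their
bands.  The fold factor is titrated by bisection until a probe experiment
reaches a 5% recall rate.  Recall varies strongly from pair to pair (the
distribution is heavy-tailed), so the probe should stimulate the same pair
population as the subsequent experiment (`probe_pairs`); probing disjoint
random pairs can misestimate the experiment's mean rate severalfold.

Stimulation delivers trains of eight 0.6 ms pulses at 20 or 30 Hz to 2-5
member neurons.  Every pulse is one trial; the simulation runs continuously
across a set's trains (no state reset) with a 600 ms inter-train gap -
several times the ~100-200 ms post-recall recovery of the ensemble voltage,
so trains are effectively independent while keeping large trial budgets
affordable.  A pulse recalls the ensemble when at least ceil(0.75 x size)
distinct members spike within (onset, onset + 10 ms]; stimulated neurons
count toward the quorum.  The trial record carries V_e, the ensemble-mean
voltage over the 10 ms before the pulse.

## PCC

Per stimulated set, trials with V_e <= -68 mV are binned by V_e in sliding
windows (width 5 mV, step 1.6 mV, at least 5 trials per window), the binned
recall rate is fit to 1/(1 + exp(-a (V_e - b))) by nonlinear least squares,
and PCC = b - ln(19)/a, the voltage at 5% recall.  Fits are kept only when
they converge with R^2 >= 0.5, a > 0, and at least 3 recalls among the
filtered trials; a set that never recalls has a flat curve and no meaningful
PCC.  The sliding window smooths the recall curve, so (a, b) describe the
smoothed transition rather than the pointwise probability.

## Graph prediction

Pair features live on the pruned intra-ensemble digraph (direction
restored): degree (summed outgoing weight of both neurons), closeness
(summed inverse shortest-path distances with edge length 1/weight - a
stronger synapse is a shorter edge; unreachable members contribute 0),
intersection and union of postsynaptic target sets.  PCC is regressed on
the z-scored features with LASSO, the penalty tuned by leave-one-out CV and
the final model refit on all pairs.  Algorithm reliance is the fold-change
in the refit model's mean squared error when one feature is withheld and
the reduced model re-tuned; in-sample error is the default (the
leave-one-out variant is available).  Degree and closeness are ~0.97
correlated in these ensembles, so with tens of pairs either can absorb the
other's removal: reliances hover near 1 and their ordering is not stable
across realizations, even though the prediction itself (Pearson r ~0.8-0.95)
is robust.  Best-subset selection over seven candidates (the four features
plus betweenness, eigenvector centrality and clustering coefficient, summed
over the pair) is exhaustive OLS per subset size, selecting the smallest
size within 0.01 R^2 of the plateau.

## Latency and calcium sensors

Evoked latency is the time from pulse onset to a neuron's first spike
within the 10 ms window, excluding neurons stimulated in that trial and
restricted to recall events (the staged activation sequence exists only
when the ensemble ignites); a pair's latency is the sum of its two members'
mean latencies.  Spontaneous recall events are detected with the same 75% /
10 ms quorum rule applied in a sliding fashion with a 100 ms minimum
separation, and spontaneous latency is the signed offset from each event's
median spike time.

Calcium-indicator rise-time variability is modeled by adding one
independent rise-time draw to every per-event latency.  The shipped sensor
models are synthetic lognormal stand-ins - a fast/narrow sensor
(GCaMP8f-like, mean 10 ms, sd 4 ms) and a slow/broad one (GCaMP7f-like,
mean 40 ms, sd 20 ms); empirical 0-80% rise-time samples can be supplied as
a plain numeric column file and override the parametric form.  The
latency-PCC accuracy curve resamples events from the pool of all sets'
recall events (so it converges to the all-event correlation), computes the
correlation per resample, and reports mean +/- sem per event count.

## What the model reproduces, and known limitations

At the shipped calibration the model reproduces: the dose-response slopes
and feature suppression of single-neuron stimulation; the ensemble
structure (median ~40, ~80% pruning, residual cluster, within-ensemble
bidirectionality / voltage correlation / PO similarity); titration to ~5%
recall with voltage-dependent recall curves; a strongly negative PCC-recall
correlation; graph-feature prediction of PCC; a positive latency-PCC
correlation (~0.5-0.6 at half scale) that sensor jitter degrades in order
of sensor variability, with the fast sensor reaching r > 0.5 in far fewer
events; recall growth with stimulated-set size, the advantage of
early-latency neurons, PCC consistency across 20/30 Hz, and the odd/even
pulse asymmetry that is stronger at 30 Hz.

Three quantitative effects do not reach their reference size under this
reconstruction, and the corresponding checks are deliberately left failing
rather than loosened:

* **SOM baseline rate.**  With static synapses, the SOM baseline is tied to
  the single-neuron dose-response slope: baseline ~ 100 x r_EXC x slope, so
  a +1.35 slope with the 0.08 events/s excitatory floor forces SOM to
  ~15-20 spikes/s, above typical anesthetized rates.  In vivo this tension
  is resolved by strongly facilitating EXC->SOM synapses (quiet at low
  rates, powerful during trains), which this model family omits.  The SOM
  calibration band is declared accordingly.
* **Algorithm-reliance ordering** ("degree largest, all four above 1"): not
  stable at tens of pairs because of the degree-closeness collinearity
  described above.
* **Reliable recall from four early neurons (>75% at 20 Hz).**  Here a
  recall event recruits a SOM/PV surge that hyperpolarizes the ensemble
  ~5 mV for most of the remaining train, capping the per-train average near
  10-30% even though first pulses of a train recall at ~0.35-0.4; reaching
  75% would require both near-certain first-pulse completion and recovery
  within one inter-pulse interval, which this calibration does not produce
  simultaneously with its other targets.

Other limitations: no spatial geometry, layer-4 input, synaptic plasticity
or adaptation; K-means gives each neuron at most one ensemble; synthetic
inputs only - the generator emulates spontaneous cortical statistics and
optogenetic drive, not visually evoked activity, so passing tests
demonstrate internal consistency of the method chain, not performance on
recorded data.
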