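"""Detection of orientation-selective excitatory ensembles.

Pipeline: (1) keep only excitatory neurons and EXC->EXC synapses whose
single-spike EPSP reaches a threshold (0.9 mV by default, which removes about
80% of recurrent excitatory connections under the default calibration);
(2) drop directionality: any surviving synapse in either direction makes an
undirected edge; (3) build the shared-neighbor similarity matrix A, where
A_ij counts the neurons connected to both i and j; (4) K-means cluster the
rows of A, tuning k until the median cluster size reaches a target (~40
neurons); (5) keep clusters whose preferred orientations are tight (circular
std below 0.25 rad on the doubled-angle scale), excluding the large residual
cluster of weakly connected neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans

from .config import rng_stream
from .network import Connectome, circular_dpo, psp_threshold_weight


@dataclass
class Ensemble:
    """An orientation-selective cluster of excitatory neurons."""

    members: np.ndarray          # neuron ids in the full network
    mean_po_deg: float
    po_circ_std_rad: float

    @property
    def size(self) -> int:
        return len(self.members)


def prune_weak_connections(connectome: Connectome,
                           epsp_threshold_mv: float | None = None) -> sp.csr_matrix:
    """Undirected EXC graph of strong recurrent connections.

    Returns a boolean symmetric CSR adjacency over the excitatory neurons
    (indexed in EXC order).  A pair is connected when at least one of its two
    directed EXC->EXC synapses evokes an EPSP of at least the threshold.
    """
    cfg = connectome.config
    thr = epsp_threshold_mv if epsp_threshold_mv is not None else cfg.analysis.epsp_threshold_mv
    exc = connectome.type_indices("EXC")
    v_leak = cfg.network.cell_type("EXC").v_leak
    w_thr = psp_threshold_weight(thr, v_leak, cfg.simulation)
    sub = connectome.weights[exc][:, exc].tocsr()
    strong = sub >= w_thr
    und = (strong + strong.T).astype(bool)
    und.setdiag(False)
    und.eliminate_zeros()
    return und.tocsr()


def pruned_fraction(connectome: Connectome, epsp_threshold_mv: float | None = None) -> float:
    """Fraction of directed EXC->EXC synapses removed by the EPSP threshold."""
    cfg = connectome.config
    thr = epsp_threshold_mv if epsp_threshold_mv is not None else cfg.analysis.epsp_threshold_mv
    exc = connectome.type_indices("EXC")
    v_leak = cfg.network.cell_type("EXC").v_leak
    w_thr = psp_threshold_weight(thr, v_leak, cfg.simulation)
    sub = connectome.weights[exc][:, exc]
    if sub.nnz == 0:
        return 0.0
    return float((sub.data < w_thr).mean())


def shared_neighbor_matrix(adjacency: sp.spmatrix) -> np.ndarray:
    """A_ij = number of common neighbors of i and j in the undirected graph.

    The diagonal is zeroed by convention.
    """
    a = sp.csr_matrix(adjacency, dtype=np.float64)
    a = ((a + a.T) > 0).astype(np.float64)  # tolerate directed input
    a.setdiag(0)
    a.eliminate_zeros()
    common = (a @ a).toarray()
    np.fill_diagonal(common, 0)
    return common


def kmeans_ensembles(a: np.ndarray, k: int, seed: int, n_init: int = 3) -> np.ndarray:
    """Cluster rows of the shared-neighbor matrix with seeded k-means++."""
    n = a.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of neurons {n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed & 0x7FFFFFFF)
    return km.fit_predict(a.astype(np.float32))


def tune_k(a: np.ndarray, target_median_size: int = 40, seed: int = 0,
           k_range=None, n_init: int = 3) -> tuple[int, dict[int, float]]:
    """Find k whose median cluster size is closest to the target.

    Searches the configured k grid; ties go to the smaller k.  Returns the
    chosen k and the median size per candidate.
    """
    n = a.shape[0]
    if k_range is None:
        k_range = range(30, 81, 5)
    medians: dict[int, float] = {}
    for k in k_range:
        if k < 2 or k > n:
            continue
        labels = kmeans_ensembles(a, k, seed, n_init=n_init)
        sizes = np.bincount(labels, minlength=k)
        medians[k] = float(np.median(sizes[sizes > 0]))
    if not medians:
        raise ValueError("no feasible k in range")
    best = min(medians, key=lambda k: (abs(medians[k] - target_median_size), k))
    return best, medians


def circular_po_stats(po_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean (deg) and circular std (rad) of orientations.

    Orientations have period 180 deg, so angles are doubled before the
    circular statistics and the mean is halved back; the std is reported in
    radians on the doubled-angle scale (the scale of the 0.25 rad threshold).
    """
    ang = np.deg2rad(np.asarray(po_deg, dtype=float) * 2.0)
    mean = np.rad2deg(stats.circmean(ang, high=2 * np.pi, low=0)) / 2.0
    std = float(stats.circstd(ang, high=2 * np.pi, low=0))
    return float(mean % 180.0), std


def filter_orientation_selective(labels: np.ndarray, exc_ids: np.ndarray,
                                 po_deg: np.ndarray,
                                 std_threshold_rad: float = 0.25,
                                 exclude_largest: bool = True,
                                 min_size: int = 2) -> list[Ensemble]:
    """Keep clusters with tight POs; drop the giant residual cluster.

    ``labels`` assigns a cluster to every retained EXC neuron, ``exc_ids``
    maps rows to neuron ids in the full network, ``po_deg`` are full-network
    POs.
    """
    sizes = np.bincount(labels)
    largest = int(np.argmax(sizes)) if exclude_largest else -1
    out = []
    for c in range(labels.max() + 1):
        if c == largest or sizes[c] < min_size:
            continue
        members = exc_ids[labels == c]
        mean_po, std = circular_po_stats(po_deg[members])
        if std < std_threshold_rad:
            out.append(Ensemble(members=np.sort(members), mean_po_deg=mean_po,
                                po_circ_std_rad=std))
    return out


def detect_ensembles(connectome: Connectome, seed: int = 0,
                     target_median_size: int | None = None,
                     k_range=None) -> tuple[list[Ensemble], dict]:
    """Full detection pipeline on a connectome.

    Returns the orientation-selective ensembles plus a diagnostics dict
    (chosen k, median size, labels, cluster sizes, pruned fraction).
    """
    cfg = connectome.config.analysis
    target = target_median_size if target_median_size is not None else cfg.target_median_size
    if k_range is None:
        k_range = range(cfg.kmeans_k_min, cfg.kmeans_k_max + 1, cfg.kmeans_k_step)
    und = prune_weak_connections(connectome)
    a = shared_neighbor_matrix(und)
    k, medians = tune_k(a, target, seed, k_range=k_range, n_init=cfg.kmeans_n_init)
    labels = kmeans_ensembles(a, k, seed, n_init=cfg.kmeans_n_init)
    exc = connectome.type_indices("EXC")
    ensembles = filter_orientation_selective(labels, exc, connectome.po,
                                             cfg.po_std_threshold_rad)
    sizes = np.bincount(labels)
    info = dict(k=k, medians=medians, labels=labels, cluster_sizes=sizes,
                median_size=float(np.median(sizes[sizes > 0])),
                pruned_fraction=pruned_fraction(connectome),
                n_selective=len(ensembles))
    return ensembles, info


# ------------------------------------------------------------------ validation

def bidirectional_fraction(connectome: Connectome, pairs: np.ndarray) -> float:
    """Fraction of given (i, j) pairs connected in both directions."""
    w = connectome.weights
    n_bi = 0
    for i, j in pairs:
        if w[i, j] > 0 and w[j, i] > 0:
            n_bi += 1
    return n_bi / len(pairs)


def ensemble_validation_stats(connectome: Connectome, result, ensembles,
                              n_sets: int = 10, seed: int = 0) -> pd.DataFrame:
    """Within-ensemble vs random comparisons of three ensemble signatures.

    For ``n_sets`` draws each: (i) bidirectional-connection probability over
    sets of 100 neuron pairs, (ii) mean pairwise voltage-trace correlation
    over sets of 10 neurons, (iii) mean pairwise orientation difference over
    sets of 10 neurons.  ``result`` must carry voltage traces for the sampled
    neurons.  Returns a tidy frame with one row per (metric, group, set) plus
    one-tailed rank-sum p-values in ``attrs['p_values']``.
    """
    rng = rng_stream(seed, "ensemble-validation")
    exc = connectome.type_indices("EXC")
    if result.voltages is None:
        raise ValueError("validation requires recorded voltages")
    rec_pos = {int(nid): row for row, nid in enumerate(result.record_ids)}

    def sample_pairs(pool, n_pairs):
        a = rng.choice(pool, size=n_pairs)
        b = rng.choice(pool, size=n_pairs)
        redo = a == b
        while redo.any():
            b[redo] = rng.choice(pool, size=int(redo.sum()))
            redo = a == b
        return np.column_stack([a, b])

    recorded_exc = np.array([nid for nid in result.record_ids
                             if connectome.type_of[nid] == 0])
    rows = []
    for s in range(n_sets):
        ens = ensembles[int(rng.integers(len(ensembles)))]
        # (i) bidirectionality over 100 pairs
        rows.append(("bidirectional", "ensemble", s,
                     bidirectional_fraction(connectome, sample_pairs(ens.members, 100))))
        rows.append(("bidirectional", "random", s,
                     bidirectional_fraction(connectome, sample_pairs(exc, 100))))
        # (ii) voltage correlation over 10 recorded neurons
        ens_rec = np.array([nid for nid in ens.members if int(nid) in rec_pos])
        if len(ens_rec) < 10 or len(recorded_exc) < 10:
            raise ValueError("insufficient recorded neurons for correlation stats")
        for group, pool in (("ensemble", ens_rec), ("random", recorded_exc)):
            ids = rng.choice(pool, size=10, replace=False)
            tr = result.voltages[[rec_pos[int(i)] for i in ids]]
            c = np.corrcoef(tr)
            rows.append(("correlation", group, s,
                         float(np.mean(c[np.triu_indices(10, 1)]))))
        # (iii) pairwise dPO over 10 neurons
        for group, pool in (("ensemble", ens.members), ("random", exc)):
            ids = rng.choice(pool, size=10, replace=False)
            po = connectome.po[ids]
            d = circular_dpo(po[:, None], po[None, :])
            rows.append(("dpo", group, s,
                         float(np.mean(d[np.triu_indices(10, 1)]))))
    df = pd.DataFrame(rows, columns=["metric", "group", "set", "value"])
    pvals = {}
    for metric, alternative in (("bidirectional", "greater"),
                                ("correlation", "greater"),
                                ("dpo", "less")):
        e = df.query("metric == @metric and group == 'ensemble'")["value"]
        r = df.query("metric == @metric and group == 'random'")["value"]
        pvals[metric] = float(stats.ranksums(e, r, alternative=alternative).pvalue)
    df.attrs["p_values"] = pvals
    return df


def ensembles_to_frame(ensembles: list[Ensemble]) -> pd.DataFrame:
    rows = [dict(ensemble_id=i, neuron_id=int(n))
            for i, e in enumerate(ensembles) for n in e.members]
    return pd.DataFrame(rows)
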