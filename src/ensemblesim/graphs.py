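"""Graph-theoretic prediction of pattern completion capability.

Features are computed on the pruned intra-ensemble excitatory digraph (weak
connections removed, inhibitory neurons and non-members removed, direction
restored).  For a stimulated pair (A, B):

* degree        - summed outgoing synaptic weight of A plus of B (nS);
* closeness     - sum over reachable members of 1/d(A, k) plus the same for
                  B, where path length uses edge length 1/weight (stronger
                  synapse = shorter edge) and unreachable members add 0;
* intersection  - number of members postsynaptic to both A and B;
* union         - members postsynaptic to A plus to B minus the intersection.

PCC is predicted from the four features with L1-penalized (LASSO) linear
regression; the penalty is tuned by leave-one-out cross-validation.  Feature
importance is quantified as algorithm reliance: the fold-increase in
cross-validated prediction error when a feature is withheld and the model
retrained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import LeaveOneOut

from .ensembles import Ensemble
from .network import Connectome, psp_threshold_weight

PAIR_FEATURES = ("degree", "closeness", "intersection", "union")


def ensemble_subgraph(connectome: Connectome, ensemble: Ensemble,
                      epsp_threshold_mv: float | None = None) -> nx.DiGraph:
    """Directed weighted graph over ensemble members, weak synapses removed."""
    if ensemble.size == 0:
        raise ValueError("ensemble is empty")
    cfg = connectome.config
    thr = epsp_threshold_mv if epsp_threshold_mv is not None else cfg.analysis.epsp_threshold_mv
    v_leak = cfg.network.cell_type("EXC").v_leak
    w_thr = psp_threshold_weight(thr, v_leak, cfg.simulation)
    members = np.asarray(ensemble.members)
    sub = connectome.weights[members][:, members].tocoo()
    g = nx.DiGraph()
    g.add_nodes_from(int(m) for m in members)
    for i, j, w in zip(sub.row, sub.col, sub.data):
        if w >= w_thr:
            g.add_edge(int(members[i]), int(members[j]), weight=float(w),
                       length=1.0 / float(w))
    return g


def _node_closeness(graph: nx.DiGraph, node) -> float:
    dist = nx.single_source_dijkstra_path_length(graph, node, weight="length")
    return float(sum(1.0 / d for k, d in dist.items() if k != node and d > 0))


@dataclass
class PairFeatures:
    degree: float
    closeness: float
    intersection: int
    union: int


def pair_features(graph: nx.DiGraph, a: int, b: int) -> PairFeatures:
    """The four pair-level predictors for stimulated neurons ``a`` and ``b``."""
    if a == b:
        raise ValueError("pair must be two distinct neurons")
    for node in (a, b):
        if node not in graph:
            raise KeyError(f"neuron {node} not in ensemble graph")
    degree = sum(d["weight"] for _, _, d in graph.out_edges(a, data=True)) \
        + sum(d["weight"] for _, _, d in graph.out_edges(b, data=True))
    closeness = _node_closeness(graph, a) + _node_closeness(graph, b)
    ta = set(graph.successors(a))
    tb = set(graph.successors(b))
    inter = len(ta & tb)
    union = len(ta) + len(tb) - inter
    return PairFeatures(degree=float(degree), closeness=closeness,
                        intersection=inter, union=union)


def features_table(graph: nx.DiGraph, neuron_sets: list[np.ndarray]) -> pd.DataFrame:
    """Pair features for each stimulated set (sets of two neurons)."""
    rows = []
    for set_id, s in enumerate(neuron_sets):
        a, b = (int(x) for x in s)
        f = pair_features(graph, a, b)
        rows.append(dict(set_id=set_id, degree=f.degree, closeness=f.closeness,
                         intersection=f.intersection, union=f.union))
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ LASSO

@dataclass
class LassoModel:
    """LASSO fit of PCC on standardized features with LOOCV-tuned penalty."""

    feature_names: list[str]
    coef_standardized: np.ndarray
    coef_raw: np.ndarray
    intercept: float
    alpha: float
    predictions: np.ndarray        # final model, in-sample
    loo_predictions: np.ndarray    # per-pair leave-one-out predictions
    pearson_r: float               # in-sample predicted vs actual
    pearson_r_loo: float
    loo_mse: float

    @property
    def mse(self) -> float:
        """In-sample mean squared error of the final refit model."""
        return float(np.mean((self.predictions - self._y) ** 2))


def _standardize(x: np.ndarray):
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    keep = std > 0
    z = np.zeros_like(x, dtype=float)
    z[:, keep] = (x[:, keep] - mean[keep]) / std[keep]
    return z, mean, std, keep


def _loo_predictions(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    preds = np.empty(len(y))
    for i, (tr, te) in enumerate(LeaveOneOut().split(x)):
        m = Lasso(alpha=alpha, max_iter=50000) if alpha > 0 else LinearRegression()
        m.fit(x[tr], y[tr])
        preds[te] = m.predict(x[te])
    return preds


def fit_lasso_loocv(features: pd.DataFrame, pcc: np.ndarray,
                    feature_names=PAIR_FEATURES, n_alphas: int = 40) -> LassoModel:
    """Fit PCC ~ features with the L1 penalty chosen by leave-one-out CV.

    Features are z-scored before penalization (constant columns are dropped
    from the fit with zero coefficient).  The final model is refit on all
    pairs at the selected penalty; coefficients are reported on both the
    standardized and the raw feature scale.
    """
    names = list(feature_names)
    x = features[names].to_numpy(dtype=float)
    y = np.asarray(pcc, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 pairs")
    z, mean, std, keep = _standardize(x)
    zk = z[:, keep]
    cv = LassoCV(alphas=n_alphas, cv=LeaveOneOut(), max_iter=50000,
                 random_state=0)
    cv.fit(zk, y)
    alpha = float(cv.alpha_)
    final = Lasso(alpha=alpha, max_iter=50000).fit(zk, y)
    coef_std = np.zeros(len(names))
    coef_std[keep] = final.coef_
    coef_raw = np.zeros(len(names))
    coef_raw[keep] = final.coef_ / std[keep]
    preds = final.predict(zk)
    loo = _loo_predictions(zk, y, alpha)
    r_in = float(np.corrcoef(preds, y)[0, 1]) if np.std(preds) > 0 else 0.0
    r_loo = float(np.corrcoef(loo, y)[0, 1]) if np.std(loo) > 0 else 0.0
    model = LassoModel(feature_names=names, coef_standardized=coef_std,
                       coef_raw=coef_raw, intercept=float(final.intercept_),
                       alpha=alpha, predictions=preds, loo_predictions=loo,
                       pearson_r=r_in, pearson_r_loo=r_loo,
                       loo_mse=float(np.mean((loo - y) ** 2)))
    model._y = y
    return model


def algorithm_reliance(features: pd.DataFrame, pcc: np.ndarray, variable: str,
                       feature_names=PAIR_FEATURES, ratio: bool = True,
                       cross_validated: bool = False) -> float:
    """Fold-change in prediction error when ``variable`` is withheld.

    The reduced model is retrained (with its own LOOCV-tuned penalty) and its
    final-model mean squared error is compared with the full model's, as a
    ratio by default.  ``ratio=False`` returns the difference instead;
    ``cross_validated=True`` compares leave-one-out prediction errors rather
    than in-sample errors of the refit models.
    """
    names = list(feature_names)
    if variable not in names:
        raise KeyError(f"unknown feature {variable!r}")
    full = fit_lasso_loocv(features, pcc, feature_names=names)
    reduced_names = [n for n in names if n != variable]
    reduced = fit_lasso_loocv(features, pcc, feature_names=reduced_names)
    mse_full = full.loo_mse if cross_validated else full.mse
    mse_red = reduced.loo_mse if cross_validated else reduced.mse
    if ratio:
        return mse_red / mse_full
    return mse_red - mse_full


def reliance_table(features: pd.DataFrame, pcc: np.ndarray,
                   feature_names=PAIR_FEATURES) -> pd.Series:
    return pd.Series({v: algorithm_reliance(features, pcc, v, feature_names)
                      for v in feature_names}, name="algorithm_reliance")


# ------------------------------------------------------------------ best subset

def candidate_features(graph: nx.DiGraph, neuron_sets: list[np.ndarray]) -> pd.DataFrame:
    """Seven candidate pair-level predictors for best-subset selection.

    Node-level centralities (degree strength, closeness, betweenness,
    eigenvector centrality, clustering coefficient) are summed over the two
    stimulated neurons; intersection and union are pair-native.
    """
    betw = nx.betweenness_centrality(graph, weight="length")
    try:
        eig = nx.eigenvector_centrality(graph.reverse(), weight="weight",
                                        max_iter=2000, tol=1e-8)
    except nx.PowerIterationFailedConvergence:
        eig = {n: 0.0 for n in graph}
    clust = nx.clustering(graph.to_undirected(), weight=None)
    rows = []
    for set_id, s in enumerate(neuron_sets):
        a, b = (int(x) for x in s)
        f = pair_features(graph, a, b)
        rows.append(dict(set_id=set_id, degree=f.degree, closeness=f.closeness,
                         betweenness=betw[a] + betw[b],
                         eigenvector=eig[a] + eig[b],
                         clustering=clust[a] + clust[b],
                         intersection=f.intersection, union=f.union))
    return pd.DataFrame(rows)


def best_subset_selection(features: pd.DataFrame, pcc: np.ndarray,
                          candidate_names=None,
                          plateau_tol: float = 0.01) -> dict:
    """Exhaustive best-subset linear regression of PCC on candidate features.

    For each subset size the best-R^2 ordinary least squares model is
    recorded; the selected model is the smallest size whose best R^2 is
    within ``plateau_tol`` of the overall maximum (the R^2 plateau).
    """
    if candidate_names is None:
        candidate_names = [c for c in features.columns if c != "set_id"]
    names = list(candidate_names)
    if len(names) > 12:
        raise ValueError("at most 12 candidates for exhaustive search")
    y = np.asarray(pcc, dtype=float)
    x_all = features[names].to_numpy(dtype=float)
    z_all, _, _, keep = _standardize(x_all)
    best_by_size = {}
    for size in range(1, len(names) + 1):
        best = (-np.inf, None)
        for combo in combinations(range(len(names)), size):
            x = z_all[:, combo]
            model = LinearRegression().fit(x, y)
            r2 = model.score(x, y)
            if r2 > best[0]:
                best = (r2, combo)
        best_by_size[size] = dict(r2=best[0],
                                  subset=[names[i] for i in best[1]])
    r2_max = max(v["r2"] for v in best_by_size.values())
    chosen = min(s for s, v in best_by_size.items() if v["r2"] >= r2_max - plateau_tol)
    return dict(by_size=best_by_size, chosen_size=chosen,
                chosen_subset=best_by_size[chosen]["subset"],
                chosen_r2=best_by_size[chosen]["r2"])
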