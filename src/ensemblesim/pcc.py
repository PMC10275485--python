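"""Pattern Completion Capability (PCC).

Recall probability rises steeply as the ensemble's mean pre-stimulation
voltage V_e approaches the -55 mV spike threshold.  For each stimulated
neuron set, trials are binned by V_e in a sliding window (width 5 mV, step
1.6 mV, trials above -68 mV excluded), the per-bin recall rate is fit to a
logistic

    rate(V_e) = 1 / (1 + exp(-a (V_e - b))),

and the PCC is the voltage at which the fitted curve reaches the 5% recall
rate: PCC = b - ln(1/0.05 - 1)/a.  A pair that recalls the ensemble at
voltages far below threshold (low PCC) is a capable pattern-completion set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisParams


class BinningError(ValueError):
    """Raised when no trials survive the V_e cutoff."""


@dataclass
class LogisticFit:
    """Fitted logistic recall curve for one stimulated set."""

    a: float                 # slope, 1/mV
    b: float                 # midpoint, mV
    r_squared: float
    n_trials: int
    converged: bool = True

    @property
    def retained(self) -> bool:
        return self.converged and np.isfinite(self.r_squared)


@dataclass
class PairResult:
    """Per-set summary: overall recall rate, fit, and derived PCC."""

    set_id: int
    recall_rate: float
    fit: LogisticFit
    pcc_mv: float
    retained: bool


def logistic(v, a, b):
    z = np.clip(-a * (np.asarray(v, dtype=float) - b), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


def binned_recall_curve(v_e: np.ndarray, recall: np.ndarray,
                        width_mv: float = 5.0, step_mv: float = 1.6,
                        v_max_mv: float = -68.0,
                        min_trials: int = 5) -> pd.DataFrame:
    """Sliding-window recall rate versus pre-stimulation voltage.

    Windows of ``width_mv`` advance by ``step_mv`` from the lowest retained
    V_e; trials with V_e above ``v_max_mv`` are excluded; windows with fewer
    than ``min_trials`` trials are omitted.  Returns columns
    (v_center_mv, recall_rate, n_trials).
    """
    v_e = np.asarray(v_e, dtype=float)
    recall = np.asarray(recall, dtype=bool)
    keep = v_e <= v_max_mv
    if not keep.any():
        raise BinningError(f"no trials at or below {v_max_mv} mV")
    v, r = v_e[keep], recall[keep]
    lo = v.min()
    rows = []
    start = lo
    while start < v_max_mv + 1e-9:
        end = start + width_mv
        sel = (v >= start) & (v < end)
        n = int(sel.sum())
        if n >= min_trials:
            rows.append((0.5 * (start + end), float(r[sel].mean()), n))
        start += step_mv
    return pd.DataFrame(rows, columns=["v_center_mv", "recall_rate", "n_trials"])


def fit_logistic(curve: pd.DataFrame) -> LogisticFit:
    """Nonlinear least squares fit of the logistic recall curve.

    Requires at least 4 bins.  R^2 is computed against the binned rates; a
    non-convergent fit is returned flagged for downstream exclusion.
    """
    if len(curve) < 4:
        raise ValueError("need at least 4 bins to fit the logistic")
    v = curve["v_center_mv"].to_numpy()
    y = curve["recall_rate"].to_numpy()
    n = int(curve["n_trials"].sum())
    if np.ptp(y) == 0:
        # constant recall curve (e.g. no recalls at all): nothing to fit
        return LogisticFit(a=np.nan, b=np.nan, r_squared=np.nan, n_trials=n,
                           converged=False)
    b0 = float(v[np.argmin(np.abs(y - 0.5))]) if (y > 0).any() else float(v.mean())
    try:
        popt, _ = optimize.curve_fit(logistic, v, y, p0=[0.5, b0],
                                     maxfev=10000)
        a, b = float(popt[0]), float(popt[1])
        resid = y - logistic(v, a, b)
        ss_res = float(np.sum(resid ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-12 else 0.0)
        return LogisticFit(a=a, b=b, r_squared=r2, n_trials=n)
    except RuntimeError:
        return LogisticFit(a=np.nan, b=np.nan, r_squared=np.nan, n_trials=n,
                           converged=False)


def pcc_from_fit(fit: LogisticFit, target_rate: float = 0.05) -> float:
    """Invert the fitted logistic at the target recall rate (closed form)."""
    if not np.isfinite(fit.a) or fit.a <= 0:
        raise ValueError("degenerate fit: slope must be positive and finite")
    return fit.b - np.log(1.0 / target_rate - 1.0) / fit.a


def pair_results(trials: pd.DataFrame,
                 params: AnalysisParams | None = None) -> list[PairResult]:
    """Compute the binned curve, logistic fit, and PCC for every set.

    The overall recall rate uses all trials of a set; the fit uses only the
    V_e-filtered trials.  Sets with non-convergent or low-R^2 fits (below the
    retention threshold) are flagged ``retained=False`` and carry NaN PCC.
    """
    p = params or AnalysisParams()
    out = []
    for set_id, grp in trials.groupby("set_id"):
        overall = float(grp["recall"].mean())
        try:
            curve = binned_recall_curve(grp["v_e_mv"].to_numpy(),
                                        grp["recall"].to_numpy(),
                                        p.pcc_bin_width_mv, p.pcc_bin_step_mv,
                                        p.pcc_v_max_mv, p.pcc_min_trials_per_bin)
            fit = fit_logistic(curve)
        except (BinningError, ValueError):
            fit = LogisticFit(np.nan, np.nan, np.nan, len(grp), converged=False)
        n_recalls = int((grp.loc[grp["v_e_mv"] <= p.pcc_v_max_mv, "recall"]).sum())
        ok = (fit.converged and np.isfinite(fit.r_squared)
              and fit.r_squared >= p.r2_retention_threshold and fit.a > 0
              and n_recalls >= 3)
        pcc = pcc_from_fit(fit, p.pcc_target_rate) if ok else np.nan
        out.append(PairResult(set_id=int(set_id), recall_rate=overall, fit=fit,
                              pcc_mv=pcc, retained=ok))
    return out


def results_frame(results: list[PairResult]) -> pd.DataFrame:
    return pd.DataFrame([dict(set_id=r.set_id, recall_rate=r.recall_rate,
                              a=r.fit.a, b=r.fit.b, r_squared=r.fit.r_squared,
                              pcc_mv=r.pcc_mv, retained=r.retained)
                         for r in results])


def pcc_recall_correlation(results: list[PairResult]) -> tuple[float, float]:
    """Pearson r (and regression p-value) between PCC and overall recall rate.

    Uses only retained sets; a full-scale experiment yields a strongly
    negative r (capable sets recall at voltages further from threshold).
    """
    kept = [r for r in results if r.retained]
    if len(kept) < 3:
        raise ValueError("need at least 3 retained sets")
    pcc = np.array([r.pcc_mv for r in kept])
    rate = np.array([r.recall_rate for r in kept])
    fit = stats.linregress(rate, pcc)
    return float(fit.rvalue), float(fit.pvalue)
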