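"""Decision-curve analysis: net benefit and net interventions avoided.

At an intervention threshold ``p_t`` the net benefit of a risk model is
``TP/N - (FP/N) * p_t / (1 - p_t)`` — true positives gained per person,
discounting false positives at the exchange rate implied by the
threshold (at 10%, nine false positives per true positive).  The
true-negative analogue is ``TN/N - (FN/N) * (1 - p_t)/p_t``.  Curves are
computed per cohort and averaged across cohorts, optionally recomputed
with profile-probability weights for per-profile curves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = np.round(np.arange(0.001, 0.1501, 0.001), 3)


def _counts(risk, outcome, p_t, w=None):
    risk = np.asarray(risk, dtype=float)
    y = np.asarray(outcome, dtype=float)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    treated = risk >= p_t
    tp = (w * (treated & (y == 1))).sum()
    fp = (w * (treated & (y == 0))).sum()
    tn = (w * (~treated & (y == 0))).sum()
    fn = (w * (~treated & (y == 1))).sum()
    return tp, fp, tn, fn, w.sum()


def net_benefit(risk, outcome, p_t: float, weights=None) -> float:
    """Net benefit (true-positive units) of treating at ``risk >= p_t``."""
    if not 0 < p_t < 1:
        raise ValueError("threshold must be in (0, 1)")
    tp, fp, _, _, n = _counts(risk, outcome, p_t, weights)
    return float(tp / n - (fp / n) * p_t / (1 - p_t))


def net_benefit_avoided(risk, outcome, p_t: float, weights=None) -> float:
    """Net interventions avoided (true-negative units)."""
    if not 0 < p_t < 1:
        raise ValueError("threshold must be in (0, 1)")
    _, _, tn, fn, n = _counts(risk, outcome, p_t, weights)
    return float(tn / n - (fn / n) * (1 - p_t) / p_t)


def decision_curve(models: dict, outcome, thresholds=None,
                   cohort_ids=None) -> pd.DataFrame:
    """Tidy net-benefit curves for several risk models plus references.

    ``models`` maps strategy name -> predicted risk vector.  When
    ``cohort_ids`` is given, curves are computed within each cohort and
    additionally averaged (unweighted) into ``cohort='pooled'`` rows;
    cohorts without events are skipped with a warning.  Treat-all and
    treat-none reference strategies are always included.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    y = np.asarray(outcome, dtype=float)
    ids = np.zeros(len(y)) if cohort_ids is None else np.asarray(cohort_ids)
    rows = []
    for c in np.unique(ids):
        m = ids == c
        if y[m].sum() == 0:
            warnings.warn(f"cohort {c!r} has no events; skipped")
            continue
        strategies = dict(models)
        strategies["treat_all"] = np.ones(int(m.sum()))
        strategies["treat_none"] = np.zeros(int(m.sum()))
        for name, risk in strategies.items():
            r = np.asarray(risk, dtype=float)
            r = r[m] if r.shape[0] == len(y) else r
            for t in thresholds:
                nb = net_benefit(r, y[m], t) if name != "treat_none" else 0.0
                nba = net_benefit_avoided(r, y[m], t) if name != "treat_all" else 0.0
                rows.append({"strategy": name, "threshold": float(t),
                             "net_benefit": nb, "nb_avoided": nba,
                             "cohort": c})
    df = pd.DataFrame(rows)
    pooled = (df.groupby(["strategy", "threshold"], as_index=False)
                [["net_benefit", "nb_avoided"]].mean())
    pooled["cohort"] = "pooled"
    return pd.concat([df, pooled], ignore_index=True)


def delta_per_10000(curves: pd.DataFrame, base: str, full: str,
                    p_t: float = 0.10, cohort="pooled"):
    """(additional TP, additional TN) per 10,000 individuals at ``p_t``."""
    sub = curves[(curves["cohort"] == cohort)
                 & (np.isclose(curves["threshold"], p_t))]
    nb = sub.set_index("strategy")["net_benefit"]
    nba = sub.set_index("strategy")["nb_avoided"]
    d_tp = 1e4 * (nb[full] - nb[base])
    d_tn = 1e4 * (nba[full] - nba[base])
    return float(d_tp), float(d_tn)


def profile_specific_curves(models: dict, outcome, alloc: pd.DataFrame,
                            thresholds=None, min_weight: float = 1.0) -> pd.DataFrame:
    """Per-profile decision curves with probability-weighted counts.

    Each TP/FP/TN/FN count is replaced by its allocation-probability
    weighted version; profiles with near-zero total weight are suppressed
    with a warning.  Weighted per-profile net benefits, averaged with the
    profile weights, recover the overall curve.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    P = np.asarray(alloc, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("allocation rows must sum to 1")
    y = np.asarray(outcome, dtype=float)
    rows = []
    for k, lab in enumerate(alloc.columns):
        w = P[:, k]
        if w.sum() < min_weight:
            warnings.warn(f"profile {lab!r} has near-zero weight; curve suppressed")
            continue
        for name, risk in models.items():
            for t in thresholds:
                rows.append({
                    "strategy": name, "profile": lab, "threshold": float(t),
                    "net_benefit": net_benefit(risk, y, t, weights=w),
                    "nb_avoided": net_benefit_avoided(risk, y, t, weights=w),
                    "weight": float(w.sum()),
                })
    return pd.DataFrame(rows)


def plot_decision_curves(curves: pd.DataFrame, cohort="pooled", ax=None):
    """Basic net-benefit plot, one line per strategy."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = curves[curves["cohort"] == cohort]
    for name, grp in sub.groupby("strategy"):
        ax.plot(grp["threshold"], grp["net_benefit"], label=name)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.legend(fontsize=8)
    return ax
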