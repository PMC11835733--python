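"""Probability-weighted profile estimates and cross-cohort pooling.

Every estimator here weights individuals by their profile allocation
probabilities, so estimates degenerate to plain subgroup statistics when
allocations are one-hot.  Weighted regressions use robust (sandwich)
standard errors since the weights are themselves estimated.  Per-cohort
estimates are pooled by fixed-effect (inverse-variance) or
DerSimonian-Laird random-effects meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_Z = sps.norm.ppf(0.975)


@dataclass
class ProfileEstimate:
    profile: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_effective: float
    scale: str = "identity"  # "identity" | "ratio"
    extra: dict = field(default_factory=dict)


@dataclass
class MetaResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    method: str
    q: float = float("nan")


def weighted_summary(values, probs) -> dict:
    """Weighted mean, SD, median and IQR of one variable in one profile.

    Quantiles use cumulative-weight interpolation at positions
    ``(cumw_i - w_i/2) / W``, which reproduces the plain median under
    equal weights.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(probs, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and probs must have the same length")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    W = w.sum()
    mean = float((w * x).sum() / W)
    if W > 1:
        sd = float(np.sqrt((w * (x - mean) ** 2).sum() / (W - 1)))
    else:
        sd = float("nan")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    pos = (np.cumsum(ws) - 0.5 * ws) / W
    q25, med, q75 = np.interp([0.25, 0.5, 0.75], pos, xs)
    return {"mean": mean, "sd": sd, "median": float(med),
            "q25": float(q25), "q75": float(q75), "n_effective": float(W)}


def weighted_slope(biomarker, bmi, covariates, probs, profile: str = "") -> ProfileEstimate:
    """Profile-specific biomarker change per BMI unit (weighted least squares).

    ``covariates`` is a DataFrame of adjustment columns (age, smoking).
    Allocation probabilities are the regression weights; SEs are
    heteroskedasticity-robust.
    """
    y = np.asarray(biomarker, dtype=float)
    w = np.asarray(probs, dtype=float)
    X = pd.DataFrame({"bmi": np.asarray(bmi, dtype=float)})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design in weighted_slope")
    res = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
    b, se = float(res.params["bmi"]), float(res.bse["bmi"])
    return ProfileEstimate(profile, b, se, b - _Z * se, b + _Z * se,
                           float(res.pvalues["bmi"]), float(w.sum()))


def weighted_prevalence_incidence(events, probs, followup=None,
                                  profile: str = "") -> ProfileEstimate:
    """Probability-weighted prevalence, or incidence rate when follow-up given.

    Prevalence: sum(case*p) / sum(p).  Incidence: sum(event*p) /
    sum(followup*p), per person-year.  CIs come from the weighted
    binomial/Poisson likelihood with Kish's effective sample size.
    """
    y = np.asarray(events, dtype=float)
    w = np.asarray(probs, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("events must be coded 0/1")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("invalid weights")
    if followup is None:
        W = w.sum()
        p = float((w * y).sum() / W)
        n_eff = W**2 / (w**2).sum()
        se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_eff))
        lo, hi = max(p - _Z * se, 0.0), min(p + _Z * se, 1.0)
        pv = float(2 * sps.norm.sf(abs(p - 0) / se)) if se > 0 else 0.0
        return ProfileEstimate(profile, p, se, lo, hi, pv, float(W))
    fu = np.asarray(followup, dtype=float)
    if np.any(fu <= 0):
        raise ValueError("follow-up times must be positive")
    pt = (w * fu).sum()
    if pt == 0:
        raise ValueError("zero weighted person-time")
    rate = float((w * y).sum() / pt)
    d_eff = (w * y).sum() ** 2 / max((w**2 * y).sum(), 1e-300)
    se_log = 1.0 / np.sqrt(max(d_eff, 1e-12))
    lo, hi = rate * np.exp(-_Z * se_log), rate * np.exp(_Z * se_log)
    return ProfileEstimate(profile, rate, float(rate * se_log), float(lo),
                           float(hi), float("nan"), float(w.sum()))


def _firth_logistic(y, X, w, max_iter=100, tol=1e-8):
    """Jeffreys-prior penalized weighted logistic regression (Newton)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = w * mu * (1 - mu)
        XtW = X.T * v
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * v
        score = X.T @ (w * (y - mu) + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


def profile_ratio(outcome, exposure_probs, reference_probs,
                  family: str = "binomial", followup=None,
                  profile: str = "") -> ProfileEstimate:
    """OR (binomial) or RR (Poisson) of a discordant vs the concordant profile.

    Each individual contributes twice — once to the exposure group with
    weight equal to the discordant allocation probability and once to the
    reference group with the concordant probability — in a weighted GLM
    with robust SEs.  Separation in the binomial model falls back to a
    Firth-style penalized fit (flagged in ``extra``).
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be coded 0/1")
    we = np.asarray(exposure_probs, dtype=float)
    wr = np.asarray(reference_probs, dtype=float)
    yy = np.concatenate([y, y])
    gg = np.concatenate([np.ones_like(y), np.zeros_like(y)])
    ww = np.concatenate([we, wr])
    keep = ww > 0
    yy, gg, ww = yy[keep], gg[keep], ww[keep]
    X = sm.add_constant(pd.DataFrame({"exposure": gg}))
    extra = {}
    if family == "binomial":
        fam = sm.families.Binomial()
        offset = None
    elif family == "poisson":
        fam = sm.families.Poisson()
        if followup is None:
            raise ValueError("poisson family requires follow-up times")
        fu = np.asarray(followup, dtype=float)
        offset = np.log(np.concatenate([fu, fu])[keep])
    else:
        raise ValueError("family must be 'binomial' or 'poisson'")
    try:
        res = sm.GLM(yy, X, family=fam, freq_weights=ww, offset=offset).fit(cov_type="HC0")
        b, se = float(res.params["exposure"]), float(res.bse["exposure"])
        converged = res.converged and abs(b) < 15
    except Exception:
        converged = False
    if not converged and family == "binomial":
        beta, ses = _firth_logistic(yy, X.to_numpy(), ww)
        b, se = float(beta[1]), float(ses[1])
        extra["firth"] = True
    elif not converged:
        raise RuntimeError("Poisson profile_ratio did not converge")
    z = b / se if se > 0 else np.inf
    return ProfileEstimate(profile, float(np.exp(b)), se,
                           float(np.exp(b - _Z * se)), float(np.exp(b + _Z * se)),
                           float(2 * sps.norm.sf(abs(z))), float(ww.sum()),
                           scale="ratio", extra=extra)


def fdr_adjust(estimates, alpha: float = 0.05):
    """Benjamini-Hochberg adjustment across a batch of estimates (in place)."""
    pv = np.array([e.pvalue for e in estimates])
    ok = np.isfinite(pv)
    flags = np.zeros(len(pv), dtype=bool)
    qv = np.full(len(pv), np.nan)
    if ok.any():
        rej, q, *_ = multipletests(pv[ok], alpha=alpha, method="fdr_bh")
        flags[ok], qv[ok] = rej, q
    for e, f, q in zip(estimates, flags, qv):
        e.extra["fdr_significant"] = bool(f)
        e.extra["qvalue"] = float(q)
    return estimates


def meta_analyze(estimates, ses=None, method: str = "random") -> MetaResult:
    """Inverse-variance pooling of per-cohort (log-scale) estimates.

    ``method='fixed'`` is plain inverse-variance; ``method='random'`` is
    DerSimonian-Laird: tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 /
    sum w)), then inverse-variance with v_i + tau^2.
    """
    if ses is None:  # allow a list of (estimate, se) pairs
        arr = np.asarray(estimates, dtype=float)
        est, se = arr[:, 0], arr[:, 1]
    else:
        est = np.asarray(estimates, dtype=float)
        se = np.asarray(ses, dtype=float)
    v = se**2
    w = 1.0 / v
    mu_fe = (w * est).sum() / w.sum()
    q = float((w * (est - mu_fe) ** 2).sum())
    k = len(est)
    if method == "fixed" or k == 1:
        tau2 = 0.0
        wr = w
        meth = "fixed" if method == "fixed" else method
    elif method == "random":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        wr = 1.0 / (v + tau2)
        meth = "random"
    else:
        raise ValueError("method must be 'fixed' or 'random'")
    mu = float((wr * est).sum() / wr.sum())
    se_p = float(np.sqrt(1.0 / wr.sum()))
    return MetaResult(mu, se_p, mu - _Z * se_p, mu + _Z * se_p,
                      float(tau2), method, q=q)


def estimates_to_frame(estimates, cohort: str = "pooled") -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "profile": e.profile, "estimate": e.estimate, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
            "n_effective": e.n_effective, "scale": e.scale, "cohort": cohort,
            "fdr_significant": e.extra.get("fdr_significant"),
        })
    return pd.DataFrame(rows)
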