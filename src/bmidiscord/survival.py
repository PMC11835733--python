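"""Added predictive value of profiles via log-contrast Cox models.

Allocation probabilities sum to 1 and cannot enter a regression directly;
they are represented as log-ratios against the concordant reference
profile (the log-contrast transform of compositional data analysis).
Nested Cox proportional-hazards models with and without the log-ratio
terms are compared by likelihood-ratio test, likelihood-based explained
variation and the difference in Harrell's C.  Risk shifts (moving
probability mass from the concordant to a discordant profile, with the
consistent biomarker changes) are translated into hazard ratios via the
fitted coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy import optimize, stats as sps

from .cluster import MixtureModel
from .simulate import CONCORDANT
from .stats import ProfileEstimate

_Z = sps.norm.ppf(0.975)


def log_contrast(alloc: pd.DataFrame, reference: str = CONCORDANT,
                 floor: float = 1e-6) -> pd.DataFrame:
    """Log-ratios of discordant probabilities to the reference profile.

    Probabilities are floored at ``floor`` and renormalized first, so the
    transform is finite even for one-hot rows.  Columns are named
    ``lr_<profile>``.
    """
    if reference not in alloc.columns:
        raise ValueError(f"reference profile {reference!r} not in allocation matrix")
    P = np.clip(np.asarray(alloc, dtype=float), floor, None)
    P = P / P.sum(axis=1, keepdims=True)
    cols = list(alloc.columns)
    ref = cols.index(reference)
    out = {}
    for j, c in enumerate(cols):
        if j == ref:
            continue
        out[f"lr_{c}"] = np.log(P[:, j] / P[:, ref])
    return pd.DataFrame(out, index=alloc.index)


def _efron_null_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood of the null (beta = 0) Cox model."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    ll = 0.0
    i = 0
    while i < n:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d > 0:
            nrisk = n - i
            ll -= np.log(nrisk - np.arange(d)).sum()
        i = j
    return float(ll)


@dataclass
class SurvivalFit:
    """Fitted Cox model with the pieces needed for nested comparison."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    loglik_null: float
    concordance: float
    n: int
    n_events: int
    covariates: list
    duration: np.ndarray = field(repr=False)
    event: np.ndarray = field(repr=False)
    lp: np.ndarray = field(repr=False)
    model: object = field(default=None, repr=False)
    penalizer: float = 0.0

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def predict_risk(self, X: pd.DataFrame, horizon: float) -> np.ndarray:
        """Absolute event risk by ``horizon`` via the baseline survival."""
        sf = self.model.predict_survival_function(X[self.covariates], times=[horizon])
        return 1.0 - sf.iloc[0].to_numpy()


def fit_cox(design: pd.DataFrame, duration_col: str, event_col: str,
            covariates=None, penalizer: float = 0.0,
            l1_ratio: float = 0.0) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling, Harrell's C).

    Rows with prevalent disease must be excluded upstream.  Requires
    strictly positive follow-up times and at least 10 events.
    """
    if covariates is None:
        covariates = [c for c in design.columns if c not in (duration_col, event_col)]
    covariates = list(covariates)
    t = design[duration_col].to_numpy(dtype=float)
    e = design[event_col].to_numpy(dtype=int)
    if np.any(t <= 0):
        raise ValueError("follow-up times must be strictly positive")
    if e.sum() < 10:
        raise ValueError(f"too few events ({e.sum()}); need at least 10")
    df = design[[duration_col, event_col] + covariates]
    cph = CoxPHFitter(penalizer=penalizer, l1_ratio=l1_ratio)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    lp = cph.predict_log_partial_hazard(df).to_numpy(dtype=float)
    return SurvivalFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        loglik=float(cph.log_likelihood_),
        loglik_null=_efron_null_loglik(t, e),
        concordance=float(cph.concordance_index_),
        n=len(df), n_events=int(e.sum()),
        covariates=covariates, duration=t, event=e, lp=lp, model=cph,
        penalizer=penalizer,
    )


@dataclass
class NestedComparison:
    lrt: float
    df: int
    pvalue: float
    r2_base: float
    r2_full: float
    added_variance_pct: float       # 100*(R2_full - R2_base)/R2_full
    added_variance_pct_base: float  # same difference against the base R2
    c_base: float
    c_full: float
    delta_c: float
    delta_c_se: float
    delta_c_pvalue: float

    def summary_row(self) -> dict:
        return {
            "lrt_p": self.pvalue, "added_variance_pct": self.added_variance_pct,
            "c_base": self.c_base, "c_full": self.c_full,
            "delta_c": self.delta_c, "delta_c_p": self.delta_c_pvalue,
        }


def compare_nested(base: SurvivalFit, full: SurvivalFit,
                   n_boot: int = 200, seed: int = 0) -> NestedComparison:
    """Likelihood-ratio test, added explained variation and Delta-C.

    Explained variation per model is the likelihood-ratio based
    ``R^2 = 1 - exp(-LR_vs_null / n)``; the profile contribution is the
    difference as a percentage of the full-model R^2.  The SE of the
    C-statistic difference comes from a paired bootstrap over individuals
    (risk scores held fixed), capturing the covariance between the two
    C-statistics.
    """
    if not set(base.covariates) <= set(full.covariates):
        raise ValueError("models are not nested (base covariates not a subset)")
    if base.n != full.n or base.n_events != full.n_events:
        raise ValueError("nested models must be fitted on the same rows")
    df = len(full.covariates) - len(base.covariates)
    lrt = 2.0 * (full.loglik - base.loglik)
    if lrt < -1e-6:
        warnings.warn("full model has lower likelihood than base; LRT clipped at 0")
    lrt = max(lrt, 0.0)
    p = float(sps.chi2.sf(lrt, df)) if df > 0 else 1.0

    n = full.n
    r2b = 1.0 - np.exp(-2.0 * (base.loglik - base.loglik_null) / n)
    r2f = 1.0 - np.exp(-2.0 * (full.loglik - full.loglik_null) / n)
    added = 100.0 * (r2f - r2b) / r2f if r2f > 0 else 0.0
    added_base = 100.0 * (r2f - r2b) / r2b if r2b > 0 else float("inf")

    dc = full.concordance - base.concordance
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if full.event[idx].sum() == 0:
            reps[b] = 0.0
            continue
        cb = concordance_index(full.duration[idx], -base.lp[idx], full.event[idx])
        cf = concordance_index(full.duration[idx], -full.lp[idx], full.event[idx])
        reps[b] = cf - cb
    se = float(reps.std(ddof=1))
    pz = float(2 * sps.norm.sf(abs(dc) / se)) if se > 0 else float(dc == 0)
    return NestedComparison(float(lrt), df, p, float(r2b), float(r2f),
                            float(added), float(added_base),
                            base.concordance, full.concordance,
                            float(dc), se, pz)


def lasso_cox(design: pd.DataFrame, duration_col: str, event_col: str,
              covariates=None, n_folds: int = 10, lambdas=None,
              seed: int = 0) -> SurvivalFit:
    """L1-penalized Cox fit with the penalty chosen by cross-validation.

    The penalty path is evaluated by K-fold cross-validated partial
    log-likelihood deviance (seeded fold assignment); the refit at the
    best penalty is returned.  Covariates should be on comparable scales.
    """
    if covariates is None:
        covariates = [c for c in design.columns if c not in (duration_col, event_col)]
    covariates = list(covariates)
    e = design[event_col].to_numpy(dtype=int)
    if e.sum() < n_folds:
        raise ValueError("need at least one event per fold")
    if lambdas is None:
        lambdas = np.geomspace(1.0, 1e-4, 13)
    from sklearn.model_selection import KFold

    df = design[[duration_col, event_col] + covariates]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(lambdas))
    for tr, te in kf.split(df):
        train, test = df.iloc[tr], df.iloc[te]
        for i, lam in enumerate(lambdas):
            cph = CoxPHFitter(penalizer=float(lam), l1_ratio=1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(train, duration_col=duration_col, event_col=event_col)
                score = cph.score(test, scoring_method="log_likelihood")
            dev[i] += -2.0 * score * len(test)
    best = float(lambdas[int(np.argmin(dev))])
    fit = fit_cox(design, duration_col, event_col, covariates,
                  penalizer=best, l1_ratio=1.0)
    if np.all(np.abs(fit.params.to_numpy()) < 1e-5):
        warnings.warn("all lasso coefficients are zero at the selected penalty")
    fit.penalizer = best
    return fit


@dataclass
class ShiftPoint:
    """A point on the concordant-to-profile ray with its raw biomarkers."""

    biomarkers: pd.Series
    residual: np.ndarray
    t: float
    posterior: pd.Series


def _posterior_on_ray(mixture: MixtureModel, target: str, t: float) -> np.ndarray:
    mu = next(c.mean for c in mixture.components if c.label == target)
    from .cluster import allocate

    return allocate(mixture, (t * mu)[None, :]).iloc[0].to_numpy()


def shift_biomarkers(mixture: MixtureModel, target: str, target_prob: float,
                     fit_params: pd.DataFrame, age: float = 55.0,
                     bmi: float = 30.0, smoking: float = 0.0,
                     t_max: float = 3.0, tol: float = 1e-8) -> ShiftPoint:
    """Raw biomarker values at a given discordant profile probability.

    Finds the residual vector on the segment from the concordant center
    (0) toward the target component mean whose posterior probability for
    the target equals ``target_prob`` (monotone root finding), then maps
    the residuals back to the raw biomarker scale for an individual with
    the fixed covariates via the stored residualization parameters.
    """
    if not 0 < target_prob < 1:
        raise ValueError("target_prob must lie strictly between 0 and 1")
    labels = mixture.labels
    if target not in labels or target == CONCORDANT:
        raise ValueError(f"{target!r} is not a discordant profile of the mixture")
    k = labels.index(target)

    def g(t):
        return _posterior_on_ray(mixture, target, t)[k] - target_prob

    g0, g1 = g(0.0), g(t_max)
    if g0 * g1 > 0:
        lo = target_prob if g0 > 0 else _posterior_on_ray(mixture, target, 0.0)[k]
        hi = _posterior_on_ray(mixture, target, t_max)[k]
        raise ValueError(
            f"target_prob={target_prob} unreachable on the segment; attainable "
            f"range is [{min(lo, hi):.4g}, {max(lo, hi):.4g}]"
        )
    t_star = optimize.brentq(g, 0.0, t_max, xtol=tol)
    mu = next(c.mean for c in mixture.components if c.label == target)
    z = t_star * mu
    vals = {}
    for j, b in enumerate(fit_params.index):
        p = fit_params.loc[b]
        dev = z[j] * p["scale"] + p["center"]
        bmi_adj = bmi - (p["b_int"] + p["b_age"] * age + p["b_smk"] * smoking)
        vals[b] = (p["s1_int"] + p["age"] * age + p["smoking"] * smoking
                   + p["s2_int"] + p["bmi"] * bmi_adj + dev)
    post = pd.Series(_posterior_on_ray(mixture, target, t_star), index=labels)
    return ShiftPoint(pd.Series(vals), z, float(t_star), post)


def shift_risk(full: SurvivalFit, mixture: MixtureModel,
               fit_params: pd.DataFrame, target: str, delta: float = 0.10,
               baseline_probs=None, age: float = 55.0, bmi: float = 30.0,
               smoking: float = 0.0, floor: float = 1e-6) -> ProfileEstimate:
    """Hazard ratio of moving ``delta`` probability mass to a discordant profile.

    Compares two covariate vectors: baseline profile probabilities
    (population mixture weights by default) versus the same with ``delta``
    moved from the concordant to the target profile, the other discordant
    profiles held at their population values.  Each vector carries its
    consistent biomarker values from :func:`shift_biomarkers`; the HR is
    ``exp`` of the linear-predictor difference, with a delta-method CI
    from the coefficient covariance.
    """
    labels = mixture.labels
    if baseline_probs is None:
        p0 = mixture.weights.astype(float).copy()
    else:
        p0 = np.asarray(baseline_probs, dtype=float).copy()
    kc = labels.index(CONCORDANT)
    kt = labels.index(target)
    p1 = p0.copy()
    p1[kt] += delta
    p1[kc] -= delta
    if np.any(p1 <= 0) or np.any(p1 >= 1):
        raise ValueError("delta pushes a profile probability outside (0, 1)")

    def logratios(p):
        p = np.clip(p, floor, None)
        p = p / p.sum()
        return {f"lr_{labels[j]}": np.log(p[j] / p[kc])
                for j in range(len(labels)) if j != kc}

    z0, z1 = logratios(p0), logratios(p1)
    b0 = shift_biomarkers(mixture, target, float(p0[kt]), fit_params,
                          age=age, bmi=bmi, smoking=smoking)
    b1 = shift_biomarkers(mixture, target, float(p1[kt]), fit_params,
                          age=age, bmi=bmi, smoking=smoking)
    dx = np.zeros(len(full.covariates))
    for i, c in enumerate(full.covariates):
        if c in z0:
            dx[i] = z1[c] - z0[c]
        elif c in b0.biomarkers.index:
            dx[i] = b1.biomarkers[c] - b0.biomarkers[c]
    beta = full.params.reindex(full.covariates).to_numpy()
    dlp = float(beta @ dx)
    Sig = full.cov.reindex(index=full.covariates, columns=full.covariates).to_numpy()
    se = float(np.sqrt(dx @ Sig @ dx))
    z = dlp / se if se > 0 else np.inf
    return ProfileEstimate(target, float(np.exp(dlp)), se,
                           float(np.exp(dlp - _Z * se)), float(np.exp(dlp + _Z * se)),
                           float(2 * sps.norm.sf(abs(z))), float(full.n),
                           scale="ratio",
                           extra={"delta": delta, "dlp": dlp})
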