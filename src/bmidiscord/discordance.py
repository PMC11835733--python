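"""Quantifying BMI-biomarker discordance.

Within a sex stratum, each biomarker is residualized against BMI after
adjusting for age and current smoking (two-stage least squares in the
Frisch-Waugh sense: the age/smoking-adjusted biomarker is regressed on
BMI).  Residuals are centered and scaled to unit standard deviation, and
multivariate discordance is scored as the squared Mahalanobis distance of
the standardized residual vector, which follows a chi-square distribution
(df = number of biomarkers) under multivariate normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BIOMARKERS

#: Columns that must be complete before clustering.
REQUIRED = ["age", "smoking", "bmi"] + BIOMARKERS


def validate_cohort(cohort: pd.DataFrame, biomarkers=BIOMARKERS) -> None:
    missing = [c for c in ["age", "smoking", "bmi"] + list(biomarkers) if c not in cohort]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    if cohort[["age", "bmi"]].le(0).any().any():
        raise ValueError("age and bmi must be strictly positive")
    if cohort[["age", "smoking", "bmi"] + list(biomarkers)].isna().any().any():
        raise ValueError("missing values in clustering columns; QC first")


def remove_outliers(cohort: pd.DataFrame, sd_threshold: float = 5.0,
                    biomarkers=BIOMARKERS):
    """Drop individuals with any biomarker beyond ``sd_threshold`` SDs.

    Values that far from the stratum mean are treated as erroneous
    measurements; the whole row is removed (complete-case analysis).

    Returns
    -------
    (clean, log) : (pandas.DataFrame, dict)
        ``log`` maps each biomarker to the number of individuals flagged
        on that column, plus ``n_removed`` / ``n_kept`` totals.
    """
    cols = list(biomarkers)
    X = cohort[cols].to_numpy(dtype=float)
    z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    bad = np.abs(z) > sd_threshold
    log = {c: int(bad[:, j].sum()) for j, c in enumerate(cols)}
    keep = ~bad.any(axis=1)
    log["n_removed"] = int((~keep).sum())
    log["n_kept"] = int(keep.sum())
    if log["n_kept"] == 0:
        raise ValueError("outlier removal left no individuals")
    return cohort.loc[keep].reset_index(drop=True), log


@dataclass
class ResidualMatrix:
    """Standardized BMI-discordance deviations with their fitted parameters.

    ``values`` is N x 10 in z-units; ``fit_params`` stores, per biomarker,
    the two regression stages and the centering/scaling constants so the
    transformation can be re-applied to new raw data (validation cohorts,
    biomarker back-mapping).
    """

    values: np.ndarray
    #: index: biomarker; columns: s1_int, age, smoking (biomarker stage),
    #: b_int, b_age, b_smk (BMI adjustment), s2_int, bmi, center, scale
    fit_params: pd.DataFrame
    stratum: str = ""
    ids: np.ndarray | None = None
    biomarkers: list = field(default_factory=lambda: list(BIOMARKERS))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.biomarkers)
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        return df

    def apply(self, cohort: pd.DataFrame) -> np.ndarray:
        """Re-apply the stored residualization to (possibly new) raw data.

        Uses the same arithmetic as the fit, so on the fitting cohort the
        result is bit-identical to ``values``.
        """
        age = cohort["age"].to_numpy(dtype=float)
        smk = cohort["smoking"].to_numpy(dtype=float)
        bmi = cohort["bmi"].to_numpy(dtype=float)
        out = np.empty((len(cohort), len(self.biomarkers)))
        for j, b in enumerate(self.biomarkers):
            p = self.fit_params.loc[b]
            y = cohort[b].to_numpy(dtype=float)
            r1 = y - (p["s1_int"] + p["age"] * age + p["smoking"] * smk)
            bmi_adj = bmi - (p["b_int"] + p["b_age"] * age + p["b_smk"] * smk)
            dev = r1 - (p["s2_int"] + p["bmi"] * bmi_adj)
            out[:, j] = (dev - p["center"]) / p["scale"]
        return out


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def residualize(cohort: pd.DataFrame, biomarkers=BIOMARKERS,
                stratum: str | None = None) -> ResidualMatrix:
    """Residualize each biomarker against BMI with age/smoking adjustment.

    Two-stage least squares in the Frisch-Waugh sense: stage 1 partials
    age and smoking out of the biomarker (and out of BMI), stage 2
    regresses the adjusted biomarker on the adjusted BMI, so the
    deviations equal the residuals of the joint regression on age,
    smoking and BMI.  Deviations are centered and scaled to unit SD on
    this stratum.  A constant smoking column is dropped with a warning.
    """
    validate_cohort(cohort, biomarkers)
    n = len(cohort)
    age = cohort["age"].to_numpy(dtype=float)
    smk = cohort["smoking"].to_numpy(dtype=float)
    bmi = cohort["bmi"].to_numpy(dtype=float)

    smoking_constant = np.ptp(smk) == 0
    if smoking_constant:
        warnings.warn("smoking column is constant; dropped from adjustment")

    ones = np.ones(n)
    X1 = np.column_stack([ones, age] if smoking_constant else [ones, age, smk])
    bcoef = _ols(bmi, X1)
    b_smk = 0.0 if smoking_constant else bcoef[2]
    bmi_adj = bmi - (bcoef[0] + bcoef[1] * age + b_smk * smk)
    X2 = np.column_stack([ones, bmi_adj])

    rows = {}
    values = np.empty((n, len(biomarkers)))
    for j, b in enumerate(biomarkers):
        y = cohort[b].to_numpy(dtype=float)
        a = _ols(y, X1)
        c = _ols(y - X1 @ a, X2)
        center_scale_y = max(1.0, float(np.std(y)))
        # re-apply through the same arithmetic as ResidualMatrix.apply so
        # stored parameters reproduce values bit-identically
        a_smk = 0.0 if smoking_constant else a[2]
        r1 = y - (a[0] + a[1] * age + a_smk * smk)
        dev = r1 - (c[0] + c[1] * bmi_adj)
        center = dev.mean()
        scale = dev.std(ddof=1)
        if scale <= 1e-10 * center_scale_y:
            raise ValueError(f"biomarker {b!r} has zero residual variance")
        values[:, j] = (dev - center) / scale
        rows[b] = dict(s1_int=a[0], age=a[1], smoking=a_smk,
                       b_int=bcoef[0], b_age=bcoef[1], b_smk=b_smk,
                       s2_int=c[0], bmi=c[1], center=center, scale=scale)

    fp = pd.DataFrame.from_dict(rows, orient="index")
    ids = cohort["id"].to_numpy() if "id" in cohort else np.arange(n)
    sex = stratum
    if sex is None:
        sex = str(cohort["sex"].iloc[0]) if "sex" in cohort else ""
    return ResidualMatrix(values=values, fit_params=fp, stratum=sex,
                          ids=ids, biomarkers=list(biomarkers))


def mahalanobis_discordance(residuals: ResidualMatrix | np.ndarray,
                            cov: np.ndarray | None = None) -> pd.DataFrame:
    """Squared Mahalanobis distance to the BMI-based expectation.

    The distance is taken to the multivariate normal centered at zero with
    the stratum residual covariance (estimated unless ``cov`` is given);
    p-values are upper-tail chi-square with df = number of biomarkers.
    """
    X = residuals.values if isinstance(residuals, ResidualMatrix) else np.asarray(residuals, float)
    d = X.shape[1]
    if cov is None:
        cov = np.cov(X, rowvar=False)
    cov = np.asarray(cov, dtype=float)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("residual covariance is singular") from e
    sol = np.linalg.solve(L, X.T)
    d2 = np.einsum("ij,ij->j", sol, sol)
    pval = stats.chi2.sf(d2, df=d)
    return pd.DataFrame({"d2": d2, "pvalue": pval})


def excess_discordance_test(pvalues, alpha: float = 0.05):
    """Observed fraction of substantial discordance vs the nominal rate.

    Under multivariate normality a fraction ``alpha`` of individuals is
    expected below the critical threshold; the observed proportion is
    compared with an exact binomial test.

    Returns ``(observed_proportion, binomial_p)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no discordance scores supplied")
    k = int((p < alpha).sum())
    res = stats.binomtest(k, p.size, alpha)
    return k / p.size, res.pvalue
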