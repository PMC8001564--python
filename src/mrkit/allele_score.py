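"""Individual-level MR replication arm: allele scores, CKD-EPI eGFR, and
covariate-adjusted linear models.

An allele score for an exposure is the dosage-weighted sum of instrument
effect sizes, score_i = sum_j dosage_ij * beta_j, standardized so results
read "eGFR change per 1 SD of the allele score". The score is regressed on
eGFR with either the main covariate set (age, sex, genotyping batch, first
10 genetic principal components) or the clinical sensitivity set that adds
hypertension, diabetes and obesity flags. Analyses are complete-case per
model; the number of individuals actually used is reported.

eGFR is computed from serum creatinine with the CKD-EPI 2009 creatinine
equation, race coefficient omitted by default (2021 convention; a flag
restores the 2009 race term for strict replication of older studies).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, ConfigurationError, DataError, DomainError, MRKitError
from .summary_data import InstrumentSet

__all__ = [
    "CohortData",
    "ScoreResult",
    "LinearFit",
    "allele_score",
    "egfr_ckd_epi",
    "creatinine_for_egfr",
    "fit_linear",
    "score_mr",
    "MAIN_COVARIATES",
    "CLINICAL_COVARIATES",
]

logger = logging.getLogger(__name__)

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]
MAIN_COVARIATES = ["age", "sex", "batch"] + PC_COLUMNS
CLINICAL_COVARIATES = ["hypertension", "diabetes", "obesity"]


@dataclass
class CohortData:
    """Individual-level cohort: dosages, phenotype and covariates.

    ``dosages``: individuals x SNPs, values in [0, 2], columns are rsids.
    ``snp_meta``: per-SNP effect allele and frequency, indexed by rsid.
    ``phenotype``: one row per individual (same index as dosages) with
    columns among ``egfr`` (mL/min/1.73 m^2), ``creatinine`` (mg/dL),
    ``age`` (years), ``sex`` (0 male / 1 female), ``batch`` (categorical),
    ``pc1``..``pc10``, ``hypertension``/``diabetes``/``obesity`` (0/1).
    Missing values are NaN, never sentinel numbers.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame
    phenotype: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.phenotype.index):
            raise DataError("dosage and phenotype tables must share the same individuals")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise DataError("dosages must lie in [0, 2]")
        missing_meta = set(self.dosages.columns) - set(self.snp_meta.index)
        if missing_meta:
            raise DataError(f"snp_meta missing entries for {sorted(missing_meta)[:5]}")

    @property
    def n_individuals(self) -> int:
        return len(self.phenotype)


@dataclass
class ScoreResult:
    """Allele-score regression result for one exposure and one model."""

    exposure_name: str
    model: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_used: int


@dataclass
class LinearFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    n_used: int
    df_resid: float


def allele_score(
    cohort: CohortData,
    instrument: InstrumentSet,
    standardize: bool = True,
    missing_snp: Literal["error", "drop"] = "error",
) -> pd.Series:
    """Per-individual weighted allele score for an exposure instrument.

    Cohort SNPs stored on the opposite allele are flip-corrected
    (dosage -> 2 - dosage) before weighting. With ``standardize`` the score
    is centered and scaled to unit SD.
    """
    cols, betas, inst_ea_list = [], [], []
    for v in instrument.variants:
        if v.rsid not in cohort.dosages.columns:
            if missing_snp == "error":
                raise ConfigurationError(f"instrument SNP {v.rsid} absent from cohort dosages")
            logger.warning("allele_score: dropping %s (absent from cohort)", v.rsid)
            continue
        cols.append(v.rsid)
        betas.append(v.beta)
        inst_ea_list.append(v.effect_allele)
    if not cols:
        raise ConfigurationError("no instrument SNPs present in cohort")
    dos = cohort.dosages[cols].to_numpy(dtype=float).copy()
    meta_ea = cohort.snp_meta.loc[cols, "effect_allele"].astype(str).str.upper().to_numpy()
    inst_ea = np.array(inst_ea_list)
    flip = meta_ea != inst_ea
    dos[:, flip] = 2.0 - dos[:, flip]
    score = dos @ np.asarray(betas, dtype=float)
    s = pd.Series(score, index=cohort.dosages.index, name=f"score_{instrument.exposure_name}")
    if standardize:
        sd = s.std(ddof=1)
        if not sd > 0:
            raise DomainError("allele score has zero variance; cannot standardize")
        s = (s - s.mean()) / sd
    return s


def egfr_ckd_epi(creatinine, age, female, race_black=False):
    """CKD-EPI 2009 creatinine eGFR (mL/min/1.73 m^2), race term off by default.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [if female] (* 1.159 if the 2009 race term is enabled),
    with k = 0.7 (female) / 0.9 (male) and a = -0.329 / -0.411.
    """
    scr = np.asarray(creatinine, dtype=float)
    age_a = np.asarray(age, dtype=float)
    fem = np.asarray(female, dtype=bool)
    if np.any(scr <= 0) or np.any(age_a <= 0):
        raise DomainError("creatinine and age must be positive")
    kappa = np.where(fem, 0.7, 0.9)
    alpha = np.where(fem, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age_a
        * np.where(fem, 1.018, 1.0)
    )
    if race_black:
        egfr = egfr * 1.159
    return float(egfr) if egfr.ndim == 0 else egfr


def creatinine_for_egfr(egfr, age, female, race_black=False):
    """Invert :func:`egfr_ckd_epi`: the serum creatinine that yields ``egfr``.

    The equation is a strictly decreasing, piecewise power law in
    creatinine, so the inverse is closed-form on each side of the knot at
    Scr = kappa.
    """
    egfr_a = np.asarray(egfr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    fem = np.asarray(female, dtype=bool)
    if np.any(egfr_a <= 0) or np.any(age_a <= 0):
        raise DomainError("egfr and age must be positive")
    kappa = np.where(fem, 0.7, 0.9)
    alpha = np.where(fem, -0.329, -0.411)
    base = egfr_a / (
        141.0 * 0.993**age_a * np.where(fem, 1.018, 1.0) * (1.159 if race_black else 1.0)
    )
    # base > 1 corresponds to Scr < kappa (the low-creatinine branch).
    scr = np.where(base > 1.0, kappa * base ** (1.0 / alpha), kappa * base ** (-1.0 / 1.209))
    return float(scr) if scr.ndim == 0 else scr


def fit_linear(response: pd.Series, design: pd.DataFrame) -> LinearFit:
    """OLS with complete-case row handling and explicit rank checking.

    Incomplete rows (NaN in the response or any design column) are dropped
    first; the remaining design must be full column rank, otherwise a
    :class:`CollinearityError` names the offending columns. The fit itself
    uses a QR-based least squares; SEs use the unbiased residual-variance
    estimator and p-values the t distribution on n - k df.
    """
    df = pd.concat([response.rename("__y__"), design], axis=1).dropna()
    y = df["__y__"].to_numpy(dtype=float)
    X = df.drop(columns="__y__")
    Xv = X.to_numpy(dtype=float)
    n, k = Xv.shape
    if n <= k:
        raise DataError(f"too few complete cases ({n}) for {k} design columns")
    # Column-scaled QR rank check so the error can name the culprits.
    norms = np.linalg.norm(Xv, axis=0)
    norms[norms == 0] = 1.0
    r_diag = np.abs(np.diag(np.linalg.qr(Xv / norms, mode="r")))
    tol = max(n, k) * np.finfo(float).eps
    bad = [str(c) for c, d in zip(X.columns, r_diag) if d < tol * r_diag.max()]
    if bad:
        raise CollinearityError(bad)
    res = sm.OLS(y, Xv).fit()
    names = list(X.columns)
    ci = res.conf_int(alpha=0.05)
    return LinearFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        conf_int=pd.DataFrame(ci, index=names, columns=["low", "high"]),
        n_used=n,
        df_resid=float(res.df_resid),
    )


def _egfr_series(cohort: CohortData) -> pd.Series:
    """Outcome eGFR: the recorded value, else CKD-EPI from creatinine."""
    ph = cohort.phenotype
    egfr = ph["egfr"].copy() if "egfr" in ph.columns else pd.Series(np.nan, index=ph.index)
    if "creatinine" in ph.columns:
        need = egfr.isna() & ph["creatinine"].notna()
        if need.any():
            egfr.loc[need] = egfr_ckd_epi(
                ph.loc[need, "creatinine"], ph.loc[need, "age"], ph.loc[need, "sex"] == 1
            )
    if egfr.notna().sum() == 0:
        raise DataError("no individual has an eGFR (or creatinine) value")
    return egfr.rename("egfr")


def _design_matrix(cohort: CohortData, score: pd.Series, model: str) -> pd.DataFrame:
    covars = list(MAIN_COVARIATES)
    if model == "clinical_adjusted":
        covars += CLINICAL_COVARIATES
    elif model != "main":
        raise ConfigurationError(f"unknown model {model!r}; use 'main' or 'clinical_adjusted'")
    missing = [c for c in covars if c not in cohort.phenotype.columns]
    if missing:
        raise ConfigurationError(f"cohort phenotype table lacks covariate column(s): {missing}")
    ph = cohort.phenotype
    parts = [pd.Series(1.0, index=ph.index, name="const"), score.rename("score")]
    for c in covars:
        if c == "batch":
            dummies = pd.get_dummies(ph["batch"], prefix="batch", drop_first=True, dtype=float)
            # all-NaN-safe: get_dummies drops NaN rows implicitly -> reinstate NaN
            dummies = dummies.reindex(ph.index)
            dummies[ph["batch"].isna()] = np.nan
            parts.append(dummies)
        else:
            parts.append(ph[c].astype(float))
    return pd.concat(parts, axis=1)


def score_mr(
    cohort: CohortData,
    instrument: InstrumentSet,
    model: Literal["main", "clinical_adjusted"] = "main",
    standardize: bool = True,
) -> ScoreResult:
    """Allele-score MR: regress eGFR on the standardized score + covariates.

    ``main`` adjusts for age, sex, genotyping batch and the first 10
    principal components; ``clinical_adjusted`` additionally adjusts for
    hypertension, diabetes and obesity. Complete-case per model; the score
    coefficient is reported per 1 SD of the allele score on the raw eGFR
    scale.
    """
    score = allele_score(cohort, instrument, standardize=standardize)
    y = _egfr_series(cohort)
    X = _design_matrix(cohort, score, model)
    fit = fit_linear(y, X)
    return ScoreResult(
        exposure_name=instrument.exposure_name,
        model=model,
        beta=float(fit.params["score"]),
        se=float(fit.bse["score"]),
        ci_low=float(fit.conf_int.loc["score", "low"]),
        ci_high=float(fit.conf_int.loc["score", "high"]),
        pval=float(fit.pvalues["score"]),
        n_used=fit.n_used,
    )
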