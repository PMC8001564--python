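"""Synthetic summary-level and individual-level data generators.

These emulate the statistical structure the MR analysis assumes, so every
pipeline stage can be exercised without downloading GWAS or cohort data.

Summary level: per-SNP true instrument effects gamma_j (by default the
packaged homocysteine per-SD effect sizes, discovery n = 44,147), outcome
effects theta*gamma_j plus an optional direct (pleiotropic) effect alpha_j
for a configurable fraction of invalid instruments, and sampling noise with
standard errors from the per-allele variance approximation
se^2 ~ 1/(2*eaf*(1-eaf)*n). The outcome GWAS size defaults to 567,460
(the CKDGen European log-eGFR meta-analysis scale) and theta defaults to
-0.0095 log-eGFR per SD (about a -0.95% eGFR change), so recovery tests
run at the magnitudes the real analysis operates at. Optional allele
scrambling re-expresses outcome records on the opposite allele to exercise
harmonization.

Individual level: genotypes Binomial(2, eaf), an exposure built from
standardized genotypes plus a shared normal confounder U (the minimal
structure that biases naive observational regression while leaving MR
consistent), a log-normal eGFR centered on median ~92.5 mL/min/1.73 m^2,
creatinine back-derived through the CKD-EPI equation, and age/sex/batch/
PC/comorbidity covariates in the ranges of a 40-69-year-old population
cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .allele_score import CohortData, creatinine_for_egfr
from .errors import ConfigurationError
from .summary_data import (
    GWAS_SAMPLE_SIZES,
    InstrumentSet,
    VariantAssociation,
    load_instrument_fixture,
    pval_from_beta_se,
)

__all__ = [
    "SummarySimConfig",
    "CohortSimConfig",
    "SummaryTruth",
    "CohortTruth",
    "simulate_summary",
    "simulate_outcome_for_instruments",
    "simulate_cohort",
]

# Non-palindromic allele pairs assigned to simulated SNPs.
_ALLELE_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass
class SummarySimConfig:
    """Generative parameters for two-sample summary statistics.

    ``noise_scale`` multiplies the sampling noise (0 gives noise-free
    effects while keeping the reported SEs, useful for exact-recovery
    checks). ``inside_violation`` is the correlation between pleiotropic
    effects and instrument strength (0 = InSIDE holds).
    """

    seed: int
    m_snps: int = 16
    theta: float = -0.0095
    gamma_source: str = "fixture"  # packaged homocysteine strengths, or "random"
    n_exp: int = GWAS_SAMPLE_SIZES["homocysteine"]
    n_out: int = 567460
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: float = 0.0
    prop_invalid: float = 0.0
    eaf_range: tuple[float, float] = (0.1, 0.9)
    prop_palindromic: float = 0.0
    allele_scramble: bool = False
    noise_scale: float = 1.0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.m_snps < 1:
            raise ConfigurationError("m_snps must be >= 1")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ConfigurationError("prop_invalid must be in [0, 1]")
        if not 0.0 <= self.prop_palindromic <= 1.0:
            raise ConfigurationError("prop_palindromic must be in [0, 1]")
        if self.n_exp < 10 or self.n_out < 10:
            raise ConfigurationError("n_exp and n_out must be >= 10")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("eaf_range must satisfy 0 < lo < hi < 1")
        if not -1.0 <= self.inside_violation <= 1.0:
            raise ConfigurationError("inside_violation is a correlation in [-1, 1]")
        if self.gamma_source not in ("fixture", "random"):
            raise ConfigurationError("gamma_source must be 'fixture' or 'random'")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")


@dataclass
class SummaryTruth:
    """Ground truth carried alongside simulated summary data."""

    theta: float
    rsids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray  # bool per SNP
    scrambled: np.ndarray  # bool per SNP: outcome record stored on opposite allele
    eaf: np.ndarray
    se_exp: np.ndarray
    se_out: np.ndarray


def _gamma_values(
    config: SummarySimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    """True per-SD instrument effects, and fixture eafs when applicable.

    With ``gamma_source='fixture'`` instrument strength is taken whole from
    the packaged homocysteine set — both the per-SD beta and the effect
    allele frequency — since strength is the (beta, frequency) pair.
    """
    if config.gamma_source == "fixture":
        fixture = load_instrument_fixture("homocysteine").variants
        base = np.array([v.beta for v in fixture])
        base_eaf = np.array([v.eaf for v in fixture])
        if config.m_snps <= base.size:
            return base[: config.m_snps].copy(), base_eaf[: config.m_snps].copy()
        extra = rng.normal(0.0, 0.06, size=config.m_snps - base.size)
        extra = np.sign(extra) * np.maximum(np.abs(extra), 0.03)
        pad = np.full(config.m_snps - base.size, np.nan)
        return np.concatenate([base, extra]), np.concatenate([base_eaf, pad])
    g = np.abs(rng.normal(0.0, 0.08, size=config.m_snps)) + 0.03  # half-normal, floored
    return g * rng.choice([-1.0, 1.0], size=config.m_snps), None


def _se_approx(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def simulate_summary(
    config: SummarySimConfig,
) -> tuple[InstrumentSet, list[VariantAssociation], SummaryTruth]:
    """Generate exposure instruments, outcome records and the ground truth.

    Per SNP j: observed beta_exp_j = gamma_j + N(0, se_exp_j) and
    beta_out_j = theta*gamma_j + alpha_j + N(0, se_out_j), alpha_j nonzero
    only for a random subset of round(prop_invalid*m) invalid instruments.
    p-values are two-sided normal computed in log-space so genome-wide
    instruments never underflow to zero.
    """
    config.validate()
    # Independent streams per component: toggling allele_scramble (or any
    # later component) never perturbs the effect sizes drawn earlier.
    streams = np.random.SeedSequence(config.seed).spawn(7)
    (
        rng_eaf,
        rng_gamma,
        rng_invalid,
        rng_alpha,
        rng_noise,
        rng_alleles,
        rng_scramble,
    ) = map(np.random.default_rng, streams)
    m = config.m_snps
    rsids = [f"rs{90000000 + j}" for j in range(m)]
    eaf = rng_eaf.uniform(*config.eaf_range, size=m)
    gamma, fixture_eaf = _gamma_values(config, rng_gamma)
    if fixture_eaf is not None:
        known = ~np.isnan(fixture_eaf)
        eaf[known] = fixture_eaf[known]
    se_exp = _se_approx(eaf, config.n_exp)
    se_out = _se_approx(eaf, config.n_out)

    # Invalid instruments are a random subset (of fixed size) so that
    # pleiotropy is not systematically tied to instrument strength, which
    # would itself violate InSIDE.
    n_invalid = int(round(config.prop_invalid * m))
    valid = np.ones(m, dtype=bool)
    if n_invalid:
        valid[rng_invalid.choice(m, size=n_invalid, replace=False)] = False
    alpha = np.zeros(m)
    if n_invalid and (config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0):
        # Direct effects are expressed per exposure-increasing allele (the
        # orientation in which "directional" pleiotropy is defined), then
        # mapped back to each SNP's stored coding via sign(gamma).
        idx = ~valid
        strength = np.abs(gamma[idx])
        z_strength = (strength - strength.mean()) / (strength.std() or 1.0)
        rho = config.inside_violation
        eps = rng_alpha.standard_normal(n_invalid)
        alpha_oriented = config.pleiotropy_mean + config.pleiotropy_sd * (
            rho * z_strength + math.sqrt(max(0.0, 1.0 - rho**2)) * eps
        )
        alpha[idx] = alpha_oriented * np.sign(gamma[idx])

    beta_exp = gamma + config.noise_scale * se_exp * rng_noise.standard_normal(m)
    beta_out = (
        config.theta * gamma + alpha + config.noise_scale * se_out * rng_noise.standard_normal(m)
    )

    pair_idx = rng_alleles.integers(0, len(_ALLELE_PAIRS), size=m)
    pairs = [list(_ALLELE_PAIRS[i]) for i in pair_idx]
    if config.prop_palindromic > 0:
        pal = rng_alleles.random(m) < config.prop_palindromic
        pal_idx = rng_alleles.integers(0, len(_PALINDROMIC_PAIRS), size=m)
        for j in np.flatnonzero(pal):
            pairs[j] = list(_PALINDROMIC_PAIRS[pal_idx[j]])

    scrambled = (
        rng_scramble.random(m) < 0.5 if config.allele_scramble else np.zeros(m, dtype=bool)
    )

    exp_records, out_records = [], []
    for j in range(m):
        ea, oa = pairs[j]
        exp_records.append(
            VariantAssociation(
                rsid=rsids[j],
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[j]),
                beta=float(beta_exp[j]),
                se=float(se_exp[j]),
                pval=pval_from_beta_se(beta_exp[j], se_exp[j]),
                n=config.n_exp,
            )
        )
        rec = VariantAssociation(
            rsid=rsids[j],
            effect_allele=ea,
            other_allele=oa,
            eaf=float(eaf[j]),
            beta=float(beta_out[j]),
            se=float(se_out[j]),
            pval=pval_from_beta_se(beta_out[j], se_out[j]),
            n=config.n_out,
        )
        out_records.append(rec.flipped() if scrambled[j] else rec)

    instrument = InstrumentSet(exposure_name="simulated_exposure", variants=exp_records)
    truth = SummaryTruth(
        theta=config.theta,
        rsids=rsids,
        gamma=gamma,
        alpha=alpha,
        valid=valid,
        scrambled=scrambled,
        eaf=eaf,
        se_exp=se_exp,
        se_out=se_out,
    )
    return instrument, out_records, truth


def simulate_outcome_for_instruments(
    instrument: InstrumentSet,
    theta: float,
    n_out: int = 567460,
    seed: int = 0,
    drop_rsids: Sequence[str] = (),
    noise_scale: float = 1.0,
) -> list[VariantAssociation]:
    """Outcome summary statistics keyed to an existing instrument set.

    Used to run the packaged (real) instruments end-to-end: for each
    instrument SNP not in ``drop_rsids``, beta_out = theta*beta_exp +
    noise, with the SE implied by the SNP's frequency at the outcome-GWAS
    sample size. Alleles match the instrument's effect allele (a
    deterministic non-palindromic partner is assigned when the instrument
    omits the other allele).
    """
    rng = np.random.default_rng(seed)
    drop = set(drop_rsids)
    records = []
    for v in instrument.variants:
        if v.rsid in drop:
            continue
        eaf = v.eaf if v.eaf is not None else 0.5
        eaf_se = min(max(eaf, 0.01), 0.99)  # SE approximation needs eaf away from 0/1
        se_out = float(1.0 / math.sqrt(2.0 * eaf_se * (1.0 - eaf_se) * n_out))
        beta_out = theta * v.beta + noise_scale * se_out * rng.standard_normal()
        other = v.other_allele
        if other is None:
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            # any base that is neither the effect allele nor its complement
            other = next(b for b in "ACGT" if b not in (v.effect_allele, comp.get(v.effect_allele)))
        records.append(
            VariantAssociation(
                rsid=v.rsid,
                effect_allele=v.effect_allele,
                other_allele=other,
                eaf=eaf,
                beta=float(beta_out),
                se=se_out,
                pval=pval_from_beta_se(beta_out, se_out),
                n=n_out,
            )
        )
    return records


@dataclass
class CohortSimConfig:
    """Generative parameters for an individual-level cohort.

    Defaults emulate a population cohort aged 40-69 with median eGFR near
    92.5 mL/min/1.73 m^2: log-eGFR is centered at log(92.5) with residual
    SD 0.16, declines slightly with age, and responds to the (unit-
    variance) exposure with slope ``theta`` on the log scale. The shared
    confounder U affects both exposure and outcome. Comorbidity
    prevalences (hypertension 25%, diabetes 5%, obesity 24%) are
    independent of the genotypes.
    """

    seed: int
    n_individuals: int = 20000
    instrument: InstrumentSet | None = None  # default: packaged homocysteine set
    theta: float = -0.0095
    confounder_effect_exposure: float = 0.3
    confounder_effect_outcome: float = 0.05
    egfr_log_mean: float = math.log(92.5)
    egfr_log_sd: float = 0.16
    age_effect_log_egfr: float = -0.004
    age_range: tuple[int, int] = (40, 69)
    female_fraction: float = 0.54
    n_batches: int = 5
    n_pcs: int = 10
    prevalence_hypertension: float = 0.25
    prevalence_diabetes: float = 0.05
    prevalence_obesity: float = 0.24
    phenotype_missing_rate: float = 0.05
    comorbidity_missing_rate: float = 0.01
    flip_fraction: float = 0.0  # cohort SNPs stored on the opposite allele

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_individuals < 10:
            raise ConfigurationError("n_individuals must be >= 10")
        for name in (
            "female_fraction",
            "prevalence_hypertension",
            "prevalence_diabetes",
            "prevalence_obesity",
            "phenotype_missing_rate",
            "comorbidity_missing_rate",
            "flip_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        if self.egfr_log_sd <= 0:
            raise ConfigurationError("egfr_log_sd must be > 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")


@dataclass
class CohortTruth:
    theta: float
    exposure: np.ndarray
    confounder: np.ndarray
    flipped_rsids: list[str]


def simulate_cohort(config: CohortSimConfig) -> tuple[CohortData, CohortTruth]:
    """Generate an individual-level cohort and its ground truth.

    Genotypes G_ij ~ Binomial(2, eaf_j); the exposure is the per-SD-scaled
    genetic score plus confounder and noise, normalized to unit total
    variance; log eGFR = mean + theta*exposure + confounder and age
    effects + normal noise; creatinine is back-derived so the CKD-EPI
    equation reproduces the simulated eGFR for each individual's age/sex.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_geno, rng_conf, rng_expo, rng_covar, rng_miss, rng_flip = map(
        np.random.default_rng, streams
    )
    instrument = config.instrument or load_instrument_fixture("homocysteine")
    n = config.n_individuals
    m = len(instrument)
    rsids = instrument.rsids
    eaf = np.array([v.eaf if v.eaf is not None else 0.5 for v in instrument.variants])
    eaf = np.clip(eaf, 0.01, 0.99)
    gamma = np.array([v.beta for v in instrument.variants])

    G = rng_geno.binomial(2, eaf, size=(n, m)).astype(float)
    g_std = (G - 2.0 * eaf) / np.sqrt(2.0 * eaf * (1.0 - eaf))
    U = rng_conf.standard_normal(n)
    var_gen = float(np.sum(gamma**2))
    var_conf = config.confounder_effect_exposure**2
    var_noise = max(1e-6, 1.0 - var_gen - var_conf)
    exposure = (
        g_std @ gamma
        + config.confounder_effect_exposure * U
        + math.sqrt(var_noise) * rng_expo.standard_normal(n)
    )

    age = rng_covar.integers(config.age_range[0], config.age_range[1] + 1, size=n).astype(float)
    female = rng_covar.random(n) < config.female_fraction
    batch = rng_covar.integers(0, config.n_batches, size=n)
    pcs = rng_covar.standard_normal((n, config.n_pcs))

    log_egfr = (
        config.egfr_log_mean
        + config.theta * exposure
        + config.confounder_effect_outcome * U
        + config.age_effect_log_egfr * (age - 55.0)
        + config.egfr_log_sd * rng_expo.standard_normal(n)
    )
    egfr = np.exp(log_egfr)
    creatinine = creatinine_for_egfr(egfr, age, female)

    pheno = pd.DataFrame(
        {
            "age": age,
            "sex": female.astype(float),
            "batch": batch,
            **{f"pc{i+1}": pcs[:, i] for i in range(config.n_pcs)},
            "hypertension": (rng_covar.random(n) < config.prevalence_hypertension).astype(float),
            "diabetes": (rng_covar.random(n) < config.prevalence_diabetes).astype(float),
            "obesity": (rng_covar.random(n) < config.prevalence_obesity).astype(float),
            "creatinine": creatinine,
            "egfr": egfr,
        }
    )
    miss = rng_miss.random(n) < config.phenotype_missing_rate
    pheno.loc[miss, ["egfr", "creatinine"]] = np.nan
    for col in ("hypertension", "diabetes", "obesity"):
        pheno.loc[rng_miss.random(n) < config.comorbidity_missing_rate, col] = np.nan

    meta_ea = [v.effect_allele for v in instrument.variants]
    dosages = G.copy()
    flipped = rng_flip.random(m) < config.flip_fraction
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    flipped_rsids = []
    for j in np.flatnonzero(flipped):
        v = instrument.variants[j]
        other = v.other_allele or comp.get(v.effect_allele, "N")
        if other == v.effect_allele:
            continue
        dosages[:, j] = 2.0 - dosages[:, j]
        meta_ea[j] = other
        flipped_rsids.append(rsids[j])

    index = pd.RangeIndex(n, name="sample_id")
    cohort = CohortData(
        dosages=pd.DataFrame(dosages, columns=rsids, index=index),
        snp_meta=pd.DataFrame(
            {"effect_allele": meta_ea, "eaf": eaf}, index=pd.Index(rsids, name="rsid")
        ),
        phenotype=pheno.set_axis(index, axis=0),
    )
    truth = CohortTruth(
        theta=config.theta, exposure=exposure, confounder=U, flipped_rsids=flipped_rsids
    )
    return cohort, truth
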