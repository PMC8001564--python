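"""Summary-level Mendelian randomization estimators.

Given a harmonized set of J instruments with SNP-exposure effects
``beta_exp_j`` (per SD of the exposure) and SNP-outcome effects
``beta_out_j`` (log-eGFR units here), each method estimates the causal
effect theta of a one-SD exposure increase on the log outcome:

* Wald ratio — per-SNP theta_j = beta_out_j / beta_exp_j with first-order
  delta-method SE, used alone for single-variant instruments.
* Fixed-effects IVW — precision-weighted combination of the ratios,
  algebraically the zero-intercept weighted least squares of beta_out on
  beta_exp with weights se_out^-2. Efficient but biased by directional
  pleiotropy.
* MR-Egger — the same regression with a free intercept; the slope is a
  pleiotropy-robust estimate under the InSIDE assumption and a nonzero
  intercept is the formal test for directional pleiotropy. Standard errors
  come from a seeded parametric bootstrap. Because Egger is not invariant
  to allele coding, variants are first re-expressed so all exposure effects
  are positive.
* (Penalized) weighted median — consistent when valid instruments carry a
  majority of the weight; penalization down-weights heterogeneity outliers
  through chi-square tail probabilities of their contribution.
* Contamination mixture — profile likelihood over a grid of candidate
  effects, modelling each variant as valid (ratio centered on theta) or
  invalid (centered at zero with extra dispersion psi); robust to invalid
  instruments and able to return a non-contiguous confidence set.

For reporting, effects on the natural-log outcome scale are transformed to
percent change, 100*(exp(beta) - 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientInstrumentsError, MRKitError
from .harmonize import HarmonizedSet, HarmonizedVariant
from .summary_data import pval_from_beta_se

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "wald_ratio",
    "ivw_fixed",
    "egger",
    "weighted_median",
    "contamination_mixture",
    "transform_pct",
    "run_all_methods",
]

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)

TABLE_ORDER = ("ivw_fixed", "egger", "penalized_weighted_median", "contamination_mixture")


@dataclass(frozen=True)
class RatioEstimate:
    """Single-SNP Wald ratio with its inverse-variance weight."""

    rsid: str
    theta: float
    se_theta: float

    @property
    def weight(self) -> float:
        return self.se_theta**-2


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty and method diagnostics.

    ``beta`` is on the log-outcome scale per SD of exposure; ``pct_beta``
    and ``pct_ci`` are populated by :func:`transform_pct`. The
    contamination mixture may report a non-contiguous 95% confidence set in
    ``ci_segments`` (``ci_low``/``ci_high`` are its envelope); intercept
    fields are populated by MR-Egger only.
    """

    method: str
    beta: float
    se: float | None
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    ci_segments: list[tuple[float, float]] | None = None
    pct_beta: float | None = None
    pct_ci: tuple[float, float] | None = None
    pct_segments: list[tuple[float, float]] | None = None


def _kept_arrays(hset: HarmonizedSet):
    kept = hset.kept
    if not kept:
        raise InsufficientInstrumentsError("harmonized set has no kept variants")
    be = np.array([v.beta_exp for v in kept], dtype=float)
    se_e = np.array([math.nan if v.se_exp is None else v.se_exp for v in kept], dtype=float)
    bo = np.array([v.beta_out for v in kept], dtype=float)
    se_o = np.array([v.se_out for v in kept], dtype=float)
    if np.any(be == 0):
        bad = [v.rsid for v, b in zip(kept, be) if b == 0]
        raise DomainError(f"degenerate instruments with zero exposure effect: {bad}")
    return kept, be, se_e, bo, se_o


def wald_ratio(hv: HarmonizedVariant, second_order: bool = False) -> RatioEstimate:
    """Per-SNP causal estimate beta_out / beta_exp.

    The default SE is the first-order delta method, se_out / |beta_exp|
    (standard two-sample practice with strong instruments); the
    second-order form additionally propagates the exposure SE.
    """
    if hv.beta_exp == 0:
        raise DomainError(f"{hv.rsid}: zero exposure effect, Wald ratio undefined")
    theta = hv.beta_out / hv.beta_exp
    se = hv.se_out / abs(hv.beta_exp)
    if second_order:
        if hv.se_exp is None:
            raise DomainError(f"{hv.rsid}: second-order SE needs se_exp")
        se = math.sqrt(
            hv.se_out**2 / hv.beta_exp**2 + hv.beta_out**2 * hv.se_exp**2 / hv.beta_exp**4
        )
    return RatioEstimate(rsid=hv.rsid, theta=theta, se_theta=se)


def _normal_estimate(method: str, beta: float, se: float, n_snps: int, **extra) -> MREstimate:
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval_from_beta_se(beta, se),
        n_snps=n_snps,
        **extra,
    )


def wald_ratio_estimate(hv: HarmonizedVariant, second_order: bool = False) -> MREstimate:
    """Wald ratio wrapped as an :class:`MREstimate` (single-SNP instruments)."""
    r = wald_ratio(hv, second_order=second_order)
    return _normal_estimate("wald_ratio", r.theta, r.se_theta, 1)


def ivw_fixed(hset: HarmonizedSet) -> MREstimate:
    """Fixed-effects inverse-variance weighted estimate.

    beta = sum(be*bo*w) / sum(be^2*w), se = sum(be^2*w)^-1/2 with
    w = se_out^-2; identical to the precision-weighted mean of the per-SNP
    ratios and to zero-intercept WLS of beta_out on beta_exp.
    """
    _, be, _, bo, se_o = _kept_arrays(hset)
    w = se_o**-2.0
    denom = float(np.sum(be * be * w))
    beta = float(np.sum(be * bo * w)) / denom
    se = denom**-0.5
    return _normal_estimate("ivw_fixed", beta, se, len(be))


def _orient_positive(be: np.ndarray, bo: np.ndarray):
    """Re-express variants so every exposure effect is positive."""
    sign = np.where(be < 0, -1.0, 1.0)
    return be * sign, bo * sign


def _wls_line(be: np.ndarray, bo: np.ndarray, w: np.ndarray):
    """Weighted least squares with intercept; vectorized over leading axes."""
    sw = np.sum(w, axis=-1)
    xbar = np.sum(w * be, axis=-1) / sw
    ybar = np.sum(w * bo, axis=-1) / sw
    dx = be - xbar[..., None]
    slope = np.sum(w * dx * (bo - ybar[..., None]), axis=-1) / np.sum(w * dx * dx, axis=-1)
    intercept = ybar - slope * xbar
    return slope, intercept


def _bootstrap_draws(be, se_e, bo, se_o, n_boot: int, seed):
    if np.any(np.isnan(se_e)):
        raise DomainError("parametric bootstrap needs exposure SEs on all variants")
    rng = np.random.default_rng(seed)
    shape = (n_boot, be.size)
    return (
        be + se_e * rng.standard_normal(shape),
        bo + se_o * rng.standard_normal(shape),
    )


def egger(hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """MR-Egger regression with parametric-bootstrap standard errors.

    Point estimates are the WLS intercept and slope of beta_out on beta_exp
    (weights se_out^-2) after orienting all exposure effects positive. Each
    bootstrap replicate redraws beta_exp_j ~ N(beta_exp_j, se_exp_j) and
    beta_out_j ~ N(beta_out_j, se_out_j), re-orients and refits; the SE is
    the SD of replicate estimates and p-values are two-sided normal.
    """
    _, be, se_e, bo, se_o = _kept_arrays(hset)
    if be.size < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >=3 variants, got {be.size}")
    if n_boot < 100:
        logger.warning("egger: n_boot=%d is small; SEs will be noisy", n_boot)
    w = se_o**-2.0
    obe, obo = _orient_positive(be, bo)
    slope, intercept = _wls_line(obe, obo, w)

    bbe, bbo = _bootstrap_draws(be, se_e, bo, se_o, n_boot, seed)
    bbe, bbo = _orient_positive(bbe, bbo)
    slopes, intercepts = _wls_line(bbe, bbo, w)
    se_slope = float(np.std(slopes, ddof=1))
    se_int = float(np.std(intercepts, ddof=1))

    return _normal_estimate(
        "egger",
        float(slope),
        se_slope,
        be.size,
        intercept=float(intercept),
        intercept_se=se_int,
        intercept_pval=pval_from_beta_se(float(intercept), se_int),
    )


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted median via cumulative-weight interpolation, rows independent.

    Sort ratios ascending; at cumulative weight s_j = (sum_{i<=j} w_i -
    w_j/2) / sum(w), interpolate theta linearly at s = 0.5. Clamps to the
    extreme ratios when one variant holds a majority of the weight.
    """
    theta = np.atleast_2d(theta)
    w = np.atleast_2d(w)
    order = np.argsort(theta, axis=1)
    th = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    ww = ww / np.sum(ww, axis=1, keepdims=True)
    s = np.cumsum(ww, axis=1) - ww / 2.0
    idx = np.sum(s < 0.5, axis=1)
    m = theta.shape[1]
    rows = np.arange(theta.shape[0])
    res = np.empty(theta.shape[0])
    lo_clamp = idx == 0
    hi_clamp = idx == m
    mid = ~(lo_clamp | hi_clamp)
    res[lo_clamp] = th[lo_clamp, 0]
    res[hi_clamp] = th[hi_clamp, -1]
    if np.any(mid):
        i = idx[mid]
        r = rows[mid]
        s0, s1 = s[r, i - 1], s[r, i]
        t0, t1 = th[r, i - 1], th[r, i]
        res[mid] = t0 + (0.5 - s0) * (t1 - t0) / (s1 - s0)
    return res


def _penalized_weights(theta: np.ndarray, w: np.ndarray, penalty_k: float) -> np.ndarray:
    """Down-weight outliers: w_j * min(1, k * P(chi2_1 > Q_j)) with
    Q_j = w_j*(theta_j - theta_WM)^2 against the unpenalized estimate."""
    wm = _weighted_median_rows(theta, w)
    q_stat = w * (theta - wm[..., None] if theta.ndim > 1 else theta - wm) ** 2
    tail = stats.chi2.sf(q_stat, df=1)
    return w * np.minimum(1.0, penalty_k * tail)


def weighted_median(
    hset: HarmonizedSet,
    penalized: bool = False,
    penalty_k: float = 20.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """(Penalized) weighted median of the per-SNP Wald ratios.

    Consistent when valid instruments contribute a majority of the
    inverse-variance weight. With ``penalized=True``, variants whose ratio
    is heterogeneous with the unpenalized estimate are down-weighted by the
    chi-square(1) tail probability of their contribution (multiplier
    ``penalty_k``, default 20). SE by the same parametric bootstrap as
    :func:`egger`.
    """
    _, be, se_e, bo, se_o = _kept_arrays(hset)
    if be.size < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >=3 variants, got {be.size}")
    theta = bo / be
    se_theta = se_o / np.abs(be)
    w = se_theta**-2.0
    if penalized:
        w_use = _penalized_weights(theta[None, :], w[None, :], penalty_k)[0]
    else:
        w_use = w
    beta = float(_weighted_median_rows(theta[None, :], w_use[None, :])[0])

    bbe, bbo = _bootstrap_draws(be, se_e, bo, se_o, n_boot, seed)
    btheta = bbo / bbe
    bw = (se_o / np.abs(bbe)) ** -2.0
    if penalized:
        bw = _penalized_weights(btheta, bw, penalty_k)
    reps = _weighted_median_rows(btheta, bw)
    se = float(np.std(reps, ddof=1))
    method = "penalized_weighted_median" if penalized else "weighted_median"
    return _normal_estimate(method, beta, se, be.size)


def _conmix_profile(theta_grid: np.ndarray, theta_j: np.ndarray, se_j: np.ndarray, psi: float):
    """Profile log-likelihood: each variant takes the better of the valid
    (centered on theta) and invalid (centered at zero, dispersion psi)
    component."""
    valid = -((theta_j[None, :] - theta_grid[:, None]) ** 2) / (2.0 * se_j**2) - np.log(se_j)
    var_inv = se_j**2 + psi**2
    invalid = -(theta_j**2) / (2.0 * var_inv) - 0.5 * np.log(var_inv)
    return np.sum(np.maximum(valid, invalid[None, :]), axis=1)


def contamination_mixture(
    hset: HarmonizedSet,
    psi: float | None = None,
    grid_points: int = 5001,
    alpha: float = 0.05,
) -> MREstimate:
    """Contamination-mixture estimate by profile likelihood over a grid.

    ``psi`` is the dispersion of invalid instruments' ratios; by default
    1.5x the SD of the per-SNP ratios. The confidence set is every grid
    point whose likelihood-ratio statistic is below the chi-square(1)
    quantile at 1 - alpha; it may be a union of disjoint intervals,
    reported in ``ci_segments`` with ``ci_low``/``ci_high`` as the
    envelope. The p-value is a likelihood-ratio test of theta = 0.
    """
    _, be, _, bo, se_o = _kept_arrays(hset)
    if be.size < 2:
        raise InsufficientInstrumentsError("contamination mixture needs >=2 variants")
    theta_j = bo / be
    se_j = se_o / np.abs(be)
    if psi is None:
        psi = 1.5 * float(np.std(theta_j, ddof=1))
        if psi <= 0:  # all ratios identical; any positive dispersion works
            psi = float(np.max(se_j))
    if psi <= 0:
        raise DomainError(f"psi must be > 0, got {psi}")

    lo = float(np.min(theta_j) - 2.0 * np.max(se_j))
    hi = float(np.max(theta_j) + 2.0 * np.max(se_j))
    for _attempt in range(6):
        grid = np.linspace(lo, hi, grid_points)
        ll = _conmix_profile(grid, theta_j, se_j, psi)
        imax = int(np.argmax(ll))
        if 0 < imax < grid_points - 1:
            break
        span = hi - lo
        lo, hi = lo - span, hi + span  # widen and retry
    else:
        raise MRKitError("contamination mixture: likelihood maximum not bracketed by grid")

    beta = float(grid[imax])
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    inside = 2.0 * (ll[imax] - ll) <= crit
    segments: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        segments.append((float(grid[start]), float(grid[-1])))
    ci_low, ci_high = segments[0][0], segments[-1][1]

    ll0 = float(_conmix_profile(np.array([0.0]), theta_j, se_j, psi)[0])
    pval = float(stats.chi2.sf(2.0 * (ll[imax] - ll0), df=1))
    pval = max(pval, np.finfo(float).tiny)
    return MREstimate(
        method="contamination_mixture",
        beta=beta,
        se=(ci_high - ci_low) / (2.0 * Z95),  # envelope-implied summary SE
        ci_low=ci_low,
        ci_high=ci_high,
        pval=pval,
        n_snps=be.size,
        ci_segments=segments,
    )


def transform_pct(est: MREstimate) -> MREstimate:
    """Express a log-scale effect as % change in the outcome.

    pct = 100*(exp(beta) - 1), applied to the point estimate, both CI
    endpoints and every confidence-set segment (a monotone map, so coverage
    is preserved).
    """
    pct = lambda x: 100.0 * math.expm1(x)
    return replace(
        est,
        pct_beta=pct(est.beta),
        pct_ci=(pct(est.ci_low), pct(est.ci_high)),
        pct_segments=(
            None
            if est.ci_segments is None
            else [(pct(a), pct(b)) for a, b in est.ci_segments]
        ),
    )


def run_all_methods(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    penalty_k: float = 20.0,
    psi: float | None = None,
    grid_points: int = 5001,
    alpha: float = 0.05,
    fallback_wald: bool = False,
) -> list[MREstimate]:
    """Run the full estimator battery on a harmonized, filtered set.

    Returns IVW, MR-Egger, penalized weighted median and contamination
    mixture (in that reporting order), all %-transformed. With a single
    kept variant and ``fallback_wald=True``, returns the Wald ratio alone
    instead of raising. Deterministic for a fixed ``seed``: bootstrap
    streams for Egger and the median are split from one root seed so the
    two never share draws.
    """
    n_kept = hset.n_kept()
    if n_kept == 1:
        if fallback_wald:
            return [transform_pct(wald_ratio_estimate(hset.kept[0]))]
        raise InsufficientInstrumentsError(
            "single-variant set; use wald_ratio_estimate or fallback_wald=True"
        )
    seed_egger, seed_median = np.random.SeedSequence(seed).generate_state(2) >> 1
    ests = [
        ivw_fixed(hset),
        egger(hset, n_boot=n_boot, seed=int(seed_egger)),
        weighted_median(hset, penalized=True, penalty_k=penalty_k, n_boot=n_boot, seed=int(seed_median)),
        contamination_mixture(hset, psi=psi, grid_points=grid_points, alpha=alpha),
    ]
    return [transform_pct(e) for e in ests]
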