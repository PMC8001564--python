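"""Summary-level MR estimators: oracle equivalences, invariants, edge cases."""

import math

import numpy as np
import pytest
from scipy import stats

from mrkit.errors import DomainError, InsufficientInstrumentsError
from mrkit.harmonize import Action, HarmonizedVariant
from mrkit.mr_estimators import (
    contamination_mixture,
    egger,
    ivw_fixed,
    run_all_methods,
    transform_pct,
    wald_ratio,
    weighted_median,
)
from tests.conftest import make_hset, random_hset


def _hv(be, bo, se_o, se_e=0.01, rsid="rs1"):
    return HarmonizedVariant(
        rsid=rsid,
        effect_allele="A",
        beta_exp=be,
        se_exp=se_e,
        beta_out=bo,
        se_out=se_o,
        action=Action.KEPT_AS_IS,
    )


class TestWaldRatio:
    @pytest.mark.parametrize(
        "be,bo,se_o,theta,se",
        [
            (0.5, 0.25, 0.05, 0.5, 0.1),
            (-0.2, 0.1, 0.02, -0.5, 0.1),
            (0.1583, -0.0015, 0.0004, -0.0015 / 0.1583, 0.0004 / 0.1583),
        ],
    )
    def test_ratio_and_first_order_se(self, be, bo, se_o, theta, se):
        r = wald_ratio(_hv(be, bo, se_o))
        assert r.theta == pytest.approx(theta)
        assert r.se_theta == pytest.approx(se)
        assert r.weight == pytest.approx(se**-2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DomainError):
            wald_ratio(_hv(0.0, 0.1, 0.01))

    def test_second_order_se_exceeds_first_order(self):
        hv = _hv(0.1, 0.05, 0.01, se_e=0.02)
        assert wald_ratio(hv, second_order=True).se_theta > wald_ratio(hv).se_theta


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        hv = _hv(0.5, 0.25, 0.05)
        est = ivw_fixed(make_hset([0.5], [0.25], [0.05]))
        r = wald_ratio(hv)
        assert est.beta == pytest.approx(r.theta)
        assert est.se == pytest.approx(r.se_theta)

    def test_equal_weight_average_of_ratios(self):
        # ratios 0.4 and 0.6 with equal weights (be/se_o)^2 -> 0.5
        est = ivw_fixed(make_hset([0.1, 0.1], [0.04, 0.06], [0.01, 0.01]))
        assert est.beta == pytest.approx(0.5)

    def test_matches_zero_intercept_wls_normal_equations(self, rng):
        """IVW equals (X'WX)^-1 X'Wy with X = beta_exp, W = diag(se_out^-2)."""
        for _ in range(20):
            hs = random_hset(rng)
            be = np.array([v.beta_exp for v in hs.kept])
            bo = np.array([v.beta_out for v in hs.kept])
            w = np.array([v.se_out for v in hs.kept]) ** -2.0
            beta_orc = float(be @ (w * bo)) / float(be @ (w * be))
            se_orc = float(be @ (w * be)) ** -0.5
            est = ivw_fixed(hs)
            assert est.beta == pytest.approx(beta_orc, rel=1e-10)
            assert est.se == pytest.approx(se_orc, rel=1e-10)

    def test_matches_precision_weighted_mean_of_ratios(self, rng):
        hs = random_hset(rng)
        theta = np.array([v.beta_out / v.beta_exp for v in hs.kept])
        w = np.array([(v.beta_exp / v.se_out) ** 2 for v in hs.kept])
        assert ivw_fixed(hs).beta == pytest.approx(float(np.average(theta, weights=w)))

    def test_empty_set_is_error(self):
        from mrkit.harmonize import HarmonizedSet

        with pytest.raises(InsufficientInstrumentsError):
            ivw_fixed(HarmonizedSet("x", "y", []))


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        """Noise-free beta_out = c + theta*beta_exp gives intercept c, slope theta."""
        be = np.array([0.05, 0.08, 0.12, 0.2])
        c, theta = 0.003, -0.4
        est = egger(make_hset(be, c + theta * be, np.full(4, 0.002)), n_boot=100, seed=0)
        assert est.beta == pytest.approx(theta, rel=1e-10)
        assert est.intercept == pytest.approx(c, rel=1e-10)

    def test_zero_intercept_wls_reproduces_ivw(self, rng):
        """Constraining the intercept to zero must collapse Egger onto IVW."""
        hs = random_hset(rng)
        be = np.array([v.beta_exp for v in hs.kept])
        bo = np.array([v.beta_out for v in hs.kept])
        w = np.array([v.se_out for v in hs.kept]) ** -2.0
        slope_zero_int = float(np.sum(w * be * bo) / np.sum(w * be * be))
        assert ivw_fixed(hs).beta == pytest.approx(slope_zero_int, rel=1e-12)

    def test_bootstrap_seeded_determinism(self, rng):
        hs = random_hset(rng)
        a = egger(hs, n_boot=200, seed=42)
        b = egger(hs, n_boot=200, seed=42)
        c = egger(hs, n_boot=200, seed=43)
        assert (a.se, a.intercept_se) == (b.se, b.intercept_se)
        assert a.se != c.se

    def test_orientation_invariance(self, rng):
        """Recoding any variant to its opposite allele leaves Egger unchanged."""
        hs = random_hset(rng)
        flipped = make_hset(
            [-v.beta_exp for v in hs.kept],
            [-v.beta_out for v in hs.kept],
            [v.se_out for v in hs.kept],
            [v.se_exp for v in hs.kept],
        )
        a = egger(hs, n_boot=200, seed=1)
        b = egger(flipped, n_boot=200, seed=1)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_requires_three_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]), seed=0)


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_sample_median(self):
        est = weighted_median(
            make_hset([1, 1, 1], [0.1, 0.2, 0.9], [0.01, 0.01, 0.01]), n_boot=100, seed=0
        )
        assert est.beta == pytest.approx(0.2)

    def test_balanced_dominant_snp_returns_its_ratio(self):
        # middle SNP carries 60% of the weight, flanked symmetrically
        be = np.array([0.1, 0.1, 0.1])
        bo = np.array([0.01, 0.05, 0.09])
        se_o = 0.1 / np.sqrt(np.array([0.2, 0.6, 0.2]))
        est = weighted_median(make_hset(be, bo, se_o), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_identical_ratios_unchanged_by_penalization(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        est = weighted_median(
            make_hset(be, 0.5 * be, np.full(4, 0.01)), penalized=True, n_boot=100, seed=0
        )
        assert est.beta == pytest.approx(0.5, rel=1e-10)

    def test_penalization_pulls_outlier_toward_majority(self):
        """9 SNPs with ratios around 0.5 + 1 high-precision outlier at 5.0:
        the penalized estimate sits strictly closer to the majority (brute-
        force interpolation as oracle)."""
        be = np.full(10, 0.1)
        bo = 0.1 * np.concatenate([np.linspace(0.45, 0.55, 9), [5.0]])
        se_o = np.concatenate([np.full(9, 0.01), [0.004]])  # outlier: 41% of weight
        hs = make_hset(be, bo, se_o)
        plain = weighted_median(hs, penalized=False, n_boot=100, seed=0)
        pen = weighted_median(hs, penalized=True, n_boot=100, seed=0)
        assert abs(pen.beta - 0.5) < abs(plain.beta - 0.5)

        # oracle: cumulative-weight interpolation with chi-square penalty
        theta = bo / be
        w = (se_o / np.abs(be)) ** -2.0

        def wm(th, ww):
            o = np.argsort(th)
            th, ww = th[o], ww[o] / ww[o].sum()
            s = np.cumsum(ww) - ww / 2
            return float(np.interp(0.5, s, th))

        est0 = wm(theta, w)
        q = stats.chi2.sf(w * (theta - est0) ** 2, 1)
        w_pen = w * np.minimum(1, 20 * q)
        assert pen.beta == pytest.approx(wm(theta, w_pen), rel=1e-10)

    def test_requires_three_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([0.1], [0.05], [0.01]), seed=0)


class TestContaminationMixture:
    def test_identical_ratios_recovered(self):
        be = np.full(5, 0.1)
        est = contamination_mixture(make_hset(be, 0.5 * be, np.full(5, 1e-4)))
        assert est.beta == pytest.approx(0.5, abs=1e-3)
        assert len(est.ci_segments) == 1
        assert est.ci_segments[0][0] <= 0.5 <= est.ci_segments[0][1]

    def test_majority_group_wins_against_contaminants(self, rng):
        """70% of variants share ratio 0.5; 30% sit at 3.0 with distinct
        precisions: the estimate tracks the majority."""
        m = 20
        be = rng.uniform(0.05, 0.2, m)
        theta_j = np.where(np.arange(m) < 14, 0.5, 3.0)
        se_o = rng.uniform(0.001, 0.01, m)
        hs = make_hset(be, theta_j * be + rng.normal(0, 0.3, m) * se_o, se_o)
        est = contamination_mixture(hs, psi=1.0, grid_points=2001)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_matches_finer_grid_oracle(self, rng):
        """Estimate agrees with an exhaustive 10x-resolution profile search."""
        for _ in range(5):
            hs = random_hset(rng)
            est = contamination_mixture(hs, psi=0.5, grid_points=501)
            theta_j = np.array([v.beta_out / v.beta_exp for v in hs.kept])
            se_j = np.array([v.se_out / abs(v.beta_exp) for v in hs.kept])
            lo = theta_j.min() - 2 * se_j.max()
            hi = theta_j.max() + 2 * se_j.max()
            step = (hi - lo) / 500
            grid = np.linspace(lo, hi, 5001)
            best, best_ll = None, -np.inf
            for th in grid:  # deliberately naive exhaustive oracle
                valid = -((theta_j - th) ** 2) / (2 * se_j**2) - np.log(se_j)
                invalid = -(theta_j**2) / (2 * (se_j**2 + 0.25)) - 0.5 * np.log(se_j**2 + 0.25)
                ll = float(np.sum(np.maximum(valid, invalid)))
                if ll > best_ll:
                    best, best_ll = th, ll
            assert abs(est.beta - best) <= step

    def test_confidence_set_contains_estimate(self, rng):
        hs = random_hset(rng)
        est = contamination_mixture(hs)
        assert any(lo <= est.beta <= hi for lo, hi in est.ci_segments)
        assert est.ci_low <= est.beta <= est.ci_high

    def test_psi_domain_error(self, rng):
        with pytest.raises(DomainError):
            contamination_mixture(random_hset(rng), psi=-1.0)


class TestTransformPct:
    @pytest.mark.parametrize(
        "beta,pct",
        [(0.0, 0.0), (0.01, 1.0050167084), (-0.009545, -0.9499586)],
    )
    def test_percent_change_closed_form(self, beta, pct):
        est = ivw_fixed(make_hset([0.1], [0.1 * beta], [0.01]))
        out = transform_pct(est)
        assert out.pct_beta == pytest.approx(pct, abs=1e-6)
        assert out.pct_ci[0] == pytest.approx(100 * math.expm1(est.ci_low))

    def test_segments_transformed(self):
        be = np.full(5, 0.1)
        est = contamination_mixture(make_hset(be, 0.5 * be, np.full(5, 1e-4)))
        out = transform_pct(est)
        assert out.pct_segments is not None
        assert out.pct_segments[0][0] == pytest.approx(100 * math.expm1(est.ci_segments[0][0]))


class TestEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_exposure_scale_equivariance(self, rng, c):
        """Multiplying all exposure betas by c>0 divides every estimate by c."""
        hs = random_hset(rng)
        scaled = make_hset(
            [c * v.beta_exp for v in hs.kept],
            [v.beta_out for v in hs.kept],
            [v.se_out for v in hs.kept],
            [c * v.se_exp for v in hs.kept],
        )
        for fn in (
            ivw_fixed,
            lambda h: egger(h, n_boot=200, seed=5),
            lambda h: weighted_median(h, penalized=True, n_boot=200, seed=5),
        ):
            assert fn(scaled).beta == pytest.approx(fn(hs).beta / c, rel=1e-9)
        a = contamination_mixture(hs, psi=0.3, grid_points=4001)
        b = contamination_mixture(scaled, psi=0.3 / c, grid_points=4001)
        assert b.beta == pytest.approx(a.beta / c, rel=5e-3, abs=1e-4)

    def test_outcome_sign_equivariance(self, rng):
        """Negating all outcome betas negates estimates and reflects CIs."""
        hs = random_hset(rng)
        neg = make_hset(
            [v.beta_exp for v in hs.kept],
            [-v.beta_out for v in hs.kept],
            [v.se_out for v in hs.kept],
            [v.se_exp for v in hs.kept],
        )
        a, b = ivw_fixed(hs), ivw_fixed(neg)
        assert b.beta == pytest.approx(-a.beta)
        assert (b.ci_low, b.ci_high) == pytest.approx((-a.ci_high, -a.ci_low))
        am = weighted_median(hs, n_boot=200, seed=9)
        bm = weighted_median(neg, n_boot=200, seed=9)
        assert bm.beta == pytest.approx(-am.beta, rel=1e-9)


class TestRunAll:
    def test_reporting_order_and_transforms(self, rng):
        hs = random_hset(rng)
        ests = run_all_methods(hs, n_boot=150, seed=3)
        assert [e.method for e in ests] == [
            "ivw_fixed",
            "egger",
            "penalized_weighted_median",
            "contamination_mixture",
        ]
        assert all(e.pct_beta is not None for e in ests)
        assert ests[1].intercept is not None and ests[0].intercept is None

    def test_single_snp_fallback_contract(self):
        hs = make_hset([0.5], [0.25], [0.05])
        with pytest.raises(InsufficientInstrumentsError):
            run_all_methods(hs, seed=0)
        (est,) = run_all_methods(hs, seed=0, fallback_wald=True)
        assert est.method == "wald_ratio"
        assert est.beta == pytest.approx(0.5)

    def test_deterministic_given_seed(self, rng):
        hs = random_hset(rng)
        a = run_all_methods(hs, n_boot=150, seed=8)
        b = run_all_methods(hs, n_boot=150, seed=8)
        assert [(e.beta, e.se, e.pval) for e in a] == [(e.beta, e.se, e.pval) for e in b]
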