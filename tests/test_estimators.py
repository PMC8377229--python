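"""Estimator correctness: hand values, independent WLS/grid/Monte-Carlo
oracles, known limits and invariance properties."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from tsmr.estimators import (
    EstimatorError,
    estimate_all,
    ivw,
    max_likelihood,
    median_estimator,
    mode_estimator,
    mr_egger,
    wald_ratio,
)
from tsmr.summary_data import HarmonizedInstrument

from conftest import make_instruments, random_instruments, study_scale_ses


def inst(bx, sx, by, sy, rsid="rs1"):
    return HarmonizedInstrument(
        rsid=rsid, effect_allele="A",
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
    )


class TestWaldRatio:
    def test_hand_arithmetic(self):
        e = wald_ratio(inst(0.05, 0.004, 0.012, 0.004))
        assert e.beta == pytest.approx(0.24)
        assert e.se == pytest.approx(0.08)
        assert e.or_value == pytest.approx(math.exp(0.24))

    def test_zero_outcome_effect(self):
        assert wald_ratio(inst(0.05, 0.004, 0.0, 0.004)).beta == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(EstimatorError):
            wald_ratio(inst(0.0, 0.004, 0.01, 0.004))

    def test_second_order_se_against_monte_carlo(self, rng):
        """Delta-method SE vs the empirical SD of ratio draws."""
        g, sx, G, sy = 0.1, 0.008, 0.05, 0.004
        e = wald_ratio(inst(g, sx, G, sy), second_order=True)
        draws = rng.normal(G, sy, 1_000_000) / rng.normal(g, sx, 1_000_000)
        assert e.se == pytest.approx(draws.std(), rel=0.02)


class TestIvw:
    def test_single_instrument_reduces_to_wald(self):
        i = inst(0.05, 0.004, 0.012, 0.004)
        assert ivw([i]).beta == pytest.approx(wald_ratio(i).beta)
        assert ivw([i]).se == pytest.approx(wald_ratio(i).se)

    def test_equal_weight_mean(self):
        # ratios 0.2 and 0.4, both with first-order SE 0.1
        insts = [inst(1.0, 0.01, 0.2, 0.1, "rs1"), inst(1.0, 0.01, 0.4, 0.1, "rs2")]
        e = ivw(insts, model="fixed")
        assert e.beta == pytest.approx(0.3)
        assert e.se == pytest.approx(0.1 / math.sqrt(2), rel=1e-12)

    def test_matches_wls_through_origin(self, rng):
        insts = random_instruments(rng, 40)
        by = np.array([i.beta_outcome for i in insts])
        bx = np.array([i.beta_exposure for i in insts])
        w = np.array([i.se_outcome for i in insts]) ** -2.0
        fit = sm.WLS(by, bx, weights=w).fit()
        assert ivw(insts, model="fixed").beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_empty_input(self):
        with pytest.raises(EstimatorError):
            ivw([])


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.02, 0.04, 0.06, 0.08])
        by = 0.1 + 0.5 * bx
        insts = make_instruments(bx, np.full(4, 0.004), by, np.full(4, 0.005))
        e = mr_egger(insts)
        assert e.intercept == pytest.approx(0.1, abs=1e-12)
        assert e.slope.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_wls_with_intercept(self, rng):
        insts = random_instruments(rng, 40, het_sd=0.005)
        bx = np.array([i.beta_exposure for i in insts])
        by = np.array([i.beta_outcome for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=sy**-2.0).fit()
        e = mr_egger(insts)
        assert e.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert e.slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        # statsmodels scales by RSS/(J-2); ours additionally floors at 1
        scale_floor = max(1.0, fit.scale) / fit.scale
        assert e.slope.se == pytest.approx(fit.bse[1] * math.sqrt(scale_floor), rel=1e-8)

    def test_zero_intercept_fit_equals_ivw_fixed(self, rng):
        """Egger's slope collapses to fixed-effects IVW when the
        intercept is constrained to zero (checked via the WLS oracle)."""
        insts = random_instruments(rng, 25)
        bx = np.array([i.beta_exposure for i in insts])
        by = np.array([i.beta_outcome for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        fit = sm.WLS(by, bx, weights=sy**-2.0).fit()
        assert ivw(insts, model="fixed").beta == pytest.approx(fit.params[0], rel=1e-12)

    def test_too_few_instruments(self, rng):
        with pytest.raises(EstimatorError):
            mr_egger(random_instruments(rng, 2))


class TestMedian:
    def test_middle_value_equal_weights(self):
        insts = [inst(1.0, 0.01, r, 0.1, f"rs{i}") for i, r in enumerate([0.1, 0.3, 0.2])]
        e = median_estimator(insts, weighted=False, n_boot=50, seed=0)
        assert e.beta == pytest.approx(0.2)

    def test_seed_determinism(self, rng):
        insts = random_instruments(rng, 10)
        a = median_estimator(insts, n_boot=200, seed=42)
        b = median_estimator(insts, n_boot=200, seed=42)
        assert a == b

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(10):
            insts = random_instruments(rng, int(rng.integers(3, 20)), het_sd=0.01)
            ratios = [i.beta_outcome / i.beta_exposure for i in insts]
            for weighted in (False, True):
                e = median_estimator(insts, weighted=weighted, n_boot=20, seed=1)
                assert min(ratios) <= e.beta <= max(ratios)

    def test_robust_to_planted_invalid_fraction(self, rng):
        """70% valid instruments around β=0.25, 30% with strong
        directional pleiotropy: the weighted median stays near the truth."""
        J = 60
        sx, sy = study_scale_ses(rng, J)
        gamma = rng.uniform(0.015, 0.06, J)
        alpha = np.zeros(J)
        alpha[: int(0.3 * J)] = 0.05
        bx = gamma + rng.normal(0, sx)
        by = 0.25 * gamma + alpha + rng.normal(0, sy)
        insts = make_instruments(bx, sx, by, sy)
        med = median_estimator(insts, weighted=True, n_boot=100, seed=2)
        assert abs(med.beta - 0.25) < abs(ivw(insts).beta - 0.25)
        assert med.beta == pytest.approx(0.25, abs=0.05)


class TestMode:
    def test_degenerate_identical_ratios(self):
        insts = [inst(1.0, 0.01, 0.3, 0.1, f"rs{i}") for i in range(5)]
        e = mode_estimator(insts, n_boot=20, seed=0)
        assert e.beta == pytest.approx(0.3)

    def test_argmax_matches_dense_grid(self, rng):
        from tsmr.estimators import _kde_argmax, _mode_bandwidth

        ratios = rng.normal(0.25, 0.05, 15)
        w = rng.uniform(0.5, 2.0, 15)
        w = w / w.sum()
        h = _mode_bandwidth(ratios, None, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 100_001)
        dens = (w[:, None] * np.exp(-0.5 * ((grid[None] - ratios[:, None]) / h) ** 2)).sum(0)
        assert _kde_argmax(ratios, w, h) == pytest.approx(grid[np.argmax(dens)], abs=2 * (grid[1] - grid[0]))

    def test_insensitive_to_single_outlier(self, rng):
        """Ratios tightly clustered at 0.3 plus one far outlier of equal
        weight: the mode stays near 0.3 while IVW is dragged off."""
        J = 20
        bx = np.full(J, 0.04)
        sx = np.full(J, 0.002)
        sy = np.full(J, 0.004)
        by = 0.3 * bx + rng.normal(0, 0.0004, J)
        by[0] = 1.5 * bx[0]  # ratio 1.5 instead of ~0.3
        insts = make_instruments(bx, sx, by, sy)
        mode = mode_estimator(insts, weighted=True, n_boot=50, seed=3)
        assert mode.beta == pytest.approx(0.3, abs=0.03)
        assert abs(mode.beta - 0.3) < abs(ivw(insts, model="fixed").beta - 0.3)


class TestMaxLikelihood:
    def test_tiny_exposure_se_limit_is_ivw_fixed(self, rng):
        insts = random_instruments(rng, 20)
        shrunk = [
            HarmonizedInstrument(
                rsid=i.rsid, effect_allele=i.effect_allele,
                beta_exposure=i.beta_exposure, se_exposure=1e-8,
                beta_outcome=i.beta_outcome, se_outcome=i.se_outcome,
            )
            for i in insts
        ]
        ml = max_likelihood(shrunk)
        fixed = ivw(shrunk, model="fixed")
        assert ml.beta == pytest.approx(fixed.beta, rel=1e-5)
        assert ml.se == pytest.approx(fixed.se, rel=1e-3)

    def test_two_instrument_grid_oracle(self):
        insts = [inst(0.05, 0.01, 0.015, 0.006, "rs1"), inst(0.03, 0.012, 0.006, 0.005, "rs2")]
        from tsmr.estimators import _ml_profile_negll

        bx = np.array([0.05, 0.03]); sx = np.array([0.01, 0.012])
        by = np.array([0.015, 0.006]); sy = np.array([0.006, 0.005])
        grid = np.linspace(-2, 2, 400_001)
        vals = [_ml_profile_negll(b, bx, sx, by, sy) for b in grid]
        assert max_likelihood(insts).beta == pytest.approx(grid[int(np.argmin(vals))], abs=1e-4)

    def test_parameter_recovery_without_pleiotropy(self, rng):
        ests = [max_likelihood(random_instruments(rng, 50, beta=0.25)).beta for _ in range(30)]
        assert np.mean(ests) == pytest.approx(0.25, abs=0.01)


class TestEstimateAll:
    def test_seven_labeled_estimates(self, rng):
        insts = random_instruments(rng, 30)
        ests, skipped = estimate_all(insts, n_boot=30, seed=5)
        assert len(ests) == 7 and not skipped
        assert {e.method for e in ests} == {
            "IVW", "Maximum likelihood", "Simple median", "Weighted median",
            "Simple mode", "Weighted mode", "MR-Egger",
        }

    def test_two_instruments_skips_with_reasons(self, rng):
        insts = random_instruments(rng, 2)
        ests, skipped = estimate_all(insts, n_boot=30, seed=5)
        assert {e.method for e in ests} == {"IVW", "Maximum likelihood"}
        assert set(skipped) == {"Simple median", "Weighted median", "Simple mode", "Weighted mode", "MR-Egger"}

    def test_no_pleiotropy_cis_cover_truth(self, rng):
        insts = random_instruments(rng, 60, beta=0.25)
        ests, _ = estimate_all(insts, n_boot=200, seed=6)
        for e in ests:
            assert e.ci_low <= 0.25 <= e.ci_high, e.method


def test_unit_invariance_of_outcome_scale(rng):
    """Multiplying Γ and σ_y by c rescales every method's beta and SE by c."""
    insts = random_instruments(rng, 20, het_sd=0.005)
    c = 3.7
    scaled = [
        HarmonizedInstrument(
            rsid=i.rsid, effect_allele=i.effect_allele,
            beta_exposure=i.beta_exposure, se_exposure=i.se_exposure,
            beta_outcome=c * i.beta_outcome, se_outcome=c * i.se_outcome,
        )
        for i in insts
    ]
    base, _ = estimate_all(insts, n_boot=50, seed=9)
    big, _ = estimate_all(scaled, n_boot=50, seed=9)
    for a, b in zip(base, big):
        assert b.beta == pytest.approx(c * a.beta, rel=1e-5), a.method
        assert b.se == pytest.approx(c * a.se, rel=1e-4), a.method
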