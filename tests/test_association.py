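import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import grskit as gk
from grskit.errors import SeparationError, ValidationError


def table_2x2_data(a, b, c, d):
    """Binary response/predictor data from a 2x2 table (exposed cases = a)."""
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.concatenate([np.ones(245), np.zeros(489)])
        fit = gk.fit_logistic(y, np.ones((734, 1)))
        assert fit.coef[0] == pytest.approx(math.log(245 / 489), abs=1e-8)
        assert fit.loglik <= 0

    def test_2x2_closed_form(self):
        y, X = table_2x2_data(30, 70, 20, 80)
        fit = gk.fit_logistic(y, X, ["intercept", "exposed"])
        # independently computed ln(ad/bc) = ln((30*80)/(70*20))
        assert fit.coef[1] == pytest.approx(0.538997, abs=1e-6)
        se_expected = math.sqrt(1 / 30 + 1 / 70 + 1 / 20 + 1 / 80)
        assert fit.se[1] == pytest.approx(se_expected, abs=1e-6)

    @given(st.integers(5, 60), st.integers(5, 60), st.integers(5, 60), st.integers(5, 60))
    @settings(deadline=None, max_examples=30)
    def test_matches_contingency_formula(self, a, b, c, d):
        y, X = table_2x2_data(a, b, c, d)
        fit = gk.fit_logistic(y, X)
        assert fit.coef[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
        assert fit.se[1] == pytest.approx(
            math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            gk.fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_rank_deficiency_rejected(self):
        y = np.array([0, 1, 0, 1.0])
        X = np.column_stack([np.ones(4), np.arange(4), 2 * np.arange(4)])
        with pytest.raises(ValidationError, match="rank"):
            gk.fit_logistic(y, X)

    def test_perfect_separation_detected(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.concatenate([np.zeros(10), np.ones(10)])
        with pytest.raises(SeparationError):
            gk.fit_logistic(y, np.column_stack([np.ones(20), x]))


class TestPseudoR2:
    def test_no_improvement_gives_zero(self):
        assert gk.pseudo_r2(-100.0, -100.0, 200) == (0.0, 0.0)

    def test_perfect_prediction_nagelkerke_one(self):
        cs, nag = gk.pseudo_r2(-1e-12, -467.43, 734)
        assert nag == pytest.approx(1.0, abs=1e-10)

    def test_derived_example(self):
        # independently evaluated at n=734, case fraction 245/734
        P = 245 / 734
        ll_null = 734 * (P * math.log(P) + (1 - P) * math.log(1 - P))
        cs, nag = gk.pseudo_r2(ll_null + 3.30, ll_null, 734)
        assert cs == pytest.approx(0.008952, abs=2e-6)
        assert nag == pytest.approx(0.012430, abs=2e-6)

    def test_ordering_enforced(self):
        with pytest.raises(ValidationError):
            gk.pseudo_r2(-120.0, -100.0, 200)

    @given(st.floats(0.01, 40.0), st.floats(0.01, 40.0))
    @settings(deadline=None, max_examples=40)
    def test_monotone_in_model_loglik(self, gain1, gain2):
        ll_null = -300.0
        lo, hi = sorted([gain1, gain2])
        _, nag_lo = gk.pseudo_r2(ll_null + lo, ll_null, 500)
        _, nag_hi = gk.pseudo_r2(ll_null + hi, ll_null, 500)
        assert nag_hi >= nag_lo


class TestAssociate:
    def test_report_schema_and_consistency(self, simulated_cohort):
        cohort, _ = simulated_cohort
        scores = gk.score_cohort(cohort)
        res = gk.associate(scores, cohort.phenotypes)
        assert res.ci_low <= res.or_per_sd <= res.ci_high
        assert res.or_per_sd > 0 and res.ci_low > 0
        assert 0 <= res.r2_nagelkerke_full <= 1
        assert res.delta_r2_nagelkerke == pytest.approx(
            res.r2_nagelkerke_full - res.r2_nagelkerke_reduced, abs=1e-15
        )
        assert res.delta_r2_nagelkerke >= -1e-12  # full nests reduced
        assert res.loglik_full >= res.loglik_reduced >= res.loglik_null
        assert res.n == 734 and res.case_fraction == pytest.approx(245 / 734)
        # Wald p is exactly the two-sided normal tail of beta/se
        z = res.beta / res.se
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-15)

    def test_or_exponentiates_coefficient(self, simulated_cohort):
        cohort, _ = simulated_cohort
        scores = gk.score_cohort(cohort)
        res = gk.associate(scores, cohort.phenotypes)
        assert res.or_per_sd == pytest.approx(math.exp(res.beta), abs=1e-12)
        assert res.ci_low == pytest.approx(
            math.exp(res.beta - 1.959964 * res.se), rel=1e-10
        )

    def test_null_effect_calibration(self, bundled_weights):
        """With beta=0 the estimated per-SD log-OR is centered at zero and
        the delta-R2 stays at the noise floor (Monte Carlo, 60 replicates)."""
        dist = gk.exact_distribution(gk.SimulationSpec(beta_per_sd=0.0, seed=0))
        rng = np.random.default_rng(123)
        betas, dr2 = [], []
        for _ in range(60):
            spec = gk.SimulationSpec(beta_per_sd=0.0, seed=int(rng.integers(2**31)))
            cohort, _ = gk.sample_cohort(spec, dist)
            res = gk.associate(gk.score_cohort(cohort), cohort.phenotypes)
            betas.append(res.beta)
            dr2.append(res.delta_r2_nagelkerke)
        # se of mean beta ~ 0.078/sqrt(60) ~ 0.010; allow 3 sigma
        assert abs(np.mean(betas)) < 0.032
        assert np.mean(dr2) < 0.01

    def test_term_table_covers_design(self, simulated_cohort):
        cohort, _ = simulated_cohort
        res = gk.associate(gk.score_cohort(cohort), cohort.phenotypes)
        terms = set(res.term_table["term"])
        assert {"intercept", "std_score", "sex[female]", "country[CH]"} <= terms
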