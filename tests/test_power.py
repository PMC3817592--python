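"""Operating characteristics derived from the marginal moments: thresholds,
true type-1 error, power at nominal and recalibrated thresholds, GRAMMAR
bias, genomic-control inflation, effect conversions and design sizing."""

import numpy as np
import pytest

from assocpower.marginal import marginal_test_moments
from assocpower.models import ModelParams
from assocpower.models import TestMoments as Moments
from assocpower.pedigree import HalfSibDesign, RelationshipSet
from assocpower.power import (
    effect_conversions,
    gc_inflation,
    grammar_bias,
    nominal_threshold,
    power,
    rate_result,
    rate_table,
    required_sample_size,
    threshold_for_true_alpha,
    true_type1,
)

BETA_2PCT = float(np.sqrt(0.02))
DESIGN_600 = HalfSibDesign(10, 60)


def _unit_moments(method="fasta", E=0.0, V=1.0, hyp="H0"):
    return Moments(method, hyp, 0.0, 1.0, 1.0, E, V, 598)


class TestThresholds:
    @pytest.mark.parametrize("alpha,expected", [
        (0.05, 1.95996), (0.01, 2.57583), (0.5, 0.67449),
    ])
    def test_standard_quantiles(self, alpha, expected):
        assert nominal_threshold(alpha) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            nominal_threshold(alpha)


class TestTrueType1:
    def test_calibrated_test_recovers_nominal(self):
        assert true_type1(_unit_moments(), 0.01) == pytest.approx(0.01, abs=1e-12)

    def test_regression_halfsib_inflation(self):
        m0 = marginal_test_moments("regression", DESIGN_600, ModelParams(h2_true=0.5), "H0")
        assert true_type1(m0, 0.01) == pytest.approx(0.119, abs=0.001)

    def test_grammar_halfsib_deflation(self):
        m0 = marginal_test_moments("grammar", DESIGN_600, ModelParams(h2_true=0.5), "H0")
        assert true_type1(m0, 0.01) == pytest.approx(0.0038, abs=5e-5)

    def test_requires_null_moments(self):
        with pytest.raises(ValueError, match="null"):
            true_type1(_unit_moments(hyp="H1"), 0.01)


class TestPowerFunction:
    def test_effect_at_threshold_gives_half(self):
        m = _unit_moments(E=2.0, V=1.0, hyp="H1")
        assert power(m, 2.0) == pytest.approx(0.5)

    def test_threshold_roundtrip(self):
        for method, h2 in (("regression", 0.5), ("grammar", 0.3), ("qtdt", 0.7)):
            m0 = marginal_test_moments(method, DESIGN_600, ModelParams(h2_true=h2), "H0")
            t = threshold_for_true_alpha(m0, 0.01)
            assert true_type1(m0, 0.01) != pytest.approx(0.01, abs=1e-6) or method == "qtdt"
            # at the recalibrated threshold the null tail mass is alpha
            from scipy.stats import norm
            tail = 2 * (1 - norm.cdf(t / np.sqrt(m0.V_tau)))
            assert tail == pytest.approx(0.01, abs=1e-12)

    def test_inflated_null_needs_higher_threshold(self):
        m0 = marginal_test_moments("regression", DESIGN_600, ModelParams(h2_true=0.5), "H0")
        assert threshold_for_true_alpha(m0, 0.01) > nominal_threshold(0.01)

    def test_qtdt_power_matches_closed_form(self):
        """Discussion closed form: P = 1 - Phi(t_{alpha/2} - sqrt(n/2) b/sigma_y)."""
        from scipy.stats import norm
        params = ModelParams(h2_true=0.5, beta=BETA_2PCT)
        m0 = marginal_test_moments("qtdt", DESIGN_600, params, "H0")
        m1 = marginal_test_moments("qtdt", DESIGN_600, params, "H1")
        p = power(m1, threshold_for_true_alpha(m0, 0.01))
        closed = 1 - norm.cdf(nominal_threshold(0.01) - np.sqrt(300) * BETA_2PCT)
        assert p == pytest.approx(closed, abs=0.01)


class TestGrammarBias:
    def test_headline_value(self):
        params = ModelParams(h2_true=0.5, beta=BETA_2PCT)
        assert grammar_bias(DESIGN_600, params) == pytest.approx(-0.56, abs=0.005)

    def test_vanishing_heritability_no_shrinkage(self):
        params = ModelParams(h2_true=1e-6, beta=BETA_2PCT, h2_used=1e-6)
        assert grammar_bias(DESIGN_600, params) == pytest.approx(0.0, abs=1e-3)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            grammar_bias(DESIGN_600, ModelParams(h2_true=0.5, beta=0.0))

    def test_bias_matches_simulator(self):
        """E(beta_hat)/b - 1 against the mean replicated GRAMMAR estimate
        (variance components re-estimated by REML per replicate)."""
        from assocpower.simulate import SimConfig, empirical_rates

        ds = HalfSibDesign(10, 60)
        params = ModelParams(h2_true=0.5, beta=BETA_2PCT)
        expected = grammar_bias(ds, params)
        cfg = SimConfig(design=ds, beta_allele=0.2, h2_grid=(0.5,),
                        n_reps=2000, seed=23, methods=("grammar",))
        df = empirical_rates(cfg)
        row = df[(df.hypothesis == "H1")].iloc[0]
        emp_bias = row.mean_beta_hat / cfg.beta - 1.0
        # SE of the mean relative estimate, from the analytic estimator SD
        m1 = marginal_test_moments("grammar", ds, params, "H1")
        se = np.sqrt(m1.V_beta_hat) / cfg.beta / np.sqrt(row.n_reps)
        assert emp_bias == pytest.approx(expected, abs=3 * se)


class TestGCInflation:
    def test_identity_A_exactly_one(self):
        rel = RelationshipSet(np.eye(50), 0.5 * np.eye(50))
        m0 = marginal_test_moments("regression", rel, ModelParams(h2_true=0.6), "H0")
        assert gc_inflation(m0) == pytest.approx(1.0, abs=1e-12)

    def test_halfsib_patterns(self):
        params = ModelParams(h2_true=0.5)
        m_reg = marginal_test_moments("regression", DESIGN_600, params, "H0")
        m_gra = marginal_test_moments("grammar", DESIGN_600, params, "H0")
        m_fas = marginal_test_moments("fasta", DESIGN_600, params, "H0")
        assert gc_inflation(m_reg) > 1.0
        assert gc_inflation(m_gra) < 1.0
        assert gc_inflation(m_fas) == pytest.approx(1.0, abs=1e-6)


class TestEffectConversions:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.20), (0.1, 0.33)])
    def test_allele_substitution_effect(self, p, expected):
        params = ModelParams(h2_true=0.5, beta=0.1414, p=p)
        beta_allele, _ = effect_conversions(params)
        assert beta_allele == pytest.approx(expected, abs=0.005)

    def test_full_ld_keeps_beta(self):
        params = ModelParams(h2_true=0.5, beta=0.1414, r2=1.0)
        assert effect_conversions(params)[1] == pytest.approx(0.1414)

    def test_partial_ld_scales_up_qtl_effect(self):
        params = ModelParams(h2_true=0.5, beta=0.1, r2=0.25)
        assert effect_conversions(params)[1] == pytest.approx(0.2)


class TestMethodComparisons:
    H2_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
    DESIGNS = ((120, 5), (20, 30), (10, 60))

    def _power_true(self, method, ds, h2, h2_used=None):
        params = ModelParams(h2_true=h2, beta=BETA_2PCT, h2_used=h2_used)
        m0 = marginal_test_moments(method, ds, params, "H0")
        m1 = marginal_test_moments(method, ds, params, "H1")
        return power(m1, threshold_for_true_alpha(m0, 0.01))

    def test_grammar_equals_fasta_at_true_alpha(self):
        """The two statistics share their numerator, so given the variance
        components, recalibrating the threshold makes their powers identical;
        the plug-in expectation of the estimated components adds only a small
        low-heritability deviation."""
        for f, d in self.DESIGNS:
            for h2 in self.H2_GRID:
                ds = HalfSibDesign(f, d)
                pg = self._power_true("grammar", ds, h2, h2_used=h2)
                pf = self._power_true("fasta", ds, h2, h2_used=h2)
                assert abs(pg - pf) < 0.005, (f, d, h2)
                # default plug-in rule: the extra component-estimation effect
                pg = self._power_true("grammar", ds, h2)
                pf = self._power_true("fasta", ds, h2)
                assert abs(pg - pf) < 0.006, (f, d, h2)

    def test_regression_never_beats_fasta_at_true_alpha(self):
        for f, d in self.DESIGNS:
            for h2 in self.H2_GRID:
                ds = HalfSibDesign(f, d)
                assert (
                    self._power_true("regression", ds, h2)
                    <= self._power_true("fasta", ds, h2) + 1e-9
                )

    def test_fasta_true_alpha_stays_nominal(self):
        for f, d in self.DESIGNS:
            for h2 in self.H2_GRID:
                params = ModelParams(h2_true=h2)
                m0 = marginal_test_moments("fasta", HalfSibDesign(f, d), params, "H0")
                assert 0.008 <= true_type1(m0, 0.01) <= 0.012

    def test_misspecified_heritability_type1(self):
        """True h2 = 0.30 but 0.05 plugged into the two-step methods."""
        params = ModelParams(h2_true=0.30, h2_used=0.05)
        mg = marginal_test_moments("grammar", DESIGN_600, params, "H0")
        mf = marginal_test_moments("fasta", DESIGN_600, params, "H0")
        assert true_type1(mg, 0.01) == pytest.approx(0.019, abs=0.001)
        assert true_type1(mf, 0.01) == pytest.approx(0.025, abs=0.001)

    def test_overestimated_heritability_is_safe(self):
        for h2_used in (0.30, 0.40, 0.55):
            params = ModelParams(h2_true=0.30, h2_used=h2_used)
            for method in ("grammar", "fasta"):
                m0 = marginal_test_moments(method, DESIGN_600, params, "H0")
                assert true_type1(m0, 0.01) <= 0.012

    def test_fasta_power_loss_from_underestimated_h2(self):
        loss = self._power_true("fasta", DESIGN_600, 0.30, h2_used=0.30) - \
            self._power_true("fasta", DESIGN_600, 0.30, h2_used=0.10)
        assert loss == pytest.approx(0.04, abs=0.005)


class TestRequiredSampleSize:
    def test_power_monotone_in_n(self):
        params = ModelParams(h2_true=0.5, beta=BETA_2PCT)
        powers = []
        for k in (5, 10, 20, 40):
            ds = HalfSibDesign(k, 30)
            m0 = marginal_test_moments("fasta", ds, params, "H0")
            m1 = marginal_test_moments("fasta", ds, params, "H1")
            powers.append(power(m1, threshold_for_true_alpha(m0, 0.01)))
        assert np.all(np.diff(powers) > 0)

    def test_bracketing(self):
        """Returned n reaches the target; one family fewer does not."""
        n = required_sample_size(0.8, 0.01, 60, 0.5, 0.02)
        params = ModelParams(h2_true=0.5, beta=BETA_2PCT)

        def p_true(k):
            ds = HalfSibDesign(k, 60)
            m0 = marginal_test_moments("fasta", ds, params, "H0")
            m1 = marginal_test_moments("fasta", ds, params, "H1")
            return power(m1, threshold_for_true_alpha(m0, 0.01))

        k = n // 60
        assert p_true(k) >= 0.8
        assert p_true(k - 1) < 0.8

    def test_no_structure_effect_without_heritability(self):
        """With h2 = 0 and no shrinkage, relatives carry no phenotypic
        information about each other; the only residual family-size effect is
        through the genotypic variance of the centred SNP code,
        Ex(x'x) = n - (1 + (d-1)/4), plus rounding to whole families."""
        base = required_sample_size(0.8, 0.01, 1, 0.0, 0.02, h2_used=0.0)
        info_needed = base - 1.0  # Ex(x'x) at the single-animal-family design
        for d in (5, 30, 60):
            n = required_sample_size(0.8, 0.01, d, 0.0, 0.02, h2_used=0.0)
            k = n // d
            assert k * d - (1 + 0.25 * (d - 1)) >= info_needed - 1e-6
            assert (k - 1) * d - (1 + 0.25 * (d - 1)) < info_needed

    def test_unreachable_target_raises(self):
        with pytest.raises(RuntimeError, match="not reached"):
            required_sample_size(0.999999, 1e-12, 60, 0.5, 1e-7, max_n=5000)


class TestRateTable:
    def test_tidy_output_columns_and_rates(self):
        df = rate_table(HalfSibDesign(6, 10), [0.2, 0.6], alpha=0.01)
        assert list(df.columns) == [
            "method", "n", "family_size", "h2_true", "h2_used", "alpha_nominal",
            "alpha_true", "power_nominal", "power_true", "bias_rel", "gc_lambda",
        ]
        assert len(df) == 8
        assert ((df.alpha_true > 0) & (df.alpha_true < 1)).all()
        assert ((df.power_true >= 0) & (df.power_true <= 1)).all()

    def test_rate_result_without_effect(self):
        res = rate_result("fasta", HalfSibDesign(6, 10), ModelParams(h2_true=0.4))
        assert res.bias_rel is None
        assert res.alpha_true == pytest.approx(0.01, abs=1e-4)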