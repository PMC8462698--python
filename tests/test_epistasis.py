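"""Bootstrap machinery, additive expectation, and interaction classification."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import binomtest

from thermopanel.effects import EffectEstimate
from thermopanel.epistasis import (
    additive_expectation,
    bootstrap_effect,
    classify_locus_interaction,
    enumerate_boot_means,
    epistasis_test,
    panel_bootstrap_effects,
    resample_means,
    trend_binomial_test,
)
from thermopanel.model import PanelError
from thermopanel.synthetic import (
    generate_growth_panel,
    panel_strains,
    strain_id_for,
)

from test_effects import table_from


def est(effect, boot, locus="L", ci=None):
    e = EffectEstimate(
        locus=locus,
        background="recipient_wt",
        effect=effect,
        n_focal=8,
        n_ref=8,
        boot=np.asarray(boot, dtype=float),
    )
    e.ci = ci if ci is not None else e.ci_from_boot()
    return e


class TestBootstrapEffect:
    def test_zero_variance_groups_constant_iterates(self, rng):
        t = table_from({"a": [0.7, 0.7, 0.7], "b": [0.2, 0.2, 0.2]})
        boot = bootstrap_effect(t, "a", "b", 39.0, 200, rng)
        assert np.all(boot == pytest.approx(0.5))

    def test_seed_determinism(self):
        t = table_from({"a": [0.5, 0.9, 0.7], "b": [0.1, 0.3, 0.2]})
        b1 = bootstrap_effect(t, "a", "b", 39.0, 500, np.random.default_rng(3))
        b2 = bootstrap_effect(t, "a", "b", 39.0, 500, np.random.default_rng(3))
        assert np.array_equal(b1, b2)

    def test_boot_mean_consistent_with_point_estimate(self, rng):
        t = table_from(
            {"a": list(np.linspace(0.4, 0.8, 8)), "b": list(np.linspace(0.1, 0.3, 8))}
        )
        boot = bootstrap_effect(t, "a", "b", 39.0, 5000, rng)
        point = 0.6 - 0.2
        se = boot.std()
        assert abs(boot.mean() - point) < 3 * se / np.sqrt(5000) * 50  # MC slack
        assert abs(boot.mean() - point) < 3 * se

    def test_single_replicate_warns_but_runs(self, rng):
        t = table_from({"a": [0.5], "b": [0.1, 0.2]})
        with pytest.warns(UserWarning, match="degenerate"):
            boot = bootstrap_effect(t, "a", "b", 39.0, 50, rng)
        assert boot.size == 50

    def test_matches_exhaustive_enumeration_two_replicates(self):
        """MC frequencies match the exact with-replacement resample law."""
        x, y = [0.5, 0.9], [0.1, 0.3]
        t = table_from({"a": x, "b": y})
        n_boot = 40_000
        boot = bootstrap_effect(
            t, "a", "b", 39.0, n_boot, np.random.default_rng(12)
        )
        mx, px = enumerate_boot_means(x)
        my, py = enumerate_boot_means(y)
        attainable = {}
        for (vx, pxi), (vy, pyi) in product(zip(mx, px), zip(my, py)):
            attainable[round(vx - vy, 12)] = (
                attainable.get(round(vx - vy, 12), 0) + pxi * pyi
            )
        # every draw lies in the attainable set
        assert set(np.round(boot, 12)) <= set(attainable)
        # frequencies agree with exact probabilities
        for v, p in attainable.items():
            freq = np.mean(np.round(boot, 12) == v)
            se = np.sqrt(p * (1 - p) / n_boot)
            assert abs(freq - p) < 4 * se + 1e-9


class TestAdditiveExpectation:
    def test_zero_effects_sum_zero(self, rng):
        effects = [est(0.0, np.zeros(100)) for _ in range(8)]
        exp = additive_expectation(effects)
        assert exp.point == 0.0
        assert np.all(exp.boot == 0.0)

    def test_eight_equal_effects(self, rng):
        effects = [est(0.05, np.full(100, 0.05)) for _ in range(8)]
        assert additive_expectation(effects).point == pytest.approx(0.4)

    def test_mismatched_boot_lengths_rejected(self):
        with pytest.raises(PanelError, match="mismatch"):
            additive_expectation([est(0.1, np.zeros(10)), est(0.1, np.zeros(20))])

    def test_independent_variances_add(self, rng):
        """Var of the summed bootstrap ~ sum of per-locus boot variances."""
        effects = []
        for i in range(8):
            boot = rng.normal(0.05, 0.01 * (i + 1), 20_000)
            effects.append(est(0.05, boot))
        exp = additive_expectation(effects)
        expected_var = sum(e.boot.var() for e in effects)
        assert exp.boot.var() == pytest.approx(expected_var, rel=0.05)


class TestEpistasisTest:
    def test_identical_distributions_label_none(self, rng):
        boot = rng.normal(0.4, 0.05, 2000)
        observed = est(0.4, boot)
        from thermopanel.epistasis import AdditiveExpectation

        expected = AdditiveExpectation(point=0.4, boot=boot.copy())
        res = epistasis_test(observed, expected)
        assert res.label == "none"
        assert res.epsilon == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_noise_additive_panel_max_p(self, zero_noise_config, rng):
        strains = panel_strains(zero_noise_config)
        t = generate_growth_panel(zero_noise_config, strains, 39.0)
        singles = [
            strain_id_for([1 if j == i else 0 for j in range(8)])
            for i in range(8)
        ]
        joint = strain_id_for([1] * 8)
        ests = panel_bootstrap_effects(
            t, singles + [joint], "recipient_wt", 39.0, 500, rng
        )
        exp = additive_expectation([ests[s] for s in singles])
        res = epistasis_test(ests[joint], exp)
        assert abs(res.epsilon) < 1e-12
        assert res.p_value == pytest.approx(1.0)
        assert res.label == "none"

    def test_smoothed_p_strictly_inside_unit_interval(self, rng):
        observed = est(-1.0, np.full(1000, -1.0))
        from thermopanel.epistasis import AdditiveExpectation

        expected = AdditiveExpectation(point=0.0, boot=np.zeros(1000))
        res = epistasis_test(observed, expected, alternative="less")
        assert 0 < res.p_value <= 1
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.label == "negative_magnitude"

    def test_two_sided_doubles(self, rng):
        boot_o = rng.normal(-0.1, 0.02, 4000)
        observed = est(-0.1, boot_o)
        from thermopanel.epistasis import AdditiveExpectation

        expected = AdditiveExpectation(point=0.0, boot=rng.normal(0, 0.02, 4000))
        one = epistasis_test(observed, expected, alternative="less").p_value
        two = epistasis_test(observed, expected, alternative="two_sided").p_value
        assert two == pytest.approx(min(1.0, 2 * one))

    def test_small_n_boot_warns(self, rng):
        observed = est(0.0, np.zeros(10))
        from thermopanel.epistasis import AdditiveExpectation

        with pytest.warns(UserWarning, match="unstable"):
            epistasis_test(observed, AdditiveExpectation(0.0, np.zeros(10)))

    def test_mismatched_lengths_rejected(self, rng):
        from thermopanel.epistasis import AdditiveExpectation

        with pytest.raises(PanelError):
            epistasis_test(
                est(0.0, np.zeros(10)), AdditiveExpectation(0.0, np.zeros(20))
            )


class TestClassification:
    def test_masking_definition(self, rng):
        alone = est(0.1, rng.normal(0.10, 0.025, 4000))
        combo = est(0.005, rng.normal(0.005, 0.018, 4000))
        assert classify_locus_interaction(alone, combo) == "masking"

    def test_sign_definition(self, rng):
        alone = est(0.1, rng.normal(0.10, 0.025, 4000))
        combo = est(-0.1, rng.normal(-0.10, 0.025, 4000))
        assert classify_locus_interaction(alone, combo) == "sign"

    def test_negative_magnitude_definition(self, rng):
        alone = est(0.30, rng.normal(0.30, 0.01, 4000))
        combo = est(0.10, rng.normal(0.10, 0.01, 4000))
        assert classify_locus_interaction(alone, combo) == "negative_magnitude"

    def test_equal_effects_none(self, rng):
        boot = rng.normal(0.2, 0.02, 4000)
        assert classify_locus_interaction(est(0.2, boot), est(0.2, boot.copy())) == (
            "none"
        )

    def test_missing_boot_rejected(self):
        a = EffectEstimate("L", "wt", 0.1, 8, 8)
        with pytest.raises(PanelError):
            classify_locus_interaction(a, a)


class TestTrendBinomial:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(7, 8, 9 / 256), (8, 8, 1 / 256), (4, 8, 163 / 256)],
    )
    def test_closed_form_cases(self, k, n, expected):
        effects = [est(0.1 if i < k else -0.1, np.zeros(10)) for i in range(n)]
        res = trend_binomial_test(effects)
        assert res.n_positive == k
        assert res.p_value == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_matches_exact_binomial_tail_all_k(self, n):
        for k in range(n + 1):
            effects = [est(0.1 if i < k else -0.1, np.zeros(4)) for i in range(n)]
            res = trend_binomial_test(effects)
            oracle = binomtest(k, n, 0.5, alternative="greater").pvalue
            assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_significant_positive_criterion(self, rng):
        strong = est(0.1, rng.normal(0.1, 0.01, 1000))
        weak = est(0.02, rng.normal(0.02, 0.05, 1000))
        res = trend_binomial_test([strong, weak], criterion="significant_positive")
        assert res.n_positive == 1

    def test_empty_path_rejected(self):
        with pytest.raises(PanelError):
            trend_binomial_test([])


def test_resample_means_reference_sharing(rng):
    """Shared-reference effects carry the reference's iterate correlation."""
    t = table_from(
        {
            "wt": list(np.linspace(0.1, 0.5, 8)),
            "a": list(np.linspace(0.4, 0.8, 8)),
            "b": list(np.linspace(0.5, 0.9, 8)),
        }
    )
    ests = panel_bootstrap_effects(t, ["a", "b"], "wt", 39.0, 4000, rng)
    r = np.corrcoef(ests["a"].boot, ests["b"].boot)[0, 1]
    assert r > 0.2  # common wild-type draw induces positive correlation
    ests_ind = panel_bootstrap_effects(
        t, ["a", "b"], "wt", 39.0, 4000, rng, share_reference=False
    )
    r_ind = np.corrcoef(ests_ind["a"].boot, ests_ind["b"].boot)[0, 1]
    assert abs(r_ind) < 0.1
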