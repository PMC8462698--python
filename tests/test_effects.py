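"""Effect estimation, path decomposition, and rank-test inference."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermopanel.effects import (
    bh_adjust,
    compare_strains,
    fold_change,
    marginal_effect,
    path_effects,
    pairwise_comparisons,
    rank_sum_test,
    recapitulation_fraction,
    strain_efficiencies,
)
from thermopanel.model import PanelError
from thermopanel.phenotypes import with_efficiency
from thermopanel.synthetic import (
    SyntheticConfig,
    generate_growth_panel,
    panel_strains,
    strain_id_for,
)


def table_from(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for sid, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "strain_id": sid,
                    "genotype": "",
                    "temperature_C": 39.0,
                    "replicate": f"r{i}",
                    "day": "d1",
                    "od_initial": 0.1,
                    "od_final": 0.1 + v,
                    "duration_h": 24.0,
                }
            )
    return pd.DataFrame(rows)


class TestMarginalEffect:
    def test_identical_groups_zero(self):
        t = table_from({"a": [0.5, 0.6], "b": [0.5, 0.6]})
        assert marginal_effect(t, "a", "b", 39.0).effect == 0.0

    def test_arithmetic(self):
        t = table_from({"a": [0.5, 0.6, 0.7], "b": [0.2, 0.3, 0.4]})
        est = marginal_effect(t, "a", "b", 39.0)
        assert est.effect == pytest.approx(0.3)
        assert (est.n_focal, est.n_ref) == (3, 3)

    def test_zero_noise_panel_recovers_configured_effect(
        self, zero_noise_config
    ):
        strains = panel_strains(zero_noise_config)
        t = generate_growth_panel(zero_noise_config, strains, 39.0)
        single = strain_id_for([1] + [0] * 7)
        est = marginal_effect(t, single, "recipient_wt", 39.0)
        assert est.effect == pytest.approx(
            zero_noise_config.effect_of("DYN1"), abs=1e-12
        )

    def test_missing_strain_named_in_error(self):
        t = table_from({"a": [0.5]})
        with pytest.raises(PanelError, match="ghost"):
            marginal_effect(t, "ghost", "a", 39.0)

    def test_row_order_invariance(self, growth_table):
        shuffled = growth_table.sample(frac=1, random_state=1)
        a = marginal_effect(growth_table, "swap_11111111", "recipient_wt", 39.0)
        b = marginal_effect(shuffled, "swap_11111111", "recipient_wt", 39.0)
        assert a.effect == b.effect


class TestPathEffects:
    def test_zero_noise_path_equals_configured_effects(self, zero_noise_config):
        strains = panel_strains(zero_noise_config)
        t = generate_growth_panel(zero_noise_config, strains, 39.0)
        names = list(zero_noise_config.locus_names)
        path = ["recipient_wt"]
        bits = [0] * 8
        for n in names:
            bits[names.index(n)] = 1
            path.append(strain_id_for(bits))
        steps = path_effects(t, path, 39.0, loci=names)
        for step, locus in zip(steps, names):
            assert step.locus == locus
            assert step.effect == pytest.approx(
                zero_noise_config.effect_of(locus), abs=1e-12
            )

    def test_two_bit_jump_rejected(self, zero_noise_config):
        strains = panel_strains(zero_noise_config)
        t = generate_growth_panel(zero_noise_config, strains, 39.0)
        path = ["recipient_wt", strain_id_for([1, 1] + [0] * 6)]
        with pytest.raises(PanelError, match="toggles 2"):
            path_effects(t, path, 39.0)

    def test_telescoping_conservation(self, synth_config):
        """Path effects sum exactly to the endpoint mean difference."""
        strains = panel_strains(synth_config)
        t = generate_growth_panel(synth_config, strains, 39.0)
        names = list(synth_config.locus_names)
        path = ["recipient_wt"]
        bits = [0] * 8
        for n in names:
            bits[names.index(n)] = 1
            path.append(strain_id_for(bits))
        steps = path_effects(t, path, 39.0, loci=names)
        total = sum(s.effect for s in steps)
        end = strain_efficiencies(t, path[-1], 39.0).mean()
        start = strain_efficiencies(t, path[0], 39.0).mean()
        assert total == pytest.approx(end - start, abs=1e-12)


class TestRatios:
    def test_fold_change_identity(self):
        t = table_from({"a": [0.3, 0.4], "b": [0.3, 0.4]})
        assert fold_change(t, "a", "b", 39.0) == pytest.approx(1.0)

    def test_fold_change_matches_published_style_ratio(self):
        t = table_from({"a": [0.62], "b": [0.30]})
        assert fold_change(t, "a", "b", 39.0) == pytest.approx(2.0667, abs=1e-3)

    def test_fold_change_nonpositive_reference(self):
        t = table_from({"a": [0.5], "b": [0.0]})
        with pytest.raises(PanelError, match="not positive"):
            fold_change(t, "a", "b", 39.0)

    def test_recapitulation_endpoints_and_example(self):
        t = table_from(
            {"rec": [0.2], "don": [2.2], "trans": [0.5]}
        )
        assert recapitulation_fraction(t, "rec", "rec", "don", 39.0) == 0.0
        assert recapitulation_fraction(t, "don", "rec", "don", 39.0) == 100.0
        assert recapitulation_fraction(t, "trans", "rec", "don", 39.0) == (
            pytest.approx(15.0, abs=1e-12)
        )

    def test_recapitulation_degenerate(self):
        t = table_from({"rec": [0.2], "trans": [0.5]})
        with pytest.raises(PanelError):
            recapitulation_fraction(t, "trans", "rec", "rec", 39.0)


def brute_force_rank_p(x, y, alternative):
    """Enumerate all rank partitions; exact Mann-Whitney tail probability."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def u_stat(a, b):
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = u_stat(x, y)
    idx = range(len(pooled))
    hits = total = 0
    for comb in combinations(idx, n1):
        a = pooled[list(comb)]
        b = pooled[[i for i in idx if i not in comb]]
        u = u_stat(a, b)
        total += 1
        if alternative == "greater":
            hits += u >= u_obs - 1e-12
        elif alternative == "less":
            hits += u <= u_obs + 1e-12
        else:
            u_mean = n1 * (len(pooled) - n1) / 2
            hits += abs(u - u_mean) >= abs(u_obs - u_mean) - 1e-12
    return hits / total


class TestRankSum:
    def test_identical_samples_two_sided_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3], "two-sided")
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_exact_case(self):
        # complete separation, 3 vs 3: one of C(6,3)=20 orderings
        res = rank_sum_test([1, 2, 3], [4, 5, 6], "less")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)

    def test_two_sided_doubles_one_sided_without_ties(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        one = min(
            rank_sum_test(x, y, "less").p_value,
            rank_sum_test(x, y, "greater").p_value,
        )
        two = rank_sum_test(x, y, "two-sided").p_value
        assert two == pytest.approx(2 * one)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (6, 6)])
    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_exact_p_matches_enumeration(self, n1, n2, alternative):
        rng = np.random.default_rng(n1 * 10 + n2)
        x, y = rng.normal(0, 1, n1), rng.normal(0.5, 1, n2)
        res = rank_sum_test(x, y, alternative)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            brute_force_rank_p(x, y, alternative), abs=1e-12
        )

    def test_ties_fall_back_to_corrected_normal(self):
        res = rank_sum_test([1, 1, 2, 3], [2, 2, 3, 4], "two-sided")
        assert res.method == "asymptotic"
        assert 0 < res.p_value <= 1

    def test_compare_strains_from_table(self):
        t = table_from({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = compare_strains(t, "a", "b", 39.0, sidedness="less")
        assert res.p_value == pytest.approx(0.05)


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_p_unchanged(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(PanelError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12),
        st.randoms(use_true_random=False),
    )
    def test_order_invariance_and_dominance(self, pvals, rnd):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q_perm = bh_adjust([pvals[i] for i in perm])
        assert np.allclose(q_perm, q[perm])


def test_pairwise_family_q_monotone(growth_table):
    strains = ["recipient_wt", "swap_11111111", "swap_10000000"]
    df = pairwise_comparisons(growth_table, strains, 39.0, sidedness="greater")
    assert len(df) == 3
    s = df.sort_values("p_value")
    assert s["q_value"].is_monotonic_increasing
    assert (df["q_value"] >= df["p_value"] - 1e-15).all()
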