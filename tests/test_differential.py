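"""CLR, two-way ANOVA, two-group tests, presence screen, Shannon, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tknet.differential import (
    align_union,
    bh_adjust,
    clr_transform,
    compartment_specific_features,
    shannon_diversity,
    two_group_differential,
    two_way_anova,
)
from tknet.exceptions import DesignError, ValidationError


def table(values, prefix="f"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


# ----------------------------------------------------------------------- CLR
class TestClr:
    def test_equal_parts_map_to_zero(self):
        out = clr_transform(table([[1], [1], [1], [1]]), pseudocount=0.5)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_hand_computed_values(self):
        # ln(1), ln(10), ln(100) centred: (-2.302585, 0, +2.302585)
        out = clr_transform(table([[1], [10], [100]]), pseudocount=0.0)
        np.testing.assert_allclose(
            out.to_numpy().ravel(), [-2.302585093, 0.0, 2.302585093], atol=1e-8
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 500, size=(rng.integers(2, 40), rng.integers(1, 15)))
        out = clr_transform(table(counts), pseudocount=0.5)
        assert np.abs(out.sum(axis=0)).max() < 1e-9 * counts.shape[0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            clr_transform(table([[1], [-1]]))

    def test_zero_pseudocount_needs_positive_counts(self):
        with pytest.raises(ValidationError):
            clr_transform(table([[0], [1]]), pseudocount=0.0)


# -------------------------------------------------------------- two-way ANOVA
def _design(n_per_cell=3, seed=0):
    diet = np.repeat(["NC", "HFD"], 2 * n_per_cell)
    seg = np.tile(np.repeat(["A", "B"], n_per_cell), 2)
    return diet, seg


class TestTwoWayAnova:
    def test_matches_statsmodels_type2(self):
        """Hand-sized 2x2 with n=3/cell against an independent type-II ANOVA."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        diet, seg = _design(3)
        y = rng.normal(size=(4, 12)) + 0.8 * (diet == "HFD") + 0.5 * (seg == "B")
        res = two_way_anova(table(y), diet, seg)
        for i in range(4):
            df = pd.DataFrame({"y": y[i], "diet": diet, "seg": seg})
            fit = ols("y ~ C(diet) * C(seg)", data=df).fit()
            ref = sm.stats.anova_lm(fit, typ=2)
            np.testing.assert_allclose(res["F_diet"].iloc[i], ref.loc["C(diet)", "F"], rtol=1e-8)
            np.testing.assert_allclose(res["F_segment"].iloc[i], ref.loc["C(seg)", "F"], rtol=1e-8)
            np.testing.assert_allclose(
                res["F_interaction"].iloc[i], ref.loc["C(diet):C(seg)", "F"], rtol=1e-8
            )
            np.testing.assert_allclose(
                res["p_interaction"].iloc[i], ref.loc["C(diet):C(seg)", "PR(>F)"], rtol=1e-8
            )

    def test_f_diet_equals_squared_t_on_balanced_design(self):
        """On a balanced 2x2 the diet factor is orthogonal to the others, so
        the type-II F equals the squared t of the diet coefficient in the full
        linear model."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        diet, seg = _design(4)
        y = rng.normal(size=(3, 16))
        res = two_way_anova(table(y), diet, seg)
        # centred (effect) coding keeps the three terms orthogonal
        d = (diet == diet[0]).astype(float) - 0.5
        s = (seg == seg[0]).astype(float) - 0.5
        x = sm.add_constant(np.column_stack([d, s, d * s]))
        for i in range(3):
            fit = sm.OLS(y[i], x).fit()
            np.testing.assert_allclose(res["F_diet"].iloc[i], fit.tvalues[1] ** 2, rtol=1e-8)

    def test_interaction_null_pass_rate_controlled(self):
        """Purely additive truth: interaction discoveries at FDR 5% stay rare."""
        rng = np.random.default_rng(17)
        diet, seg = _design(6)
        n_feat = 1000
        y = (
            rng.normal(size=(n_feat, 24))
            + rng.normal(size=(n_feat, 1)) * (diet == "HFD")
            + rng.normal(size=(n_feat, 1)) * (seg == "B")
        )
        res = two_way_anova(table(y), diet, seg)
        assert res["pass"].mean() <= 0.07

    def test_null_diet_term_uniform(self):
        rng = np.random.default_rng(2)
        diet, seg = _design(6)
        y = rng.normal(size=(400, 24))
        res = two_way_anova(table(y), diet, seg)
        assert stats.kstest(res["p_diet"].to_numpy(), "uniform").pvalue > 0.01

    def test_small_cell_rejected(self):
        diet = np.array(["NC", "NC", "NC", "HFD", "HFD", "HFD"])
        seg = np.array(["A", "A", "B", "A", "A", "B"])  # B cells have 1 sample
        with pytest.raises(DesignError):
            two_way_anova(table(np.zeros((2, 6))), diet, seg)

    def test_zero_variance_feature_gets_missing_p(self):
        rng = np.random.default_rng(3)
        diet, seg = _design(3)
        y = np.vstack([np.full(12, 7.0), rng.normal(size=12)])
        res = two_way_anova(table(y), diet, seg)
        assert np.isnan(res["p_interaction"].iloc[0])
        assert np.isfinite(res["p_interaction"].iloc[1])


# ------------------------------------------------------------------ two-group
class TestTwoGroup:
    diet = np.array(["NC"] * 12 + ["HFD"] * 12)

    def test_null_q_values_near_one(self):
        rng = np.random.default_rng(4)
        res = two_group_differential(table(rng.normal(size=(200, 24))), self.diet)
        assert (res["q"] > 0.5).mean() > 0.8

    def test_planted_effects_recovered(self):
        """+2 SD shift on 10% of features, n = 12 vs 12: at least 80% of the
        planted features are recovered at q < 0.05 (averaged over 10 seeds)."""
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = rng.normal(size=(120, 24))
            y[:12, 12:] += 2.0
            res = two_group_differential(table(y), self.diet)
            rates.append(res["pass"].iloc[:12].mean())
        assert np.mean(rates) >= 0.80

    def test_swapped_labels_negate_signs(self):
        rng = np.random.default_rng(6)
        y = table(rng.normal(size=(30, 24)))
        a = two_group_differential(y, self.diet)
        swapped = np.where(self.diet == "NC", "HFD", "NC")
        b = two_group_differential(y, swapped)
        np.testing.assert_array_equal(a["sign"].to_numpy(), -b["sign"].to_numpy())
        np.testing.assert_allclose(a["p"].to_numpy(), b["p"].to_numpy())

    def test_constant_feature_missing_p_and_zero_sign(self):
        y = table(np.vstack([np.full(24, 3.0), np.random.default_rng(0).normal(size=24)]))
        res = two_group_differential(y, self.diet)
        assert np.isnan(res["p"].iloc[0]) and res["sign"].iloc[0] == 0

    def test_welch_method(self):
        rng = np.random.default_rng(9)
        y = table(rng.normal(size=(10, 24)))
        res = two_group_differential(y, self.diet, method="welch")
        assert res["p"].between(0, 1).all()

    def test_group_too_small_rejected(self):
        with pytest.raises(DesignError):
            two_group_differential(
                table(np.zeros((2, 4))), np.array(["NC", "NC", "HFD", "HFD"])
            )


# --------------------------------------------------------------- BH adjust
def _bh_reference(p):
    """Brute-force step-up: sort, p*m/rank, cumulative min from the largest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.mark.parametrize("n", [1, 5, 100, 1000])
def test_bh_agrees_with_brute_force(n):
    rng = np.random.default_rng(n)
    p = rng.random(n)
    np.testing.assert_allclose(bh_adjust(p), _bh_reference(p), atol=1e-12)


def test_bh_ignores_nan():
    q = bh_adjust(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1])
    np.testing.assert_allclose(q[[0, 2]], _bh_reference([0.01, 0.5]))


# -------------------------------------------------- compartment-specific taxa
class TestSpecificFeatures:
    def test_trivial_membership(self):
        a = table([[5] * 6, [0] * 6], prefix="g")
        b = table([[0] * 6, [0] * 6], prefix="g")
        set_a, set_b = compartment_specific_features(a, b)
        assert set_a == {"g0"} and set_b == set()

    def test_randomised_presence_yields_empty_sets(self):
        rng = np.random.default_rng(12)
        a = table((rng.random((100, 12)) < 0.5).astype(int), prefix="g")
        b = table((rng.random((100, 12)) < 0.5).astype(int), prefix="g")
        set_a, set_b = compartment_specific_features(a, b)
        assert len(set_a) + len(set_b) <= 2  # ~0 expected under the default rule

    def test_namespace_mismatch_rejected(self):
        a = table([[1]], prefix="x")
        b = table([[1]], prefix="y")
        with pytest.raises(ValidationError):
            compartment_specific_features(a, b)
        aa, bb = align_union(a, b)
        assert aa.index.equals(bb.index)
        assert bb.loc["x0"].sum() == 0


# ------------------------------------------------------------------- Shannon
class TestShannon:
    def test_uniform_maximum(self):
        h = shannon_diversity(table([[10], [10], [10], [10]]))
        np.testing.assert_allclose(h.iloc[0], np.log(4), atol=1e-12)

    def test_single_taxon_is_zero(self):
        h = shannon_diversity(table([[7], [0], [0]]))
        assert h.iloc[0] == 0.0

    def test_hand_computed_value(self):
        # p = (.1, .2, .3, .4): H = 1.27985422583
        h = shannon_diversity(table([[1], [2], [3], [4]]))
        np.testing.assert_allclose(h.iloc[0], 1.2798542258, atol=1e-9)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            shannon_diversity(table([[0], [0]]))
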