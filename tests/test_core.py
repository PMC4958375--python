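"""Closed-form belief updates against quadrature oracles and model properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from bcv.core import (
    CuedContextModel,
    FlatContextModel,
    GaussianBelief,
    HierarchicalContextModel,
    InvalidModelError,
    hierarchical_posterior_chain,
    hierarchical_weights,
    incentive_value_cued,
    incentive_value_flat,
    incentive_value_hierarchical,
    posterior_context_given_reward,
    update_on_context_cue,
)

variances = st.floats(0.3, 3.0)
observations = st.floats(-3.0, 3.0)
SETTINGS = settings(max_examples=25, deadline=None, derandomize=True)


def flat(mu, var_c, var_r):
    return FlatContextModel(GaussianBelief(mu, var_c), var_r)


class TestFlatModel:
    def test_no_update_when_reward_equals_prior_mean(self):
        post = posterior_context_given_reward(flat(3.5, 1.0, 1.0), 3.5)
        assert post.mean == pytest.approx(3.5)
        assert incentive_value_flat(flat(3.5, 1.0, 1.0), 3.5) == 0.0

    def test_equal_variances_give_half_gain(self):
        post = posterior_context_given_reward(flat(0.0, 1.0, 1.0), 2.0)
        assert post.mean == pytest.approx(1.0)
        assert post.variance == pytest.approx(0.5)
        assert incentive_value_flat(flat(3.5, 1.0, 1.0), 4.0) == pytest.approx(0.25)

    def test_posterior_matches_quadrature(self):
        post = posterior_context_given_reward(flat(0.0, 2.0, 1.0), 3.0)
        mean_num, var_num = oracles.flat_posterior_numeric(0.0, 2.0, 1.0, 3.0)
        assert post.mean == pytest.approx(2.0)
        assert post.mean == pytest.approx(mean_num, rel=1e-6)
        assert post.variance == pytest.approx(var_num, rel=1e-6)

    def test_gain_vanishes_with_unreliable_reward(self):
        assert incentive_value_flat(flat(3.5, 1.0, 1e12), 10.0) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_invalid_variance_rejected(self):
        with pytest.raises(InvalidModelError):
            FlatContextModel(GaussianBelief(0.0, 1.0), -1.0)
        with pytest.raises(InvalidModelError):
            GaussianBelief(0.0, 0.0)

    @SETTINGS
    @given(mu=observations, var_c=variances, var_r=variances, reward=observations)
    def test_conjugacy_against_oracle(self, mu, var_c, var_r, reward):
        post = posterior_context_given_reward(flat(mu, var_c, var_r), reward)
        mean_num, var_num = oracles.flat_posterior_numeric(mu, var_c, var_r, reward)
        assert post.mean == pytest.approx(mean_num, rel=1e-6, abs=1e-9)
        assert post.variance == pytest.approx(var_num, rel=1e-6)
        # value is the posterior-mean shift
        value = incentive_value_flat(flat(mu, var_c, var_r), reward)
        assert value == pytest.approx(post.mean - mu, rel=1e-9, abs=1e-12)

    @SETTINGS
    @given(mu=observations, var_c=variances, var_r=variances, reward=observations)
    def test_variance_shrinks_and_value_affine(self, mu, var_c, var_r, reward):
        model = flat(mu, var_c, var_r)
        post = posterior_context_given_reward(model, reward)
        assert post.variance < var_c
        # affine in R with slope = gain in (0, 1]
        v0 = incentive_value_flat(model, reward)
        v1 = incentive_value_flat(model, reward + 1.0)
        slope = v1 - v0
        assert 0.0 < slope <= 1.0
        v2 = incentive_value_flat(model, reward + 2.0)
        assert v2 - v1 == pytest.approx(slope, rel=1e-9)


class TestCuedModel:
    def test_equal_variance_shrinkage(self):
        post = update_on_context_cue(CuedContextModel(1.0, 1.0, 1.0), 2.0)
        assert post.mean == pytest.approx(1.0)
        assert post.variance == pytest.approx(0.5)

    def test_uninformative_cue_limit(self):
        post = update_on_context_cue(CuedContextModel(1.0, 1e12, 1.0), 57.0)
        assert post.mean == pytest.approx(0.0, abs=1e-9)
        assert post.variance == pytest.approx(1.0, rel=1e-9)

    def test_cue_update_matches_quadrature(self):
        post = update_on_context_cue(CuedContextModel(4.0, 1.0, 1.0), 5.0)
        mean_num, var_num = oracles.cued_posterior_numeric(4.0, 1.0, 5.0)
        assert post.mean == pytest.approx(4.0)
        assert post.variance == pytest.approx(0.8)
        assert post.mean == pytest.approx(mean_num, rel=1e-6)
        assert post.variance == pytest.approx(var_num, rel=1e-6)

    def test_value_zero_at_cue_conditioned_mean(self):
        model = CuedContextModel(1.0, 1.0, 0.5)
        mean = update_on_context_cue(model, 2.0).mean
        assert incentive_value_cued(model, 2.0, mean) == pytest.approx(0.0)

    def test_two_step_value_example(self):
        assert incentive_value_cued(
            CuedContextModel(1.0, 1.0, 1.0), cue=2.0, reward=3.0
        ) == pytest.approx(2.0 / 3.0)

    def test_reduces_to_flat_model_without_cue_information(self):
        model = CuedContextModel(1.3, 1e12, 0.7)
        flat_equiv = flat(0.0, 1.3, 0.7)
        for reward in (-2.0, 0.5, 3.0):
            assert incentive_value_cued(model, 9.9, reward) == pytest.approx(
                incentive_value_flat(flat_equiv, reward), rel=1e-9
            )

    @SETTINGS
    @given(
        var_c=variances,
        var_o=variances,
        var_r=variances,
        cue=observations,
        reward=observations,
    )
    def test_sequential_value_against_oracle(self, var_c, var_o, var_r, cue, reward):
        model = CuedContextModel(var_c, var_o, var_r)
        value = incentive_value_cued(model, cue, reward)
        value_num = oracles.cued_value_numeric(var_c, var_o, var_r, cue, reward)
        assert value == pytest.approx(value_num, rel=1e-6, abs=1e-9)


class TestHierarchicalModel:
    def test_symmetric_zero_evidence(self):
        model = HierarchicalContextModel(1, 1, 1, 1, 1)
        assert hierarchical_posterior_chain(model, 0.0, 0.0).mean == pytest.approx(0.0)

    def test_unit_variance_chain(self):
        model = HierarchicalContextModel(1, 1, 1, 1, 1)
        post = hierarchical_posterior_chain(model, 1.0, 1.0)
        assert post.mean == pytest.approx(0.8)
        assert post.variance == pytest.approx(0.6)
        mean_num, var_num = oracles.hierarchical_posterior_numeric(1, 1, 1, 1, 1.0, 1.0)
        assert post.mean == pytest.approx(mean_num, rel=1e-6)
        assert post.variance == pytest.approx(var_num, rel=1e-6)
        assert incentive_value_hierarchical(model, 1.0, 1.0, 1.0) == pytest.approx(0.075)

    def test_perfectly_observed_low_context(self):
        model = HierarchicalContextModel(1, 1, 1, 1e-12, 1)
        post = hierarchical_posterior_chain(model, 0.3, 1.7)
        assert post.mean == pytest.approx(1.7, abs=1e-9)
        assert post.variance == pytest.approx(0.0, abs=1e-9)

    def test_weights_sum_for_unit_variances(self):
        w = hierarchical_weights(HierarchicalContextModel(1, 1, 1, 1, 1))
        assert w.low_weight + w.high_weight == pytest.approx(0.8)

    def test_weights_match_finite_differences(self):
        model = HierarchicalContextModel(0.8, 1.4, 0.6, 1.1, 0.9)
        w = hierarchical_weights(model)
        base = incentive_value_hierarchical(model, 0.0, 0.0, 0.0)
        d_lo = incentive_value_hierarchical(model, 0.0, 1.0, 0.0) - base
        d_hi = incentive_value_hierarchical(model, 1.0, 0.0, 0.0) - base
        d_r = incentive_value_hierarchical(model, 0.0, 0.0, 1.0) - base
        assert d_r == pytest.approx(w.gain, rel=1e-9)
        assert d_lo == pytest.approx(-w.gain * w.low_weight, rel=1e-9)
        assert d_hi == pytest.approx(-w.gain * w.high_weight, rel=1e-9)

    def test_zero_value_at_weighted_cue_combination(self):
        model = HierarchicalContextModel(1.2, 0.7, 0.9, 1.5, 0.4)
        w = hierarchical_weights(model)
        reward = w.low_weight * 1.3 + w.high_weight * (-0.4)
        assert incentive_value_hierarchical(model, -0.4, 1.3, reward) == pytest.approx(
            0.0, abs=1e-12
        )

    @SETTINGS
    @given(
        var_hc=variances,
        var_ho=variances,
        var_lc=variances,
        var_lo=variances,
        var_r=variances,
        ho=observations,
        lo=observations,
        reward=observations,
    )
    def test_chain_and_weight_form_agree_with_oracle(
        self, var_hc, var_ho, var_lc, var_lo, var_r, ho, lo, reward
    ):
        model = HierarchicalContextModel(var_hc, var_ho, var_lc, var_lo, var_r)
        post = hierarchical_posterior_chain(model, ho, lo)
        mean_num, var_num = oracles.hierarchical_posterior_numeric(
            var_hc, var_ho, var_lc, var_lo, ho, lo
        )
        assert post.mean == pytest.approx(mean_num, rel=1e-6, abs=1e-9)
        assert post.variance == pytest.approx(var_num, rel=1e-6)
        # weight form V = K (R - tau_LO LO - tau_HO HO) equals the chain value
        w = hierarchical_weights(model)
        chain_value = incentive_value_hierarchical(model, ho, lo, reward)
        weight_value = w.gain * (reward - w.low_weight * lo - w.high_weight * ho)
        assert chain_value == pytest.approx(weight_value, abs=1e-10)
        assert 0.0 < w.gain <= 1.0
        assert w.low_weight >= 0.0 and w.high_weight >= 0.0
        assert w.low_weight + w.high_weight < 1.0

    @SETTINGS
    @given(
        var_hc=variances,
        var_ho=variances,
        var_lc=variances,
        var_lo=variances,
        var_r=variances,
        ho=observations,
        lo=observations,
    )
    def test_each_conditioning_step_reduces_variance(
        self, var_hc, var_ho, var_lc, var_lo, var_r, ho, lo
    ):
        model = HierarchicalContextModel(var_hc, var_ho, var_lc, var_lo, var_r)
        post = hierarchical_posterior_chain(model, ho, lo)
        w_high = var_hc / (var_hc + var_ho)
        predictive_var = var_hc * (1 - w_high) + var_lc
        assert post.variance < predictive_var

    def test_high_weight_vanishes_with_uninformative_high_cue(self):
        weights = [
            hierarchical_weights(HierarchicalContextModel(1, v, 1, 1, 1)).high_weight
            for v in (1e2, 1e4, 1e6)
        ]
        assert weights[0] > weights[1] > weights[2]
        assert weights[-1] == pytest.approx(0.0, abs=1e-5)

    def test_high_weight_vanishes_with_perfect_low_cue(self):
        weights = [
            hierarchical_weights(HierarchicalContextModel(1, 1, 1, v, 1)).high_weight
            for v in (1e-2, 1e-4, 1e-6)
        ]
        assert weights[0] > weights[1] > weights[2]
        assert weights[-1] == pytest.approx(0.0, abs=1e-5)

    def test_degenerates_to_single_level_model_in_low_branch(self):
        # As the high level becomes totally uncertain, the chain behaves like
        # a single-level update around the low cue with variance sigma_LO^2.
        var_lo, var_r = 1.1, 0.8
        lo, ho, reward = 0.9, -0.6, 2.0
        limit_value = var_lo / (var_lo + var_r) * (reward - lo)
        errors = []
        for v in (1e2, 1e4, 1e6):
            model = HierarchicalContextModel(v, v, 1.0, var_lo, var_r)
            errors.append(
                abs(incentive_value_hierarchical(model, ho, lo, reward) - limit_value)
            )
        assert errors[0] > errors[1] > errors[2]
        assert errors[-1] < 1e-4


class TestQualitativeContextEffects:
    """The three predicted normalization patterns on constructed contexts."""

    def test_lower_mean_context_gives_larger_values(self):
        low = flat(2.0, 1.0, 1.0)
        high = flat(3.0, 1.0, 1.0)
        for reward in (1.5, 2.5, 3.5):
            assert incentive_value_flat(low, reward) > incentive_value_flat(high, reward)

    def test_variance_context_crossover_on_common_rewards(self):
        mu = 3.5
        low_var = flat(mu, 1.0, 0.5)
        high_var = flat(mu, 1.0, 2.0)
        below, above = 3.0, 4.0
        assert incentive_value_flat(high_var, below) > incentive_value_flat(
            low_var, below
        )
        assert incentive_value_flat(low_var, above) > incentive_value_flat(
            high_var, above
        )

    def test_hierarchical_values_ordered_by_combined_context_level(self):
        model = HierarchicalContextModel(1.0, 1.0, 1.0, 1.0, 1.0)
        reward = 1.0
        # (high cue, low cue) combinations from lowest to highest overall
        # contextual expectation; values must be strictly decreasing.
        contexts = [(-1.0, -1.0), (-1.0, 0.0), (0.0, 0.0), (1.0, 0.0), (1.0, 1.0)]
        values = [incentive_value_hierarchical(model, ho, lo, reward) for ho, lo in contexts]
        assert all(a > b for a, b in zip(values, values[1:]))
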