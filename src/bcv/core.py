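"""Conjugate-Gaussian generative models of context and incentive value.

Incentive value is modelled as a precision-weighted prediction error: the
difference between an observed reward and the reward expected under the
current belief about the context, multiplied by a gain term set by the
relative precision (inverse variance) of the contextual belief and of the
reward distribution.  Three generative models are supported:

* a *flat* model, where a single Gaussian prior over the context mean
  directly parameterises the reward distribution;
* a *cued* model, where the context has a zero-mean Gaussian prior and is
  additionally signalled by a noisy observation (cue) before the reward;
* a *hierarchical* model with two nested context levels (e.g. deck-set and
  deck, or neighbourhood and restaurant), each with its own noisy cue.

All posteriors are available in closed form because every conditional in the
generative models is Gaussian with a mean supplied by its parent.  Beliefs
are updated *sequentially* in the order the information arrives: high-level
cue, low-level cue, reward.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "InvalidModelError",
    "GaussianBelief",
    "FlatContextModel",
    "CuedContextModel",
    "HierarchicalContextModel",
    "HierarchicalWeights",
    "posterior_context_given_reward",
    "incentive_value_flat",
    "update_on_context_cue",
    "incentive_value_cued",
    "hierarchical_posterior_chain",
    "incentive_value_hierarchical",
    "hierarchical_weights",
]


class InvalidModelError(ValueError):
    """A generative model was constructed with a non-positive variance."""


def _check_positive(name: str, value: float) -> None:
    if not value > 0.0:
        raise InvalidModelError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class GaussianBelief:
    """A one-dimensional Gaussian belief about a hidden variable.

    Parameters
    ----------
    mean
        Expected value, in reward units (pound EV).
    variance
        Strictly positive variance, in squared reward units.  Degenerate
        (certain or fully uninformative) beliefs are expressed by taking
        limits with small or large finite variances, never by zero.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        _check_positive("belief variance", self.variance)

    @property
    def precision(self) -> float:
        return 1.0 / self.variance


@dataclass(frozen=True)
class FlatContextModel:
    """Single-level generative model: context prior -> reward.

    The context variable holds a Gaussian prior belief over the mean of the
    reward distribution; rewards are drawn around the context with variance
    ``reward_variance``.
    """

    context_prior: GaussianBelief
    reward_variance: float

    def __post_init__(self) -> None:
        _check_positive("reward_variance", self.reward_variance)


@dataclass(frozen=True)
class CuedContextModel:
    """Single-level model with a zero-mean context prior and a noisy cue.

    The context C ~ N(0, context_variance); a cue O ~ N(C,
    observation_variance) arrives before the reward R ~ N(C,
    reward_variance).  The identity link between context and cue mean is
    assumed throughout.
    """

    context_variance: float
    observation_variance: float
    reward_variance: float

    def __post_init__(self) -> None:
        _check_positive("context_variance", self.context_variance)
        _check_positive("observation_variance", self.observation_variance)
        _check_positive("reward_variance", self.reward_variance)


@dataclass(frozen=True)
class HierarchicalContextModel:
    """Two-level nested context model.

    The high-level context HC ~ N(0, high_context_variance) is cued by
    HO ~ N(HC, high_obs_variance); the low-level context LC ~ N(HC,
    low_context_variance) is cued by LO ~ N(LC, low_obs_variance); rewards
    R ~ N(LC, reward_variance).
    """

    high_context_variance: float
    high_obs_variance: float
    low_context_variance: float
    low_obs_variance: float
    reward_variance: float

    def __post_init__(self) -> None:
        _check_positive("high_context_variance", self.high_context_variance)
        _check_positive("high_obs_variance", self.high_obs_variance)
        _check_positive("low_context_variance", self.low_context_variance)
        _check_positive("low_obs_variance", self.low_obs_variance)
        _check_positive("reward_variance", self.reward_variance)


@dataclass(frozen=True)
class HierarchicalWeights:
    """Linear coefficients of hierarchical incentive value.

    ``incentive_value_hierarchical`` is exactly affine in the reward and the
    two cues: V = gain * (R - low_weight * LO - high_weight * HO).  The gain
    lies in (0, 1]; the cue weights are non-negative and sum to less than
    one, reflecting shrinkage toward the zero prior mean.
    """

    gain: float
    low_weight: float
    high_weight: float


def posterior_context_given_reward(
    model: FlatContextModel, reward: float
) -> GaussianBelief:
    """Posterior belief about the flat context after observing a reward.

    Standard conjugate Gaussian update: the posterior mean moves from the
    prior mean toward the reward by the gain sigma_C^2 / (sigma_C^2 +
    sigma_R^2), and the posterior variance shrinks by the same factor.
    """
    prior = model.context_prior
    gain = prior.variance / (prior.variance + model.reward_variance)
    mean = prior.mean + gain * (reward - prior.mean)
    variance = prior.variance - gain * prior.variance
    return GaussianBelief(mean=mean, variance=variance)


def incentive_value_flat(model: FlatContextModel, reward: float) -> float:
    """Incentive value of a reward under the flat model.

    Equals the precision-weighted prediction error, i.e. the shift of the
    posterior context mean produced by the reward:
    V(R) = sigma_C^2 / (sigma_C^2 + sigma_R^2) * (R - mu_C).
    """
    prior = model.context_prior
    gain = prior.variance / (prior.variance + model.reward_variance)
    return gain * (reward - prior.mean)


def update_on_context_cue(model: CuedContextModel, cue: float) -> GaussianBelief:
    """Posterior belief about the cued context after observing its cue.

    With the zero-mean prior, the posterior mean is the cue shrunk by
    sigma_C^2 / (sigma_C^2 + sigma_O^2); the variance is strictly reduced.
    """
    gain = model.context_variance / (model.context_variance + model.observation_variance)
    mean = gain * cue
    variance = model.context_variance - gain * model.context_variance
    return GaussianBelief(mean=mean, variance=variance)


def incentive_value_cued(model: CuedContextModel, cue: float, reward: float) -> float:
    """Incentive value of a reward after a contextual cue.

    Sequential inference: first condition the context belief on the cue,
    then treat the cue-conditioned belief as the prior for the reward
    update.  The cue exerts a subtractive normalization (it shifts the
    expected reward) and the posterior precision sets the divisive gain.
    """
    posterior = update_on_context_cue(model, cue)
    gain = posterior.variance / (posterior.variance + model.reward_variance)
    return gain * (reward - posterior.mean)


def _chain_moments(
    model: HierarchicalContextModel, high_cue: float, low_cue: float
) -> tuple[float, float, float, float]:
    """Sequential moments of the hierarchical chain.

    Returns (predictive mean over LC, predictive variance over LC,
    posterior mean over LC, posterior variance over LC), where "predictive"
    means after the high cue only and "posterior" after both cues.
    """
    # P(HC | HO): conjugate update of the zero-mean high-level prior.
    w_high = model.high_context_variance / (
        model.high_context_variance + model.high_obs_variance
    )
    hc_mean = w_high * high_cue
    hc_var = model.high_context_variance * (1.0 - w_high)
    # P(LC | HO): the high posterior propagates down, adding the low-level
    # context dispersion.
    pred_mean = hc_mean
    pred_var = hc_var + model.low_context_variance
    # P(LC | HO, LO): conjugate update on the low cue.
    w_low = pred_var / (pred_var + model.low_obs_variance)
    lc_mean = pred_mean + w_low * (low_cue - pred_mean)
    lc_var = pred_var * (1.0 - w_low)
    return pred_mean, pred_var, lc_mean, lc_var


def hierarchical_posterior_chain(
    model: HierarchicalContextModel, high_cue: float, low_cue: float
) -> GaussianBelief:
    """Belief about the low-level context after both cues.

    Implements the three-step sequential chain: posterior over HC from HO,
    predictive prior over LC (mean = HC posterior mean, variance = HC
    posterior variance plus the low-level context variance), and posterior
    over LC from LO.
    """
    _, _, lc_mean, lc_var = _chain_moments(model, high_cue, low_cue)
    return GaussianBelief(mean=lc_mean, variance=lc_var)


def hierarchical_weights(model: HierarchicalContextModel) -> HierarchicalWeights:
    """Closed-form coefficients of the hierarchical incentive value.

    Because every update in the chain is linear in the observations, the
    posterior mean over LC is tau_LO * LO + tau_HO * HO with

        tau_LO = v1 / (v1 + sigma_LO^2)
        tau_HO = (1 - tau_LO) * sigma_HC^2 / (sigma_HC^2 + sigma_HO^2)

    where v1 is the predictive variance over LC after the high cue.  The
    divisive gain K is the usual precision ratio v2 / (v2 + sigma_R^2) with
    v2 the posterior variance over LC after both cues.  The low cue always
    outweighs the high cue route it partially screens off: as the low cue
    becomes perfectly reliable the high-level weight vanishes (the low-level
    context is then a Markov blanket for reward).
    """
    w_high = model.high_context_variance / (
        model.high_context_variance + model.high_obs_variance
    )
    pred_var = model.high_context_variance * (1.0 - w_high) + model.low_context_variance
    low_weight = pred_var / (pred_var + model.low_obs_variance)
    high_weight = (1.0 - low_weight) * w_high
    posterior_var = pred_var * (1.0 - low_weight)
    gain = posterior_var / (posterior_var + model.reward_variance)
    return HierarchicalWeights(gain=gain, low_weight=low_weight, high_weight=high_weight)


def incentive_value_hierarchical(
    model: HierarchicalContextModel, high_cue: float, low_cue: float, reward: float
) -> float:
    """Incentive value of a reward under the two-level context model.

    V(R) = K * (R - tau_LO * LO - tau_HO * HO), identically equal to the
    precision-weighted prediction error computed from the sequential
    posterior over the low-level context.
    """
    _, _, lc_mean, lc_var = _chain_moments(model, high_cue, low_cue)
    gain = lc_var / (lc_var + model.reward_variance)
    return gain * (reward - lc_mean)
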