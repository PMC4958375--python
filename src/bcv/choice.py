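"""Experiment-specific incentive-value transforms and the logistic choice rule.

Both gambling tasks present, on every trial, a sure option worth half the
on-screen amount and a 50-50 gamble over the full amount or nothing, so the
two options always share the same expected value R (the option EV).  Choice
is modelled as a logistic function of the *incentive value* of R, which is R
normalized by the contextual expectation:

* experiment one (variance-manipulation blocks): V = tau^eps * (R - mu_C),
  where eps indicates the high-variance context and mu_C = 3.5 is the common
  contextual mean EV; the divisive-only alternative is V = tau^eps * R;
* experiment two (nested deck / deck-set contexts):
  V = R - chi_LO * tau_LO - chi_HO * tau_HO, where chi_LO and chi_HO are the
  mean option EVs of the current deck and deck-set; the divisive alternative
  is V = R / (1 + chi_LO * tau_LO + chi_HO * tau_HO).

The probability of gambling is P = sigmoid(alpha * V + rho): alpha scales the
influence of incentive value (its sign says whether gambling increases or
decreases with value) and rho is a value-independent gambling bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ALPHA_BOUNDS",
    "RHO_BOUNDS",
    "TAU_BOUNDS",
    "TAU_LO_BOUNDS",
    "TAU_HI_BOUNDS",
    "PROB_CLIP",
    "ParameterBoundsError",
    "ExcludedTrialError",
    "ValueDomainError",
    "SubjectParams",
    "ModelSpec",
    "model_spec",
    "MODEL_NAMES",
    "value_exp1",
    "value_exp1_divisive",
    "value_exp2",
    "value_exp2_divisive",
    "p_gamble",
    "trial_loglik",
    "incentive_values",
    "gamble_probabilities",
    "subject_log_likelihood",
]

# Fitting box constraints; the value transforms refuse parameters outside.
ALPHA_BOUNDS = (-5.0, 5.0)
RHO_BOUNDS = (-10.0, 10.0)
TAU_BOUNDS = (0.1, 10.0)
TAU_LO_BOUNDS = (-1.0, 1.0)
TAU_HI_BOUNDS = (-1.0, 1.0)

# Gambling probabilities are clipped away from {0, 1} before taking logs so
# that saturated logistic parameters yield finite log-likelihoods.
PROB_CLIP = 1e-12

PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": ALPHA_BOUNDS,
    "rho": RHO_BOUNDS,
    "tau": TAU_BOUNDS,
    "tau_lo": TAU_LO_BOUNDS,
    "tau_hi": TAU_HI_BOUNDS,
}

# Value a parameter takes when it is not free in a model.
INACTIVE_VALUES: dict[str, float] = {
    "alpha": 0.0,
    "rho": 0.0,
    "tau": 1.0,
    "tau_lo": 0.0,
    "tau_hi": 0.0,
}


class ParameterBoundsError(ValueError):
    """A choice-model parameter lies outside its fitting bounds."""


class ExcludedTrialError(ValueError):
    """A missed trial reached the likelihood; callers must filter first."""


class ValueDomainError(ValueError):
    """The divisive value transform received a non-positive denominator."""


def _check_bounds(name: str, value: float) -> None:
    lo, hi = PARAM_BOUNDS[name]
    if not (lo <= value <= hi):
        raise ParameterBoundsError(f"{name}={value!r} outside bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class SubjectParams:
    """One subject's choice parameters.

    ``alpha`` is the value sensitivity, ``rho`` the gambling bias, ``tau``
    the experiment-one divisive gain, and ``tau_lo`` / ``tau_hi`` the
    experiment-two deck- and deck-set-level subtractive weights.  Parameters
    irrelevant to a given model sit at their inactive values (tau = 1,
    everything else 0).
    """

    alpha: float = 0.0
    rho: float = 0.0
    tau: float = 1.0
    tau_lo: float = 0.0
    tau_hi: float = 0.0

    def validate(self) -> "SubjectParams":
        for name in PARAM_BOUNDS:
            _check_bounds(name, getattr(self, name))
        return self


@dataclass(frozen=True)
class ModelSpec:
    """A point in the model lattice used for fitting and comparison.

    ``active_params`` lists the free parameters; the rest are pinned to
    their inactive values before the value transform is applied.
    ``context_mean`` (mu_C) is only used by the experiment-one subtractive
    form, where it equals the common contextual mean EV of 3.5 pounds.
    """

    experiment: str  # "exp1" | "exp2"
    value_form: str  # subtractive_divisive | divisive_only | hier_subtractive | hier_divisive
    active_params: frozenset[str] = field(default_factory=frozenset)
    context_mean: float = 3.5
    name: str = ""

    @property
    def n_params(self) -> int:
        return len(self.active_params)

    def pin_inactive(self, params: SubjectParams) -> SubjectParams:
        """Return ``params`` with every inactive parameter at its fixed value."""
        pinned = {
            name: (getattr(params, name) if name in self.active_params else value)
            for name, value in INACTIVE_VALUES.items()
        }
        return SubjectParams(**pinned)


_EXP1_FULL = frozenset({"alpha", "rho", "tau"})
_EXP2_FULL = frozenset({"alpha", "rho", "tau_lo", "tau_hi"})

# Named models reachable from the CLI and the comparison pipeline.  Dropping
# alpha makes every context parameter unidentifiable (value no longer enters
# choice), so ``no_alpha`` retains only the bias rho.
_LATTICE: dict[tuple[str, str], tuple[str, frozenset[str]]] = {
    ("exp1", "full"): ("subtractive_divisive", _EXP1_FULL),
    ("exp1", "no_rho"): ("subtractive_divisive", frozenset({"alpha", "tau"})),
    ("exp1", "no_alpha"): ("subtractive_divisive", frozenset({"rho"})),
    ("exp1", "no_tau"): ("subtractive_divisive", frozenset({"alpha", "rho"})),
    ("exp1", "random"): ("subtractive_divisive", frozenset()),
    ("exp1", "alt_divisive"): ("divisive_only", _EXP1_FULL),
    ("exp2", "full"): ("hier_subtractive", _EXP2_FULL),
    ("exp2", "no_rho"): ("hier_subtractive", frozenset({"alpha", "tau_lo", "tau_hi"})),
    ("exp2", "no_alpha"): ("hier_subtractive", frozenset({"rho"})),
    ("exp2", "no_tau_lo"): ("hier_subtractive", frozenset({"alpha", "rho", "tau_hi"})),
    ("exp2", "no_tau_hi"): ("hier_subtractive", frozenset({"alpha", "rho", "tau_lo"})),
    ("exp2", "random"): ("hier_subtractive", frozenset()),
    ("exp2", "alt_divisive"): ("hier_divisive", _EXP2_FULL),
}

MODEL_NAMES = sorted({name for (_, name) in _LATTICE})


def model_spec(name: str, experiment: str) -> ModelSpec:
    """Look up a named model for one of the two experiments."""
    key = (experiment, name)
    if key not in _LATTICE:
        raise KeyError(f"unknown model {name!r} for {experiment!r}")
    value_form, active = _LATTICE[key]
    return ModelSpec(
        experiment=experiment, value_form=value_form, active_params=active, name=name
    )


def value_exp1(option_ev: float, context: str, tau: float, mu_c: float = 3.5) -> float:
    """Subtractive + divisive incentive value for experiment one.

    V = tau^eps * (R - mu_C) with eps = 1 in the high-variance (HV) context
    and 0 in the low-variance (LV) context.
    """
    _check_bounds("tau", tau)
    base = option_ev - mu_c
    return tau * base if context == "HV" else base


def value_exp1_divisive(option_ev: float, context: str, tau: float) -> float:
    """Divisive-only alternative for experiment one: V = tau^eps * R."""
    _check_bounds("tau", tau)
    return tau * option_ev if context == "HV" else option_ev


def value_exp2(
    option_ev: float, chi_lo: float, chi_hi: float, tau_lo: float, tau_hi: float
) -> float:
    """Hierarchical subtractive incentive value for experiment two."""
    _check_bounds("tau_lo", tau_lo)
    _check_bounds("tau_hi", tau_hi)
    return option_ev - chi_lo * tau_lo - chi_hi * tau_hi


def value_exp2_divisive(
    option_ev: float, chi_lo: float, chi_hi: float, tau_lo: float, tau_hi: float
) -> float:
    """Hierarchical divisive alternative: V = R / (1 + chi_LO tau_LO + chi_HO tau_HO)."""
    _check_bounds("tau_lo", tau_lo)
    _check_bounds("tau_hi", tau_hi)
    denom = 1.0 + chi_lo * tau_lo + chi_hi * tau_hi
    if denom <= 0.0:
        raise ValueDomainError(f"non-positive denominator {denom!r}")
    return option_ev / denom


def p_gamble(value: float, alpha: float, rho: float) -> float:
    """Probability of choosing the gamble: sigmoid(alpha * V + rho)."""
    _check_bounds("alpha", alpha)
    _check_bounds("rho", rho)
    return float(expit(alpha * value + rho))


def _series_values(
    option_ev: np.ndarray,
    hv_mask: np.ndarray | None,
    chi_lo: np.ndarray | None,
    chi_hi: np.ndarray | None,
    params: SubjectParams,
    spec: ModelSpec,
) -> np.ndarray:
    form = spec.value_form
    if form == "subtractive_divisive":
        base = option_ev - spec.context_mean
        return np.where(hv_mask, params.tau * base, base)
    if form == "divisive_only":
        return np.where(hv_mask, params.tau * option_ev, option_ev)
    if form == "hier_subtractive":
        return option_ev - chi_lo * params.tau_lo - chi_hi * params.tau_hi
    if form == "hier_divisive":
        denom = 1.0 + chi_lo * params.tau_lo + chi_hi * params.tau_hi
        if np.any(denom <= 0.0):
            raise ValueDomainError("non-positive denominator in divisive value")
        return option_ev / denom
    raise ValueError(f"unknown value form {form!r}")


def _extract_columns(
    trials: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, np.ndarray | None]:
    option_ev = trials["option_ev"].to_numpy(dtype=float)
    hv_mask = chi_lo = chi_hi = None
    if spec.experiment == "exp1":
        hv_mask = (trials["variance_context"] == "HV").to_numpy()
    else:
        chi_lo = trials["chi_lo"].to_numpy(dtype=float)
        chi_hi = trials["chi_hi"].to_numpy(dtype=float)
    return option_ev, hv_mask, chi_lo, chi_hi


def incentive_values(
    trials: pd.DataFrame, params: SubjectParams, spec: ModelSpec
) -> np.ndarray:
    """Vectorized incentive value of every trial's option EV."""
    pinned = spec.pin_inactive(params).validate()
    option_ev, hv_mask, chi_lo, chi_hi = _extract_columns(trials, spec)
    return _series_values(option_ev, hv_mask, chi_lo, chi_hi, pinned, spec)


def gamble_probabilities(
    trials: pd.DataFrame, params: SubjectParams, spec: ModelSpec
) -> np.ndarray:
    """Vectorized gamble probability for every trial."""
    pinned = spec.pin_inactive(params).validate()
    values = incentive_values(trials, pinned, spec)
    return expit(pinned.alpha * values + pinned.rho)


def trial_loglik(
    trial: Mapping | pd.Series, params: SubjectParams, spec: ModelSpec
) -> float:
    """Bernoulli log-likelihood of a single trial's choice.

    Missed trials are never part of the likelihood; encountering one is an
    error because reaction-time filtering is the caller's responsibility.
    """
    choice = trial["choice"]
    if choice not in ("gamble", "sure"):
        raise ExcludedTrialError(f"trial with choice {choice!r} must be filtered out")
    frame = pd.DataFrame([dict(trial)])
    p = float(np.clip(gamble_probabilities(frame, params, spec)[0], PROB_CLIP, 1 - PROB_CLIP))
    return float(np.log(p) if choice == "gamble" else np.log1p(-p))


def subject_log_likelihood(
    trials: pd.DataFrame, params: SubjectParams, spec: ModelSpec
) -> float:
    """Summed choice log-likelihood over a subject's (filtered) trials."""
    design = TrialDesign(trials, spec)
    pinned = spec.pin_inactive(params).validate()
    return -design.negative_log_likelihood(pinned)


class TrialDesign:
    """Precomputed per-trial arrays for fast repeated likelihood evaluation.

    Fitting evaluates the likelihood thousands of times with the same trial
    data; this caches the option EVs, context columns and choice indicator
    once.  Trials must already be filtered of missed responses.
    """

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec):
        bad = ~trials["choice"].isin(["gamble", "sure"])
        if bad.any():
            raise ExcludedTrialError(
                f"{int(bad.sum())} missed/unset trials present; filter before fitting"
            )
        self.spec = spec
        self.n_trials = len(trials)
        self.gambled = (trials["choice"] == "gamble").to_numpy(dtype=float)
        self.option_ev, self.hv_mask, self.chi_lo, self.chi_hi = _extract_columns(
            trials, spec
        )

    def negative_log_likelihood(self, params: SubjectParams) -> float:
        try:
            values = _series_values(
                self.option_ev, self.hv_mask, self.chi_lo, self.chi_hi, params, self.spec
            )
        except ValueDomainError:
            return np.inf
        z = params.alpha * values + params.rho
        # log sigma(z) = -log(1 + exp(-z)); clip keeps saturated tails finite.
        log_p = -np.logaddexp(0.0, -z)
        log_q = -np.logaddexp(0.0, z)
        log_clip = np.log(PROB_CLIP)
        log_p = np.maximum(log_p, log_clip)
        log_q = np.maximum(log_q, log_clip)
        return float(-(self.gambled * log_p + (1.0 - self.gambled) * log_q).sum())
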