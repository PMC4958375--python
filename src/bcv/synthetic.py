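"""Trial schedules for both gambling tasks and simulation of synthetic cohorts.

Experiment one manipulates reward variance: eight blocks alternate between a
low-variance context (option EVs of 3 and 4 pounds) and a high-variance
context (EVs 2, 3, 4, 5), with the common EVs (3 and 4) shown equally often
in each context and a common contextual mean EV of 3.5 pounds.

Experiment two manipulates hierarchically nested contexts: cards are drawn
from decks (mean card amounts of 5, 7 or 9 pounds), and decks are grouped
into a low-value deck-set (5- and 7-pound decks) and a high-value deck-set
(7- and 9-pound decks) that alternate over 20-trial blocks; within a
deck-set block the active deck alternates over 5-trial sub-blocks.  The
7-pound deck belongs to both sets, and neighbouring decks share card values,
so rewards overlap across contexts at both levels.

Simulated subjects choose by the logistic choice rule applied to their
model's incentive values; gamble outcomes are fair coin flips over the full
amount or zero, and the sure option pays half the amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .choice import ModelSpec, SubjectParams, gamble_probabilities

__all__ = [
    "TRIAL_COLUMNS",
    "ParamDist",
    "CohortSpec",
    "default_cohort_spec",
    "generate_exp1_schedule",
    "generate_exp2_schedule",
    "sample_cohort",
    "simulate_choices",
    "simulate_cohort",
]

# Canonical column order of the tidy per-trial table (and its CSV form).
TRIAL_COLUMNS = [
    "subject_id",
    "experiment",
    "trial_index",
    "block_index",
    "variance_context",
    "deck_mean",
    "deck_set",
    "trial_amount",
    "option_ev",
    "chi_lo",
    "chi_hi",
    "choice",
    "outcome",
    "rt_ms",
]

# Experiment-one contexts: option EVs available in each block type.
_EXP1_EVS = {"LV": (3.0, 4.0), "HV": (2.0, 3.0, 4.0, 5.0)}
_EXP1_BLOCK_TRIALS = {"LV": 40, "HV": 80}

# Experiment-two decks: mean card amount -> possible card amounts.
_DECK_CARDS = {5.0: (3.0, 5.0, 7.0), 7.0: (5.0, 7.0, 9.0), 9.0: (7.0, 9.0, 11.0)}
_DECK_SETS = {"low": (5.0, 7.0), "high": (7.0, 9.0)}
# Mean option EV of each deck-set (chi_HO) on the EV scale.
_CHI_HI = {"low": 3.0, "high": 4.0}
_N_SET_BLOCKS = 24  # 480 trials / 20 per deck-set block
_DECK_BLOCK_TRIALS = 5
_SIMULATED_RT_MS = 1000.0  # constant; simulated data are never RT-filtered


def _constrained_shuffle(
    items: Sequence[float], rng: np.random.Generator, max_run: int
) -> np.ndarray:
    """Shuffle with no more than ``max_run`` consecutive identical items.

    Draws fresh permutations until the constraint holds, then falls back to
    local repair swaps; both paths are driven by ``rng`` so the result is a
    pure function of the seed.
    """
    arr = np.asarray(items)

    def longest_run(a: np.ndarray) -> int:
        run = best = 1
        for i in range(1, len(a)):
            run = run + 1 if a[i] == a[i - 1] else 1
            best = max(best, run)
        return best

    for _ in range(200):
        perm = rng.permutation(arr)
        if longest_run(perm) <= max_run:
            return perm
    # Repair: swap a run-extending element with a random different one.
    perm = rng.permutation(arr)
    for _ in range(10 * len(perm)):
        if longest_run(perm) <= max_run:
            break
        run = 1
        for i in range(1, len(perm)):
            run = run + 1 if perm[i] == perm[i - 1] else 1
            if run > max_run:
                others = np.flatnonzero(perm != perm[i])
                j = int(rng.choice(others))
                perm[i], perm[j] = perm[j], perm[i]
                break
    return perm


def _as_trials(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows).reindex(columns=TRIAL_COLUMNS)


def generate_exp1_schedule(seed: int, order: str = "LV-first") -> pd.DataFrame:
    """Trial schedule for the variance-manipulation task (choices unset).

    Eight blocks alternate between the low- and high-variance context
    starting with ``order``; low-variance blocks hold 40 trials over EVs
    {3, 4} and high-variance blocks 80 trials over {2, 3, 4, 5}, each EV
    equally often within a block, so the common EVs appear 80 times per
    context and the mean option EV is 3.5 pounds in both contexts.  Within
    a block the EV order is a seeded shuffle with runs of at most four
    identical EVs.
    """
    if order not in ("LV-first", "HV-first"):
        raise ValueError(f"order must be 'LV-first' or 'HV-first', got {order!r}")
    rng = np.random.default_rng(seed)
    first, second = ("LV", "HV") if order == "LV-first" else ("HV", "LV")
    rows: list[dict] = []
    trial_index = 0
    for block_index in range(8):
        context = first if block_index % 2 == 0 else second
        evs = _EXP1_EVS[context]
        per_ev = _EXP1_BLOCK_TRIALS[context] // len(evs)
        block_evs = _constrained_shuffle(np.repeat(evs, per_ev), rng, max_run=4)
        for ev in block_evs:
            rows.append(
                {
                    "experiment": "exp1",
                    "trial_index": trial_index,
                    "block_index": block_index,
                    "variance_context": context,
                    "trial_amount": 2.0 * ev,
                    "option_ev": float(ev),
                }
            )
            trial_index += 1
    return _as_trials(rows)


def generate_exp2_schedule(seed: int) -> pd.DataFrame:
    """Trial schedule for the nested deck / deck-set task (choices unset).

    480 trials in 24 deck-set blocks of 20 trials (12 low-value, 12
    high-value, pseudo-random order with runs of at most two); each deck-set
    block holds four 5-trial deck blocks with the two member decks
    alternating and equal exposure.  Card amounts are dealt from per-deck
    pools balanced over the deck's three values across the session.
    chi_lo / chi_hi carry the deck and deck-set mean option EVs.
    """
    rng = np.random.default_rng(seed)
    set_order = _constrained_shuffle(
        ["low"] * (_N_SET_BLOCKS // 2) + ["high"] * (_N_SET_BLOCKS // 2), rng, max_run=2
    )
    # Per-deck card pools, balanced over the three card values session-wide.
    exposure = {5.0: 120, 7.0: 240, 9.0: 120}  # trials per deck over 24 blocks
    pools = {
        mean: list(rng.permutation(np.repeat(_DECK_CARDS[mean], exposure[mean] // 3)))
        for mean in _DECK_CARDS
    }
    rows: list[dict] = []
    trial_index = 0
    for block_index, deck_set in enumerate(set_order):
        decks = _DECK_SETS[deck_set]
        start = int(rng.integers(2))  # ABAB or BABA within the deck-set block
        for sub in range(4):
            deck_mean = decks[(start + sub) % 2]
            for _ in range(_DECK_BLOCK_TRIALS):
                card = pools[deck_mean].pop()
                rows.append(
                    {
                        "experiment": "exp2",
                        "trial_index": trial_index,
                        "block_index": block_index,
                        "deck_mean": float(deck_mean),
                        "deck_set": deck_set,
                        "trial_amount": float(card),
                        "option_ev": float(card) / 2.0,
                        "chi_lo": float(deck_mean) / 2.0,
                        "chi_hi": _CHI_HI[deck_set],
                    }
                )
                trial_index += 1
    return _as_trials(rows)


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal population distribution for one parameter.

    With ``log=True`` the normal is placed on the log scale (used for the
    multiplicative gain tau) and truncated at the log-transformed bounds.
    """

    loc: float
    scale: float
    low: float
    high: float
    log: bool = False

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0.0:
            draws = np.full(n, self.loc)
        else:
            low, high = (self.low, self.high)
            if self.log:
                low, high = np.log(low), np.log(high)
            a = (low - self.loc) / self.scale
            b = (high - self.loc) / self.scale
            draws = truncnorm.rvs(
                a, b, loc=self.loc, scale=self.scale, size=n, random_state=rng
            )
        return np.exp(draws) if self.log else draws


# Population defaults: alpha and rho centred on zero (both signs of EV
# preference occur, as in the observed cohorts), log tau centred on zero,
# and small positive centres for the hierarchical subtractive weights.
DEFAULT_PARAM_DISTS: dict[str, ParamDist] = {
    "alpha": ParamDist(0.0, 1.5, -5.0, 5.0),
    "rho": ParamDist(0.0, 1.5, -10.0, 10.0),
    "tau": ParamDist(0.0, 0.5, 0.1, 10.0, log=True),
    "tau_lo": ParamDist(0.3, 0.25, -1.0, 1.0),
    "tau_hi": ParamDist(0.2, 0.25, -1.0, 1.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """How to draw a synthetic cohort of subjects."""

    n_subjects: int
    seed: int
    param_dists: Mapping[str, ParamDist] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_DISTS)
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        unknown = set(self.param_dists) - set(DEFAULT_PARAM_DISTS)
        if unknown:
            raise ValueError(f"unknown parameters in cohort spec: {sorted(unknown)}")


def default_cohort_spec(
    n_subjects: int, seed: int, **overrides: ParamDist
) -> CohortSpec:
    """Default cohort with optional per-parameter distribution overrides."""
    dists = dict(DEFAULT_PARAM_DISTS)
    dists.update(overrides)
    return CohortSpec(n_subjects=n_subjects, seed=seed, param_dists=dists)


def sample_cohort(spec: CohortSpec) -> list[SubjectParams]:
    """Draw a reproducible cohort of subject parameters."""
    rng = np.random.default_rng(spec.seed)
    dists = dict(DEFAULT_PARAM_DISTS)
    dists.update(spec.param_dists)
    draws = {name: dist.sample(spec.n_subjects, rng) for name, dist in dists.items()}
    return [
        SubjectParams(**{name: float(draws[name][i]) for name in dists})
        for i in range(spec.n_subjects)
    ]


def simulate_choices(
    schedule: pd.DataFrame,
    params: SubjectParams,
    model: ModelSpec,
    seed: int,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Fill a schedule with simulated choices, outcomes and reaction times.

    Gamble probabilities come from the choice model; each choice is an
    independent uniform draw, a chosen gamble pays the full amount or zero
    with equal probability, and the sure option pays half the amount.
    Reaction times are a plausible constant (simulated data are never
    RT-filtered).
    """
    params = model.pin_inactive(params).validate()
    rng = np.random.default_rng(seed)
    trials = schedule.copy()
    p = gamble_probabilities(trials, params, model)
    gambled = rng.random(len(trials)) < p
    won = rng.random(len(trials)) < 0.5
    amount = trials["trial_amount"].to_numpy(dtype=float)
    outcome = np.where(gambled, np.where(won, amount, 0.0), amount / 2.0)
    trials["subject_id"] = subject_id
    trials["choice"] = np.where(gambled, "gamble", "sure")
    trials["outcome"] = outcome
    trials["rt_ms"] = _SIMULATED_RT_MS
    return trials


def simulate_cohort(
    cohort: Sequence[SubjectParams],
    model: ModelSpec,
    seed: int,
    experiment: str | None = None,
) -> pd.DataFrame:
    """Simulate a full session for every subject in a cohort.

    Each subject gets an independent schedule and choice stream derived from
    ``seed``; experiment-one block order is counterbalanced across subjects
    (even-indexed subjects start with the low-variance context).  Returns a
    long table with one row per subject-trial.
    """
    experiment = experiment or model.experiment
    children = np.random.SeedSequence(seed).spawn(2 * len(cohort))
    frames = []
    for i, params in enumerate(cohort):
        sched_seed, choice_seed = children[2 * i], children[2 * i + 1]
        if experiment == "exp1":
            order = "LV-first" if i % 2 == 0 else "HV-first"
            schedule = generate_exp1_schedule(_seed_int(sched_seed), order=order)
        else:
            schedule = generate_exp2_schedule(_seed_int(sched_seed))
        frames.append(
            simulate_choices(
                schedule, params, model, _seed_int(choice_seed), subject_id=f"s{i:03d}"
            )
        )
    return pd.concat(frames, ignore_index=True)


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0])
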