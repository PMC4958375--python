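"""Behavioural statistics and replication-by-simulation.

The per-subject summaries capture how context shifts gambling for rewards
that are common to several contexts:

* experiment one: gamble rates per (EV, variance context) cell for the
  common EVs of 3 and 4 pounds; the *EV preference* (gamble rate at 4 minus
  at 3, pooled over contexts); and the context-by-EV *interaction term*
  (the across-context rate difference for 4-pound choices minus the same
  difference for 3-pound choices);
* experiment two: the logistic slope of gambling on option EV (the EV
  preference); the *deck effect* (gamble rate in the lower- minus the
  higher-value deck of each deck-set, on card EVs common to both member
  decks, averaged over the two sets); and the *deck-set effect* (gamble rate
  in the low- minus the high-value deck-set on trials of the shared 7-pound
  deck).

Group statistics correlate these context effects with the EV preference
across subjects (Pearson and Spearman), mirroring the moderation of context
effects by each subject's value sensitivity.  The replication loop
re-simulates every subject's session from fitted parameters under a chosen
(possibly ablated) model variant and averages the group statistics over
replicates, which is how the behavioural pattern is validated against the
choice model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .choice import ModelSpec
from .fitting import SubjectFit
from .synthetic import simulate_choices

__all__ = [
    "RT_MIN_MS",
    "RT_MAX_MS",
    "SubjectSummary",
    "Correlation",
    "GroupStats",
    "ReplicationResult",
    "rt_filter",
    "summarize_exp1",
    "summarize_exp2",
    "summarize",
    "group_stats",
    "replicate_by_simulation",
]

# Responses faster than 400 ms or slower than 3 s are excluded (strict
# inequalities define exclusion, so the boundary values are retained).
RT_MIN_MS = 400.0
RT_MAX_MS = 3000.0

# Card EVs common to both member decks of each deck-set, and the member
# decks ordered (lower-value, higher-value).
_COMMON_EVS = {"low": (2.5, 3.5), "high": (3.5, 4.5)}
_SET_DECKS = {"low": (5.0, 7.0), "high": (7.0, 9.0)}


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject behavioural summary; undefined fields are None."""

    subject_id: str
    experiment: str
    gamble_rate_overall: float | None
    cell_rates: Mapping[tuple, float] = field(default_factory=dict)
    ev_preference: float | None = None
    interaction_term: float | None = None  # exp1
    deck_effect: float | None = None  # exp2
    deckset_effect: float | None = None  # exp2
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class Correlation:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class GroupStats:
    """Across-subject correlations and one-sample tests."""

    experiment: str
    n_subjects: int
    correlations: Mapping[str, Correlation]
    t_tests: Mapping[str, tuple[float, int, float]]  # name -> (t, df, p)


@dataclass(frozen=True)
class ReplicationResult:
    """Averaged group statistics over simulated replicates of a cohort."""

    model_name: str
    n_reps: int
    per_rep: Mapping[str, np.ndarray]  # statistic name -> per-replicate values
    mean_statistic: Mapping[str, float]
    mean_p_value: Mapping[str, float]


def rt_filter(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop missed trials and responses outside the 400 ms - 3 s window.

    Returns the retained trials (order preserved) and the exclusion count.
    Boundary reaction times are kept: only strictly faster / slower
    responses are excluded.
    """
    rt = trials["rt_ms"].astype(float)
    keep = (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS) & (trials["choice"] != "missed")
    return trials[keep], int((~keep).sum())


def _rate(mask_trials: pd.DataFrame) -> float | None:
    if len(mask_trials) == 0:
        return None
    return float((mask_trials["choice"] == "gamble").mean())


def _subject_id(trials: pd.DataFrame) -> str:
    ids = trials["subject_id"].dropna().unique()
    return str(ids[0]) if len(ids) else "subject"


def summarize_exp1(trials: pd.DataFrame) -> SubjectSummary:
    """Summary of one subject's variance-task session (RT-filtered trials).

    Analyses are restricted to the choices common to both contexts (EVs of
    3 and 4 pounds).  The interaction term is
    [rate(4, LV) - rate(4, HV)] - [rate(3, LV) - rate(3, HV)].
    """
    common = trials[trials["option_ev"].astype(float).isin([3.0, 4.0])]
    flags: list[str] = []
    cells: dict[tuple, float] = {}
    for ev in (3.0, 4.0):
        for context in ("LV", "HV"):
            cell = common[
                (common["option_ev"].astype(float) == ev)
                & (common["variance_context"] == context)
            ]
            rate = _rate(cell)
            if rate is None:
                flags.append(f"missing cell ({ev:g}, {context})")
            else:
                cells[(ev, context)] = rate

    def cell(ev: float, context: str) -> float | None:
        return cells.get((ev, context))

    ev_pref = interaction = None
    rate4 = _rate(common[common["option_ev"].astype(float) == 4.0])
    rate3 = _rate(common[common["option_ev"].astype(float) == 3.0])
    if rate4 is not None and rate3 is not None:
        ev_pref = rate4 - rate3
    if len(cells) == 4:
        interaction = (cell(4.0, "LV") - cell(4.0, "HV")) - (
            cell(3.0, "LV") - cell(3.0, "HV")
        )
    return SubjectSummary(
        subject_id=_subject_id(trials),
        experiment="exp1",
        gamble_rate_overall=_rate(common),
        cell_rates=cells,
        ev_preference=ev_pref,
        interaction_term=interaction,
        flags=tuple(flags),
    )


def _logistic_ev_slope(trials: pd.DataFrame) -> tuple[float | None, str | None]:
    """Plain ML logistic slope of gambling on option EV (with intercept)."""
    y = (trials["choice"] == "gamble").to_numpy(dtype=float)
    if y.min() == y.max():
        return None, "degenerate slope (constant choice)"
    x = sm.add_constant(trials["option_ev"].to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(method="lbfgs", disp=0, maxiter=200)
        slope = float(fit.params[1])
    except Exception:
        return None, "degenerate slope (separation or non-convergence)"
    if not np.isfinite(slope):
        return None, "degenerate slope (non-finite)"
    return slope, None


def summarize_exp2(trials: pd.DataFrame) -> SubjectSummary:
    """Summary of one subject's deck-task session (RT-filtered trials)."""
    flags: list[str] = []
    ev = trials["option_ev"].to_numpy(dtype=float)
    deck = trials["deck_mean"].to_numpy(dtype=float)
    dset = trials["deck_set"].to_numpy()
    gambled = (trials["choice"] == "gamble").to_numpy(dtype=float)
    cells = {
        (float(card_ev), float(deck_mean), str(set_name)): float(rate)
        for (set_name, deck_mean, card_ev), rate in pd.Series(gambled)
        .groupby([pd.Series(dset), pd.Series(deck), pd.Series(ev)])
        .mean()
        .items()
    }

    slope, slope_flag = _logistic_ev_slope(trials)
    if slope_flag:
        flags.append(slope_flag)

    def cell_rate(card_ev: float, deck_mean: float, set_name: str) -> float | None:
        return cells.get((card_ev, deck_mean, set_name))

    set_diffs = []
    for set_name, (lower, higher) in _SET_DECKS.items():
        lows = [cell_rate(e, lower, set_name) for e in _COMMON_EVS[set_name]]
        highs = [cell_rate(e, higher, set_name) for e in _COMMON_EVS[set_name]]
        if any(r is None for r in lows + highs):
            flags.append(f"missing common-EV cells in {set_name} deck-set")
        else:
            # Gamble-rate difference on the pooled common EVs (each EV is
            # equally represented by design, so the cell mean is unweighted).
            set_diffs.append(float(np.mean(lows) - np.mean(highs)))
    deck_effect = float(np.mean(set_diffs)) if len(set_diffs) == 2 else None

    seven_low = gambled[(deck == 7.0) & (dset == "low")]
    seven_high = gambled[(deck == 7.0) & (dset == "high")]
    if len(seven_low) == 0 or len(seven_high) == 0:
        flags.append("missing 7-pound-deck cells")
        deckset_effect = None
    else:
        deckset_effect = float(seven_low.mean() - seven_high.mean())

    return SubjectSummary(
        subject_id=_subject_id(trials),
        experiment="exp2",
        gamble_rate_overall=_rate(trials),
        cell_rates=cells,
        ev_preference=slope,
        deck_effect=deck_effect,
        deckset_effect=deckset_effect,
        flags=tuple(flags),
    )


def summarize(trials: pd.DataFrame) -> SubjectSummary:
    experiment = trials["experiment"].iloc[0]
    return summarize_exp1(trials) if experiment == "exp1" else summarize_exp2(trials)


def _correlate(x: np.ndarray, y: np.ndarray) -> Correlation:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return Correlation(np.nan, np.nan, np.nan, np.nan, len(x), defined=False)
    pr, pp = stats.pearsonr(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sr, sp = stats.spearmanr(x, y)
    return Correlation(float(pr), float(pp), float(sr), float(sp), len(x))


def _collect(summaries: Sequence[SubjectSummary], attr: str) -> np.ndarray:
    return np.array(
        [np.nan if getattr(s, attr) is None else getattr(s, attr) for s in summaries],
        dtype=float,
    )


def group_stats(summaries: Sequence[SubjectSummary]) -> GroupStats:
    """Across-subject correlations of context effects with EV preference.

    All correlations are reported as Pearson r with a Spearman rho
    alongside (two-sided p-values); one-sample t-tests check the
    interaction term (experiment one) and the overall gamble rate against
    chance.  Undefined statistics (missing cells, degenerate slopes) drop
    out pairwise; a correlation on degenerate variance is returned flagged
    as undefined rather than raised.
    """
    if len(summaries) < 3:
        raise ValueError("group statistics need at least three subjects")
    experiment = summaries[0].experiment
    ev_pref = _collect(summaries, "ev_preference")
    rate = _collect(summaries, "gamble_rate_overall")
    correlations: dict[str, Correlation] = {}
    t_tests: dict[str, tuple[float, int, float]] = {}

    def ttest(name: str, values: np.ndarray, popmean: float) -> None:
        values = values[np.isfinite(values)]
        if len(values) < 2 or np.std(values) == 0.0:
            return
        res = stats.ttest_1samp(values, popmean)
        t_tests[name] = (float(res.statistic), len(values) - 1, float(res.pvalue))

    correlations["rate_vs_ev_preference"] = _correlate(rate, ev_pref)
    ttest("rate_vs_chance", rate - 0.5, 0.0)
    if experiment == "exp1":
        interaction = _collect(summaries, "interaction_term")
        correlations["interaction_vs_ev_preference"] = _correlate(interaction, ev_pref)
        ttest("interaction_vs_zero", interaction, 0.0)
    else:
        deck = _collect(summaries, "deck_effect")
        deckset = _collect(summaries, "deckset_effect")
        correlations["deck_effect_vs_ev_preference"] = _correlate(deck, ev_pref)
        correlations["deckset_effect_vs_ev_preference"] = _correlate(deckset, ev_pref)
    return GroupStats(
        experiment=experiment,
        n_subjects=len(summaries),
        correlations=correlations,
        t_tests=t_tests,
    )


def replicate_by_simulation(
    fits: Sequence[SubjectFit],
    model: ModelSpec,
    trials: pd.DataFrame,
    n_reps: int = 100,
    seed: int = 0,
) -> ReplicationResult:
    """Re-simulate every subject's session from fitted parameters.

    ``trials`` supplies each subject's trial sequence (choices are ignored
    and regenerated).  ``model`` may be an ablated variant of the fitted
    model: parameters it does not carry are pinned to their inactive values,
    which is how the contribution of individual parameters to the group
    pattern is probed.  Group statistics are computed per replicate and
    averaged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for fit in fits:
        missing = model.active_params - fit.model.active_params
        if missing and fit.model.active_params:
            raise ValueError(
                f"fits lack parameters {sorted(missing)} required by {model.name!r}"
            )
    schedules = {
        str(sid): group.drop(columns=["choice", "outcome", "rt_ms"])
        for sid, group in trials.groupby("subject_id")
    }
    children = np.random.SeedSequence(seed).spawn(n_reps)
    per_rep: dict[str, list[float]] = {}
    per_rep_p: dict[str, list[float]] = {}
    for rep, child in enumerate(children):
        subject_seeds = child.spawn(len(fits))
        summaries = []
        for fit, sseq in zip(fits, subject_seeds):
            sched = schedules[fit.subject_id]
            sim = simulate_choices(
                sched,
                fit.estimates,
                model,
                seed=int(sseq.generate_state(1, dtype=np.uint32)[0]),
                subject_id=fit.subject_id,
            )
            summaries.append(summarize(sim))
        gs = group_stats(summaries)
        for name, corr in gs.correlations.items():
            per_rep.setdefault(name, []).append(corr.pearson_r)
            per_rep_p.setdefault(name, []).append(corr.pearson_p)
    arrays = {name: np.asarray(vals) for name, vals in per_rep.items()}
    return ReplicationResult(
        model_name=model.name or model.value_form,
        n_reps=n_reps,
        per_rep=arrays,
        mean_statistic={name: float(np.nanmean(v)) for name, v in arrays.items()},
        mean_p_value={
            name: float(np.nanmean(np.asarray(v))) for name, v in per_rep_p.items()
        },
    )
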