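"""Reading and writing the tidy per-trial CSV and fit-result tables.

The per-trial table is a comma-delimited UTF-8 file with a mandatory header
and one row per trial; absent fields (e.g. deck columns on variance-task
rows) are empty.  Fit results are one row per subject, with an optional
JSON sidecar echoing the configuration and seeds of the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .choice import ModelSpec, SubjectParams, model_spec
from .fitting import FitConfig, SubjectFit
from .synthetic import TRIAL_COLUMNS

__all__ = [
    "read_trials_csv",
    "write_trials_csv",
    "fits_to_frame",
    "write_fits_csv",
    "read_fits_csv",
    "write_run_metadata",
]

_NUMERIC_COLUMNS = [
    "trial_index",
    "block_index",
    "deck_mean",
    "trial_amount",
    "option_ev",
    "chi_lo",
    "chi_hi",
    "outcome",
    "rt_ms",
]


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a per-trial table with the canonical column order."""
    trials.reindex(columns=TRIAL_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-trial table, validating the canonical columns."""
    trials = pd.read_csv(path, encoding="utf-8")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    for column in _NUMERIC_COLUMNS:
        trials[column] = pd.to_numeric(trials[column], errors="coerce")
    return trials[TRIAL_COLUMNS]


def fits_to_frame(fits: Sequence[SubjectFit]) -> pd.DataFrame:
    rows = []
    for fit in fits:
        row = {
            "subject_id": fit.subject_id,
            "experiment": fit.model.experiment,
            "model": fit.model.name,
            **asdict(fit.estimates),
            "neg_log_posterior": fit.neg_log_posterior,
            "neg_log_likelihood": fit.neg_log_likelihood,
            "converged": fit.converged,
            "n_trials_used": fit.n_trials_used,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits_csv(fits: Sequence[SubjectFit], path: str | Path) -> None:
    fits_to_frame(fits).to_csv(path, index=False, encoding="utf-8")


def read_fits_csv(path: str | Path) -> list[SubjectFit]:
    frame = pd.read_csv(path, encoding="utf-8")
    fits = []
    for _, row in frame.iterrows():
        spec = model_spec(str(row["model"]), str(row["experiment"]))
        params = SubjectParams(
            alpha=float(row["alpha"]),
            rho=float(row["rho"]),
            tau=float(row["tau"]),
            tau_lo=float(row["tau_lo"]),
            tau_hi=float(row["tau_hi"]),
        )
        fits.append(
            SubjectFit(
                subject_id=str(row["subject_id"]),
                model=spec,
                estimates=params,
                neg_log_posterior=float(row["neg_log_posterior"]),
                neg_log_likelihood=float(row["neg_log_likelihood"]),
                converged=bool(row["converged"]),
                n_trials_used=int(row["n_trials_used"]),
            )
        )
    return fits


def write_run_metadata(
    path: str | Path, config: FitConfig, model: ModelSpec, extra: dict | None = None
) -> None:
    """JSON sidecar recording how a fit run was configured."""
    payload = {
        "config": asdict(config),
        "model": {
            "name": model.name,
            "experiment": model.experiment,
            "value_form": model.value_form,
            "active_params": sorted(model.active_params),
            "context_mean": model.context_mean,
        },
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
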