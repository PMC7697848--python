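"""Shared fixtures: in-memory cohort analyses reused across test modules.

The expensive full-size analyses (19 participants x 8 trials x 3 magnitudes)
are session-scoped so the parameter-recovery checks all share one run.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from betabalance.cohort import CohortConfig, simulate_cohort, trials_to_epochset
from betabalance.emg import normalize_and_combine, preprocess_emg
from betabalance.epochs import filter_nonstep
from betabalance.ersp import (
    average_by_condition,
    beta_timecourse,
    compute_ersp,
    subtract_baseline,
)
from betabalance.pipeline import _wavelet_block


def beta_condition_averages(cfg):
    """simulate -> nonstep filter -> ERSP -> beta -> baseline -> condition avg."""
    trials, parts = simulate_cohort(cfg)
    es, counts = filter_nonstep(trials_to_epochset(trials, cfg, "Cz"))
    bt = subtract_baseline(beta_timecourse(compute_ersp(es)))
    return average_by_condition(bt), parts, trials, counts


def condition_frame(avg, value_col):
    return pd.DataFrame(
        {
            "participant": np.repeat(avg.meta["participant"].to_numpy(), avg.times.size),
            "magnitude": np.repeat(avg.meta["magnitude"].to_numpy(), avg.times.size),
            "time_ms": np.tile(avg.times, len(avg.meta)),
            value_col: (avg.power if hasattr(avg, "power") else avg.value).ravel(),
        }
    )


def emg_condition_averages(trials, cfg, muscle):
    envs = {}
    for side in ("L", "R"):
        es, _ = filter_nonstep(trials_to_epochset(trials, cfg, f"{muscle}_{side}"))
        envs[side] = preprocess_emg(es, muscle=muscle)
    return normalize_and_combine(envs["L"], envs["R"])


@pytest.fixture(scope="session")
def default_analysis():
    """Full default synthetic cohort pushed through the whole analysis."""
    cfg = CohortConfig()
    avg, parts, trials, counts = beta_condition_averages(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta_curves, beta_onsets = _wavelet_block(
            condition_frame(avg, "beta_db"), "beta_db", "beta", 0.75, 0.05
        )
        mg = emg_condition_averages(trials, cfg, "MG")
        mg_curves, mg_onsets = _wavelet_block(
            condition_frame(mg, "value_nu"), "value_nu", "emg", 0.02, 0.05
        )
    return {
        "cfg": cfg,
        "participants": parts,
        "abilities": {p.id: p.balance_ability for p in parts},
        "avg": avg,
        "beta_curves": beta_curves,
        "beta_onsets": beta_onsets,
        "mg_curves": mg_curves,
        "mg_onsets": mg_onsets,
        "trial_counts": counts,
        "trials": trials,
    }


@pytest.fixture(scope="session")
def null_medium_analysis():
    """Cohort with no medium effect injected (medium gain == small gain)."""
    cfg = CohortConfig(magnitude_gain={"small": 1.0, "medium": 1.0, "large": 2.1})
    avg, parts, trials, _ = beta_condition_averages(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curves, onsets = _wavelet_block(
            condition_frame(avg, "beta_db"), "beta_db", "beta", 0.75, 0.05
        )
    return {"cfg": cfg, "curves": curves, "onsets": onsets}
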