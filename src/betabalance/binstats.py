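"""Time-bin peak measures and scalar statistics.

Peak beta power (signed maximum of the baseline-subtracted trace) is taken in
three post-perturbation bins — overall 0-400 ms, early 50-150 ms, late
150-250 ms — and compared (i) pre vs post with a two-way additive ANOVA
(time bin, participant), (ii) across perturbation magnitudes with a two-way
additive ANOVA (magnitude, participant) plus Tukey HSD post hocs, and (iii)
against balance ability with a linear model (magnitude + ability,
participant-clustered standard errors) alongside a univariate regression of
participant-mean peaks on ability.  Confound regressions relate large-
perturbation non-stepping success rates to ability and to the peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._anova import AnovaResult, additive_two_way_anova, tukey_hsd
from .ersp import BetaTimecourse

__all__ = [
    "TIME_BINS",
    "peak_in_bin",
    "compute_time_bin_peaks",
    "pre_post_anova",
    "magnitude_anova",
    "ability_association",
    "confound_regressions",
]

#: Post-perturbation analysis bins in ms.
TIME_BINS = {"overall": (0.0, 400.0), "early": (50.0, 150.0), "late": (150.0, 250.0)}


def peak_in_bin(times: np.ndarray, trace: np.ndarray, bin_window: tuple[float, float]
                ) -> float:
    """Signed maximum of ``trace`` over grid centers inside the closed bin."""
    lo, hi = bin_window
    in_bin = (times >= lo) & (times <= hi)
    if not in_bin.any():
        raise ValueError(f"bin {bin_window} contains no grid center")
    return float(np.max(np.asarray(trace)[..., in_bin], axis=-1))


def compute_time_bin_peaks(avg: BetaTimecourse, bins: dict | None = None
                           ) -> pd.DataFrame:
    """Per participant x magnitude x bin peak table from condition averages.

    ``avg`` must be baseline-subtracted and hold one trace per
    (participant, magnitude) with matching meta.
    """
    if not avg.baseline_subtracted:
        raise ValueError("traces must be baseline-subtracted before peak measures")
    bins = TIME_BINS if bins is None else bins
    rows = []
    for i, rec in avg.meta.iterrows():
        for name, window in bins.items():
            rows.append(
                {
                    "participant": rec["participant"],
                    "magnitude": rec["magnitude"],
                    "bin": name,
                    "peak_db": peak_in_bin(avg.times, avg.power[i], window),
                }
            )
    return pd.DataFrame(rows)


def pre_post_anova(pre_means: np.ndarray, post_peaks: np.ndarray,
                   participants: np.ndarray) -> AnovaResult:
    """Two-way additive ANOVA (time bin, participant) of pre vs post power.

    ``pre_means`` and ``post_peaks`` are aligned per observation (typically
    one per participant x magnitude); the design must be balanced.
    """
    pre = np.asarray(pre_means, dtype=float)
    post = np.asarray(post_peaks, dtype=float)
    participants = np.asarray(participants)
    if pre.shape != post.shape or pre.shape[0] != participants.shape[0]:
        raise ValueError("pre, post and participant labels must align")
    values = np.concatenate([pre, post])
    bin_factor = np.array(["pre"] * pre.size + ["post"] * post.size)
    part_factor = np.concatenate([participants, participants])
    return additive_two_way_anova(values, bin_factor, part_factor,
                                  names=("time_bin", "participant"))


def magnitude_anova(peaks: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Magnitude x participant additive ANOVA + Tukey HSD for one bin.

    ``peaks`` must contain columns participant, magnitude, peak_db for a
    single bin.  Participants missing any magnitude level are dropped (e.g.
    those with no successful feet-in-place large trials).
    """
    n_levels = peaks["magnitude"].nunique()
    if n_levels < 2:
        raise ValueError("need at least two magnitude levels")
    complete = peaks.groupby("participant", observed=True)["magnitude"].nunique()
    keep = complete[complete == n_levels].index
    df = peaks[peaks["participant"].isin(keep)]
    res = additive_two_way_anova(
        df["peak_db"].to_numpy(),
        df["magnitude"].to_numpy(),
        df["participant"].to_numpy(),
        names=("magnitude", "participant"),
    )
    means = df.groupby("magnitude", observed=True)["peak_db"].mean()
    n_per = len(keep)
    res.posthoc = tukey_hsd(
        means.to_dict(), n_per, res.mse, res.df["residual"], alpha=alpha
    )
    return res


def _ols_summary(y: np.ndarray, x: np.ndarray) -> dict:
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "p": float(fit.pvalues[1]),
        "F": float(fit.fvalue),
        "r2": float(fit.rsquared),
        "n": int(fit.nobs),
    }


def ability_association(peaks: pd.DataFrame, abilities: dict, bin_name: str | None = None
                        ) -> dict:
    """Association between peak beta power and balance ability.

    Fits peak ~ magnitude + ability with participant-clustered standard
    errors (participant identity and the between-participant ability score
    are confounded, so participant cannot enter as a fixed effect alongside
    ability), and a univariate regression of participant-mean peak on ability
    whose R^2 equals the squared Pearson correlation.
    """
    df = peaks if bin_name is None else peaks[peaks["bin"] == bin_name]
    df = df.copy()
    df["ability"] = df["participant"].map(abilities)
    if df["ability"].nunique() < 2:
        raise ValueError("degenerate design: ability scores are constant")

    X = pd.get_dummies(df["magnitude"], drop_first=True, dtype=float)
    X["ability"] = df["ability"].to_numpy()
    X = sm.add_constant(X)
    fit = sm.OLS(df["peak_db"].to_numpy(), X).fit(
        cov_type="cluster", cov_kwds={"groups": df["participant"].to_numpy()}
    )
    part_means = df.groupby("participant", observed=True).agg(
        peak=("peak_db", "mean"), ability=("ability", "first")
    )
    uni = _ols_summary(part_means["peak"].to_numpy(), part_means["ability"].to_numpy())
    return {
        "model_slope": float(fit.params["ability"]),
        "model_p": float(fit.pvalues["ability"]),
        "univariate": uni,
    }


def confound_regressions(success_rates: dict, abilities: dict,
                         peaks_large: pd.DataFrame) -> dict:
    """Trial-count confound checks for the large perturbation.

    (a) ability ~ non-stepping success rate, over all participants;
    (b) per-bin large-magnitude peak ~ success rate, excluding participants
    with zero successful trials (no peak measurable).  Constant predictors
    are flagged degenerate instead of fitted.
    """
    parts = sorted(success_rates)
    if len(parts) < 3:
        raise ValueError("need at least 3 participants")
    rates = np.array([success_rates[p] for p in parts], dtype=float)
    out: dict = {}
    if np.ptp(rates) == 0:
        out["ability_vs_success"] = {"degenerate": True}
    else:
        ab = np.array([abilities[p] for p in parts], dtype=float)
        out["ability_vs_success"] = _ols_summary(ab, rates)

    nonzero = [p for p in parts if success_rates[p] > 0]
    for bin_name, sub in peaks_large.groupby("bin", observed=True):
        sub = sub[sub["participant"].isin(nonzero)]
        r = np.array([success_rates[p] for p in sub["participant"]], dtype=float)
        if len(sub) < 3 or np.ptp(r) == 0:
            out[f"peak_vs_success_{bin_name}"] = {"degenerate": True}
        else:
            out[f"peak_vs_success_{bin_name}"] = _ols_summary(
                sub["peak_db"].to_numpy(), r
            )
    return out
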