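"""File-based pipeline: simulate -> ERSP/EMG -> bin statistics -> wavelet stats.

Each stage reads the CSV outputs of the previous one from the run directory
and writes its own, so stages are independently runnable and testable; the
run manifest records the seed and package version.  Defaults reproduce the
analysis parameters: time bins 0-400 / 50-150 / 150-250 ms, beta band
13-30 Hz, alpha 0.05, onset thresholds 0.75 dB (beta) and 0.02 normalized
units (EMG).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binstats import (
    TIME_BINS,
    ability_association,
    compute_time_bin_peaks,
    confound_regressions,
    magnitude_anova,
    pre_post_anova,
)
from .cohort import MAGNITUDES, CohortConfig, simulate_cohort, write_cohort
from .emg import normalize_and_combine, preprocess_emg
from .epochs import EpochSet, filter_nonstep, read_epochs
from .ersp import (
    BETA_BAND,
    average_by_condition,
    beta_timecourse,
    compute_ersp,
    subtract_baseline,
)
from .wfa import (
    BETA_ONSET_THRESHOLD_DB,
    EMG_ONSET_THRESHOLD_NU,
    detect_onset_offset,
    dwt_coif3,
    to_128_samples,
    wavelet_anova,
    wavelet_ttest,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclasses.dataclass
class RunConfig:
    """All knobs of one analysis run."""

    outdir: str = "betabalance_run"
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    band: tuple[float, float] = BETA_BAND
    bins: dict = dataclasses.field(default_factory=lambda: dict(TIME_BINS))
    alpha: float = 0.05
    beta_onset_threshold: float = BETA_ONSET_THRESHOLD_DB
    emg_onset_threshold: float = EMG_ONSET_THRESHOLD_NU

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "bins" in raw:
            raw["bins"] = {k: tuple(v) for k, v in raw["bins"].items()}
        return cls(cohort=cohort, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def _outdir(cfg: RunConfig) -> pathlib.Path:
    p = pathlib.Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: pathlib.Path, stage: str) -> pathlib.Path:
    if not path.exists():
        raise StageError(
            f"stage {stage!r}: missing upstream output {path.name}; "
            "run the earlier stages first"
        )
    return path


def stage_simulate(cfg: RunConfig) -> None:
    trials, participants = simulate_cohort(cfg.cohort)
    write_cohort(trials, participants, cfg.cohort, _outdir(cfg))


def _read_channel(path: pathlib.Path, channel: str, stage: str) -> EpochSet:
    df = pd.read_csv(_require(path, stage))
    sub = df[df["channel"] == channel]
    if sub.empty:
        raise StageError(f"stage {stage!r}: channel {channel!r} absent from {path.name}")
    tmp = path.with_suffix(f".{channel}.tmp.csv")
    sub.drop(columns=["channel"]).to_csv(tmp, index=False)
    try:
        es = read_epochs(tmp, channel=channel)
    finally:
        tmp.unlink(missing_ok=True)
    return es


def stage_ersp(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    eeg = _read_channel(out / "eeg.csv", "Cz", "ersp")
    if eeg.n_trials == 0:
        raise StageError("stage 'ersp': empty trial set")
    eeg, counts = filter_nonstep(eeg)
    counts.to_csv(out / "trial_counts.csv", index=False)
    bt = subtract_baseline(beta_timecourse(compute_ersp(eeg), band=cfg.band))
    long = pd.DataFrame(
        {
            "trial_id": np.repeat(bt.meta["trial_id"].to_numpy(), bt.times.size),
            "participant": np.repeat(bt.meta["participant"].to_numpy(), bt.times.size),
            "magnitude": np.repeat(bt.meta["magnitude"].to_numpy(), bt.times.size),
            "time_ms": np.tile(bt.times, bt.power.shape[0]),
            "beta_db": bt.power.ravel(),
        }
    )
    long.to_csv(out / "beta_trials.csv", index=False)
    pd.DataFrame(
        {
            "trial_id": bt.meta["trial_id"],
            "participant": bt.meta["participant"],
            "magnitude": bt.meta["magnitude"],
            "baseline_db": bt.baseline_value,
        }
    ).to_csv(out / "beta_baselines.csv", index=False)
    avg = average_by_condition(bt)
    pd.DataFrame(
        {
            "participant": np.repeat(avg.meta["participant"].to_numpy(), avg.times.size),
            "magnitude": np.repeat(avg.meta["magnitude"].to_numpy(), avg.times.size),
            "time_ms": np.tile(avg.times, avg.power.shape[0]),
            "beta_db": avg.power.ravel(),
        }
    ).to_csv(out / "beta_condition_avg.csv", index=False)


def stage_emg(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    frames = []
    for muscle in ("MG", "TA"):
        sides = {}
        for side in ("L", "R"):
            es = _read_channel(out / "emg.csv", f"{muscle}_{side}", "emg")
            es, _ = filter_nonstep(es)
            sides[side] = preprocess_emg(es, muscle=muscle)
        combined = normalize_and_combine(sides["L"], sides["R"])
        frames.append(
            pd.DataFrame(
                {
                    "participant": np.repeat(
                        combined.meta["participant"].to_numpy(), combined.times.size
                    ),
                    "magnitude": np.repeat(
                        combined.meta["magnitude"].to_numpy(), combined.times.size
                    ),
                    "muscle": muscle,
                    "time_ms": np.tile(combined.times, combined.value.shape[0]),
                    "value_nu": combined.value.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "emg_envelopes.csv", index=False)


def stage_binstats(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    avg = pd.read_csv(_require(out / "beta_condition_avg.csv", "binstats"))
    baselines = pd.read_csv(_require(out / "beta_baselines.csv", "binstats"))
    participants = pd.read_csv(_require(out / "participants.csv", "binstats"))
    abilities = dict(
        zip(participants["participant"], participants["balance_ability"])
    )

    from .ersp import BetaTimecourse

    piv = avg.pivot_table(index=["participant", "magnitude"], columns="time_ms",
                          values="beta_db", observed=True, sort=False)
    times = piv.columns.to_numpy(dtype=float)
    meta = piv.index.to_frame(index=False)
    bt = BetaTimecourse(times=times, power=piv.to_numpy(),
                        baseline_subtracted=True, meta=meta)
    peaks = compute_time_bin_peaks(bt, bins=cfg.bins)
    peaks.to_csv(out / "time_bin_peaks.csv", index=False)

    pre = baselines.groupby(["participant", "magnitude"], observed=True)[
        "baseline_db"
    ].mean().reset_index()
    overall = peaks[peaks["bin"] == "overall"].merge(
        pre, on=["participant", "magnitude"]
    )
    # pre/post ANOVA needs a balanced participant x magnitude table: drop
    # participants left without nonstep trials in some magnitude
    n_mag = overall["magnitude"].nunique()
    complete = overall.groupby("participant")["magnitude"].transform("nunique") == n_mag
    overall = overall[complete]
    # peaks are baseline-subtracted: restore absolute dB for the pre/post test
    res_prepost = pre_post_anova(
        overall["baseline_db"].to_numpy(),
        overall["peak_db"].to_numpy() + overall["baseline_db"].to_numpy(),
        overall["participant"].to_numpy(),
    )

    report: dict = {
        "pre_post": {
            "F": res_prepost.factor_F["time_bin"],
            "p": res_prepost.factor_p["time_bin"],
        },
        "magnitude": {},
        "ability": {},
    }
    for bin_name in cfg.bins:
        sub = peaks[peaks["bin"] == bin_name]
        res = magnitude_anova(sub, alpha=cfg.alpha)
        report["magnitude"][bin_name] = {
            "F": res.factor_F["magnitude"],
            "p": res.factor_p["magnitude"],
            "tukey": [
                {**r, "pair": list(r["pair"])} for r in res.posthoc
            ],
        }
        report["ability"][bin_name] = ability_association(sub, abilities)

    manifest = pd.read_csv(_require(out / "manifest.csv", "binstats"))
    large = manifest[manifest["magnitude"] == "large"]
    success = (
        (1.0 - large.groupby("participant")["is_step"].mean()) * 100.0
    ).to_dict()
    report["confounds"] = confound_regressions(
        success, abilities, peaks[peaks["bin"].isin(cfg.bins)].query("magnitude == 'large'")
    )
    with open(out / "binstats.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)


def _wavelet_block(avg: pd.DataFrame, value_col: str, kind: str, threshold: float,
                   alpha: float) -> tuple[list[dict], list[dict]]:
    """Run t-tests + ANOVA on one signal's condition averages."""
    curves, onsets = [], []
    decomps: dict = {}
    times128 = None
    for (p, m), sub in avg.groupby(["participant", "magnitude"], observed=True):
        sub = sub.sort_values("time_ms")
        t128, x128 = to_128_samples(sub["time_ms"].to_numpy(),
                                    sub[value_col].to_numpy(), kind=kind)
        decomps[(p, m)] = dwt_coif3(x128)
        times128 = t128
    levels = sorted({m for _, m in decomps})
    participants = sorted({p for p, _ in decomps})

    for m in levels:
        have = [p for p in participants if (p, m) in decomps]
        sc = wavelet_ttest([decomps[(p, m)] for p in have], times128,
                           alpha_family=alpha)
        oo = detect_onset_offset(sc, threshold)
        curves.append({"kind": "mean", "level": m, "curve": sc})
        onsets.append({"signal_kind": kind, "test": "mean", "level": m,
                       "onset_ms": oo.onset_ms, "offset_ms": oo.offset_ms,
                       "threshold": threshold})

    complete = [p for p in participants if all((p, m) in decomps for m in levels)]
    anova_in = {(p, m): decomps[(p, m)] for p in complete for m in levels}
    res = wavelet_anova(anova_in, times128, reference="small", alpha=alpha)
    for m, sc in res.items():
        if m == "info":
            continue
        oo = detect_onset_offset(sc, threshold)
        curves.append({"kind": "contrast_vs_small", "level": m, "curve": sc})
        onsets.append({"signal_kind": kind, "test": "contrast_vs_small", "level": m,
                       "onset_ms": oo.onset_ms, "offset_ms": oo.offset_ms,
                       "threshold": threshold})
    return curves, onsets


def stage_wfa(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    rows, onset_rows = [], []

    beta = pd.read_csv(_require(out / "beta_condition_avg.csv", "wfa"))
    curves, onsets = _wavelet_block(beta, "beta_db", "beta",
                                    cfg.beta_onset_threshold, cfg.alpha)
    for c in curves:
        sc = c["curve"]
        rows.append(pd.DataFrame({
            "signal": "beta", "test": c["kind"], "level": c["level"],
            "time_ms": sc.times, "value": sc.curve,
            "n_significant_coeffs": int(sc.mask.sum()),
        }))
    for o in onsets:
        onset_rows.append({**o, "signal": "beta"})

    emg = pd.read_csv(_require(out / "emg_envelopes.csv", "wfa"))
    for muscle, sub in emg.groupby("muscle"):
        curves, onsets = _wavelet_block(sub, "value_nu", "emg",
                                        cfg.emg_onset_threshold, cfg.alpha)
        for c in curves:
            sc = c["curve"]
            rows.append(pd.DataFrame({
                "signal": muscle, "test": c["kind"], "level": c["level"],
                "time_ms": sc.times, "value": sc.curve,
                "n_significant_coeffs": int(sc.mask.sum()),
            }))
        for o in onsets:
            onset_rows.append({**o, "signal": muscle})

    pd.concat(rows, ignore_index=True).to_csv(out / "wfa_curves.csv", index=False)
    with open(out / "wfa_onsets.json", "w") as fh:
        json.dump(onset_rows, fh, indent=2)


def stage_report(cfg: RunConfig) -> dict:
    out = _outdir(cfg)
    report = {
        "seed": cfg.cohort.seed,
        "version": __version__,
        "n_wavelet_coefficients": 160,
        "parameters": {
            "bins": {k: list(v) for k, v in cfg.bins.items()},
            "band": list(cfg.band),
            "alpha": cfg.alpha,
            "beta_onset_threshold_db": cfg.beta_onset_threshold,
            "emg_onset_threshold_nu": cfg.emg_onset_threshold,
        },
    }
    with open(_require(out / "binstats.json", "report")) as fh:
        report["binstats"] = json.load(fh)
    with open(_require(out / "wfa_onsets.json", "report")) as fh:
        report["onsets"] = json.load(fh)
    curves = pd.read_csv(_require(out / "wfa_curves.csv", "report"))
    report["any_significant_curve"] = bool(
        (curves["n_significant_coeffs"] > 0).any()
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


STAGES = {
    "simulate": stage_simulate,
    "ersp": stage_ersp,
    "emg": stage_emg,
    "binstats": stage_binstats,
    "wfa": stage_wfa,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and return the final report."""
    report: dict = {}
    for name, fn in STAGES.items():
        try:
            result = fn(cfg)
        except StageError:
            raise
        except Exception as exc:  # label the failing stage
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        if name == "report":
            report = result
    cfg.to_yaml(_outdir(cfg) / "run_config.yaml")
    return report
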