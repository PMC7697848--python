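"""Epoched single-trial containers, long-format CSV I/O, and trial filters.

Epoch windows are closed on both ends at the stated millisecond bounds, so a
-1000..2000 ms window at 1000 Hz holds 3001 samples and time 0 maps to a
unique sample index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "BalanceAbility",
    "FormatError",
    "read_epochs",
    "write_epochs",
    "detect_step_trial",
    "filter_nonstep",
    "balance_ability_score",
]

#: Vertical-load threshold (Newtons) below which a foot is considered unloaded.
STEP_FORCE_THRESHOLD_N = 5.0
#: Window after perturbation onset in which unloading counts as a step (ms).
STEP_WINDOW_MS = 2000.0


class FormatError(ValueError):
    """Malformed epoch table (missing columns, ragged trials, ...)."""


@dataclass
class EpochSet:
    """Trial x sample matrix with its sampling grid and per-trial metadata.

    Attributes
    ----------
    data : array, shape (n_trials, n_samples)
    fs : float
        Sampling rate in Hz.
    epoch_window : (float, float)
        Epoch bounds in ms, closed on both ends; 0 = perturbation onset.
    channel : str
    meta : pandas.DataFrame
        One row per trial; expected columns include ``trial_id``,
        ``participant``, ``magnitude`` and, where relevant, ``is_step``.
    """

    data: np.ndarray
    fs: float
    epoch_window: tuple[float, float]
    channel: str
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        t0, t1 = self.epoch_window
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (t0 <= 0.0 <= t1):
            raise ValueError("epoch window must contain time 0")
        expected = int(round((t1 - t0) * self.fs / 1000.0)) + 1
        if self.data.shape[1] != expected:
            raise FormatError(
                f"epoch window {t0}..{t1} ms at {self.fs} Hz implies "
                f"{expected} samples, got {self.data.shape[1]}"
            )
        if len(self.meta) and len(self.meta) != self.data.shape[0]:
            raise FormatError("metadata rows must match number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        t0, t1 = self.epoch_window
        return t0 + np.arange(self.data.shape[1]) * 1000.0 / self.fs

    @property
    def onset_index(self) -> int:
        """Sample index of time 0."""
        return int(round(-self.epoch_window[0] * self.fs / 1000.0))

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        meta = self.meta.loc[mask].reset_index(drop=True) if len(self.meta) else self.meta
        return replace(self, data=self.data[mask], meta=meta)


@dataclass
class BalanceAbility:
    """Normalized beam-walking score for one participant, in [0, 1]."""

    participant: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("balance ability score must lie in [0, 1]")


_META_COLS = ("participant", "magnitude", "is_step")


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet as long-format CSV.

    Columns: trial_id, participant, magnitude, is_step (when present),
    time_ms, value.  Full float precision so that read(write(x)) == x.
    """
    times = epochs.times
    n_t, n_s = epochs.data.shape
    meta = epochs.meta
    frame = {
        "trial_id": np.repeat(
            meta["trial_id"].to_numpy() if "trial_id" in meta else np.arange(n_t), n_s
        )
    }
    for col in _META_COLS:
        if col in meta:
            frame[col] = np.repeat(meta[col].to_numpy(), n_s)
    frame["time_ms"] = np.tile(times, n_t)
    frame["value"] = epochs.data.ravel()
    pd.DataFrame(frame).to_csv(path, index=False)


def read_epochs(path, channel: str = "") -> EpochSet:
    """Read a long-format epoch CSV written by :func:`write_epochs`.

    Raises :class:`FormatError` on missing columns or ragged trials.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("trial_id", "time_ms", "value"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    counts = df.groupby("trial_id", sort=False)["value"].size()
    if counts.nunique() != 1:
        raise FormatError("inconsistent trial lengths in epoch table")
    n_s = int(counts.iloc[0])
    trial_ids = counts.index.to_numpy()
    data = df["value"].to_numpy().reshape(len(trial_ids), n_s)
    times = df["time_ms"].to_numpy()[:n_s]
    if n_s < 2:
        raise FormatError("trials must contain at least two samples")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0]):
        raise FormatError("non-uniform sample times")
    fs = 1000.0 / dt[0]
    meta_cols = ["trial_id"] + [c for c in _META_COLS if c in df.columns]
    meta = df.iloc[::n_s][meta_cols].reset_index(drop=True)
    return EpochSet(
        data=data,
        fs=float(fs),
        epoch_window=(float(times[0]), float(times[-1])),
        channel=channel,
        meta=meta,
    )


def detect_step_trial(
    vforce_left: np.ndarray, vforce_right: np.ndarray, fs: float
) -> bool:
    """True if either foot's vertical load drops strictly below 5 N in (0, 2000] ms.

    The force series are taken to start at perturbation onset (t = 0 at the
    first sample) and must cover the full 2000 ms detection window.
    """
    left = np.asarray(vforce_left, dtype=float)
    right = np.asarray(vforce_right, dtype=float)
    n_needed = int(round(STEP_WINDOW_MS * fs / 1000.0)) + 1
    if left.size < n_needed or right.size < n_needed:
        raise ValueError("force series must cover 2000 ms after onset")
    sl = slice(1, n_needed)  # (0, 2000] ms: exclude the onset sample itself
    return bool(
        (left[sl] < STEP_FORCE_THRESHOLD_N).any()
        or (right[sl] < STEP_FORCE_THRESHOLD_N).any()
    )


def filter_nonstep(epochs: EpochSet) -> tuple[EpochSet, pd.DataFrame]:
    """Drop stepping trials; report retained trial counts.

    Returns the filtered EpochSet (sample values untouched) and a tidy count
    table (participant, magnitude, n_trials, n_retained).  Participants left
    with zero retained trials in some magnitude are flagged with
    ``zero_retained = True`` so downstream magnitude comparisons can exclude
    them.
    """
    if "is_step" not in epochs.meta:
        raise ValueError("metadata must contain an 'is_step' column")
    keep = ~epochs.meta["is_step"].to_numpy(dtype=bool)
    counts = (
        epochs.meta.assign(retained=keep)
        .groupby(["participant", "magnitude"], observed=True)
        .agg(n_trials=("retained", "size"), n_retained=("retained", "sum"))
        .reset_index()
    )
    counts["zero_retained"] = counts["n_retained"] == 0
    return epochs.select(keep), counts


def balance_ability_score(
    distances, beam_length: float, participant: str = ""
) -> BalanceAbility:
    """Normalized beam-walking balance ability.

    score = (sum of the 6 per-attempt distances) / (6 * beam_length), so six
    full traverses score 1.0 and six immediate losses score 0.0.
    """
    d = np.asarray(distances, dtype=float)
    if d.size != 6:
        raise ValueError("exactly 6 beam-walking attempts are required")
    if beam_length <= 0:
        raise ValueError("beam length must be positive")
    if (d < 0).any() or (d > beam_length).any():
        raise ValueError("distances must lie in [0, beam_length]")
    return BalanceAbility(participant=participant, score=float(d.sum() / (6.0 * beam_length)))
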