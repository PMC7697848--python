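"""EMG envelope extraction, normalization, and bilateral averaging.

Processing order matters and is fixed: 35 Hz high-pass (3rd-order zero-lag
Butterworth, i.e. forward-backward), mean subtraction over the epoch,
half-wave rectification (negatives clipped, not absolute value), then a
40 Hz zero-lag low-pass of the same design.  Single-trial envelopes are
normalized to a within-participant, within-side maximum of 1 before the two
sides are averaged, and trial-averaged within each perturbation magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .epochs import EpochSet

__all__ = ["EMGEnvelope", "preprocess_emg", "normalize_and_combine"]

HIGHPASS_HZ = 35.0
LOWPASS_HZ = 40.0
FILTER_ORDER = 3


@dataclass
class EMGEnvelope:
    """Rectified, filtered EMG envelopes on the EMG epoch grid.

    value has shape (n_trials, n_samples); values are non-negative up to
    low-pass overshoot.  ``side_combined`` marks bilaterally averaged data.
    """

    times: np.ndarray
    value: np.ndarray
    muscle: str
    side_combined: bool = False
    normalized: bool = False
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)


def preprocess_emg(raw: EpochSet, muscle: str = "") -> EMGEnvelope:
    """Raw EMG -> envelope: high-pass, demean, half-wave rectify, low-pass."""
    for cutoff in (HIGHPASS_HZ, LOWPASS_HZ):
        if cutoff >= raw.fs / 2.0:
            raise ValueError(f"cutoff {cutoff} Hz not below Nyquist for fs={raw.fs}")
    sos_hp = butter(FILTER_ORDER, HIGHPASS_HZ, btype="highpass", fs=raw.fs, output="sos")
    sos_lp = butter(FILTER_ORDER, LOWPASS_HZ, btype="lowpass", fs=raw.fs, output="sos")
    x = sosfiltfilt(sos_hp, raw.data, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    x = np.clip(x, 0.0, None)  # half-wave
    x = sosfiltfilt(sos_lp, x, axis=-1)
    return EMGEnvelope(times=raw.times, value=x, muscle=muscle, meta=raw.meta.copy())


def normalize_and_combine(left: EMGEnvelope, right: EMGEnvelope) -> EMGEnvelope:
    """Per-side within-participant max-normalization, bilateral mean, then
    trial averaging within participant x magnitude.

    Each side is divided by its within-participant maximum over trials and
    samples (so a value of 1 is attained on at least one trial per side per
    participant), the two sides are averaged per trial, and trials are
    averaged within each magnitude.  Returns one condition-averaged envelope
    per (participant, magnitude).
    """
    if left.muscle != right.muscle:
        raise ValueError("left/right envelopes must be the same muscle")
    if left.value.shape != right.value.shape:
        raise ValueError("left/right envelopes must have matching trials")
    meta = left.meta
    if not {"participant", "magnitude"} <= set(meta.columns):
        raise ValueError("meta must contain participant and magnitude")

    combined = np.empty_like(left.value)
    participants = meta["participant"].to_numpy()
    for p in np.unique(participants):
        idx = participants == p
        for env in (left, right):
            peak = env.value[idx].max()
            if peak <= 0:
                raise ValueError(f"all-zero EMG for participant {p}: cannot normalize")
        combined[idx] = 0.5 * (
            left.value[idx] / left.value[idx].max()
            + right.value[idx] / right.value[idx].max()
        )

    groups = meta.groupby(["participant", "magnitude"], observed=True, sort=True)
    rows, traces = [], []
    for (p, m), idx in groups.indices.items():
        rows.append({"participant": p, "magnitude": m, "n_trials": len(idx)})
        traces.append(combined[idx].mean(axis=0))
    return EMGEnvelope(
        times=left.times,
        value=np.asarray(traces),
        muscle=left.muscle,
        side_combined=True,
        normalized=True,
        meta=pd.DataFrame(rows),
    )
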