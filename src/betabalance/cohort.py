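"""Synthetic multi-participant balance-perturbation cohort.

Generates single-trial Cz EEG, bilateral MG/TA EMG and vertical ground
reaction forces with the statistical structure the downstream analysis
assumes: a beta-band (carrier ~20 Hz) amplitude-modulated burst starting
~50 ms after perturbation onset with early (~100 ms) and late (~200 ms)
Gaussian-envelope peaks plus a magnitude-dependent sustained component,
superposed on 1/f background noise and 60 Hz line noise; muscle bursts from
~100 ms scaling with perturbation magnitude, with a second agonist-like
tibialis component after platform deceleration (~500 ms); and step trials in
the large magnitude in which one foot unloads below 5 N.

The late beta component is coupled to balance ability with a negative slope,
so that participants with lower ability show larger late-phase beta power —
the between-participant effect the analysis is designed to detect.  All
amplitudes are free parameters of the generator; defaults give comfortable
statistical power at 19 participants x 8 trials per magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["CohortConfig", "Participant", "SyntheticTrial", "simulate_cohort",
           "ground_truth", "beta_envelope", "write_cohort", "trials_to_epochset"]

MAGNITUDES = ("small", "medium", "large")

#: Overall EEG scale; calibrated once so that baseline beta power sits near
#: the realistic ~67 dB regime.  Cosmetic (all downstream statistics are
#: shift/scale covariant in dB), not tested quantitatively.
_EEG_SCALE = 1700.0


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class CohortConfig:
    """All parameters of the synthetic study.

    Times are ms relative to perturbation onset; sampling rates in Hz.
    ``magnitude_gain`` multiplies burst amplitudes and must be non-decreasing
    small <= medium <= large (ties give a null condition, e.g. no medium
    effect); ``ability_late_slope`` couples the late beta component to
    balance ability (negative: lower ability, larger late beta).
    """

    n_participants: int = 19
    trials_per_magnitude: int = 8
    fs_eeg: float = 1000.0
    fs_emg: float = 1000.0
    eeg_epoch: tuple[float, float] = (-1000.0, 2000.0)
    emg_epoch: tuple[float, float] = (-400.0, 1400.0)
    beta_burst_onset: float = 50.0
    early_peak_center: float = 100.0
    late_peak_center: float = 200.0
    early_peak_sd: float = 30.0
    late_peak_sd: float = 45.0
    #: burst amplitude rises linearly from zero over this span after onset
    onset_ramp_ms: float = 40.0
    #: burst envelope amplitudes in units of the background-noise SD
    early_amp: float = 0.42
    late_amp: float = 0.6
    sustained_amp: float = 0.32
    magnitude_gain: dict = field(
        default_factory=lambda: {"small": 1.0, "medium": 1.45, "large": 2.1}
    )
    ability_late_slope: float = -0.7
    sustained_duration: dict = field(
        default_factory=lambda: {"small": 250.0, "medium": 400.0, "large": 950.0}
    )
    emg_onset: float = 100.0
    platform_decel_time: float = 500.0
    noise_exponent: float = 1.0
    eeg_noise_sd: float = 1.0
    line_noise_amp: float = 0.5
    emg_noise_sd: float = 0.04
    step_prob_large: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_magnitude < 1:
            raise ConfigurationError("participant and trial counts must be positive")
        if self.fs_eeg <= 0 or self.fs_emg <= 0:
            raise ConfigurationError("sampling rates must be positive")
        for win in (self.eeg_epoch, self.emg_epoch):
            if not (win[0] <= 0.0 <= win[1]):
                raise ConfigurationError("epoch windows must contain time 0")
        gains = [self.magnitude_gain[m] for m in MAGNITUDES]
        if any(b < a for a, b in zip(gains, gains[1:])):
            raise ConfigurationError("magnitude_gain must be non-decreasing")
        durs = [self.sustained_duration[m] for m in MAGNITUDES]
        if any(b < a for a, b in zip(durs, durs[1:])):
            raise ConfigurationError("sustained_duration must be non-decreasing")
        if not 0.0 <= self.step_prob_large <= 1.0:
            raise ConfigurationError("step_prob_large must be a probability")


@dataclass
class Participant:
    """One synthetic participant: beam-walking ability in [0,1] and a
    height-like multiplier applied to the medium/large perturbations."""

    id: str
    balance_ability: float
    height_proxy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.balance_ability <= 1.0:
            raise ValueError("balance_ability must lie in [0, 1]")


@dataclass
class SyntheticTrial:
    participant: str
    magnitude: str
    eeg: np.ndarray           # Cz, arbitrary uV-scale units
    emg: dict                 # keys MG_L, MG_R, TA_L, TA_R
    vforce: np.ndarray        # (2, n) left/right vertical GRF in N, from t=0
    is_step: bool


def _times(win: tuple[float, float], fs: float) -> np.ndarray:
    n = int(round((win[1] - win[0]) * fs / 1000.0)) + 1
    return win[0] + np.arange(n) * 1000.0 / fs


def beta_envelope(
    config: CohortConfig, magnitude: str, ability: float, t_ms: np.ndarray
) -> np.ndarray:
    """Analytic amplitude envelope of the injected beta burst (noise units).

    Sum of early and late Gaussian components plus a smooth sustained
    plateau, gated to zero before ``beta_burst_onset``.  Only the late
    component carries the ability coupling.
    """
    g = config.magnitude_gain[magnitude]
    late_factor = max(0.0, 1.0 + config.ability_late_slope * ability)
    env = config.early_amp * np.exp(
        -((t_ms - config.early_peak_center) ** 2) / (2.0 * config.early_peak_sd**2)
    )
    env = env + config.late_amp * late_factor * np.exp(
        -((t_ms - config.late_peak_center) ** 2) / (2.0 * config.late_peak_sd**2)
    )
    t_end = config.late_peak_center + config.sustained_duration[magnitude]
    plateau = 0.25 * (1.0 + np.tanh((t_ms - config.late_peak_center) / 40.0)) * (
        1.0 - np.tanh((t_ms - t_end) / 80.0)
    )
    env = env + config.sustained_amp * plateau
    env = g * env
    # bursts rise smoothly from zero at onset (no discontinuous step)
    ramp = np.clip((t_ms - config.beta_burst_onset) / max(config.onset_ramp_ms, 1e-9),
                   0.0, 1.0)
    return env * ramp


def _mg_envelope(config: CohortConfig, magnitude: str, t_ms: np.ndarray) -> np.ndarray:
    g = config.magnitude_gain[magnitude]
    burst = np.exp(-((t_ms - 160.0) ** 2) / (2.0 * 45.0**2))
    t_end = 250.0 + config.sustained_duration[magnitude]
    plateau = 0.25 * (1.0 + np.tanh((t_ms - 220.0) / 40.0)) * (
        1.0 - np.tanh((t_ms - t_end) / 100.0)
    )
    env = g * (burst + 0.5 * plateau)
    ramp = np.clip((t_ms - config.emg_onset) / 30.0, 0.0, 1.0)
    return env * ramp


def _ta_envelope(config: CohortConfig, magnitude: str, t_ms: np.ndarray) -> np.ndarray:
    g = config.magnitude_gain[magnitude]
    antagonist = 0.6 * np.exp(-((t_ms - 190.0) ** 2) / (2.0 * 55.0**2))
    antagonist[t_ms < config.emg_onset + 20.0] = 0.0
    # second agonist-like burst once the platform decelerates
    decel = 0.8 * np.exp(
        -((t_ms - (config.platform_decel_time + 150.0)) ** 2) / (2.0 * 90.0**2)
    )
    decel[t_ms < config.platform_decel_time] = 0.0
    return g * (antagonist + decel)


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float
                      ) -> np.ndarray:
    """Unit-SD spectrally shaped (1/f^exponent power) Gaussian noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_participants(config: CohortConfig, rng: np.random.Generator) -> list[Participant]:
    out = []
    for i in range(config.n_participants):
        ability = rng.uniform(0.1, 1.0)
        height = max(0.8, 1.0 + 0.05 * rng.standard_normal())
        out.append(Participant(id=f"P{i + 1:02d}", balance_ability=ability,
                               height_proxy=height))
    return out


def simulate_cohort(config: CohortConfig
                    ) -> tuple[list[SyntheticTrial], list[Participant]]:
    """Generate the full cohort; bit-identical for a fixed config/seed."""
    rng = np.random.default_rng(config.seed)
    participants = _draw_participants(config, rng)
    t_eeg = _times(config.eeg_epoch, config.fs_eeg)
    t_emg = _times(config.emg_epoch, config.fs_emg)
    n_force = int(round(2000.0 * config.fs_eeg / 1000.0)) + 1  # t = 0..2000 ms
    t_force = np.arange(n_force) * 1000.0 / config.fs_eeg

    trials: list[SyntheticTrial] = []
    for part in participants:
        for magnitude in MAGNITUDES:
            height_gain = 1.0 if magnitude == "small" else part.height_proxy
            for _ in range(config.trials_per_magnitude):
                env = beta_envelope(config, magnitude, part.balance_ability, t_eeg)
                carrier_phase = rng.uniform(0.0, 2.0 * np.pi)
                carrier = np.sin(2.0 * np.pi * 20.0 * t_eeg / 1000.0 + carrier_phase)
                noise = _one_over_f_noise(rng, t_eeg.size, config.fs_eeg,
                                          config.noise_exponent)
                line_phase = rng.uniform(0.0, 2.0 * np.pi)
                line = config.line_noise_amp * np.sin(
                    2.0 * np.pi * 60.0 * t_eeg / 1000.0 + line_phase
                )
                eeg = _EEG_SCALE * (
                    config.eeg_noise_sd * noise + line + height_gain * env * carrier
                )

                emg = {}
                for muscle, env_fn in (("MG", _mg_envelope), ("TA", _ta_envelope)):
                    m_env = height_gain * env_fn(config, magnitude, t_emg)
                    for side in ("L", "R"):
                        side_gain = 1.0 + 0.1 * rng.standard_normal()
                        drive = config.emg_noise_sd + abs(side_gain) * m_env
                        emg[f"{muscle}_{side}"] = drive * rng.standard_normal(t_emg.size)

                is_step = magnitude == "large" and rng.uniform() < config.step_prob_large
                vforce = 350.0 + 5.0 * rng.standard_normal((2, n_force))
                if is_step:
                    side = int(rng.integers(0, 2))
                    t_step = rng.uniform(300.0, 1200.0)
                    dip = np.clip((t_force - t_step) / 50.0, 0.0, 1.0) * np.clip(
                        (t_step + 400.0 - t_force) / 50.0, 0.0, 1.0
                    )
                    vforce[side] = vforce[side] * (1.0 - dip)
                trials.append(
                    SyntheticTrial(
                        participant=part.id,
                        magnitude=magnitude,
                        eeg=eeg,
                        emg=emg,
                        vforce=vforce,
                        is_step=is_step,
                    )
                )
    return trials, participants


def ground_truth(config: CohortConfig) -> dict:
    """Injected parameters, for parameter-recovery tests.

    Participants are re-drawn deterministically from the seed, so the
    per-participant expected late-phase amplitude factors here match the
    simulated cohort exactly.
    """
    rng = np.random.default_rng(config.seed)
    participants = _draw_participants(config, rng)
    t_fine = np.arange(config.eeg_epoch[0], config.eeg_epoch[1], 0.5)
    peak_times = {}
    for m in MAGNITUDES:
        env = beta_envelope(config, m, 0.5, t_fine)
        peak_times[m] = float(t_fine[np.argmax(env)])
    return {
        "beta_onset_ms": config.beta_burst_onset,
        "emg_onset_ms": config.emg_onset,
        "early_peak_center_ms": config.early_peak_center,
        "late_peak_center_ms": config.late_peak_center,
        "magnitude_gain": dict(config.magnitude_gain),
        "gain_order": sorted(MAGNITUDES, key=lambda m: config.magnitude_gain[m]),
        "envelope_peak_ms": peak_times,
        "ability_late_slope": config.ability_late_slope,
        "abilities": {p.id: p.balance_ability for p in participants},
        "late_factor": {
            p.id: max(0.0, 1.0 + config.ability_late_slope * p.balance_ability)
            for p in participants
        },
    }


def trials_to_epochset(trials: list[SyntheticTrial], config: CohortConfig,
                       channel: str = "Cz"):
    """Stack one channel of a simulated cohort into an in-memory EpochSet.

    ``channel`` is "Cz" for EEG or one of MG_L/MG_R/TA_L/TA_R for EMG.
    """
    from .epochs import EpochSet

    if channel == "Cz":
        window, fs = config.eeg_epoch, config.fs_eeg
        getter = lambda t: t.eeg  # noqa: E731
    else:
        window, fs = config.emg_epoch, config.fs_emg
        getter = lambda t: t.emg[channel]  # noqa: E731
    meta = pd.DataFrame(
        {
            "trial_id": range(len(trials)),
            "participant": [t.participant for t in trials],
            "magnitude": [t.magnitude for t in trials],
            "is_step": [t.is_step for t in trials],
        }
    )
    return EpochSet(
        data=np.array([getter(t) for t in trials]),
        fs=fs, epoch_window=window, channel=channel, meta=meta,
    )


def _long_frame(trials: list[SyntheticTrial], times: np.ndarray,
                series_of) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(trials):
        for name, values in series_of(tr):
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": i,
                        "participant": tr.participant,
                        "magnitude": tr.magnitude,
                        "is_step": tr.is_step,
                        "channel": name,
                        "time_ms": times,
                        "value": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_cohort(trials: list[SyntheticTrial], participants: list[Participant],
                 config: CohortConfig, outdir) -> None:
    """Write the cohort as long-format CSV plus a manifest and config."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_eeg = _times(config.eeg_epoch, config.fs_eeg)
    t_emg = _times(config.emg_epoch, config.fs_emg)
    n_force = trials[0].vforce.shape[1]
    t_force = np.arange(n_force) * 1000.0 / config.fs_eeg

    _long_frame(trials, t_eeg, lambda tr: [("Cz", tr.eeg)]).to_csv(
        outdir / "eeg.csv", index=False
    )
    _long_frame(trials, t_emg, lambda tr: list(tr.emg.items())).to_csv(
        outdir / "emg.csv", index=False
    )
    _long_frame(
        trials, t_force,
        lambda tr: [("left", tr.vforce[0]), ("right", tr.vforce[1])],
    ).to_csv(outdir / "force.csv", index=False)
    pd.DataFrame(
        [
            {"participant": p.id, "balance_ability": p.balance_ability,
             "height_proxy": p.height_proxy}
            for p in participants
        ]
    ).to_csv(outdir / "participants.csv", index=False)
    pd.DataFrame(
        [
            {"trial_id": i, "participant": tr.participant,
             "magnitude": tr.magnitude, "is_step": tr.is_step}
            for i, tr in enumerate(trials)
        ]
    ).to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
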