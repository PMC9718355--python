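"""Synthetic laminar-population session generator.

Emulates a delayed-saccade session recorded with a laminar probe in the
superior colliculus: 8 radially equidistant targets at 45deg spacing,
6-17 simultaneously recorded channels sharing (up to jitter) a preferred
direction, a transient visual burst ~50-150 ms after target onset, tonic
delay activity, a motor burst around saccade onset, and per-channel LFP
traces with direction-tuned evoked deflections plus Gaussian noise.

Spiking is an inhomogeneous Poisson process driven by a per-channel rate
profile; rates are tuned by a circular Gaussian in direction around each
channel's preferred direction.  All event times are in milliseconds
relative to target onset; the trial window is [-600, saccade + 400] ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionConfig",
    "ChannelModel",
    "SessionData",
    "spatial_tuning",
    "rate_profile",
    "simulate_trial",
    "simulate_session",
    "sample_channels",
]

#: Time before target onset at which every trial's recording starts (ms).
TRIAL_START_MS = -600.0
#: Recording continues this long past saccade onset (ms).
POST_SACCADE_MS = 400.0

# Temporal kernel parameters (ms).  The visual burst rises after a 50-ms
# onset latency and peaks ~100 ms post-target; the motor burst is centered
# on saccade onset.  Tonic delay activity spans the gap between them.
VISUAL_ONSET_MS = 50.0
VISUAL_PEAK_MS = 100.0
VISUAL_SD_MS = 20.0
MOTOR_SD_MS = 17.0
DELAY_START_MS = 200.0
DELAY_END_BEFORE_SACCADE_MS = 100.0

# LFP evoked-deflection shape (ms) and relative size of the weakly tuned
# sustained delay deflection.
LFP_EVOKED_SD_MS = 30.0
LFP_DELAY_FRACTION = 0.05

# Reaction time between the (implicit) go cue at delay end and saccade
# onset, drawn uniformly per trial (ms).
REACTION_RANGE_MS = (150.0, 250.0)


@dataclass(frozen=True)
class SessionConfig:
    """Generative parameters for one synthetic session.

    Parameters
    ----------
    n_channels
        Number of simultaneously recorded channels (laminar contacts).
    trials_per_target
        Correct trials per target direction; the session has
        ``8 * trials_per_target`` trials total.
    preferred_direction
        Shared preferred direction of the population in degrees; each
        channel's own preferred direction is jittered around it.
    delay_range
        (low, high) uniform range of the delay-period duration in ms.
    """

    n_channels: int = 15
    n_targets: int = 8
    target_directions: tuple[float, ...] = tuple(float(45 * k) for k in range(8))
    preferred_direction: float = 0.0
    trials_per_target: int = 100
    delay_range: tuple[float, float] = (700.0, 1500.0)
    lfp_sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets != 8:
            raise ValueError("the task has exactly 8 target directions")
        dirs = np.asarray(self.target_directions, dtype=float)
        if len(dirs) != 8 or len(np.unique(dirs % 360.0)) != 8:
            raise ValueError("target_directions must be 8 distinct angles")
        spacing = np.diff(np.sort(dirs % 360.0))
        if not np.allclose(spacing, 45.0):
            raise ValueError("target directions must be spaced 45 degrees apart")
        if self.delay_range[0] < 600.0 or self.delay_range[1] < self.delay_range[0]:
            raise ValueError("delay_range lower bound must be >= 600 ms")
        if self.trials_per_target < 20:
            raise ValueError("trials_per_target must be >= 20")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.lfp_sampling_rate <= 0:
            raise ValueError("lfp_sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_targets * self.trials_per_target

    @property
    def preferred_target_index(self) -> int:
        """1-based index of the target closest to the preferred direction."""
        dirs = np.asarray(self.target_directions, dtype=float)
        diff = np.abs(wrap_angle(dirs - self.preferred_direction))
        return int(np.argmin(diff)) + 1


@dataclass(frozen=True)
class ChannelModel:
    """Generative parameters for one recorded channel.

    Rates are in spikes/s; any instantiated rate is clipped at 0.
    ``opposite_field_modulation`` is a signed event-locked rate change for
    targets away from the preferred direction (elevation or suppression,
    mixed in sign across channels), the mechanism by which a population —
    but no single channel — can discriminate anti-preferred targets.
    """

    preferred_direction: float
    tuning_width: float = 45.0
    baseline_rate: float = 10.0
    visual_gain: float = 60.0
    delay_gain: float = 10.0
    motor_gain: float = 60.0
    opposite_field_modulation: float = 0.0
    lfp_amplitude: float = 45.0
    lfp_latency: float = 100.0
    lfp_noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.tuning_width <= 0:
            raise ValueError("tuning_width must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be nonnegative")


@dataclass
class SessionData:
    """One session: per-trial events plus spikes and LFP per channel.

    ``events`` has one row per trial with columns ``trial_id``,
    ``target_index`` (1..8), ``target_onset_ms`` (always 0: the time
    base), ``saccade_onset_ms``, ``trial_start_ms`` and ``trial_end_ms``.
    ``spikes[trial][channel]`` is a sorted float array of spike times in
    ms relative to target onset; ``lfp[trial]`` is a
    ``(n_channels, n_samples)`` float array in microvolts sampled at
    ``lfp_sampling_rate`` starting at ``trial_start_ms``.
    """

    events: pd.DataFrame
    spikes: list[list[np.ndarray]]
    lfp: list[np.ndarray]
    lfp_sampling_rate: float = 1000.0
    config: SessionConfig | None = None
    channels: list[ChannelModel] | None = None

    def __post_init__(self) -> None:
        required = {
            "trial_id",
            "target_index",
            "target_onset_ms",
            "saccade_onset_ms",
            "trial_start_ms",
            "trial_end_ms",
        }
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        if len(self.spikes) != len(self.events):
            raise ValueError("spike lists do not match the number of trials")
        if len(self.lfp) != len(self.events):
            raise ValueError("LFP matrices do not match the number of trials")

    @property
    def n_trials(self) -> int:
        return len(self.events)

    @property
    def n_channels(self) -> int:
        return len(self.spikes[0]) if self.spikes else 0

    @property
    def labels(self) -> np.ndarray:
        return self.events["target_index"].to_numpy(dtype=int)

    @property
    def preferred_target_index(self) -> int:
        if self.config is None:
            raise ValueError("session has no generator provenance")
        return self.config.preferred_target_index

    def lfp_sample_times(self, trial: int) -> np.ndarray:
        start = float(self.events["trial_start_ms"].iloc[trial])
        n = self.lfp[trial].shape[1]
        return start + np.arange(n) * (1000.0 / self.lfp_sampling_rate)


def wrap_angle(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle difference to (-180, 180] degrees."""
    return -np.mod(-np.asarray(angle_deg, dtype=float) + 180.0, 360.0) + 180.0


def spatial_tuning(angle_difference: np.ndarray | float, width: float) -> np.ndarray | float:
    """Circular-Gaussian direction tuning gain in (0, 1].

    ``exp(-d^2 / (2 width^2))`` with ``d`` the angle difference wrapped
    to (-180, 180] degrees; symmetric in the sign of the difference, so
    targets +45 and -45 deg from the preferred direction drive a channel
    equally (the single-channel ambiguity the population analysis
    resolves).
    """
    if width <= 0:
        raise ValueError("tuning width must be positive")
    d = wrap_angle(angle_difference)
    out = np.exp(-np.square(d) / (2.0 * width**2))
    return float(out) if np.isscalar(angle_difference) else out


def _visual_kernel(t: np.ndarray) -> np.ndarray:
    k = np.exp(-np.square(t - VISUAL_PEAK_MS) / (2.0 * VISUAL_SD_MS**2))
    return np.where(t >= VISUAL_ONSET_MS, k, 0.0)


def _motor_kernel(t_from_saccade: np.ndarray) -> np.ndarray:
    return np.exp(-np.square(t_from_saccade) / (2.0 * MOTOR_SD_MS**2))


def _delay_kernel(t: np.ndarray, saccade_onset: float) -> np.ndarray:
    return ((t >= DELAY_START_MS) & (t <= saccade_onset - DELAY_END_BEFORE_SACCADE_MS)).astype(
        float
    )


def rate_profile(
    channel: ChannelModel,
    target_direction: float,
    saccade_onset: float,
    t: np.ndarray | float,
) -> np.ndarray | float:
    """Instantaneous firing rate (spikes/s) of a channel at time ``t``.

    Baseline plus direction-tuned visual burst, tonic delay activity and
    motor burst, plus an event-locked opposite-field term weighted by
    ``1 - tuning`` so it acts for targets away from the preferred
    direction.  Clipped at 0.  ``t`` is ms relative to target onset and
    must lie inside the trial window.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < TRIAL_START_MS) or np.any(t_arr > saccade_onset + POST_SACCADE_MS):
        raise ValueError("time outside the trial window")
    g = spatial_tuning(target_direction - channel.preferred_direction, channel.tuning_width)
    kv = _visual_kernel(t_arr)
    km = _motor_kernel(t_arr - saccade_onset)
    kd = _delay_kernel(t_arr, saccade_onset)
    rate = (
        channel.baseline_rate
        + channel.visual_gain * kv * g
        + channel.delay_gain * kd * g
        + channel.motor_gain * km * g
        + channel.opposite_field_modulation * (1.0 - g) * (kv + km)
    )
    rate = np.clip(rate, 0.0, None)
    return float(rate[0]) if np.isscalar(t) else rate


def _lfp_trace(
    channel: ChannelModel,
    target_direction: float,
    saccade_onset: float,
    sample_times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evoked LFP (microvolts): tuned negative deflections at the visual
    latency and at saccade onset, a weakly tuned sustained delay
    deflection, plus white Gaussian noise."""
    g = spatial_tuning(target_direction - channel.preferred_direction, channel.tuning_width)
    t = sample_times
    evoked = -channel.lfp_amplitude * g * (
        np.exp(-np.square(t - channel.lfp_latency) / (2.0 * LFP_EVOKED_SD_MS**2))
        + np.exp(-np.square(t - saccade_onset) / (2.0 * LFP_EVOKED_SD_MS**2))
    )
    evoked -= (
        LFP_DELAY_FRACTION
        * channel.lfp_amplitude
        * g
        * _delay_kernel(t, saccade_onset)
    )
    noise = rng.normal(0.0, channel.lfp_noise_sd, size=t.shape) if channel.lfp_noise_sd > 0 else 0.0
    return evoked + noise


def simulate_trial(
    config: SessionConfig,
    channels: Sequence[ChannelModel],
    target_index: int,
    rng: np.random.Generator,
) -> tuple[dict, list[np.ndarray], np.ndarray]:
    """Simulate one trial: events record, per-channel spike times, LFP.

    The delay duration is uniform over ``config.delay_range``; saccade
    onset follows the delay by a uniform 150-250 ms reaction time.
    Spikes are drawn from an inhomogeneous Poisson process (rate profile
    discretized at 1 ms), so the count in any interval is Poisson with
    mean equal to the integrated rate.
    """
    if not 1 <= target_index <= config.n_targets:
        raise ValueError("target_index must be in 1..8")
    target_direction = float(config.target_directions[target_index - 1])
    delay = rng.uniform(*config.delay_range)
    saccade_onset = delay + rng.uniform(*REACTION_RANGE_MS)
    trial_end = saccade_onset + POST_SACCADE_MS

    # 1-ms rate discretization: Poisson count per bin, uniform placement.
    edges = np.arange(TRIAL_START_MS, trial_end + 1e-9, 1.0)
    centers = edges[:-1] + 0.5
    spikes: list[np.ndarray] = []
    for ch in channels:
        rates = rate_profile(ch, target_direction, saccade_onset, centers)
        counts = rng.poisson(rates * 1e-3)
        n_spk = int(counts.sum())
        if n_spk == 0:
            spikes.append(np.empty(0, dtype=float))
            continue
        bins = np.repeat(edges[:-1], counts)
        times = np.sort(bins + rng.uniform(0.0, 1.0, size=n_spk))
        spikes.append(times)

    dt = 1000.0 / config.lfp_sampling_rate
    sample_times = np.arange(TRIAL_START_MS, trial_end, dt)
    lfp = np.stack(
        [_lfp_trace(ch, target_direction, saccade_onset, sample_times, rng) for ch in channels]
    )

    event = {
        "target_index": target_index,
        "target_onset_ms": 0.0,
        "saccade_onset_ms": float(saccade_onset),
        "trial_start_ms": TRIAL_START_MS,
        "trial_end_ms": float(trial_end),
    }
    return event, spikes, lfp


# Population heterogeneity defaults: preferred directions jittered around
# the session preferred direction, mixed-sign opposite-field modulation,
# and moderate spread in gains, so single channels are ambiguous between
# +45 and -45 deg targets but the population is not.
_CHANNEL_RANGES = {
    "pd_jitter_sd": 10.0,
    "tuning_width": (35.0, 55.0),
    "baseline_rate": (5.0, 15.0),
    "visual_gain": (40.0, 80.0),
    "delay_gain": (5.0, 15.0),
    "motor_gain": (40.0, 80.0),
    "opposite_field_modulation": (-10.0, 10.0),
    "lfp_amplitude": (30.0, 60.0),
    "lfp_latency": (80.0, 120.0),
    "lfp_noise_sd": 30.0,
}


def sample_channels(
    config: SessionConfig,
    rng: np.random.Generator,
    **overrides: float,
) -> list[ChannelModel]:
    """Draw heterogeneous channel models for a session.

    Keyword overrides pin a ``ChannelModel`` field to a fixed value for
    every channel (e.g. ``tuning_width=30.0`` or
    ``opposite_field_modulation=0.0``).
    """
    channels = []
    for _ in range(config.n_channels):
        fields = {
            "preferred_direction": config.preferred_direction
            + rng.normal(0.0, _CHANNEL_RANGES["pd_jitter_sd"]),
            "tuning_width": rng.uniform(*_CHANNEL_RANGES["tuning_width"]),
            "baseline_rate": rng.uniform(*_CHANNEL_RANGES["baseline_rate"]),
            "visual_gain": rng.uniform(*_CHANNEL_RANGES["visual_gain"]),
            "delay_gain": rng.uniform(*_CHANNEL_RANGES["delay_gain"]),
            "motor_gain": rng.uniform(*_CHANNEL_RANGES["motor_gain"]),
            "opposite_field_modulation": rng.uniform(
                *_CHANNEL_RANGES["opposite_field_modulation"]
            ),
            "lfp_amplitude": rng.uniform(*_CHANNEL_RANGES["lfp_amplitude"]),
            "lfp_latency": rng.uniform(*_CHANNEL_RANGES["lfp_latency"]),
            "lfp_noise_sd": _CHANNEL_RANGES["lfp_noise_sd"],
        }
        fields.update(overrides)
        channels.append(ChannelModel(**fields))
    return channels


def simulate_session(
    config: SessionConfig,
    channels: Sequence[ChannelModel] | None = None,
    **channel_overrides: float,
) -> SessionData:
    """Simulate a full session: ``trials_per_target`` trials per target,
    interleaved in randomized order.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if channels is None:
        channels = sample_channels(config, rng, **channel_overrides)
    channels = list(channels)
    if len(channels) != config.n_channels:
        raise ValueError("channel list does not match config.n_channels")

    labels = np.repeat(np.arange(1, config.n_targets + 1), config.trials_per_target)
    labels = rng.permutation(labels)

    records, all_spikes, all_lfp = [], [], []
    for trial_id, target in enumerate(labels):
        event, spikes, lfp = simulate_trial(config, channels, int(target), rng)
        event["trial_id"] = trial_id
        records.append(event)
        all_spikes.append(spikes)
        all_lfp.append(lfp)

    events = pd.DataFrame.from_records(records)[
        [
            "trial_id",
            "target_index",
            "target_onset_ms",
            "saccade_onset_ms",
            "trial_start_ms",
            "trial_end_ms",
        ]
    ]
    return SessionData(
        events=events,
        spikes=all_spikes,
        lfp=all_lfp,
        lfp_sampling_rate=config.lfp_sampling_rate,
        config=config,
        channels=channels,
    )
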