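"""Session interchange I/O and the end-to-end synthetic replica run.

A session on disk is a directory with
``events.csv`` (trial_id, target_index, target_onset_ms,
saccade_onset_ms, trial_start_ms, trial_end_ms), ``spikes.csv``
(trial_id, channel_id, spike_time_ms) and ``lfp.h5`` (trials x channels
x samples, NaN-padded to the longest trial, with a ``sampling_rate_hz``
attribute and per-trial sample counts).  Generator provenance, when the
session is synthetic, is stored in ``meta.yaml``.

``run_replica`` orchestrates the full analysis over several simulated
sessions: feature extraction for both modalities and alignments, true
and shuffled-label decoding, baseline subtraction, preferred-direction
rotation, across-session aggregation, epoch tuning curves with AUC
statistics, and paired spike-vs-LFP comparisons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from scdecode import epoch_stats, timecourse
from scdecode.features import (
    SACCADE_ALIGNED,
    TARGET_ALIGNED,
    WindowSpec,
    extract_windows,
    select_functional_channels,
)
from scdecode.synthgen import ChannelModel, SessionConfig, SessionData, simulate_session
from scdecode.timecourse import EvalOptions

__all__ = [
    "save_session",
    "load_session",
    "ExperimentConfig",
    "ResultBundle",
    "run_replica",
    "timeseries_frame",
]

EVENT_COLUMNS = [
    "trial_id",
    "target_index",
    "target_onset_ms",
    "saccade_onset_ms",
    "trial_start_ms",
    "trial_end_ms",
]


def save_session(session: SessionData, path: str | Path) -> None:
    """Write a session to the interchange layout (round-trip exact)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.events[EVENT_COLUMNS].to_csv(path / "events.csv", index=False)

    rows = []
    for t, per_channel in enumerate(session.spikes):
        for ch, times in enumerate(per_channel):
            for s in times:
                rows.append((t, ch, repr(float(s))))
    spikes = pd.DataFrame(rows, columns=["trial_id", "channel_id", "spike_time_ms"])
    spikes.to_csv(path / "spikes.csv", index=False)

    n_trials = session.n_trials
    n_ch = session.n_channels
    lengths = np.array([m.shape[1] for m in session.lfp], dtype=int)
    padded = np.full((n_trials, n_ch, int(lengths.max())), np.nan)
    for t, m in enumerate(session.lfp):
        padded[t, :, : m.shape[1]] = m
    with h5py.File(path / "lfp.h5", "w") as f:
        d = f.create_dataset("lfp", data=padded, compression=None)
        d.attrs["sampling_rate_hz"] = session.lfp_sampling_rate
        f.create_dataset("n_samples", data=lengths)

    meta: dict = {"lfp_sampling_rate": float(session.lfp_sampling_rate)}
    if session.config is not None:
        cfg = dataclasses.asdict(session.config)
        cfg["target_directions"] = [float(v) for v in cfg["target_directions"]]
        cfg["delay_range"] = [float(v) for v in cfg["delay_range"]]
        meta["config"] = cfg
    if session.channels is not None:
        meta["channels"] = [dataclasses.asdict(c) for c in session.channels]
    with open(path / "meta.yaml", "w") as f:
        yaml.safe_dump(meta, f)


def load_session(path: str | Path) -> SessionData:
    """Read a session directory, validating cross-file consistency."""
    path = Path(path)
    events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    n_trials = len(events)
    if not np.array_equal(events["trial_id"].to_numpy(), np.arange(n_trials)):
        raise ValueError("events trial_id must be 0..n_trials-1 in order")

    with h5py.File(path / "lfp.h5", "r") as f:
        padded = f["lfp"][...]
        fs = float(f["lfp"].attrs["sampling_rate_hz"])
        lengths = f["n_samples"][...].astype(int)
    if padded.shape[0] != n_trials:
        raise ValueError(
            f"LFP matrix has {padded.shape[0]} trials but events table has {n_trials}"
        )
    n_ch = padded.shape[1]
    lfp = [padded[t, :, : lengths[t]] for t in range(n_trials)]

    spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    bad = set(spikes_df["trial_id"].unique()) - set(range(n_trials))
    if bad:
        raise ValueError(f"spikes.csv references unknown trial ids: {sorted(bad)[:5]}")
    spikes: list[list[np.ndarray]] = [
        [np.empty(0, dtype=float) for _ in range(n_ch)] for _ in range(n_trials)
    ]
    for (t, ch), grp in spikes_df.groupby(["trial_id", "channel_id"]):
        spikes[int(t)][int(ch)] = np.sort(grp["spike_time_ms"].to_numpy(dtype=float))

    config = channels = None
    meta_path = path / "meta.yaml"
    if meta_path.exists():
        with open(meta_path) as f:
            meta = yaml.safe_load(f) or {}
        if "config" in meta:
            cfg = dict(meta["config"])
            cfg["target_directions"] = tuple(cfg["target_directions"])
            cfg["delay_range"] = tuple(cfg["delay_range"])
            config = SessionConfig(**cfg)
        if "channels" in meta:
            channels = [ChannelModel(**c) for c in meta["channels"]]

    return SessionData(
        events=events,
        spikes=spikes,
        lfp=lfp,
        lfp_sampling_rate=fs,
        config=config,
        channels=channels,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything the end-to-end replica run reads.

    ``base_session`` supplies the generator parameters; each session
    gets a derived seed and a preferred direction drawn from the 8
    target angles, so the preferred-direction rotation step is
    exercised.  Spans are window-end ranges in ms.
    """

    base_session: SessionConfig = field(default_factory=SessionConfig)
    n_sessions: int = 18
    window_length: float = 100.0
    target_span: tuple[float, float] = (-600.0, 600.0)
    saccade_span: tuple[float, float] = (-400.0, 400.0)
    train_frac: float = 0.7
    n_iter: int = 10
    master_seed: int = 0

    def options(self) -> EvalOptions:
        return EvalOptions(train_frac=self.train_frac, n_iter=self.n_iter, seed=self.master_seed)


@dataclass
class ResultBundle:
    """All tables produced by one replica run."""

    config: ExperimentConfig
    timeseries: pd.DataFrame  # tidy per-session window series
    session_mean: dict  # (modality, alignment, shuffled) -> (mean, sem) arrays
    window_end_times: dict  # alignment -> grid
    epoch_tuning: pd.DataFrame  # per session x modality x epoch curves + AUCs
    comparisons: pd.DataFrame  # paired spike-vs-LFP AUC tests per epoch


def timeseries_frame(
    series: timecourse.PerformanceTimeSeries, session_id: int
) -> pd.DataFrame:
    """Tidy long-format rows for one performance series."""
    rows = []
    for target in range(1, 9):
        for end, v in zip(series.window_end_times, series.f1[target - 1]):
            rows.append(
                (
                    session_id,
                    series.modality,
                    series.alignment,
                    target,
                    float(end),
                    float(v),
                    series.shuffled,
                    series.baseline_subtracted,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "session",
            "modality",
            "alignment",
            "target",
            "window_end_ms",
            "f1_mean",
            "is_shuffled",
            "is_baseline_subtracted",
        ],
    )


def run_replica(config: ExperimentConfig) -> ResultBundle:
    """Simulate ``n_sessions`` sessions and run the full analysis.

    Deterministic under ``master_seed``.  Returns the per-session tidy
    time series (baseline-subtracted, rotated to each session's
    preferred target), across-session mean +- SEM, per-epoch tuning
    curves with AUC and normalized AUC, and paired spike-vs-LFP AUC
    comparisons per epoch (when ``n_sessions`` >= 3).
    """
    rng = np.random.default_rng((config.master_seed, 424_242))
    frames, tuning_rows = [], []
    rotated: dict = {}
    grids: dict = {}

    for s in range(config.n_sessions):
        sess_cfg = dataclasses.replace(
            config.base_session,
            seed=int(rng.integers(0, 2**31 - 1)),
            preferred_direction=float(rng.choice(np.arange(0.0, 360.0, 45.0))),
        )
        session = simulate_session(sess_cfg)
        channels = select_functional_channels(session)
        preferred = session.preferred_target_index
        opts = dataclasses.replace(config.options(), seed=config.master_seed + 7919 * s)

        per_align: dict = {}
        for alignment, span in (
            (TARGET_ALIGNED, config.target_span),
            (SACCADE_ALIGNED, config.saccade_span),
        ):
            spec = WindowSpec(length=config.window_length, alignment=alignment, span=span)
            for modality in ("spike", "lfp"):
                tensor = extract_windows(session, channels, spec, modality)
                true_ts = timecourse.decode_timecourse(tensor, opts)
                null_ts = timecourse.shuffled_null(tensor, opts)
                per_align[(modality, alignment)] = (true_ts, null_ts)
                grids[alignment] = tensor.window_end_times

        for modality in ("spike", "lfp"):
            tgt_true, tgt_null = per_align[(modality, TARGET_ALIGNED)]
            sac_true, sac_null = per_align[(modality, SACCADE_ALIGNED)]
            sub = {
                TARGET_ALIGNED: timecourse.baseline_subtract(tgt_true),
                SACCADE_ALIGNED: timecourse.baseline_subtract(sac_true, baseline_from=tgt_true),
            }
            sub_null = {
                TARGET_ALIGNED: timecourse.baseline_subtract(tgt_null),
                SACCADE_ALIGNED: timecourse.baseline_subtract(sac_null, baseline_from=tgt_null),
            }
            for shuffled, group in ((False, sub), (True, sub_null)):
                for alignment, series in group.items():
                    rot = timecourse.rotate_targets_to_preferred(series, preferred)
                    rotated.setdefault((modality, alignment, shuffled), []).append(rot)
                    frames.append(timeseries_frame(rot, s))

            epochs = epoch_stats.epoch_values(sub[TARGET_ALIGNED], sub[SACCADE_ALIGNED])
            for name, values in epochs.items():
                et = epoch_stats.EpochTuning.from_values(name, modality, values, preferred)
                tuning_rows.append(
                    {
                        "session": s,
                        "modality": modality,
                        "epoch": name,
                        **{f"t{k + 1}": float(v) for k, v in enumerate(et.curve)},
                        "auc": et.auc,
                        "norm_auc": et.norm_auc,
                    }
                )

    session_mean = {
        key: timecourse.aggregate_sessions(series_list) for key, series_list in rotated.items()
    }
    epoch_tuning = pd.DataFrame(tuning_rows)

    comp_rows = []
    if config.n_sessions >= 3:
        for epoch in epoch_tuning["epoch"].unique():
            sel = epoch_tuning[epoch_tuning["epoch"] == epoch]
            spike = sel[sel["modality"] == "spike"].sort_values("session")["auc"].to_numpy()
            lfp = sel[sel["modality"] == "lfp"].sort_values("session")["auc"].to_numpy()
            cmp_res = epoch_stats.paired_ttest(spike, lfp, "spike_auc", "lfp_auc")
            comp_rows.append(
                {
                    "epoch": epoch,
                    "comparison": "spike_vs_lfp_auc",
                    "t": cmp_res.t,
                    "p": cmp_res.p,
                    "stars": cmp_res.stars,
                }
            )
    comparisons = pd.DataFrame(comp_rows)

    return ResultBundle(
        config=config,
        timeseries=pd.concat(frames, ignore_index=True),
        session_mean=session_mean,
        window_end_times=grids,
        epoch_tuning=epoch_tuning,
        comparisons=comparisons,
    )
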