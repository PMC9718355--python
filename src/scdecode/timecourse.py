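"""Window-by-window decoding time courses, null, and sweeps.

Runs the per-window classifier over a whole session for either
modality and alignment, computes the shuffled-label chance series,
applies per-target baseline subtraction (mean performance 400-200 ms
before target onset), and performs the bin-width and population-size
sweeps with bootstrapped channel subsets shared across modalities.

Reproducibility: every window draws its random stream from
``(seed, alignment, modality, shuffled?, window end time)``, so the
series is deterministic under a master seed and individual windows are
reproducible independently and in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from scdecode.decoder import N_CLASSES, evaluate_window, fit_ecoc
from scdecode.features import (
    SWEEP_WINDOW_LENGTHS_MS,
    TARGET_ALIGNED,
    FeatureTensor,
    FunctionalChannelSet,
    WindowSpec,
    extract_windows,
)
from scdecode.synthgen import SessionData

__all__ = [
    "EvalOptions",
    "PerformanceTimeSeries",
    "SweepResult",
    "decode_timecourse",
    "shuffled_null",
    "baseline_subtract",
    "binwidth_sweep",
    "population_size_sweep",
    "rotate_targets_to_preferred",
    "aggregate_sessions",
]

BASELINE_WINDOW_MS = (-400.0, -200.0)


@dataclass(frozen=True)
class EvalOptions:
    """Split-evaluation parameters for every window."""

    train_frac: float = 0.7
    n_iter: int = 10
    seed: int = 0
    learner: object = fit_ecoc


@dataclass
class PerformanceTimeSeries:
    """Per-target mean F1 per window (8 x n_windows)."""

    f1: np.ndarray
    window_end_times: np.ndarray
    alignment: str
    modality: str
    shuffled: bool = False
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.window_end_times = np.asarray(self.window_end_times, dtype=float)
        if self.f1.shape != (N_CLASSES, len(self.window_end_times)):
            raise ValueError("f1 must be 8 x n_windows")

    def class_mean(self) -> np.ndarray:
        """Across-target mean F1 per window."""
        return self.f1.mean(axis=0)

    def target_trace(self, target: int) -> np.ndarray:
        return self.f1[target - 1]


def _window_rng(options: EvalOptions, tensor: FeatureTensor, shuffle: bool, end_ms: float):
    key = (
        int(options.seed),
        1 if tensor.alignment == TARGET_ALIGNED else 2,
        1 if tensor.modality == "spike" else 2,
        1 if shuffle else 0,
        int(round(10.0 * end_ms)) + 2**20,  # offset keeps entropy nonnegative
    )
    return np.random.default_rng(key)


def decode_timecourse(
    tensor: FeatureTensor,
    options: EvalOptions,
    shuffle: bool = False,
) -> PerformanceTimeSeries:
    """Train and test an independent classifier in every window.

    Each window's model sees only that window's features — no past or
    future activity — and is scored by per-class F1 averaged over
    ``options.n_iter`` random 70/30 splits.
    """
    f1 = np.full((N_CLASSES, tensor.n_windows), np.nan)
    for j, end in enumerate(tensor.window_end_times):
        X, y = tensor.window_data(j)
        if len(y) < N_CLASSES or len(np.unique(y)) < N_CLASSES:
            continue  # window missing from too many trials
        rng = _window_rng(options, tensor, shuffle, float(end))
        score = evaluate_window(
            X,
            y,
            rng,
            train_frac=options.train_frac,
            n_iter=options.n_iter,
            shuffle=shuffle,
            learner=options.learner,
        )
        f1[:, j] = score.f1
    return PerformanceTimeSeries(
        f1=f1,
        window_end_times=tensor.window_end_times,
        alignment=tensor.alignment,
        modality=tensor.modality,
        shuffled=shuffle,
    )


def shuffled_null(tensor: FeatureTensor, options: EvalOptions) -> PerformanceTimeSeries:
    """Empirical chance level: labels permuted independently before each
    split iteration, then the identical classification procedure."""
    return decode_timecourse(tensor, options, shuffle=True)


def baseline_constants(
    series: PerformanceTimeSeries,
    baseline_window: tuple[float, float] = BASELINE_WINDOW_MS,
) -> np.ndarray:
    """Per-target mean F1 over target-aligned windows ENDING in the
    baseline window (400-200 ms before target onset)."""
    if series.alignment != TARGET_ALIGNED:
        raise ValueError("baseline constants come from a target-aligned series")
    ends = series.window_end_times
    mask = (ends >= baseline_window[0]) & (ends <= baseline_window[1])
    mask &= ~np.isnan(series.f1).all(axis=0)
    if not mask.any():
        raise ValueError("no windows end inside the baseline window")
    return np.nanmean(series.f1[:, mask], axis=1)


def baseline_subtract(
    series: PerformanceTimeSeries,
    baseline_from: PerformanceTimeSeries | None = None,
    baseline_window: tuple[float, float] = BASELINE_WINDOW_MS,
) -> PerformanceTimeSeries:
    """Subtract each target's pre-target mean performance from its trace.

    Saccade-aligned series have no pre-target windows of their own; pass
    the paired target-aligned series of the same session/modality as
    ``baseline_from``.
    """
    source = series if baseline_from is None else baseline_from
    consts = baseline_constants(source, baseline_window)
    return PerformanceTimeSeries(
        f1=series.f1 - consts[:, None],
        window_end_times=series.window_end_times,
        alignment=series.alignment,
        modality=series.modality,
        shuffled=series.shuffled,
        baseline_subtracted=True,
    )


@dataclass
class SweepResult:
    """One decoding time series per condition x modality x bootstrap-average.

    ``series[condition][modality]`` is the bootstrap-averaged
    ``PerformanceTimeSeries``; for the population-size sweep,
    ``subsets[b]`` records the channel subset of bootstrap ``b`` for
    every size (identical for the spike and LFP runs by construction).
    """

    kind: str
    conditions: list
    series: dict
    n_boot: int
    subsets: dict | None = None


def _boot_average(
    tensor: FeatureTensor, options: EvalOptions, n_boot: int
) -> PerformanceTimeSeries:
    """Average a time course over n_boot repetitions of the split
    randomization (distinct seeds, identical data)."""
    acc = None
    for b in range(n_boot):
        opts = dc_replace(options, seed=options.seed + 100_003 * (b + 1))
        ts = decode_timecourse(tensor, opts)
        acc = ts.f1 if acc is None else acc + ts.f1
    return PerformanceTimeSeries(
        f1=acc / n_boot,
        window_end_times=tensor.window_end_times,
        alignment=tensor.alignment,
        modality=tensor.modality,
    )


def binwidth_sweep(
    session: SessionData,
    channels: FunctionalChannelSet,
    spec: WindowSpec,
    options: EvalOptions,
    widths: tuple[float, ...] = SWEEP_WINDOW_LENGTHS_MS,
    n_boot: int = 50,
    modalities: tuple[str, ...] = ("spike", "lfp"),
) -> SweepResult:
    """Repeat the time course with window lengths 20-300 ms (10-ms slide
    throughout, so all widths share one window-end grid)."""
    for w in widths:
        if w not in SWEEP_WINDOW_LENGTHS_MS:
            raise ValueError(f"window length {w} not in {SWEEP_WINDOW_LENGTHS_MS}")
    series: dict = {}
    for w in widths:
        wspec = dc_replace(spec, length=float(w))
        series[w] = {}
        for mod in modalities:
            tensor = extract_windows(session, channels, wspec, mod)
            series[w][mod] = _boot_average(tensor, options, n_boot)
    return SweepResult(kind="binwidth", conditions=list(widths), series=series, n_boot=n_boot)


def population_size_sweep(
    session: SessionData,
    channels: FunctionalChannelSet,
    spec: WindowSpec,
    options: EvalOptions,
    sizes: tuple[int, ...] | None = None,
    n_boot: int = 50,
    modalities: tuple[str, ...] = ("spike", "lfp"),
) -> SweepResult:
    """Decode with random channel subsets of increasing size.

    Per bootstrap draw, one uniformly random subset of the functional
    channels is selected for each size and reused for BOTH modalities,
    so spike and LFP curves are matched channel-for-channel.
    """
    U = channels.U
    if sizes is None:
        sizes = tuple(range(1, U + 1))
    if min(sizes) < 1 or max(sizes) > U:
        raise ValueError("population sizes must lie in 1..U")
    full = {mod: extract_windows(session, channels, spec, mod) for mod in modalities}
    rng = np.random.default_rng((int(options.seed), 777_001))
    subsets: dict = {}
    acc: dict = {s: {mod: None for mod in modalities} for s in sizes}
    for b in range(n_boot):
        subsets[b] = {}
        for s in sizes:
            pick = np.sort(rng.choice(U, size=s, replace=False))
            subsets[b][s] = pick
            for mod in modalities:
                opts = dc_replace(options, seed=options.seed + 100_003 * (b + 1) + 13 * s)
                ts = decode_timecourse(full[mod].subset_channels(pick), opts)
                prev = acc[s][mod]
                acc[s][mod] = ts.f1 if prev is None else prev + ts.f1
    series = {
        s: {
            mod: PerformanceTimeSeries(
                f1=acc[s][mod] / n_boot,
                window_end_times=full[mod].window_end_times,
                alignment=spec.alignment,
                modality=mod,
            )
            for mod in modalities
        }
        for s in sizes
    }
    return SweepResult(
        kind="popsize", conditions=list(sizes), series=series, n_boot=n_boot, subsets=subsets
    )


def rotate_targets_to_preferred(
    series: PerformanceTimeSeries, preferred_target: int
) -> PerformanceTimeSeries:
    """Rotate target indices so the session's preferred target occupies
    position 1 (angular order preserved), for across-session averaging."""
    rolled = np.roll(series.f1, -(preferred_target - 1), axis=0)
    return dc_replace(series, f1=rolled)


def aggregate_sessions(
    series_list: list[PerformanceTimeSeries],
) -> tuple[np.ndarray, np.ndarray]:
    """Across-session mean and SEM (8 x n_windows each); sessions must
    already be rotated to their preferred target and share a grid."""
    grids = [tuple(s.window_end_times) for s in series_list]
    if len(set(grids)) != 1:
        raise ValueError("sessions must share an identical window grid")
    stack = np.stack([s.f1 for s in series_list])
    mean = np.nanmean(stack, axis=0)
    n = np.sum(~np.isnan(stack), axis=0)
    sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return mean, sem
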