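"""Windowed feature extraction and channel screening.

Converts a session into aligned trials x channels x windows feature
tensors (summed spike counts or mean LFP voltage in sliding windows),
applies the functional-channel filter (peak evoked rate > 20 spikes/s
above baseline in the visual or motor epoch), and provides the
visualization-only signal conditioning (Gaussian rate smoothing,
band-pass + notch LFP filtering).

Windows are causal: the feature for a window ending at time ``t``
(relative to the alignment event) summarizes the half-open interval
``(t - length, t]``, so a spike at exactly the window end belongs to
that window and no future samples leak in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from scdecode.synthgen import SessionData

__all__ = [
    "WindowSpec",
    "FeatureTensor",
    "FunctionalChannelSet",
    "select_functional_channels",
    "smooth_firing_rate",
    "extract_windows",
    "lfp_condition_for_plots",
]

SWEEP_WINDOW_LENGTHS_MS = (20.0, 50.0, 100.0, 200.0, 300.0)

TARGET_ALIGNED = "target_onset"
SACCADE_ALIGNED = "saccade_onset"

# Epoch windows used by the functional-channel screen (ms).  Baseline is
# the same [-400, -200] pre-target window used for performance baseline
# subtraction downstream.
_BASELINE_WINDOW = (-400.0, -200.0)
_VISUAL_SCREEN_WINDOW = (0.0, 250.0)
_MOTOR_SCREEN_WINDOW = (-100.0, 100.0)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for feature extraction.

    ``length`` is the window length in ms (100 by default; the bin-width
    sweep uses 20-300), ``step`` the 10-ms slide, ``alignment`` the
    event windows are timed against, and ``span`` the (first, last)
    window-end times in ms relative to that event.
    """

    length: float = 100.0
    step: float = 10.0
    alignment: str = TARGET_ALIGNED
    span: tuple[float, float] = (-600.0, 600.0)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("window length must be positive")
        if self.step != 10.0:
            raise ValueError("window step is fixed at 10 ms")
        if self.alignment not in (TARGET_ALIGNED, SACCADE_ALIGNED):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if self.span[1] < self.span[0]:
            raise ValueError("span must be nondecreasing")

    @property
    def window_end_times(self) -> np.ndarray:
        n = int(round((self.span[1] - self.span[0]) / self.step)) + 1
        return self.span[0] + self.step * np.arange(n)


@dataclass
class FeatureTensor:
    """Trials x channels x windows feature array with window metadata.

    Spike features are summed counts (nonnegative integers stored as
    float); LFP features are mean voltage in microvolts.  Windows that
    extend beyond a trial's recorded interval are NaN for that trial and
    excluded from that window's classifier.
    """

    values: np.ndarray
    labels: np.ndarray
    window_end_times: np.ndarray
    alignment: str
    modality: str
    window_length: float
    channel_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.window_end_times = np.asarray(self.window_end_times, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x channels x windows")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels do not match trial count")
        if self.values.shape[2] != self.window_end_times.shape[0]:
            raise ValueError("window_end_times do not match window count")
        if self.modality not in ("spike", "lfp"):
            raise ValueError("modality must be 'spike' or 'lfp'")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.values.shape[1])

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    def window_data(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Features and labels for window ``j``, dropping trials for
        which the window fell outside the recorded interval."""
        X = self.values[:, :, j]
        valid = ~np.isnan(X).any(axis=1)
        return X[valid], self.labels[valid]

    def subset_channels(self, indices: np.ndarray) -> "FeatureTensor":
        indices = np.asarray(indices, dtype=int)
        return FeatureTensor(
            values=self.values[:, indices, :],
            labels=self.labels,
            window_end_times=self.window_end_times,
            alignment=self.alignment,
            modality=self.modality,
            window_length=self.window_length,
            channel_ids=self.channel_ids[indices],
        )


@dataclass
class FunctionalChannelSet:
    """Channels passing the evoked-activity screen."""

    kept: np.ndarray
    peak_above_baseline: np.ndarray  # per original channel, spikes/s

    @property
    def U(self) -> int:
        return len(self.kept)


def smooth_firing_rate(
    spike_times: np.ndarray,
    grid: np.ndarray,
    kernel_sd: float = 10.0,
) -> np.ndarray:
    """Continuous firing-rate estimate (spikes/s) on ``grid`` (ms) by
    convolving the spike train with a normalized Gaussian kernel.

    The kernel has standard deviation ``kernel_sd`` ms and unit
    integral, so the trace integrates to the spike count (up to edge
    effects).  Visualization / channel screening only; classification
    features are raw counts.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if spike_times.size == 0:
        return np.zeros_like(grid)
    d = grid[:, None] - spike_times[None, :]
    bumps = np.exp(-0.5 * np.square(d / kernel_sd)) / (kernel_sd * np.sqrt(2.0 * np.pi))
    return bumps.sum(axis=1) * 1000.0  # per-ms density -> spikes/s


def _mean_count_rate(session: SessionData, ch: int, window: tuple[float, float]) -> float:
    """Trial-averaged raw firing rate (spikes/s) in a target-aligned window."""
    lo, hi = window
    rates = []
    for spikes_t in session.spikes:
        st = spikes_t[ch]
        n = np.searchsorted(st, hi, side="right") - np.searchsorted(st, lo, side="right")
        rates.append(n / (hi - lo) * 1000.0)
    return float(np.mean(rates))


def _peak_psth(
    session: SessionData,
    ch: int,
    trials: np.ndarray,
    window: tuple[float, float],
    align_saccade: bool,
) -> float:
    """Peak of the trial-averaged 10-ms-smoothed rate in a window."""
    grid = np.arange(window[0], window[1] + 1.0, 5.0)
    acc = np.zeros_like(grid)
    sacc = session.events["saccade_onset_ms"].to_numpy()
    for t in trials:
        offset = sacc[t] if align_saccade else 0.0
        acc += smooth_firing_rate(session.spikes[t][ch] - offset, grid)
    return float(np.max(acc / len(trials)))


def select_functional_channels(
    session: SessionData,
    threshold: float = 20.0,
) -> FunctionalChannelSet:
    """Keep channels whose peak evoked rate exceeds baseline by more than
    ``threshold`` spikes/s in either the visual or the motor epoch.

    The peak is the maximum over targets of the trial-averaged smoothed
    rate (10-ms Gaussian kernel) within the visual window (0-250 ms
    post-target) or the motor window (+-100 ms around saccade onset);
    baseline is the mean rate 400-200 ms before target onset.
    """
    labels = session.labels
    targets = np.unique(labels)
    if len(session.events) < len(targets):
        raise ValueError("need at least one trial per target")
    peaks = np.zeros(session.n_channels)
    for ch in range(session.n_channels):
        baseline = _mean_count_rate(session, ch, _BASELINE_WINDOW)
        best = -np.inf
        for tgt in targets:
            trials = np.flatnonzero(labels == tgt)
            vis = _peak_psth(session, ch, trials, _VISUAL_SCREEN_WINDOW, align_saccade=False)
            mot = _peak_psth(session, ch, trials, _MOTOR_SCREEN_WINDOW, align_saccade=True)
            best = max(best, vis, mot)
        peaks[ch] = best - baseline
    kept = np.flatnonzero(peaks > threshold)
    if kept.size == 0:
        raise ValueError("no functional channels: no channel exceeds the evoked-rate threshold")
    return FunctionalChannelSet(kept=kept, peak_above_baseline=peaks)


def extract_windows(
    session: SessionData,
    channels: FunctionalChannelSet | np.ndarray | None,
    spec: WindowSpec,
    modality: str,
) -> FeatureTensor:
    """Build the trials x channels x windows feature tensor.

    Spike features sum spikes in ``(end - length, end]``; LFP features
    average the raw samples whose timestamps fall in the same interval.
    Windows not fully contained in a trial's recorded interval are NaN
    for that trial.
    """
    if modality not in ("spike", "lfp"):
        raise ValueError("modality must be 'spike' or 'lfp'")
    if channels is None:
        ch_idx = np.arange(session.n_channels)
    elif isinstance(channels, FunctionalChannelSet):
        ch_idx = channels.kept
    else:
        ch_idx = np.asarray(channels, dtype=int)

    ends = spec.window_end_times
    n_trials, n_ch, n_win = session.n_trials, len(ch_idx), len(ends)
    values = np.full((n_trials, n_ch, n_win), np.nan)

    events = session.events
    sacc = events["saccade_onset_ms"].to_numpy()
    t0 = events["trial_start_ms"].to_numpy()
    t1 = events["trial_end_ms"].to_numpy()

    for t in range(n_trials):
        offset = sacc[t] if spec.alignment == SACCADE_ALIGNED else 0.0
        abs_ends = ends + offset
        abs_starts = abs_ends - spec.length
        ok = (abs_starts >= t0[t]) & (abs_ends <= t1[t])
        if not ok.any():
            continue
        if modality == "spike":
            for c, ch in enumerate(ch_idx):
                st = session.spikes[t][ch]
                hi = np.searchsorted(st, abs_ends[ok], side="right")
                lo = np.searchsorted(st, abs_starts[ok], side="right")
                values[t, c, ok] = hi - lo
        else:
            times = session.lfp_sample_times(t)
            hi = np.searchsorted(times, abs_ends[ok], side="right")
            lo = np.searchsorted(times, abs_starts[ok], side="right")
            n_samp = hi - lo
            if np.any(n_samp <= 0):
                good = n_samp > 0
                idx = np.flatnonzero(ok)[~good]
                ok = ok.copy()
                ok[idx] = False
                hi, lo, n_samp = hi[good], lo[good], n_samp[good]
            csum = np.concatenate(
                [np.zeros((len(ch_idx), 1)), np.cumsum(session.lfp[t][ch_idx], axis=1)], axis=1
            )
            values[t, :, ok] = ((csum[:, hi] - csum[:, lo]) / n_samp).T

    return FeatureTensor(
        values=values,
        labels=session.labels,
        window_end_times=ends,
        alignment=spec.alignment,
        modality=modality,
        window_length=spec.length,
        channel_ids=np.asarray(ch_idx),
    )


def lfp_condition_for_plots(
    trace: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.5, 250.0),
    notch: float = 60.0,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase band-pass (0.5-250 Hz) + 60-Hz notch conditioning.

    For visualization only; classification features always use the raw
    per-window means.
    """
    nyq = sampling_rate / 2.0
    if sampling_rate <= 500.0:
        raise ValueError("sampling rate must exceed 500 Hz")
    if not 0.0 < band[0] < band[1] < nyq:
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    trace = np.asarray(trace, dtype=float)
    # generous padding: the 0.5-Hz high-pass edge transient decays slowly
    padlen = min(trace.shape[-1] - 1, int(2 * sampling_rate))
    sos = signal.butter(4, band, btype="bandpass", fs=sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, trace, axis=-1, padlen=padlen)
    if notch is not None:
        b, a = signal.iirnotch(notch, notch_q, fs=sampling_rate)
        out = signal.filtfilt(b, a, out, axis=-1, padlen=padlen)
    return out
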