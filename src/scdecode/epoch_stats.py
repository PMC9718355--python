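"""Epoch extraction, tuning-curve breadth statistics, and paired tests.

Five task epochs summarize each target's baseline-subtracted decoding
time course in a single value: baseline (mean, 400-200 ms before target
onset), visual (max, 100-200 ms after target onset), early delay (mean,
250-450 ms after target onset), late delay (mean, 300-100 ms before
saccade onset) and motor (max near saccade onset, default +-50 ms).
Mean-rule epochs average windows whose END time falls in the range;
max-rule epochs take the maximum there (the causal plotting convention).

Per-epoch values across the eight targets, rotated so the preferred
target occupies position 1, form a tuning curve whose trapezoidal area
(AUC) measures the total amount of spatial information and whose
shift-normalized AUC — computed after adding a constant that sets the
preferred-target value to 1 — measures breadth of tuning independently
of uniform performance offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from scdecode.features import SACCADE_ALIGNED, TARGET_ALIGNED
from scdecode.timecourse import PerformanceTimeSeries

__all__ = [
    "EpochDefinition",
    "DEFAULT_EPOCHS",
    "EpochTuning",
    "PairedComparison",
    "epoch_values",
    "tuning_curve",
    "auc_trapezoid",
    "normalized_auc",
    "paired_ttest",
    "visuomotor_index",
]


@dataclass(frozen=True)
class EpochDefinition:
    name: str
    alignment: str
    rule: str  # "mean" or "max"
    time_range: tuple[float, float]  # ms relative to alignment event

    def __post_init__(self) -> None:
        if self.rule not in ("mean", "max"):
            raise ValueError("rule must be 'mean' or 'max'")
        if self.alignment not in (TARGET_ALIGNED, SACCADE_ALIGNED):
            raise ValueError(f"unknown alignment {self.alignment!r}")


DEFAULT_EPOCHS: tuple[EpochDefinition, ...] = (
    EpochDefinition("baseline", TARGET_ALIGNED, "mean", (-400.0, -200.0)),
    EpochDefinition("visual", TARGET_ALIGNED, "max", (100.0, 200.0)),
    EpochDefinition("early_delay", TARGET_ALIGNED, "mean", (250.0, 450.0)),
    EpochDefinition("late_delay", SACCADE_ALIGNED, "mean", (-300.0, -100.0)),
    EpochDefinition("motor", SACCADE_ALIGNED, "max", (-50.0, 50.0)),
)


def _epoch_value(series: PerformanceTimeSeries, epoch: EpochDefinition) -> np.ndarray:
    ends = series.window_end_times
    mask = (ends >= epoch.time_range[0]) & (ends <= epoch.time_range[1])
    mask &= ~np.isnan(series.f1).all(axis=0)
    if not mask.any():
        raise ValueError(f"no windows end inside the {epoch.name} epoch range")
    vals = series.f1[:, mask]
    return np.nanmax(vals, axis=1) if epoch.rule == "max" else np.nanmean(vals, axis=1)


def epoch_values(
    target_aligned: PerformanceTimeSeries,
    saccade_aligned: PerformanceTimeSeries | None = None,
    epochs: tuple[EpochDefinition, ...] = DEFAULT_EPOCHS,
) -> dict[str, np.ndarray]:
    """Per-epoch, per-target scalar performance (8 values per epoch).

    Both series should already be baseline-subtracted; saccade-aligned
    epochs (late delay, motor) require the saccade-aligned series.
    """
    out = {}
    for epoch in epochs:
        if epoch.alignment == TARGET_ALIGNED:
            series = target_aligned
        else:
            if saccade_aligned is None:
                raise ValueError(f"epoch {epoch.name} needs the saccade-aligned series")
            series = saccade_aligned
        if series.alignment != epoch.alignment:
            raise ValueError(f"series alignment does not match epoch {epoch.name}")
        out[epoch.name] = _epoch_value(series, epoch)
    return out


def tuning_curve(values: np.ndarray, preferred_target: int) -> np.ndarray:
    """Rotate the 8 per-target values so the preferred target occupies
    position 1; angular order is preserved."""
    values = np.asarray(values, dtype=float)
    if values.shape != (8,):
        raise ValueError("tuning curve needs exactly 8 per-target values")
    if not 1 <= preferred_target <= 8:
        raise ValueError("preferred_target must be in 1..8")
    return np.roll(values, -(preferred_target - 1))


def auc_trapezoid(curve: np.ndarray) -> float:
    """Trapezoidal area under the 8-point tuning curve over the open
    (non-wrapped) target axis 1..8 with unit spacing."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (8,) or not np.all(np.isfinite(curve)):
        raise ValueError("curve must be 8 finite values")
    return float(np.trapezoid(curve, dx=1.0))


def normalized_auc(curve: np.ndarray, preferred_position: int = 1) -> float:
    """Breadth-of-tuning AUC: shift the curve so the preferred-target
    value is exactly 1, then take the trapezoidal area.  Invariant to
    any uniform additive offset of the input."""
    curve = np.asarray(curve, dtype=float)
    # (curve - curve[pref]) + 1 pins the preferred value to exactly 1.0
    shifted = (curve - curve[preferred_position - 1]) + 1.0
    return auc_trapezoid(shifted)


@dataclass
class EpochTuning:
    """Per-epoch tuning curve with its area statistics."""

    epoch: str
    modality: str
    curve: np.ndarray  # 8 values, preferred target at position 1
    auc: float
    norm_auc: float

    @classmethod
    def from_values(
        cls, epoch: str, modality: str, values: np.ndarray, preferred_target: int
    ) -> "EpochTuning":
        curve = tuning_curve(values, preferred_target)
        return cls(
            epoch=epoch,
            modality=modality,
            curve=curve,
            auc=auc_trapezoid(curve),
            norm_auc=normalized_auc(curve),
        )


@dataclass
class PairedComparison:
    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    t: float
    p: float
    stars: str  # "ns", "*", "**", "***"


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def paired_ttest(
    values_a: np.ndarray,
    values_b: np.ndarray,
    label_a: str = "a",
    label_b: str = "b",
) -> PairedComparison:
    """Paired two-tailed t test on per-session values.

    Degenerate zero-variance differences are handled explicitly: p = 0
    for a nonzero constant difference, p = 1 for identical samples.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    diff = a - b
    if np.allclose(np.std(diff, ddof=1), 0.0):
        t = np.inf * np.sign(diff.mean()) if diff.mean() != 0 else 0.0
        p = 0.0 if diff.mean() != 0 else 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    return PairedComparison(
        label_a=label_a,
        label_b=label_b,
        values_a=a,
        values_b=b,
        t=float(t),
        p=float(p),
        stars=_stars(float(p)),
    )


def visuomotor_index(
    visual_rates: np.ndarray,
    motor_rates: np.ndarray,
    n_groups: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Visuomotor index (V - M)/(V + M) per channel and a tercile split.

    V and M are baseline-subtracted mean rates in the visual and motor
    epochs, clipped at 0; positive index = more visual.  Channels with
    V + M = 0 get index NaN and group -1 (excluded).  The remaining
    channels are split into ``n_groups`` near-equal groups by ascending
    index (group 0 = most motor, last group = most visual).
    """
    V = np.clip(np.asarray(visual_rates, dtype=float), 0.0, None)
    M = np.clip(np.asarray(motor_rates, dtype=float), 0.0, None)
    if V.shape != M.shape:
        raise ValueError("visual and motor rate arrays must match")
    denom = V + M
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(denom > 0, (V - M) / denom, np.nan)
    groups = np.full(index.shape, -1, dtype=int)
    valid = np.flatnonzero(denom > 0)
    if valid.size:
        order = valid[np.argsort(index[valid], kind="stable")]
        for g, chunk in enumerate(np.array_split(order, n_groups)):
            groups[chunk] = g
    return index, groups
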