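"""Burst/suppression segmentation, BSR per concentration step, and onset
detection.

A sample is sub-threshold iff |value| < amplitude_threshold (raw referenced
signal, no envelope smoothing). Maximal sub-threshold runs lasting *strictly*
longer than ``min_duration_s`` are suppression; runs separated by
supra-threshold gaps no longer than ``merge_gap_s`` are merged before the
duration test. The burst-suppression ratio (BSR) is the percentage of time
spent in suppression. All comparisons are unit-checked against the
recording's declared unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import UnitMismatchError, ValidationError
from .recording import ConcentrationProtocol, EEGRecording, slice_by_step


@dataclass(frozen=True)
class SuppressionCriteria:
    """Amplitude/duration rule identifying suppression epochs.

    Defaults follow the established rodent criterion: amplitude < 5 mV
    sustained for longer than 0.5 s. ``merge_gap_s`` (default 0: no merging)
    closes brief supra-threshold glitches before the duration test.
    """

    amplitude_threshold: float = 5.0
    unit: str = "mV"
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_threshold <= 0:
            raise ValidationError("amplitude_threshold must be positive")
        if self.min_duration_s <= 0:
            raise ValidationError("min_duration_s must be positive")
        if self.merge_gap_s < 0:
            raise ValidationError("merge_gap_s must be non-negative")


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str  # "burst" | "suppression"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SuppressionSegmentation:
    """Alternating burst/suppression partition of a recording window."""

    intervals: list[Interval]
    total_s: float

    @property
    def suppression_time_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals if iv.label == "suppression")

    @property
    def bsr_percent(self) -> float:
        if self.total_s == 0:
            return 0.0
        return 100.0 * self.suppression_time_s / self.total_s

    @property
    def n_suppression_events(self) -> int:
        return sum(1 for iv in self.intervals if iv.label == "suppression")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def detect_suppression(
    rec: EEGRecording,
    channel: str = "F1",
    criteria: SuppressionCriteria | None = None,
) -> SuppressionSegmentation:
    """Segment one channel into bursts and suppressions.

    The duration comparison is strict: a sub-threshold run of exactly
    ``min_duration_s`` is *not* suppression.
    """
    criteria = criteria or SuppressionCriteria()
    if rec.n_samples == 0:
        raise ValidationError("empty recording")
    if rec.unit != criteria.unit:
        raise UnitMismatchError(
            f"criteria are in {criteria.unit!r} but recording is in "
            f"{rec.unit!r}; convert explicitly before thresholding"
        )
    x = rec.channel(channel)
    sub = np.abs(x) < criteria.amplitude_threshold
    runs = _runs(sub)

    # merge sub-threshold runs separated by short supra-threshold gaps
    gap_max = int(math.floor(criteria.merge_gap_s * rec.fs + 1e-9))
    if gap_max > 0 and runs:
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= gap_max:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged

    min_samples = criteria.min_duration_s * rec.fs  # strict: need count/fs > min
    supp_runs = [(s, e) for s, e in runs if (e - s) > min_samples + 1e-9]

    intervals: list[Interval] = []
    cursor = 0
    for s, e in supp_runs:
        if s > cursor:
            intervals.append(Interval(cursor / rec.fs, s / rec.fs, "burst"))
        intervals.append(Interval(s / rec.fs, e / rec.fs, "suppression"))
        cursor = e
    if cursor < rec.n_samples:
        intervals.append(Interval(cursor / rec.fs, rec.n_samples / rec.fs, "burst"))
    return SuppressionSegmentation(intervals=intervals, total_s=rec.n_samples / rec.fs)


@dataclass(frozen=True)
class StepBSR:
    concentration: float
    bsr_percent: float
    suppression_time_s: float


def bsr_by_step(
    rec: EEGRecording,
    channel: str,
    protocol: ConcentrationProtocol,
    criteria: SuppressionCriteria | None = None,
) -> list[StepBSR]:
    """Detect suppression independently within each concentration step."""
    out = []
    for conc, sub in slice_by_step(rec, protocol):
        seg = detect_suppression(sub, channel=channel, criteria=criteria)
        out.append(StepBSR(conc, seg.bsr_percent, seg.suppression_time_s))
    return out


def onset_concentration(
    per_step: Sequence[StepBSR | tuple[float, float]],
    epsilon_percent: float = 0.0,
) -> Optional[float]:
    """Lowest concentration whose BSR exceeds ``epsilon_percent``.

    Returns None if suppression never appears. Input must be ordered by
    concentration.
    """
    if not per_step:
        raise ValidationError("empty per-step BSR list")
    rows = [
        (r.concentration, r.bsr_percent) if isinstance(r, StepBSR) else (r[0], r[1])
        for r in per_step
    ]
    concs = [c for c, _ in rows]
    if concs != sorted(concs):
        raise ValidationError("per-step BSR must be ordered by concentration")
    for conc, bsr in rows:
        if bsr > epsilon_percent:
            return conc
    return None
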