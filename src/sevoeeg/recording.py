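"""Core in-memory containers: EEG recordings, concentration protocols and
behavioral staircase logs.

Time windows are half-open ``[start, end)`` in seconds and are converted to
sample indices by flooring ``t * fs``, so adjacent windows never share a
sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError


def _time_to_index(t_s: float, fs: float) -> int:
    # floor with a tiny tolerance so e.g. 300.0 * 500 never lands on 149999
    return int(math.floor(t_s * fs + 1e-9))


@dataclass
class EEGRecording:
    """Multi-channel EEG with explicit sampling rate and physical unit.

    ``samples`` is a (n_channels, n_samples) float array in ``unit``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    unit: str = "mV"
    subject_id: str = ""
    strain_tag: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a (channels, time) array")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"channel {label!r} not present (have {self.channel_labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def time_slice(self, start_s: float, end_s: float) -> "EEGRecording":
        """Half-open slice ``[start_s, end_s)`` as a new recording."""
        i0 = _time_to_index(start_s, self.fs)
        i1 = _time_to_index(end_s, self.fs)
        if i0 < 0 or i1 > self.n_samples:
            raise ValidationError(
                f"slice [{start_s}, {end_s}) s exceeds recording of "
                f"{self.duration_s:.3f} s"
            )
        return EEGRecording(
            samples=self.samples[:, i0:i1].copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            unit=self.unit,
            subject_id=self.subject_id,
            strain_tag=self.strain_tag,
        )


@dataclass(frozen=True)
class ProtocolStep:
    concentration: float  # vol%
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class ConcentrationProtocol:
    """Ordered, non-overlapping anesthetic concentration steps."""

    steps: Sequence[ProtocolStep]

    def __post_init__(self) -> None:
        self.steps = [
            s if isinstance(s, ProtocolStep) else ProtocolStep(*s) for s in self.steps
        ]
        if not self.steps:
            raise ValidationError("protocol needs at least one step")
        for s in self.steps:
            if s.duration_s <= 0:
                raise ValidationError("step durations must be positive")
        for a, b in zip(self.steps, self.steps[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValidationError("protocol steps overlap or are unordered")

    @property
    def concentrations(self) -> list[float]:
        return [s.concentration for s in self.steps]

    @property
    def end_s(self) -> float:
        return self.steps[-1].end_s

    @classmethod
    def stepped(
        cls,
        start_conc: float = 2.0,
        stop_conc: float = 2.8,
        increment: float = 0.2,
        step_duration_s: float = 300.0,
        t0_s: float = 0.0,
    ) -> "ConcentrationProtocol":
        """The stepped-exposure EEG protocol: 2.0→2.8 vol% in 0.2% increments,
        5 min per step, by default."""
        n = int(round((stop_conc - start_conc) / increment)) + 1
        steps = [
            ProtocolStep(
                concentration=round(start_conc + k * increment, 10),
                start_s=t0_s + k * step_duration_s,
                duration_s=step_duration_s,
            )
            for k in range(n)
        ]
        return cls(steps=steps)


def slice_by_step(
    rec: EEGRecording, protocol: ConcentrationProtocol
) -> list[tuple[float, EEGRecording]]:
    """Cut a recording into one sub-recording per concentration step.

    Windows are half-open and sample-aligned; a step that extends past the
    end of the recording (by even one sample) is an error.
    """
    out = []
    for step in protocol.steps:
        i1 = _time_to_index(step.end_s, rec.fs)
        if i1 > rec.n_samples:
            raise ValidationError(
                f"protocol step at {step.concentration} vol% ends at "
                f"{step.end_s} s, past the recording end "
                f"({rec.duration_s:.3f} s)"
            )
        out.append((step.concentration, rec.time_slice(step.start_s, step.end_s)))
    return out


Direction = Literal["ascending", "descending"]


@dataclass(frozen=True)
class StaircaseTrial:
    concentration: float  # vol%
    response: bool


@dataclass
class StaircaseLog:
    """A behavioral staircase run: one binary response per concentration.

    Ascending logs (tail-clamp immobility endpoint) increase by ``step_size``
    per trial; descending logs (righting-reflex endpoint) decrease.
    """

    trials: Sequence[StaircaseTrial]
    direction: Direction
    step_size: float = 0.1
    dwell_s: float = 600.0
    truncated: bool = False

    def __post_init__(self) -> None:
        self.trials = [
            t if isinstance(t, StaircaseTrial) else StaircaseTrial(*t)
            for t in self.trials
        ]
        if self.step_size <= 0:
            raise ValidationError("step_size must be positive")
        sign = 1.0 if self.direction == "ascending" else -1.0
        for a, b in zip(self.trials, self.trials[1:]):
            if not math.isclose(
                b.concentration - a.concentration, sign * self.step_size, abs_tol=1e-9
            ):
                raise ValidationError(
                    f"{self.direction} log must change by {self.step_size} per trial"
                )
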