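"""The six-site mouse epidural screw montage and its stereotaxic geometry.

Recording sites are named by cortical region (F = frontal, C = central,
P = parietal; 1 = left, 2 = right) with coordinates in mm relative to bregma:
positive AP is anterior, positive ML is the animal's right. Reference and
ground screws sit over the cerebellum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .errors import ValidationError

Role = Literal["signal", "reference", "ground"]


@dataclass(frozen=True)
class Site:
    """One electrode site: label, stereotaxic position, and role."""

    label: str
    ap_mm: float
    ml_mm: float
    role: Role = "signal"


@dataclass(frozen=True)
class Montage:
    """An ordered collection of electrode sites.

    Invariants: labels are unique and at least one reference site is present.
    """

    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValidationError("montage labels must be unique")
        if not any(s.role == "reference" for s in self.sites):
            raise ValidationError("montage needs at least one reference site")
        if not any(s.role == "signal" for s in self.sites):
            raise ValidationError("montage needs at least one signal site")

    @property
    def signal_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sites if s.role == "signal")

    def site(self, label: str) -> Site:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def position(self, label: str) -> tuple[float, float]:
        s = self.site(label)
        return (s.ap_mm, s.ml_mm)

    def validate_labels(self, labels: Iterable[str]) -> None:
        """Raise naming the first label that is not a signal site."""
        allowed = set(self.signal_labels)
        for lab in labels:
            if lab not in allowed:
                raise ValidationError(
                    f"channel label {lab!r} is not a signal site of the montage "
                    f"(expected one of {sorted(allowed)})"
                )


def default_mouse_montage() -> Montage:
    """Standard 6-channel mouse montage with cerebellar reference/ground.

    Frontal pair over prefrontal cortex (+1.8 AP, ±1.0 ML), central pair over
    anterior parietal cortex (−1.4 AP, ±1.0 ML), parietal pair over posterior
    parietal cortex (−2.8 AP, ±1.0 ML). Odd indices are left hemisphere.
    """
    return Montage(
        sites=(
            Site("F1", +1.8, -1.0),
            Site("F2", +1.8, +1.0),
            Site("C1", -1.4, -1.0),
            Site("C2", -1.4, +1.0),
            Site("P1", -2.8, -1.0),
            Site("P2", -2.8, +1.0),
            Site("REF", -6.0, -1.0, "reference"),
            Site("GND", -6.0, +1.0, "ground"),
        )
    )


#: Channel label -> anatomical group used by topographic contrasts.
FRONTAL_LABELS = ("F1", "F2")
CENTRAL_LABELS = ("C1", "C2")
PARIETAL_LABELS = ("P1", "P2")
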