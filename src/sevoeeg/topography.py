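"""Theta-band topographic mapping and the anteriorization index.

Per concentration step and channel, the band-integrated spectral density is
summarized by its median over windows; group maps average those medians
across animals and interpolate them over the stereotaxic (AP x ML) plane by
inverse-distance weighting. The anteriorization index — mean frontal power
over mean parietal power — is this package's own scalar summary of the
frontal shift of theta activity with deepening anesthesia (central channels
are deliberately excluded to keep it a frontal/parietal contrast).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .montage import FRONTAL_LABELS, PARIETAL_LABELS, Montage, default_mouse_montage
from .recording import ConcentrationProtocol, EEGRecording, slice_by_step
from .spectral import SpectralConfig, band_power, multitaper_spectrogram

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz; defaults to theta (4-8 Hz)."""

    low_hz: float = 4.0
    high_hz: float = 8.0

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValidationError("need 0 <= low_hz < high_hz")


@dataclass
class TopoMap:
    """Per-site band power plus an interpolated field over the montage plane."""

    site_power: dict[str, float]
    grid: np.ndarray  # (n_ap, n_ml), NaN outside the electrode neighborhood
    grid_ap_mm: np.ndarray
    grid_ml_mm: np.ndarray
    step_concentration: float
    n_animals: int = 1
    bsr_flag: bool = False  # True if this step exceeded the BSR cutoff


StepSiteMap = Mapping[float, Mapping[str, float]]


def theta_site_power(
    rec: EEGRecording,
    protocol: ConcentrationProtocol,
    band: BandSpec | None = None,
    cfg: SpectralConfig | None = None,
    montage: Optional[Montage] = None,
    channels: Optional[Sequence[str]] = None,
) -> dict[float, dict[str, float]]:
    """Median-over-windows band power per step and channel.

    ``channels`` defaults to every montage signal channel present in the
    recording; the band must lie below Nyquist.
    """
    band = band or BandSpec()
    cfg = cfg or SpectralConfig()
    montage = montage or default_mouse_montage()
    if band.high_hz > rec.fs / 2:
        raise ValidationError(
            f"band upper edge {band.high_hz} Hz exceeds Nyquist {rec.fs / 2} Hz"
        )
    labels = list(channels) if channels is not None else [
        l for l in montage.signal_labels if l in rec.channel_labels
    ]
    if not labels:
        raise ValidationError("no montage signal channels present in recording")
    out: dict[float, dict[str, float]] = {}
    for conc, sub in slice_by_step(rec, protocol):
        out[conc] = {}
        for lab in labels:
            spec = multitaper_spectrogram(sub, lab, cfg)
            bp = band_power(spec, band.low_hz, band.high_hz)
            out[conc][lab] = float(np.median(bp))
    return out


def _idw_grid(
    site_power: Mapping[str, float],
    montage: Montage,
    resolution_mm: float = 0.1,
    margin_mm: float = 1.0,
    mask_radius_mm: float = 1.5,
    power: float = 2.0,
):
    labels = list(site_power)
    ap = np.array([montage.position(l)[0] for l in labels])
    ml = np.array([montage.position(l)[1] for l in labels])
    vals = np.array([site_power[l] for l in labels])

    gap = np.arange(ap.min() - margin_mm, ap.max() + margin_mm + 1e-9, resolution_mm)
    gml = np.arange(ml.min() - margin_mm, ml.max() + margin_mm + 1e-9, resolution_mm)
    AP, ML = np.meshgrid(gap, gml, indexing="ij")
    d2 = (AP[..., None] - ap) ** 2 + (ML[..., None] - ml) ** 2
    d = np.sqrt(d2)

    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(d, 1e-300) ** power
    grid = (w * vals).sum(axis=-1) / w.sum(axis=-1)
    # exact at (numerically) coincident nodes
    hit = d.min(axis=-1) < 1e-9
    nearest = d.argmin(axis=-1)
    grid[hit] = vals[nearest[hit]]
    grid[d.min(axis=-1) > mask_radius_mm] = np.nan
    return grid, gap, gml


def group_topomap(
    per_animal: Sequence[StepSiteMap],
    montage: Optional[Montage] = None,
    missing_site_policy: str = "exclude_animal",
    bsr_flags: Optional[Mapping[float, bool]] = None,
) -> dict[float, TopoMap]:
    """Average per-animal median band powers into one map per step.

    An animal missing a site at a step is handled per
    ``missing_site_policy``: ``exclude_animal`` (default, logged) drops the
    animal from that step; ``exclude_site`` drops the site for everyone.
    """
    if not per_animal:
        raise ValidationError("no animals to aggregate")
    if missing_site_policy not in ("exclude_animal", "exclude_site"):
        raise ValidationError(f"unknown policy {missing_site_policy!r}")
    montage = montage or default_mouse_montage()

    steps = sorted({c for m in per_animal for c in m})
    out: dict[float, TopoMap] = {}
    for conc in steps:
        maps = [dict(m[conc]) for m in per_animal if conc in m]
        all_sites = sorted({s for m in maps for s in m})
        full = [m for m in maps if set(m) >= set(all_sites)]
        if missing_site_policy == "exclude_animal":
            if len(full) < len(maps):
                log.warning(
                    "step %.2f vol%%: excluded %d animal(s) missing sites",
                    conc,
                    len(maps) - len(full),
                )
            maps = full
            sites = all_sites
        else:
            sites = sorted(set.intersection(*(set(m) for m in maps)))
        if not maps or not sites:
            raise ValidationError(f"no complete animal/site data at {conc} vol%")
        site_power = {
            s: float(np.mean([m[s] for m in maps])) for s in sites
        }
        grid, gap, gml = _idw_grid(site_power, montage)
        out[conc] = TopoMap(
            site_power=site_power,
            grid=grid,
            grid_ap_mm=gap,
            grid_ml_mm=gml,
            step_concentration=conc,
            n_animals=len(maps),
            bsr_flag=bool(bsr_flags.get(conc, False)) if bsr_flags else False,
        )
    return out


def anteriorization_index(topo: TopoMap | Mapping[str, float]) -> float:
    """Mean frontal (F1,F2) over mean parietal (P1,P2) band power.

    Values > 1 indicate frontal dominance. Scale-invariant. Zero parietal
    power returns +inf with a warning.
    """
    site_power = topo.site_power if isinstance(topo, TopoMap) else topo
    try:
        front = float(np.mean([site_power[l] for l in FRONTAL_LABELS]))
        back = float(np.mean([site_power[l] for l in PARIETAL_LABELS]))
    except KeyError as e:
        raise ValidationError(f"map lacks site {e.args[0]!r}") from None
    if back == 0.0:
        warnings.warn("zero parietal power; anteriorization index is infinite")
        return math.inf
    return front / back
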