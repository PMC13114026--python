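"""Multitaper spectral estimation and density spectral arrays (DSA).

Power spectra are computed in consecutive windows (default 2 s, no overlap)
using DPSS (Slepian) tapers with time-bandwidth product NW = 3 and K = 5
tapers, giving a design half-bandwidth W = NW / window_s = 1.5 Hz at the
defaults. Densities are one-sided (unit^2/Hz): eigenspectra are scaled by
1/fs and doubled at all bins except DC and Nyquist. Group spectrograms are
aggregated by the elementwise median across animals, which is robust to
single-animal artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal.windows import dpss as _scipy_dpss

from .errors import ValidationError
from .recording import EEGRecording


@dataclass(frozen=True)
class SpectralConfig:
    """Multitaper windowing parameters.

    ``k <= 2*nw - 1`` is enforced: tapers beyond that have poor spectral
    concentration and are refused unless ``allow_leaky`` is set.
    """

    window_s: float = 2.0
    overlap_s: float = 0.0
    nw: float = 3.0
    k: int = 5
    detrend: bool = True  # per-window mean removal
    eigenvalue_weighting: bool = False
    allow_leaky: bool = False

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")
        if not (0 <= self.overlap_s < self.window_s):
            raise ValidationError("overlap_s must lie in [0, window_s)")
        if self.k < 1:
            raise ValidationError("need at least one taper")
        if self.k > 2 * self.nw - 1 and not self.allow_leaky:
            raise ValidationError(
                f"k={self.k} exceeds 2*nw-1={2 * self.nw - 1:g}; such tapers are "
                "leakage-dominated (set allow_leaky=True to override)"
            )

    @property
    def half_bandwidth_hz(self) -> float:
        return self.nw / self.window_s


@dataclass
class Spectrogram:
    """windows x frequencies power density with its window/taper metadata."""

    power: np.ndarray  # (n_windows, n_freqs), unit^2/Hz
    window_times_s: np.ndarray  # window centers
    freqs_hz: np.ndarray
    config: SpectralConfig
    channel: str = ""

    @property
    def n_windows(self) -> int:
        return self.power.shape[0]

    def to_db(self) -> np.ndarray:
        """dB rendering for DSA display; raw density stays in ``power``."""
        floor = np.finfo(float).tiny
        return 10.0 * np.log10(np.maximum(self.power, floor))


def compute_dpss(n: int, nw: float, k: int, allow_leaky: bool = False):
    """DPSS tapers (k x n, orthonormal rows) and their concentrations.

    Eigenvalues are the spectral concentrations in the design band; they are
    strictly decreasing in (0, 1). ``k > 2*nw - 1`` is refused by default.
    """
    if k < 1:
        raise ValidationError("need at least one taper")
    if k > 2 * nw - 1 and not allow_leaky:
        raise ValidationError(
            f"k={k} exceeds 2*nw-1={2 * nw - 1:g}; leakage-dominated tapers "
            "refused (allow_leaky=True to override)"
        )
    if n <= 2 * nw:
        raise ValidationError(f"need n > 2*nw samples (got n={n}, nw={nw})")
    tapers, ratios = _scipy_dpss(n, nw, Kmax=k, return_ratios=True, norm=2)
    return np.atleast_2d(tapers), np.atleast_1d(ratios)


def _window_layout(n_samples: int, fs: float, cfg: SpectralConfig):
    nper = int(math.floor(cfg.window_s * fs + 1e-9))
    nper -= nper % 2  # even window length: Nyquist bin well defined
    if nper < 2:
        raise ValidationError("window shorter than two samples")
    nover = int(math.floor(cfg.overlap_s * fs + 1e-9))
    step = nper - nover
    if step < 1:
        raise ValidationError("overlap leaves no window advance")
    if n_samples < nper:
        raise ValidationError(
            f"recording of {n_samples} samples shorter than one "
            f"{nper}-sample window"
        )
    n_windows = (n_samples - nper) // step + 1
    return nper, step, n_windows


def multitaper_spectrogram(
    rec: EEGRecording, channel: str, cfg: SpectralConfig | None = None
) -> Spectrogram:
    """Multitaper spectrogram of one channel.

    Per window: (optionally) remove the mean, taper with each DPSS, FFT, and
    average the K eigenspectra (uniformly by default; eigenvalue-weighted if
    configured). Frequency resolution is fs/nper (no zero padding).
    """
    cfg = cfg or SpectralConfig()
    x = rec.channel(channel)
    nper, step, n_windows = _window_layout(rec.n_samples, rec.fs, cfg)
    tapers, ratios = compute_dpss(nper, cfg.nw, cfg.k, allow_leaky=cfg.allow_leaky)

    idx = np.arange(n_windows)[:, None] * step + np.arange(nper)[None, :]
    segs = x[idx]  # (n_windows, nper)
    if cfg.detrend:
        segs = segs - segs.mean(axis=1, keepdims=True)

    # (n_windows, k, nper) -> rfft over last axis
    tapered = segs[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    eig = (spec.real**2 + spec.imag**2) / rec.fs  # two-sided density
    if cfg.eigenvalue_weighting:
        w = ratios / ratios.sum()
        power = np.einsum("wkf,k->wf", eig, w)
    else:
        power = eig.mean(axis=1)
    # one-sided: double everything except DC and Nyquist
    power[:, 1:-1] *= 2.0
    if nper % 2 == 1:  # odd window: no exact Nyquist bin, double last too
        power[:, -1] *= 2.0

    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.fs)
    centers = (np.arange(n_windows) * step + nper / 2.0) / rec.fs
    return Spectrogram(
        power=power,
        window_times_s=centers,
        freqs_hz=freqs,
        config=cfg,
        channel=channel,
    )


def group_median_spectrogram(specs: Sequence[Spectrogram]) -> Spectrogram:
    """Elementwise median across animals on identical time/frequency grids."""
    if not specs:
        raise ValidationError("no spectrograms to aggregate")
    ref = specs[0]
    for s in specs[1:]:
        if s.power.shape != ref.power.shape or not np.allclose(
            s.freqs_hz, ref.freqs_hz, rtol=0, atol=1e-12
        ):
            raise ValidationError("frequency grids differ between spectrograms")
        if not np.allclose(s.window_times_s, ref.window_times_s, rtol=0, atol=1e-9):
            raise ValidationError("time grids differ between spectrograms")
    stack = np.stack([s.power for s in specs])
    return Spectrogram(
        power=np.median(stack, axis=0),
        window_times_s=ref.window_times_s.copy(),
        freqs_hz=ref.freqs_hz.copy(),
        config=ref.config,
        channel=ref.channel,
    )


def band_power(
    spec: Spectrogram, low_hz: float, high_hz: float
) -> np.ndarray:
    """Per-window band-integrated density (trapezoid over bins whose centers
    lie in [low_hz, high_hz], bounds inclusive)."""
    sel = (spec.freqs_hz >= low_hz - 1e-12) & (spec.freqs_hz <= high_hz + 1e-12)
    if sel.sum() < 2:
        raise ValidationError(
            f"band [{low_hz}, {high_hz}] Hz covers fewer than two frequency bins"
        )
    return np.trapezoid(spec.power[:, sel], spec.freqs_hz[sel], axis=1)
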