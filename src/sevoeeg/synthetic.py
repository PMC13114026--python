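"""Synthetic stepped-sevoflurane EEG cohorts with known ground truth.

The generator emulates the study conditions of a stepped-concentration
sevoflurane exposure in mice: per concentration step the cortical state
alternates between *bursts* (theta-band oscillation over a 1/f background)
and *suppressions* (low-amplitude noise) according to an alternating renewal
process with exponential dwell times. The stationary suppression fraction at
concentration ``c`` follows a logistic dose-response

    p(c) = 1 / (1 + exp(-bs_slope * (c - bs_ec50)))

gated to exactly 0 below the floor concentration ``bs_ec50 - 3/bs_slope`` so
that low steps produce no suppression events at all, as seen in real
dose-ramp recordings. Burst theta amplitude per electrode site interpolates
from a posterior-dominant profile toward its anterior mirror as concentration
rises, producing the anteriorization that topographic mapping should recover.

Behavioral endpoints are modeled as Gaussian psychometric threshold agents
for the tail-clamp immobility (MAC) and righting-reflex (RR) staircases.

Every public function takes an explicit integer seed; per-subject seeds are
spawned as ``SeedSequence([master_seed, subject_index])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .montage import Montage, default_mouse_montage
from .recording import ConcentrationProtocol, EEGRecording, _time_to_index

#: Default suppression-noise scale factor: threshold / NOISE_Z. Any factor
#: >= 3.29 keeps a single suppression-period sample sub-threshold with
#: probability >= 0.999; the default is stricter (two-sided tail ~7e-6)
#: because at typical sampling rates (hundreds of samples/s) a 1e-3
#: per-sample excursion rate would repeatedly split long suppression runs
#: into fragments shorter than the detector's 0.5 s duration floor.
NOISE_Z = 4.5


def _default_theta_profile() -> dict[str, float]:
    # posterior-dominant burst theta amplitudes, mV
    return {"F1": 10.0, "F2": 10.0, "C1": 16.0, "C2": 16.0, "P1": 24.0, "P2": 24.0}


@dataclass
class StrainParams:
    """Strain-level generator parameters.

    bs_ec50/bs_slope set the logistic suppression dose-response (vol%,
    dimensionless); dwell means (s) set the renewal time scale; theta
    amplitudes are in recording units (mV); theta_shift_rate is the
    anteriorward redistribution per vol% above the first step; true_mac /
    true_rr / behavioral_sd (vol%) parameterize the behavioral agents.
    """

    bs_ec50: float = 2.45
    bs_slope: float = 20.0
    mean_suppression_dur_s: float = 6.0
    mean_burst_dur_s: float = 6.0
    theta_amp_by_site: dict[str, float] = field(default_factory=_default_theta_profile)
    theta_shift_rate: float = 0.5
    noise_sd: float = 5.0 / NOISE_Z
    true_mac: float = 2.67
    true_rr: float = 1.65
    behavioral_sd: float = 0.05
    background_sd: float = 1.0  # 1/f background scale during bursts, mV
    name: str = ""

    def __post_init__(self) -> None:
        if self.mean_suppression_dur_s <= 0 or self.mean_burst_dur_s <= 0:
            raise ValidationError("dwell means must be positive")
        if any(a < 0 for a in self.theta_amp_by_site.values()):
            raise ValidationError("theta amplitudes must be non-negative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.bs_slope <= 0:
            raise ValidationError("bs_slope must be positive")

    @property
    def suppression_floor_conc(self) -> float:
        """Concentration below which suppression probability is gated to 0."""
        return self.bs_ec50 - 3.0 / self.bs_slope

    def suppression_fraction(self, concentration: float) -> float:
        """Gated logistic stationary suppression fraction at a concentration."""
        if concentration < self.suppression_floor_conc:
            return 0.0
        z = self.bs_slope * (concentration - self.bs_ec50)
        return 1.0 / (1.0 + math.exp(-z))


def b6_like_params() -> StrainParams:
    """Control-strain (C57BL/6J-like) defaults: late suppression onset, slow
    theta anteriorization, MAC 2.67 / RR 1.65 vol%."""
    return StrainParams(
        bs_ec50=2.45,
        theta_shift_rate=0.5,
        true_mac=2.67,
        true_rr=1.65,
        behavioral_sd=0.05,
        name="B6-like",
    )


def btbr_like_params() -> StrainParams:
    """Sensitive-strain (BTBR-like) defaults: earlier suppression onset, fast
    theta anteriorization, MAC 2.68 / RR 1.10 vol%."""
    return StrainParams(
        bs_ec50=2.05,
        theta_shift_rate=1.5,
        true_mac=2.68,
        true_rr=1.10,
        behavioral_sd=0.10,
        name="BTBR-like",
    )


@dataclass
class GroundTruth:
    """Per-sample suppression mask plus programmed per-step quantities."""

    suppression_mask: np.ndarray  # (channels, samples) bool
    per_step_suppression_fraction: dict[float, float]
    theta_site_amplitudes: dict[float, dict[str, float]]


def _anterior_mirror(
    profile: Mapping[str, float], montage: Montage
) -> dict[str, float]:
    """Swap amplitudes between AP-mirrored site pairs (F<->P, C<->C)."""
    sites = {lab: montage.position(lab) for lab in profile}
    out = {}
    for lab, (ap, ml) in sites.items():
        # partner: same ML side, AP rank reversed
        ranked = sorted(
            (l for l, (a, m) in sites.items() if m == ml),
            key=lambda l: sites[l][0],
        )
        partner = ranked[len(ranked) - 1 - ranked.index(lab)]
        out[lab] = profile[partner]
    return out


def _site_amplitudes(
    params: StrainParams,
    concentration: float,
    first_conc: float,
    montage: Montage,
) -> dict[str, float]:
    w = params.theta_shift_rate * (concentration - first_conc)
    w = min(max(w, 0.0), 1.0)
    anterior = _anterior_mirror(params.theta_amp_by_site, montage)
    return {
        lab: (1.0 - w) * params.theta_amp_by_site[lab] + w * anterior[lab]
        for lab in params.theta_amp_by_site
    }


def _renewal_mask(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    p: float,
    mean_supp_s: float,
) -> np.ndarray:
    """Alternating renewal suppression mask over one step window.

    Suppression dwells are Exp(mean_supp_s); burst dwells are exponential with
    mean chosen so the stationary suppression fraction is ``p``. Exponential
    dwells are memoryless, so starting from the stationary state distribution
    yields a stationary process.
    """
    mask = np.zeros(n_samples, dtype=bool)
    if p <= 0.0:
        return mask
    if p >= 1.0:
        mask[:] = True
        return mask
    mean_burst_s = mean_supp_s * (1.0 - p) / p
    in_supp = bool(rng.random() < p)
    t = 0.0
    total_s = n_samples / fs
    while t < total_s:
        mean = mean_supp_s if in_supp else mean_burst_s
        dwell = rng.exponential(mean)
        if in_supp:
            i0 = min(int(t * fs), n_samples)
            i1 = min(int((t + dwell) * fs), n_samples)
            mask[i0:i1] = True
        t += dwell
        in_supp = not in_supp
    return mask


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f (power) background via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec[1:] /= np.sqrt(f[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


THETA_CENTER_HZ = 6.0


def simulate_recording(
    params: StrainParams,
    protocol: ConcentrationProtocol,
    fs: float = 500.0,
    seed: int | np.random.SeedSequence = 0,
    channels: Optional[Sequence[str]] = None,
    montage: Optional[Montage] = None,
    subject_id: str = "",
) -> tuple[EEGRecording, GroundTruth]:
    """Simulate one stepped-exposure recording with its ground truth.

    The suppression state is a brain-wide process: the mask is identical
    across channels. Bursts carry a 6 Hz sinusoid (random phase per channel)
    over a 1/f background; suppression periods carry only Gaussian noise with
    sd ``params.noise_sd``. ``channels`` restricts synthesis to a subset of
    montage signal sites (all six by default).
    """
    if fs < 32:
        raise ValidationError(
            f"fs={fs} cannot represent the 4-8 Hz band cleanly; need fs >= 32"
        )
    montage = montage or default_mouse_montage()
    labels = list(channels) if channels is not None else list(montage.signal_labels)
    montage.validate_labels(labels)
    missing = [l for l in labels if l not in params.theta_amp_by_site]
    if missing:
        raise ValidationError(f"no theta amplitude configured for {missing}")

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence([int(seed)])
    )
    rng = np.random.default_rng(ss)

    n_total = _time_to_index(protocol.end_s, fs)
    first_conc = protocol.steps[0].concentration

    state_mask = np.zeros(n_total, dtype=bool)
    per_step_fraction: dict[float, float] = {}
    amps_by_step: dict[float, dict[str, float]] = {}
    step_bounds: list[tuple[int, int, dict[str, float]]] = []
    for step in protocol.steps:
        i0 = _time_to_index(step.start_s, fs)
        i1 = _time_to_index(step.end_s, fs)
        p = params.suppression_fraction(step.concentration)
        state_mask[i0:i1] = _renewal_mask(
            rng, i1 - i0, fs, p, params.mean_suppression_dur_s
        )
        per_step_fraction[step.concentration] = float(state_mask[i0:i1].mean())
        amps = _site_amplitudes(params, step.concentration, first_conc, montage)
        amps_by_step[step.concentration] = {l: amps[l] for l in labels}
        step_bounds.append((i0, i1, amps))

    t = np.arange(n_total) / fs
    burst = ~state_mask
    samples = np.empty((len(labels), n_total))
    for ci, lab in enumerate(labels):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        theta = np.sin(2.0 * np.pi * THETA_CENTER_HZ * t + phase)
        amp = np.zeros(n_total)
        for i0, i1, amps in step_bounds:
            amp[i0:i1] = amps[lab]
        x = rng.standard_normal(n_total) * params.noise_sd
        x += burst * (
            amp * theta + params.background_sd * _pink_noise(rng, n_total)
        )
        samples[ci] = x

    rec = EEGRecording(
        samples=samples,
        fs=fs,
        channel_labels=labels,
        unit="mV",
        subject_id=subject_id,
        strain_tag=params.name,
    )
    truth = GroundTruth(
        suppression_mask=np.broadcast_to(state_mask, samples.shape).copy(),
        per_step_suppression_fraction=per_step_fraction,
        theta_site_amplitudes=amps_by_step,
    )
    return rec, truth


def jittered_params(
    params: StrainParams,
    n_subjects: int,
    seed: int,
    jitter_cv: float = 0.02,
    fields: Sequence[str] = ("bs_ec50",),
) -> list[StrainParams]:
    """Per-subject parameter vectors with multiplicative Gaussian jitter.

    Each named field is scaled by ``1 + cv*z`` (z standard normal, one draw
    per subject and field, truncated to stay positive).
    """
    if n_subjects < 1:
        raise ValidationError("need at least one subject")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    out = []
    for _ in range(n_subjects):
        kwargs = {}
        for f_ in fields:
            base = getattr(params, f_)
            factor = max(1.0 + jitter_cv * rng.standard_normal(), 1e-3)
            kwargs[f_] = base * factor
        out.append(replace(params, **kwargs))
    return out


def simulate_cohort(
    params: StrainParams,
    n_subjects: int,
    protocol: ConcentrationProtocol,
    fs: float = 500.0,
    seed: int = 0,
    jitter_cv: float = 0.02,
    jitter_fields: Sequence[str] = ("bs_ec50",),
    channels: Optional[Sequence[str]] = None,
) -> list[tuple[EEGRecording, GroundTruth]]:
    """Simulate ``n_subjects`` independent recordings.

    Subject ``i`` uses ``SeedSequence([seed, i])`` so cohorts are reproducible
    without reusing streams across subjects.
    """
    if n_subjects < 1:
        raise ValidationError("need at least one subject")
    plist = jittered_params(
        params, n_subjects, seed=seed, jitter_cv=jitter_cv, fields=jitter_fields
    )
    out = []
    for i, p in enumerate(plist):
        rec, truth = simulate_recording(
            p,
            protocol,
            fs=fs,
            seed=np.random.SeedSequence([int(seed), i]),
            channels=channels,
            subject_id=f"sim{i:03d}",
        )
        out.append((rec, truth))
    return out


def behavioral_agent(
    params: StrainParams, seed: int
) -> Callable[[float, str], bool]:
    """A stochastic threshold responder for staircase protocols.

    ``responder(c, "mac")`` returns True if the animal *moves* to tail clamp
    at concentration ``c``: movement probability is ``1 - Phi((c - true_mac)
    / sd)``, decreasing in concentration. ``responder(c, "rr")`` returns True
    if the animal *rights itself* at ``c``: probability ``Phi((true_rr - c) /
    sd)``, increasing as concentration falls. ``behavioral_sd == 0`` gives the
    deterministic limits: move iff c < true_mac, right iff c <= true_rr.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE]))

    def responder(concentration: float, endpoint: str) -> bool:
        if endpoint == "mac":
            if params.behavioral_sd == 0:
                return concentration < params.true_mac
            p_move = norm.sf(
                (concentration - params.true_mac) / params.behavioral_sd
            )
            return bool(rng.random() < p_move)
        if endpoint == "rr":
            if params.behavioral_sd == 0:
                return concentration <= params.true_rr
            p_right = norm.cdf(
                (params.true_rr - concentration) / params.behavioral_sd
            )
            return bool(rng.random() < p_right)
        raise ValidationError(f"unknown endpoint {endpoint!r}")

    return responder
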