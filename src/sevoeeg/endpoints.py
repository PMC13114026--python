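"""Behavioral staircase engines and endpoint estimators.

Two bracketing protocols are modeled:

* MAC-type (ascending): starting at 2.5 vol%, the concentration rises by
  0.1% after every positive (movement) response to tail clamp; the endpoint
  is the first concentration at which movement disappears.
* RR-type (descending): starting at 2.0 vol% after a 20 min pre-exposure,
  the concentration falls by 0.1% per 10 min step; the endpoint is the first
  concentration at which the animal rights itself.

Dwell and pre-exposure times are bookkeeping only (no pharmacokinetic
equilibration is modeled). For a deterministic agent the ascending estimate
is the grid ceiling of the true threshold and the descending estimate the
grid value at or just below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .recording import StaircaseLog, StaircaseTrial
from .synthetic import StrainParams, behavioral_agent, jittered_params

Responder = Callable[[float, str], bool]


@dataclass(frozen=True)
class StaircaseSpec:
    """Protocol parameters for one staircase run."""

    endpoint: str  # "mac" | "rr"
    start_conc: Optional[float] = None  # default 2.5 (mac) / 2.0 (rr)
    step: float = 0.1
    dwell_s: float = 600.0
    pre_exposure_s: Optional[float] = None  # default 1200 for rr
    max_steps: int = 50

    def __post_init__(self) -> None:
        if self.endpoint not in ("mac", "rr"):
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.step <= 0:
            raise ValidationError("step must be positive")
        if self.max_steps < 1:
            raise ValidationError("max_steps must be at least 1")
        sc = self.start

        if not (0 < sc <= 8):
            raise ValidationError("start concentration must lie in (0, 8] vol%")

    @property
    def start(self) -> float:
        if self.start_conc is not None:
            return self.start_conc
        return 2.5 if self.endpoint == "mac" else 2.0

    @property
    def direction(self) -> str:
        return "ascending" if self.endpoint == "mac" else "descending"


@dataclass
class EndpointEstimate:
    """A single-subject staircase endpoint on the concentration grid."""

    value: float  # vol%
    n_trials: int
    log: StaircaseLog


def run_staircase(agent: Responder, spec: StaircaseSpec) -> StaircaseLog:
    """Drive an agent through the staircase until the response flips.

    Ascending (mac): continue while the animal moves; stop at the first
    no-movement trial. Descending (rr): continue while the animal fails to
    right itself; stop at the first righting. ``max_steps`` bounds the run;
    exhausting it yields a log flagged ``truncated``.
    """
    sign = +1.0 if spec.endpoint == "mac" else -1.0
    trials: list[StaircaseTrial] = []
    truncated = True
    for k in range(spec.max_steps):
        c = round(spec.start + sign * k * spec.step, 10)
        if c <= 0:
            break
        resp = bool(agent(c, spec.endpoint))
        trials.append(StaircaseTrial(c, resp))
        if spec.endpoint == "mac" and not resp:
            truncated = False
            break
        if spec.endpoint == "rr" and resp:
            truncated = False
            break
    return StaircaseLog(
        trials=trials,
        direction=spec.direction,
        step_size=spec.step,
        dwell_s=spec.dwell_s,
        truncated=truncated,
    )


def estimate_endpoint(log: StaircaseLog) -> EndpointEstimate:
    """Endpoint = concentration of the terminating trial.

    MAC: first trial without movement. RR: first trial with righting. A
    truncated log (no terminating event) is an error.
    """
    if not log.trials:
        raise ValidationError("empty staircase log")
    last = log.trials[-1]
    terminated = (log.direction == "ascending" and not last.response) or (
        log.direction == "descending" and last.response
    )
    if log.truncated or not terminated:
        raise ValidationError("staircase did not reach a terminating response")
    return EndpointEstimate(value=last.concentration, n_trials=len(log.trials), log=log)


@dataclass
class CohortSummary:
    endpoint: str
    values: list[float]
    mean: float
    sd: float

    @property
    def n(self) -> int:
        return len(self.values)


def cohort_endpoints(
    params_list: Sequence[StrainParams],
    spec: StaircaseSpec,
    seed: int,
) -> CohortSummary:
    """Run one staircase per subject and summarize as mean ± SD.

    Subject ``i`` gets the agent seed ``SeedSequence([seed, i])`` hash; the
    per-subject parameter vectors are supplied by the caller (e.g. via
    ``sevoeeg.synthetic.jittered_params``).
    """
    if not params_list:
        raise ValidationError("empty cohort")
    values = []
    for i, p in enumerate(params_list):
        sub_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0])
        agent = behavioral_agent(p, seed=sub_seed)
        est = estimate_endpoint(run_staircase(agent, spec))
        values.append(est.value)
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if len(values) > 1 else 0.0
    return CohortSummary(
        endpoint=spec.endpoint, values=values, mean=float(arr.mean()), sd=sd
    )


def staircase_distribution(
    true_threshold: float,
    behavioral_sd: float,
    spec: StaircaseSpec,
) -> list[tuple[float, float]]:
    """Exact distribution of the staircase estimate for a psychometric agent.

    Enumerates trial sequences on the grid: the run stops at step ``k`` with
    probability (prod of continue-probabilities before k) x stop-probability
    at k. Used as the brute-force oracle for estimator bias. Probability mass
    beyond ``max_steps`` is dropped (reported grid is the reachable one).
    """
    from scipy.stats import norm

    out = []
    cont = 1.0
    sign = +1.0 if spec.endpoint == "mac" else -1.0
    for k in range(spec.max_steps):
        c = round(spec.start + sign * k * spec.step, 10)
        if c <= 0:
            break
        if spec.endpoint == "mac":
            if behavioral_sd == 0:
                p_continue = 1.0 if c < true_threshold else 0.0
            else:
                p_continue = norm.sf((c - true_threshold) / behavioral_sd)
        else:
            if behavioral_sd == 0:
                p_continue = 0.0 if c <= true_threshold else 1.0
            else:
                p_continue = norm.sf((true_threshold - c) / behavioral_sd)
        p_stop = cont * (1.0 - p_continue)
        if p_stop > 0:
            out.append((c, p_stop))
        cont *= p_continue
        if cont == 0:
            break
    return out
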