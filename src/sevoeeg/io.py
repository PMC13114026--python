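"""Readers and writers for EEG recordings, protocols and staircase logs.

Two on-disk dialects are supported for EEG:

* ``edf`` — European Data Format (EDF, 16-bit). The codec here writes plain
  EDF with one signal per channel and a linear digital→physical map chosen to
  cover the signal range; writing refuses to clip (an error is raised if the
  declared physical range is exceeded).
* ``csv`` — a hand-inspectable wide table: UTF-8, first column ``time_s``,
  remaining columns named by channel label. CSV carries no unit metadata, so
  the unit is supplied by the caller (default mV).

Protocols and staircase logs travel as small CSV tables.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .montage import Montage, default_mouse_montage
from .recording import (
    ConcentrationProtocol,
    EEGRecording,
    ProtocolStep,
    StaircaseLog,
    StaircaseTrial,
)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fit8(x: float) -> str:
    """Render a float into at most 8 ASCII chars (EDF numeric field)."""
    for fmt in ("%.8g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % x
        if len(s) <= 8:
            return s
    raise ValidationError(f"cannot encode {x!r} in an 8-char EDF field")


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")
    if len(b) > n:
        b = b[:n]
    return b.ljust(n)


def write_eeg(
    rec: EEGRecording,
    path: str | Path,
    dialect: str = "edf",
    phys_range: Optional[float] = None,
) -> Path:
    """Write a recording to ``path`` in the given dialect.

    For EDF, ``phys_range`` fixes the symmetric physical scale (±phys_range in
    the recording's unit); by default the scale is derived from the data. A
    signal exceeding an explicitly declared range raises instead of clipping.
    """
    path = Path(path)
    if dialect == "csv":
        t = np.arange(rec.n_samples) / rec.fs
        df = pd.DataFrame({"time_s": t})
        for i, lab in enumerate(rec.channel_labels):
            df[lab] = rec.samples[i]
        df.to_csv(path, index=False)
        return path
    if dialect != "edf":
        raise ValidationError(f"unknown dialect {dialect!r}")

    peak = float(np.max(np.abs(rec.samples))) if rec.samples.size else 0.0
    if phys_range is None:
        pmax = peak if peak > 0 else 1.0
    else:
        pmax = float(phys_range)
        if peak > pmax:
            raise ValidationError(
                f"signal peak {peak:g} {rec.unit} exceeds declared physical "
                f"range ±{pmax:g} {rec.unit}; refusing to clip"
            )
    pmin = -pmax

    fs = rec.fs
    if abs(fs - round(fs)) < 1e-9 and rec.n_samples % int(round(fs)) == 0:
        record_dur = 1.0
        spr = int(round(fs))  # samples per data record
    else:
        # fall back to a single data record holding the whole signal
        record_dur = rec.n_samples / fs
        spr = rec.n_samples
    n_records = rec.n_samples // spr

    ns = rec.n_channels
    header_bytes = 256 + ns * 256
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(rec.subject_id or "X", 80))
        f.write(_pad(rec.strain_tag or "Startdate X", 80))
        f.write(_pad("01.01.01", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad(_fit8(record_dur), 8))
        f.write(_pad(str(ns), 4))
        for lab in rec.channel_labels:
            f.write(_pad(lab, 16))
        f.write(_pad("", 80) * ns)  # transducer
        f.write(_pad(rec.unit, 8) * ns)
        f.write(_pad(_fit8(pmin), 8) * ns)
        f.write(_pad(_fit8(pmax), 8) * ns)
        f.write(_pad(str(_DIG_MIN), 8) * ns)
        f.write(_pad(str(_DIG_MAX), 8) * ns)
        f.write(_pad("", 80) * ns)  # prefiltering
        f.write(_pad(str(spr), 8) * ns)
        f.write(_pad("", 32) * ns)

        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        digital = np.rint((rec.samples - pmin) * scale + _DIG_MIN)
        digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes())
    return path


def _read_edf(path: Path) -> EEGRecording:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValidationError(f"{path} is not a valid EDF file (short header)")
        patient = head[8:88].decode("ascii", "replace").strip()
        recording_field = head[88:168].decode("ascii", "replace").strip()
        n_records = int(head[236:244].decode())
        record_dur = float(head[244:252].decode())
        ns = int(head[252:256].decode())

        def fields(width: int) -> list[str]:
            raw = f.read(width * ns)
            return [
                raw[i * width : (i + 1) * width].decode("ascii", "replace").strip()
                for i in range(ns)
            ]

        labels = fields(16)
        fields(80)  # transducer
        units = fields(8)
        pmins = [float(x) for x in fields(8)]
        pmaxs = [float(x) for x in fields(8)]
        dmins = [int(x) for x in fields(8)]
        dmaxs = [int(x) for x in fields(8)]
        fields(80)  # prefiltering
        sprs = [int(x) for x in fields(8)]
        fields(32)

        if len(set(sprs)) != 1:
            raise ValidationError(
                "channels have non-uniform sampling rates; not supported"
            )
        spr = sprs[0]
        fs = spr / record_dur
        data = np.frombuffer(f.read(2 * spr * ns * n_records), dtype="<i2")
        data = data.reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1)

    samples = np.empty(data.shape, dtype=float)
    for i in range(ns):
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        samples[i] = (data[i].astype(float) - dmins[i]) * scale + pmins[i]
    unit = units[0] if units else "mV"
    if any(u != unit for u in units):
        raise ValidationError("channels carry inconsistent physical units")
    return EEGRecording(
        samples=samples,
        fs=fs,
        channel_labels=labels,
        unit=unit,
        subject_id="" if patient == "X" else patient,
        strain_tag="" if recording_field == "Startdate X" else recording_field,
    )


def _read_csv(path: Path, unit: str) -> EEGRecording:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValidationError("CSV dialect requires a leading 'time_s' column")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValidationError("CSV recording needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("non-uniform sampling interval in CSV time column")
    labels = [c for c in df.columns if c != "time_s"]
    samples = df[labels].to_numpy(float).T
    return EEGRecording(samples=samples, fs=1.0 / dt[0], channel_labels=labels, unit=unit)


def read_eeg(
    path: str | Path,
    dialect: Optional[str] = None,
    montage: Optional[Montage] = None,
    unit: Optional[str] = None,
) -> EEGRecording:
    """Read a recording, validating channel labels against the montage.

    ``dialect`` defaults to the file extension; ``unit`` overrides the file's
    unit metadata (and is required knowledge for CSV, default mV).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect == "edf":
        rec = _read_edf(path)
        if unit is not None:
            rec.unit = unit
    elif dialect == "csv":
        rec = _read_csv(path, unit=unit or "mV")
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    (montage or default_mouse_montage()).validate_labels(rec.channel_labels)
    return rec


# -- protocol / staircase tables ------------------------------------------


def write_protocol_csv(protocol: ConcentrationProtocol, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "concentration": [s.concentration for s in protocol.steps],
            "start_s": [s.start_s for s in protocol.steps],
            "duration_s": [s.duration_s for s in protocol.steps],
        }
    ).to_csv(path, index=False)
    return path


def read_protocol_csv(path: str | Path) -> ConcentrationProtocol:
    df = pd.read_csv(path)
    steps = [
        ProtocolStep(float(r.concentration), float(r.start_s), float(r.duration_s))
        for r in df.itertuples()
    ]
    return ConcentrationProtocol(steps=steps)


def write_staircase_csv(log: StaircaseLog, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "concentration": [t.concentration for t in log.trials],
            "response": [int(t.response) for t in log.trials],
        }
    ).to_csv(path, index=False)
    return path


def read_staircase_csv(
    path: str | Path, direction: str, step_size: float = 0.1
) -> StaircaseLog:
    df = pd.read_csv(path)
    trials = [
        StaircaseTrial(float(r.concentration), bool(r.response))
        for r in df.itertuples()
    ]
    return StaircaseLog(trials=trials, direction=direction, step_size=step_size)


def write_mask_csv(
    mask: np.ndarray, fs: float, channel_labels: list[str], path: str | Path
) -> Path:
    """Long-format ground-truth sidecar: (time_s, channel, suppressed)."""
    path = Path(path)
    n = mask.shape[1]
    t = np.arange(n) / fs
    frames = [
        pd.DataFrame(
            {"time_s": t, "channel": lab, "suppressed": mask[i].astype(int)}
        )
        for i, lab in enumerate(channel_labels)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
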