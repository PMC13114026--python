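"""Burst/suppression segmentation: contract cases, brute-force oracle
equivalence, monotonicity properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sevoeeg import (
    ConcentrationProtocol,
    SuppressionCriteria,
    UnitMismatchError,
    ValidationError,
    bsr_by_step,
    detect_suppression,
    onset_concentration,
)
from sevoeeg.suppression import StepBSR

from conftest import make_recording


def brute_force_segment(x, fs, thr, min_dur_s, merge_gap_s=0.0):
    """Per-sample scan oracle: sub-threshold runs, gap merge, strict duration
    filter. Returns the suppression sample count and run list."""
    sub = [abs(v) < thr for v in x]
    runs, start = [], None
    for i, s in enumerate(sub):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(sub)))
    gap_max = int(np.floor(merge_gap_s * fs + 1e-9))
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= gap_max and gap_max > 0:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(list(r))
    keep = [(s, e) for s, e in merged if (e - s) / fs > min_dur_s + 1e-12]
    return sum(e - s for s, e in keep), keep


def seg_suppression_samples(seg, fs):
    return round(seg.suppression_time_s * fs)


class TestContractCases:
    def test_all_zero_is_one_suppression_interval(self):
        rec = make_recording(np.zeros(150000), labels=["F1"])  # 300 s
        seg = detect_suppression(rec, "F1")
        assert seg.bsr_percent == 100.0
        assert [iv.label for iv in seg.intervals] == ["suppression"]
        assert (seg.intervals[0].start_s, seg.intervals[0].end_s) == (0.0, 300.0)

    def test_large_sinusoid_never_suppressed(self):
        """10 mV 6 Hz sine: sub-threshold dips last ~1/18 s << 0.5 s."""
        t = np.arange(30000) / 500.0
        rec = make_recording(10.0 * np.sin(2 * np.pi * 6 * t), labels=["F1"])
        seg = detect_suppression(rec, "F1")
        assert seg.bsr_percent == 0.0
        assert seg.n_suppression_events == 0

    @pytest.mark.parametrize(
        "run_s,expected_events", [(0.4, 0), (0.5, 0), (0.502, 1), (0.6, 1)]
    )
    def test_duration_strictly_greater(self, run_s, expected_events):
        """'lasting longer than 0.5 s' is strict: exactly 0.5 s is burst."""
        fs = 500.0
        x = np.full(10000, 8.0)
        x[1000 : 1000 + int(run_s * fs)] = 0.0
        seg = detect_suppression(make_recording(x, labels=["F1"]), "F1")
        assert seg.n_suppression_events == expected_events

    def test_known_fraction_recovered(self):
        """Signal built from a 37.5% suppression mask -> BSR within 1 pp."""
        fs = 500.0
        n = int(300 * fs)
        mask = np.zeros(n, bool)
        # 37.5% of each 8 s block suppressed
        block = int(8 * fs)
        for s in range(0, n, block):
            mask[s : s + int(0.375 * block)] = True
        t = np.arange(n) / fs
        x = np.where(mask, 0.5, 12.0 * np.sin(2 * np.pi * 6 * t) + 6.0)
        seg = detect_suppression(make_recording(x, labels=["F1"]), "F1")
        assert seg.bsr_percent == pytest.approx(37.5, abs=1.0)

    def test_merge_gap_closes_glitches(self):
        fs = 500.0
        x = np.zeros(5000)
        x[2000] = 10.0  # single-sample glitch splitting a 10 s suppression
        strict = detect_suppression(
            make_recording(x, labels=["F1"]),
            "F1",
            SuppressionCriteria(merge_gap_s=0.0),
        )
        merged = detect_suppression(
            make_recording(x, labels=["F1"]),
            "F1",
            SuppressionCriteria(merge_gap_s=0.01),
        )
        assert strict.n_suppression_events == 2
        assert merged.n_suppression_events == 1
        assert merged.bsr_percent == 100.0

    def test_unit_mismatch_fails_loudly(self):
        rec = make_recording(np.zeros(5000), labels=["F1"], unit="uV")
        with pytest.raises(UnitMismatchError, match="uV"):
            detect_suppression(rec, "F1", SuppressionCriteria(unit="mV"))

    def test_empty_recording_rejected(self):
        rec = make_recording(np.zeros((1, 1)), labels=["F1"])
        rec.samples = rec.samples[:, :0]
        with pytest.raises(ValidationError):
            detect_suppression(rec, "F1")


class TestBsrByStep:
    def test_zero_only_in_step_four(self, short_protocol):
        fs = 500.0
        n = int(300 * fs)
        x = np.full(n, 8.0)
        x[int(180 * fs) : int(240 * fs)] = 0.0  # step 4 of the 60 s protocol
        rows = bsr_by_step(make_recording(x, labels=["F1"]), "F1", short_protocol)
        assert [round(r.bsr_percent) for r in rows] == [0, 0, 0, 100, 0]

    def test_suppression_time_arithmetic(self, full_protocol):
        fs = 500.0
        x = np.full(int(1500 * fs), 8.0)
        # 30 s suppressed inside the 2.6% step (step index 3)
        x[int(1000 * fs) : int(1030 * fs)] = 0.0
        rows = bsr_by_step(make_recording(x, labels=["F1"]), "F1", full_protocol)
        row = rows[3]
        assert row.concentration == 2.6
        assert row.bsr_percent == pytest.approx(10.0)
        assert row.suppression_time_s == pytest.approx(30.0)


class TestOnset:
    def test_first_exceeding_epsilon(self):
        rows = [(2.0, 0.0), (2.2, 0.0), (2.4, 5.0), (2.6, 20.0)]
        assert onset_concentration(rows) == 2.4
        assert onset_concentration(rows, epsilon_percent=10.0) == 2.6

    def test_all_zero_gives_none(self):
        assert onset_concentration([(2.0, 0.0), (2.2, 0.0)]) is None

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            onset_concentration([])

    def test_unordered_rejected(self):
        with pytest.raises(ValidationError):
            onset_concentration([(2.4, 1.0), (2.0, 0.0)])


@st.composite
def random_signals(draw):
    n = draw(st.integers(min_value=50, max_value=2000))
    fs = draw(st.sampled_from([100.0, 250.0, 500.0]))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    # mixture that produces plausible sub/supra threshold runs
    scale = draw(st.floats(min_value=0.5, max_value=12.0))
    x = rng.standard_normal(n) * scale
    if draw(st.booleans()):
        gate = rng.random(n) < 0.5
        x = np.where(gate, x * 0.1, x + 8.0)
    return x, fs


@given(random_signals(), st.floats(min_value=0.05, max_value=1.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_oracle_equivalence_and_conservation(sig, min_dur):
    """Segmentation equals the brute-force per-sample scan; interval lengths
    partition the recording exactly."""
    x, fs = sig
    rec = make_recording(x, fs=fs, labels=["F1"])
    crit = SuppressionCriteria(amplitude_threshold=5.0, min_duration_s=min_dur)
    seg = detect_suppression(rec, "F1", crit)
    n_supp, runs = brute_force_segment(x, fs, 5.0, min_dur)
    assert seg_suppression_samples(seg, fs) == n_supp
    assert seg.n_suppression_events == len(runs)
    total = sum(iv.duration_s for iv in seg.intervals)
    assert total == pytest.approx(rec.duration_s, abs=1e-9)
    assert 0.0 <= seg.bsr_percent <= 100.0


@given(random_signals())
@settings(max_examples=30, deadline=None, derandomize=True)
def test_threshold_and_duration_monotonicity(sig):
    """Raising the threshold never lowers BSR; raising the duration floor
    never raises it."""
    x, fs = sig
    rec = make_recording(x, fs=fs, labels=["F1"])
    bsr = lambda thr, dur: detect_suppression(
        rec, "F1", SuppressionCriteria(amplitude_threshold=thr, min_duration_s=dur)
    ).bsr_percent
    assert bsr(2.0, 0.5) <= bsr(5.0, 0.5) <= bsr(10.0, 0.5)
    assert bsr(5.0, 0.2) >= bsr(5.0, 0.5) >= bsr(5.0, 1.0)


def test_labels_alternate_and_partition(six_channel_recording):
    seg = detect_suppression(
        six_channel_recording, "F1", SuppressionCriteria(amplitude_threshold=3.0)
    )
    labels = [iv.label for iv in seg.intervals]
    assert all(a != b for a, b in zip(labels, labels[1:]))
    starts = [iv.start_s for iv in seg.intervals]
    ends = [iv.end_s for iv in seg.intervals]
    assert starts[0] == 0.0 and ends[-1] == pytest.approx(seg.total_s)
    assert all(e == pytest.approx(s) for e, s in zip(ends[:-1], starts[1:]))
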