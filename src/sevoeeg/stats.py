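"""Gated two-sample comparison rule and summary-statistic tests.

The decision rule: each group is tested for normality (Shapiro-Wilk) and the
pair for homogeneity of variance (two-sided F-ratio by default; Levene by
flag). If all three gates pass at ``alpha_gate``, a two-sided pooled-variance
Student's t-test is used; otherwise a two-sided Mann-Whitney test (exact by
enumeration for small groups, normal approximation with tie correction
beyond that). Constant samples fail the normality gate by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: groups at or below this size use the exact Mann-Whitney enumeration
EXACT_MW_MAX_PER_GROUP = 8
#: combined size cap for the exact mode
EXACT_MW_MAX_COMBINED = 25


class GateResult(NamedTuple):
    normal_a: bool
    normal_b: bool
    equal_var: bool

    @property
    def all_pass(self) -> bool:
        return self.normal_a and self.normal_b and self.equal_var


@dataclass
class TestResult:
    test_name: str  # "student_t" | "mann_whitney"
    statistic: float
    df: Optional[float]
    p_value: float
    gate: Optional[GateResult] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # constant sample: not treatable as normal
        return False
    with np.errstate(all="ignore"):
        _, p = sps.shapiro(x)
    return bool(p > alpha)


def _f_ratio_equal_var(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        return False
    f = va / vb
    dist = sps.f(len(a) - 1, len(b) - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return bool(p > alpha)


def _levene_equal_var(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    with np.errstate(all="ignore"):
        _, p = sps.levene(a, b)
    return bool(p > alpha)


def _rank_sum_distribution(pooled_2x: np.ndarray, n_a: int):
    """Exact null distribution of the group-a rank sum by subset-sum DP.

    ``pooled_2x`` holds doubled midranks (integers even with ties). Returns
    (support offset implicit) an array ``counts`` where ``counts[k][s]`` is
    the number of size-k subsets with doubled-rank sum s.
    """
    total = int(pooled_2x.sum())
    counts = np.zeros((n_a + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for v in pooled_2x:
        v = int(v)
        upper = min(n_a, len(pooled_2x))
        for k in range(upper - 1, -1, -1):
            row = counts[k]
            nz = np.flatnonzero(row)
            if nz.size:
                counts[k + 1, nz + v] += row[nz]
    return counts[n_a]


def mann_whitney_exact(
    a: Sequence[float], b: Sequence[float], gate: Optional[GateResult] = None
) -> TestResult:
    """Two-sided exact Mann-Whitney U test by full enumeration.

    Ties are handled with midranks; the null distribution is enumerated over
    all label assignments via a subset-sum recursion (equivalent to full
    permutation of group labels). Samples with combined n above
    ``EXACT_MW_MAX_COMBINED`` fall back to the tie-corrected normal
    approximation with a note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each sample needs n >= 3")
    n_a, n_b = len(a), len(b)
    if n_a + n_b > EXACT_MW_MAX_COMBINED:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return TestResult(
            test_name="mann_whitney",
            statistic=float(res.statistic),
            df=None,
            p_value=float(res.pvalue),
            gate=gate,
            note="combined n too large for exact mode; normal approximation used",
        )

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    ranks_2x = np.rint(ranks * 2).astype(int)
    dist = _rank_sum_distribution(ranks_2x, n_a)
    support = np.flatnonzero(dist)
    probs = dist[support] / dist.sum()
    mu = support @ probs  # doubled-rank-sum mean = n_a*(N+1)
    obs = np.rint(r_a * 2)
    extreme = np.abs(support - mu) >= np.abs(obs - mu) - 1e-9
    p = float(probs[extreme].sum())
    return TestResult(
        test_name="mann_whitney",
        statistic=float(u_a),
        df=None,
        p_value=p,
        gate=gate,
    )


def _mann_whitney(a: np.ndarray, b: np.ndarray, gate: GateResult) -> TestResult:
    if len(a) <= EXACT_MW_MAX_PER_GROUP and len(b) <= EXACT_MW_MAX_PER_GROUP:
        return mann_whitney_exact(a, b, gate=gate)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        gate=gate,
    )


def gated_compare(
    a: Sequence[float],
    b: Sequence[float],
    alpha_gate: float = 0.05,
    variance_test: str = "f",
) -> TestResult:
    """Two-sample comparison under the normality/homogeneity gate.

    Both groups normal (Shapiro-Wilk) and variances homogeneous → pooled
    Student's t; any gate fails → Mann-Whitney. Two-sided throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each sample needs n >= 3")
    if variance_test not in ("f", "levene"):
        raise ValidationError(f"unknown variance test {variance_test!r}")

    normal_a = _shapiro_normal(a, alpha_gate)
    normal_b = _shapiro_normal(b, alpha_gate)
    if normal_a and normal_b:
        eq = (
            _f_ratio_equal_var(a, b, alpha_gate)
            if variance_test == "f"
            else _levene_equal_var(a, b, alpha_gate)
        )
    else:
        eq = False  # not evaluated meaningfully; t-branch unreachable anyway
    gate = GateResult(normal_a, normal_b, eq)

    if gate.all_pass:
        res = sps.ttest_ind(a, b, equal_var=True)
        return TestResult(
            test_name="student_t",
            statistic=float(res.statistic),
            df=float(len(a) + len(b) - 2),
            p_value=float(res.pvalue),
            gate=gate,
        )
    return _mann_whitney(a, b, gate)


def t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> TestResult:
    """Pooled-variance two-sided Student's t from printed summary statistics.

    Lets published group summaries (mean ± SD, n) be re-tested without raw
    data; df = n_a + n_b - 2.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValidationError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValidationError("need n >= 2 per group")
    res = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return TestResult(
        test_name="student_t",
        statistic=float(res.statistic),
        df=float(n_a + n_b - 2),
        p_value=float(res.pvalue),
    )
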