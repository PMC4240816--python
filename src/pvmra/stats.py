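"""Paired protocol comparison and ordinal image-quality summaries.

Two imaging protocols measured on the same subjects are compared with a
paired t-test (continuous vessel sharpness) and a Wilcoxon signed-rank test
(ordinal 4-point quality scores). The Wilcoxon test drops zero differences,
uses mid-ranks for ties, computes the exact two-sided p by enumerating all
sign assignments when the effective sample is small (n <= 12 by default), and
falls back to the tie-corrected normal approximation otherwise. Significance
is conventionally assessed at p < 0.05.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "PairedMeasurements",
    "QualityScoreSet",
    "QUALITY_LABELS",
    "TTestResult",
    "WilcoxonResult",
    "QualitySummary",
    "paired_ttest",
    "wilcoxon_signed_rank",
    "quality_summary",
]

QUALITY_LABELS = {
    1: "poor (PVs not visible)",
    2: "fair (artifacts prevent clear delineation of all PVs)",
    3: "good (all PVs clearly defined)",
    4: "excellent (all PVs clearly defined and sharp)",
}


@dataclasses.dataclass
class PairedMeasurements:
    """Per-subject values under protocol a (conventional) and b (proposed)."""

    subjects: list[str]
    value_a: np.ndarray
    value_b: np.ndarray

    def __post_init__(self) -> None:
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_b = np.asarray(self.value_b, dtype=float)
        if not (len(self.subjects) == len(self.value_a) == len(self.value_b)):
            raise ValueError("subjects, value_a and value_b must have equal lengths")
        if len(self.value_a) < 2:
            raise ValueError("need at least two paired measurements")
        if not (np.isfinite(self.value_a).all() and np.isfinite(self.value_b).all()):
            raise ValueError("missing or non-finite values are not allowed")

    @property
    def differences(self) -> np.ndarray:
        """Protocol b minus protocol a, per subject."""
        return self.value_b - self.value_a

    @classmethod
    def from_arrays(cls, value_a, value_b) -> "PairedMeasurements":
        value_a = np.asarray(value_a, dtype=float)
        return cls([f"s{i}" for i in range(len(value_a))], value_a, value_b)


@dataclasses.dataclass
class QualityScoreSet:
    """Ordinal image-quality scores on the 4-point scale."""

    scores: np.ndarray
    labels: dict[int, str] = dataclasses.field(default_factory=lambda: dict(QUALITY_LABELS))

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.size < 1:
            raise ValueError("need at least one score")
        if not np.isin(self.scores, [1, 2, 3, 4]).all():
            raise ValueError("scores must lie in 1..4")

    @classmethod
    def from_counts(cls, counts: dict[int, int]) -> "QualityScoreSet":
        scores = np.repeat(list(counts.keys()), list(counts.values()))
        return cls(scores)


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float


class WilcoxonResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str  # "exact" | "approx"
    n_effective: int


@dataclasses.dataclass
class QualitySummary:
    mean: float
    sd: float
    fraction_ge3_pct: float
    counts: dict[int, int]


def paired_ttest(m: PairedMeasurements) -> TTestResult:
    """Paired t-test on d = value_b - value_a.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample (n-1) standard deviation;
    two-sided p from the t distribution with n-1 degrees of freedom.
    """
    d = m.differences
    n = d.size
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0)
        warnings.warn(
            "all differences identical and nonzero: t statistic is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        return TTestResult(float(np.sign(mean)) * np.inf, 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sp_stats.t.sf(abs(t), df=n - 1))
    return TTestResult(float(t), min(p, 1.0))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments of the ranks.

    Uses a convolution over doubled ranks (so mid-ranks become integers):
    p = P(W+ <= w_lo) + P(W+ >= S - w_lo) under the symmetric null.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    n_assign = 2.0 ** len(ranks)
    w_plus2 = int(np.rint(2.0 * w_plus))
    w_lo2 = min(w_plus2, total2 - w_plus2)
    p = (counts[: w_lo2 + 1].sum() + counts[total2 - w_lo2 :].sum()) / n_assign
    return float(min(p, 1.0))


def wilcoxon_signed_rank(m: PairedMeasurements, exact_threshold: int = 12) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired values (drop-zeros convention).

    Zero differences are dropped; ranks of |d| use mid-ranks for ties;
    W = min(W+, W-). Exact p by sign-assignment enumeration for effective
    n <= ``exact_threshold``, else the normal approximation with tie-corrected
    variance (no continuity correction).
    """
    d = m.differences
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn(
            "all paired differences are zero: W is undefined", RuntimeWarning, stacklevel=2
        )
        return WilcoxonResult(float("nan"), 1.0, "degenerate", 0)
    ranks = sp_stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_threshold:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w, p, "exact", n)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w, 1.0, "approx", n)
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * float(sp_stats.norm.sf(abs(z)))
    return WilcoxonResult(w, min(p, 1.0), "approx", n)


def quality_summary(s: QualityScoreSet) -> QualitySummary:
    """Mean, sample sd, percentage of scores >= 3, and per-score counts."""
    scores = s.scores.astype(float)
    sd = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
    counts = {k: int((s.scores == k).sum()) for k in (1, 2, 3, 4)}
    return QualitySummary(
        mean=float(scores.mean()),
        sd=sd,
        fraction_ge3_pct=100.0 * float((scores >= 3).mean()),
        counts=counts,
    )
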