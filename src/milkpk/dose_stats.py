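"""Exact small-sample nonparametric dose-comparison tests.

Crossover PK studies with eight animals sit far below the asymptotic
regime, so the Wilcoxon tests here compute exact permutation p-values by
full enumeration — every one of the 2^n sign assignments for the
signed-rank test, every one of the C(na+nb, na) group assignments for the
rank-sum test — with mid-ranks for ties.  The two-sided p-value is
2·min(lower tail, upper tail) capped at 1, tails inclusive of the
observed statistic.  Beyond the enumeration limits a normal approximation
with tie correction takes over (flagged in the result).

``compare_doses`` pairs two NCA result sets by subject, optionally
dose-normalizes the parameter to the reference dose, and applies the
signed-rank test (default, matching the paired crossover) or the
rank-sum test (the test the study names literally).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import PairingError, ValidationError
from .penetration import dose_normalize

__all__ = ["TestResult", "exact_signed_rank", "exact_rank_sum", "compare_doses"]

#: Largest n for which the 2^n sign enumeration is used.
SIGNED_RANK_EXACT_LIMIT = 20
#: Largest total sample for which the combination enumeration is used.
RANK_SUM_EXACT_LIMIT = 22


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    n_effective: int
    method: str                 # "signed_rank_exact" | "rank_sum_exact" | *_approx
    degenerate: bool = False    # all differences zero

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "p_two_sided": self.p_two_sided,
            "n_effective": self.n_effective, "method": self.method,
            "significant": self.significant,
        }


def _two_sided(p_lower: float, p_upper: float) -> float:
    return min(1.0, 2.0 * min(p_lower, p_upper))


def exact_signed_rank(paired_diffs) -> TestResult:
    """Exact Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |differences| are mid-ranked; W is the
    sum of ranks with positive sign.  The null distribution is built over
    all 2^n equally likely sign assignments of the observed |differences|
    (a subset-sum convolution over doubled-integer ranks, exact for ties).
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(math.nan, 1.0, 0, "signed_rank_exact", degenerate=True)
    ranks = stats.rankdata(np.abs(d))       # mid-ranks; .5 steps only
    w = float(np.sum(ranks[d > 0]))
    r2 = np.rint(2 * ranks).astype(int)      # doubled ranks are integers
    w2 = int(round(2 * w))
    if n <= SIGNED_RANK_EXACT_LIMIT:
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:                          # polynomial product Π (1 + x^r)
            counts[r:] += counts[: total + 1 - r].copy()
        counts /= counts.sum()                # uniform over 2^n assignments
        p_lower = float(counts[: w2 + 1].sum())
        p_upper = float(counts[w2:].sum())
        return TestResult(w, _two_sided(p_lower, p_upper), n, "signed_rank_exact")
    # normal approximation with tie correction for large n
    mean = n * (n + 1) / 4.0
    tie_term = _tie_correction_signed(ranks)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(w, p, n, "signed_rank_approx")


def _tie_correction_signed(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts) / 48.0)


def exact_rank_sum(a, b) -> TestResult:
    """Exact Wilcoxon rank-sum test by full combination enumeration.

    Statistic: sum of pooled mid-ranks in group ``a``; p-value from all
    C(na+nb, na) assignments of the pooled values to the groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, nb = a.size, b.size
    w = float(np.sum(ranks[:na]))
    n = na + nb
    if n <= RANK_SUM_EXACT_LIMIT:
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), na)),
            dtype=np.intp,
        ).reshape(-1, na)
        sums = ranks[combos].sum(axis=1)
        m = sums.size
        eps = 1e-9
        p_lower = float(np.count_nonzero(sums <= w + eps)) / m
        p_upper = float(np.count_nonzero(sums >= w - eps)) / m
        return TestResult(w, _two_sided(p_lower, p_upper), n, "rank_sum_exact")
    mean = na * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = np.sum(counts**3 - counts) / ((n) * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie)
    z = (w - mean) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(w, p, n, "rank_sum_approx")


def compare_doses(
    results_low,
    results_high,
    parameter: str,
    normalize: bool = True,
    method: str = "signed_rank",
) -> TestResult:
    """Compare one NCA parameter between the two dose arms of a crossover.

    ``results_low``/``results_high`` are per-subject NCA results for the
    reference and the higher dose.  With ``normalize`` the higher-dose
    values are linearly rescaled to the reference dose before testing.
    """
    low = {r.subject_id: r for r in results_low}
    high = {r.subject_id: r for r in results_high}
    if set(low) != set(high):
        raise PairingError(
            f"subject mismatch: {sorted(set(low) ^ set(high))}"
        )
    subjects = sorted(low)
    ref_dose = low[subjects[0]].dose
    x, y = [], []
    for s in subjects:
        v_low = float(low[s].params[parameter])
        v_high = float(high[s].params[parameter])
        if normalize:
            v_high = dose_normalize(v_high, high[s].dose, ref_dose)
        if math.isnan(v_low) or math.isnan(v_high):
            continue
        x.append(v_low)
        y.append(v_high)
    if method == "signed_rank":
        return exact_signed_rank(np.asarray(y) - np.asarray(x))
    if method == "rank_sum":
        return exact_rank_sum(x, y)
    raise ValidationError(f"unknown test method {method!r}")
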