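"""Group-comparison policy shared by all reporting modules.

Two-group comparisons are gated on normality: Shapiro-Wilk at alpha 0.05 on
each group; if both pass, an unpaired two-sided t-test, otherwise a
two-sided Mann-Whitney U test (exact for small tie-free samples, normal
approximation with tie correction otherwise).  Three or more groups get a
Kruskal-Wallis omnibus followed by pairwise Mann-Whitney tests with
Holm-Sidak adjustment.  Alpha is 0.05 and all tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._util import DataError

ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    dof: Optional[float] = None
    alpha: float = ALPHA
    sidedness: str = "two-sided"

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "dof": self.dof,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "alpha": self.alpha,
            "sidedness": self.sidedness,
        }


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    if np.ptp(x) == 0:  # constant sample: Shapiro undefined, clearly non-normal fit
        return False
    return sps.shapiro(x).pvalue > alpha


def compare_two_groups(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Normality-gated two-group comparison (t-test or Mann-Whitney)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise DataError("each group needs at least 3 observations")
    if _is_normal(x) and _is_normal(y):
        res = sps.ttest_ind(x, y)
        return TestResult(
            "unpaired t-test", float(res.statistic), float(res.pvalue),
            (len(x), len(y)), dof=float(res.df),
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(
        "Mann-Whitney U", float(res.statistic), float(res.pvalue), (len(x), len(y))
    )


@dataclass
class MultiGroupResult:
    omnibus: TestResult
    pairwise: list[tuple[tuple[int, int], TestResult]]
    adjusted_p: list[float]

    def to_dict(self) -> dict:
        return {
            "omnibus": self.omnibus.to_dict(),
            "pairwise": [
                {"groups": list(pair), **res.to_dict(), "p_adjusted": p_adj}
                for (pair, res), p_adj in zip(self.pairwise, self.adjusted_p)
            ],
        }


def compare_multi_groups(groups: Sequence[Sequence[float]]) -> MultiGroupResult:
    """Kruskal-Wallis omnibus + Holm-Sidak-adjusted pairwise Mann-Whitney."""
    if len(groups) < 3:
        raise ValueError("at least 3 groups are required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    kw = sps.kruskal(*arrays)
    omnibus = TestResult(
        "Kruskal-Wallis", float(kw.statistic), float(kw.pvalue),
        tuple(len(a) for a in arrays), dof=float(len(arrays) - 1),
    )
    pairwise = []
    raw_p = []
    for i, j in combinations(range(len(arrays)), 2):
        res = sps.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided", method="auto")
        tr = TestResult(
            "Mann-Whitney U", float(res.statistic), float(res.pvalue),
            (len(arrays[i]), len(arrays[j])),
        )
        pairwise.append(((i, j), tr))
        raw_p.append(tr.p_value)
    adj = multipletests(raw_p, alpha=ALPHA, method="holm-sidak")[1]
    return MultiGroupResult(omnibus, pairwise, [float(p) for p in adj])


def one_sample_vs_zero(x: Sequence[float]) -> TestResult:
    """Two-sided one-sample t-test of the mean against zero."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise DataError("at least 2 observations are required")
    if np.ptp(x) == 0:
        if x[0] != 0:
            raise DataError("zero-variance sample: one-sample t-test undefined")
        # all exactly zero: no evidence against the null at all
        return TestResult("one-sample t-test", 0.0, 1.0, (len(x),), dof=float(len(x) - 1))
    res = sps.ttest_1samp(x, 0.0)
    return TestResult(
        "one-sample t-test", float(res.statistic), float(res.pvalue),
        (len(x),), dof=float(res.df),
    )
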