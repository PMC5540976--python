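"""Group-level tests shared across analyses (subject as random effect)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InvalidParameterError


@dataclass(frozen=True)
class GroupTestResult:
    name: str
    statistic: float
    p: float
    sidedness: str
    n: int


def wilcoxon_signed_rank(
    values, mu: float = 0.0, alternative: str = "greater"
) -> GroupTestResult:
    """One-sample Wilcoxon signed-rank test of ``values`` against ``mu``.

    Zero differences are excluded (Wilcoxon's original treatment).  The
    exact null distribution is used for small samples (n <= 25, no tied
    ranks); the normal approximation with continuity correction otherwise.
    """
    if alternative not in ("greater", "two-sided", "less"):
        raise InvalidParameterError(f"unknown alternative {alternative!r}")
    diffs = np.asarray(values, dtype=float) - mu
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise DegenerateDataError("all differences are zero")
    n = nonzero.size
    has_ties = np.unique(np.abs(nonzero)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            nonzero, zero_method="wilcox", alternative=alternative,
            correction=(method == "approx"), method=method,
        )
    return GroupTestResult(
        name=f"wilcoxon_vs_{mu:g}", statistic=float(res.statistic),
        p=float(res.pvalue), sidedness=alternative, n=n,
    )


def across_subject_ttest(differences, two_sided: bool = True) -> GroupTestResult:
    """One-sample t-test of within-subject differences against 0."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InvalidParameterError("need >= 2 subjects")
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateDataError("zero variance across subjects")
    res = stats.ttest_1samp(d, 0.0, alternative="two-sided" if two_sided else "greater")
    return GroupTestResult(
        name="across_subject_ttest", statistic=float(res.statistic),
        p=float(res.pvalue), sidedness="two-sided" if two_sided else "greater", n=d.size,
    )
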