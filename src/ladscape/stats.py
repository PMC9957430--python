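"""Shared statistical tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as _stats

__all__ = ["WelchTestResult", "welch_test"]


@dataclass(frozen=True)
class WelchTestResult:
    """Unpaired two-tailed t-test with Welch's correction.

    ``dof`` is the Welch–Satterthwaite effective degrees of freedom; the
    p-value is two-tailed.
    """

    t_statistic: float
    dof: float
    p_value: float
    group_means: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.dof <= 0:
            raise ValueError("degrees of freedom must be positive")


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchTestResult:
    """Welch's unequal-variance t-test between two independent samples."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant groups: no evidence of difference
            return WelchTestResult(0.0, float(x.size + y.size - 2), 1.0,
                                   (float(np.mean(x)), float(np.mean(y))))
        raise ValueError("both groups have zero variance; t is undefined")
    res = _stats.ttest_ind(x, y, equal_var=False)
    return WelchTestResult(
        t_statistic=float(res.statistic),
        dof=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(np.mean(x)), float(np.mean(y))),
    )
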