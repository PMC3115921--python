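"""Recover the CI of a paired mean difference from means, n, and p.

For a paired z-test, the reported two-sided p pins the deviate z, and the
standard error of the mean difference follows from the test identity
``z = |d| / s``:

    s_z = |d| / z,        95% CI: d ± 1.96 * s_z,      s_d = s_z * sqrt(n)

where ``d`` is the mean of the within-pair differences (equal to the
difference of the group means) and ``s_d`` the standard deviation of the
differences. For a paired t-test the same scheme applies with the Student-t
deviate and quantile on n - 1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import deviates
from .exceptions import DegenerateInputError, DomainError, InconsistencyError

__all__ = ["ReportedContinuous", "ContinuousRecovery", "recover_continuous"]


@dataclass(frozen=True)
class ReportedContinuous:
    """Printed summary of a paired continuous comparison.

    Either both group means or the mean difference may be given; when both
    means are present the difference is ``mean_1 - mean_2``.

    Parameters
    ----------
    n : int
        Number of pairs (>= 2).
    p : float
        Two-sided p-value of the paired test.
    test : {"z", "t"}
        Which paired test produced the p-value. The scheme cannot guess:
        the two tests invert to different deviates.
    """

    n: int
    p: float
    test: str = "z"
    mean_1: float | None = None
    mean_2: float | None = None
    diff: float | None = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise DomainError(f"number of pairs must be an integer >= 2, got {self.n!r}")
        if self.test not in ("z", "t"):
            raise DomainError(f"test must be 'z' or 't', got {self.test!r}")
        if self.diff is None and (self.mean_1 is None or self.mean_2 is None):
            raise DomainError("give either diff or both mean_1 and mean_2")
        if self.diff is not None and self.mean_1 is not None:
            raise DomainError("give diff or the two means, not both")
        if not math.isfinite(self.mean_diff):
            raise DomainError("mean difference must be finite")

    @property
    def mean_diff(self) -> float:
        if self.diff is not None:
            return float(self.diff)
        return float(self.mean_1) - float(self.mean_2)


@dataclass(frozen=True)
class ContinuousRecovery:
    """Recovered standard error, CI, and SD of differences."""

    mean_diff: float
    se: float
    ci_low: float
    ci_high: float
    sd_diff: float
    test: str
    level: float
    df: int | None = None

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sd_diff": self.sd_diff,
            "test": self.test,
            "level": self.level,
            "df": self.df,
        }


def recover_continuous(
    report: ReportedContinuous,
    level: float = 0.95,
    *,
    legacy_196: bool = False,
) -> ContinuousRecovery:
    """Recover se, CI and sd of differences for a paired mean difference.

    Parameters
    ----------
    report : ReportedContinuous
    level : float
        Confidence level for the interval, default 0.95.
    legacy_196 : bool
        Use the literal multiplier 1.96 instead of the exact normal
        quantile (only meaningful with ``test='z'`` and ``level=0.95``);
        reproduces textbook arithmetic digit for digit.

    Raises
    ------
    DegenerateInputError
        If p = 1: the deviate is zero and the standard error unrecoverable.
    InconsistencyError
        If the mean difference is 0 while p < 1.
    """
    d = report.mean_diff
    p = report.p
    n = int(report.n)

    if p == 1.0:
        raise DegenerateInputError("standard error unrecoverable: p = 1")
    if d == 0.0:
        raise InconsistencyError("mean difference is 0 but p < 1: summaries inconsistent")

    if report.test == "z":
        deviate = deviates.p_to_z(p)
        df = None
        mult = 1.96 if legacy_196 else deviates.ci_multiplier(level, "normal")
    else:
        df = n - 1
        deviate = deviates.p_to_t(p, df)
        mult = deviates.ci_multiplier(level, "student_t", df)

    se = abs(d) / deviate
    return ContinuousRecovery(
        mean_diff=d,
        se=se,
        ci_low=d - mult * se,
        ci_high=d + mult * se,
        sd_diff=se * math.sqrt(n),
        test=report.test,
        level=level,
        df=df,
    )
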