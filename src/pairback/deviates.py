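"""Conversions between two-sided p-values and normal / Student-t deviates.

Every recovery scheme in this package starts from the same elementary fact:
a two-sided test reported as ``p`` pins down the absolute value of its test
statistic, ``|T| = Q(1 - p/2)`` with ``Q`` the quantile function of the
statistic's null distribution. These helpers perform that inversion (and its
forward direction) for the standard normal and Student-t families, plus the
confidence-level multipliers used to build Wald intervals.

Conventions
-----------
* All p-values are two-sided: ``p = 2 * (1 - CDF(|deviate|))``. One-sided
  inputs are not accepted.
* Deviates are returned non-negative and at full floating precision.
* ``p = 1`` maps to deviate 0 (degenerate but well defined).
"""

from __future__ import annotations

import math

from scipy import stats

from .exceptions import DomainError, OverflowPError

#: Default lower bound on accepted p-values; below this the normal quantile
#: is numerically meaningless.
P_FLOOR = 1e-300

__all__ = ["p_to_z", "z_to_p", "p_to_t", "t_to_p", "ci_multiplier", "P_FLOOR"]


def _check_p(p: float, floor: float = P_FLOOR) -> float:
    p = float(p)
    if math.isnan(p) or p <= 0.0 or p > 1.0:
        raise DomainError(f"two-sided p-value must lie in (0, 1], got {p!r}")
    if p < floor:
        raise OverflowPError(
            f"p = {p!r} is below the floor {floor!r}; deviate would overflow"
        )
    return p


def p_to_z(p: float, *, floor: float = P_FLOOR) -> float:
    """Invert a two-sided p-value to a standard normal deviate.

    Returns the z >= 0 with ``2 * (1 - Phi(z)) = p``; inverse of
    :func:`z_to_p`.
    """
    p = _check_p(p, floor)
    return float(stats.norm.isf(p / 2.0))


def z_to_p(z: float) -> float:
    """Two-sided p-value of a standard normal deviate, ``2 * (1 - Phi(z))``."""
    z = float(z)
    if math.isnan(z) or z < 0.0:
        raise DomainError(f"deviate must be non-negative, got {z!r}")
    return float(2.0 * stats.norm.sf(z))


def _check_df(df: int) -> int:
    if int(df) != df or df < 1:
        raise DomainError(f"degrees of freedom must be a positive integer, got {df!r}")
    return int(df)


def p_to_t(p: float, df: int, *, floor: float = P_FLOOR) -> float:
    """Invert a two-sided p-value to a Student-t deviate with ``df`` dof."""
    p = _check_p(p, floor)
    df = _check_df(df)
    return float(stats.t.isf(p / 2.0, df))


def t_to_p(t: float, df: int) -> float:
    """Two-sided p-value of a Student-t deviate with ``df`` dof."""
    t = float(t)
    if math.isnan(t) or t < 0.0:
        raise DomainError(f"deviate must be non-negative, got {t!r}")
    return float(2.0 * stats.t.sf(t, _check_df(df)))


def ci_multiplier(level: float, family: str = "normal", df: int | None = None) -> float:
    """Quantile multiplier for a symmetric two-sided confidence interval.

    Returns the ``1 - (1 - level)/2`` quantile of the named distribution,
    e.g. 1.959964... for a 95% normal interval.

    Parameters
    ----------
    level : float
        Confidence level in (0, 1).
    family : {"normal", "student_t"}
    df : int, optional
        Degrees of freedom; required iff ``family == "student_t"``.
    """
    level = float(level)
    if math.isnan(level) or not 0.0 < level < 1.0:
        raise DomainError(f"confidence level must lie in (0, 1), got {level!r}")
    tail = (1.0 - level) / 2.0
    if family == "normal":
        if df is not None:
            raise DomainError("df is only meaningful for the student_t family")
        return float(stats.norm.isf(tail))
    if family == "student_t":
        if df is None:
            raise DomainError("df is required for the student_t family")
        return float(stats.t.isf(tail, _check_df(df)))
    raise DomainError(f"unknown distribution family {family!r}")
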