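"""The paired 2x2 table: variances, McNemar's test, and effect measures.

A pair-matched binary comparison is summarised by the four pair-type counts

    =========  ==================  ==================
               member 2 negative   member 2 positive
    =========  ==================  ==================
    member 1
    negative          a                   c
    member 1
    positive          b                   d
    =========  ==================  ==================

with n = a + b + c + d pairs. Cells a and d are the concordant pairs, b and
c the discordant pairs; the discordant pairs alone carry the paired-test
information. The marginal event proportions are p1 = (c + d)/n (member-2
margin) and p2 = (b + d)/n (member-1 margin), estimating the event
probabilities pi_1 and pi_2.

Effect measures and their variance estimators (matched-pairs forms):

* risk difference  d_hat = (c - b)/n = p1 - p2
    - general (CI) variance:  [(b + c) - (c - b)^2 / n] / n^2
    - null (test)  variance:  (b + c) / n^2
* risk ratio       theta_hat = (b + d)/(c + d), var(ln) = (b+c)/((b+d)(c+d))
* conditional odds ratio  rho_hat = b/c, var(ln) = 1/b + 1/c
* McNemar statistic  T = |c - b| / sqrt(b + c), referred to N(0, 1)
* NNT = 1 / d_hat, CI by inverting and reversing the risk-difference CI.

No continuity corrections are applied anywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from . import deviates
from .exceptions import DegenerateInputError, DomainError, SparseDataWarning

__all__ = [
    "PairedTable",
    "Marginals",
    "EffectWithCI",
    "marginals_of",
    "rd_variance_general",
    "rd_variance_null",
    "mcnemar_z",
    "mcnemar_p",
    "risk_difference",
    "risk_ratio",
    "odds_ratio",
    "nnt",
    "all_effects",
]


@dataclass(frozen=True)
class PairedTable:
    """Pair-type counts (a, b, c, d) of a matched binary comparison.

    a: both negative; d: both positive (concordant).
    b: member 1 positive / member 2 negative;
    c: member 1 negative / member 2 positive (discordant).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise DomainError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise DomainError("table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def sparse_reasons(self) -> list[str]:
        """Diagnostics for small or skewed tables (back-calculation caveat)."""
        reasons = []
        if self.n <= 50:
            reasons.append(f"n = {self.n} <= 50 pairs")
        if min(self.b, self.c) <= 5:
            reasons.append(f"min discordant cell = {min(self.b, self.c)} <= 5")
        if (self.b + self.c) / self.n <= 0.05:
            reasons.append(f"discordant fraction {(self.b + self.c) / self.n:.3f} <= 0.05")
        return reasons


@dataclass(frozen=True)
class Marginals:
    """Per-group event proportions read off the table margins."""

    p1_hat: float
    p2_hat: float
    n: int


@dataclass(frozen=True)
class EffectWithCI:
    """A point estimate with its standard error and Wald confidence limits.

    ``se`` lives on the analysis scale: identity for the risk difference,
    log for risk and odds ratios. CI limits are always on the natural scale.
    """

    measure: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    scale: str = "identity"
    diagnostics: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "scale": self.scale,
            "diagnostics": list(self.diagnostics),
        }


def marginals_of(table: PairedTable) -> Marginals:
    """Marginal event proportions: p1 = (c+d)/n, p2 = (b+d)/n."""
    n = table.n
    return Marginals((table.c + table.d) / n, (table.b + table.d) / n, n)


def rd_variance_general(table: PairedTable) -> float:
    """Plug-in variance of the risk-difference estimator (CI form).

    ``[(b + c) - (c - b)^2 / n] / n^2``; equals the multinomial plug-in
    variance of (c - b)/n. Its square root is the CI standard error.
    """
    n = table.n
    b, c = table.b, table.c
    return ((b + c) - (c - b) ** 2 / n) / n**2


def rd_variance_null(table: PairedTable) -> float:
    """Variance of the risk-difference estimator under the null delta = 0.

    ``(b + c) / n^2``; its square root s0 satisfies the McNemar identity
    ``T = |d_hat| / s0``.
    """
    if table.b + table.c == 0:
        raise DegenerateInputError("null variance degenerate: no discordant pairs")
    return (table.b + table.c) / table.n**2


def mcnemar_z(table: PairedTable) -> float:
    """McNemar test statistic ``|c - b| / sqrt(b + c)``, a standard normal deviate."""
    bc = table.b + table.c
    if bc == 0:
        raise DegenerateInputError("McNemar statistic undefined: no discordant pairs")
    return abs(table.c - table.b) / math.sqrt(bc)


def mcnemar_p(table: PairedTable) -> float:
    """Two-sided McNemar p-value (asymptotic normal form)."""
    return deviates.z_to_p(mcnemar_z(table))


def _warn_sparse(table: PairedTable) -> tuple[str, ...]:
    reasons = table.sparse_reasons()
    for r in reasons:
        warnings.warn(f"sparse/small paired data ({r}); CI methods may diverge",
                      SparseDataWarning, stacklevel=3)
    return tuple(reasons)


def risk_difference(table: PairedTable, level: float = 0.95) -> EffectWithCI:
    """Paired risk difference (c - b)/n with the general-variance Wald CI.

    Wald limits are truncated to [-1, 1], the parameter space of a
    difference of proportions.
    """
    n = table.n
    est = (table.c - table.b) / n
    se = math.sqrt(rd_variance_general(table))
    mult = deviates.ci_multiplier(level, "normal")
    diag = _warn_sparse(table)
    if se == 0.0:
        diag = diag + ("degenerate CI: zero variance",)
    return EffectWithCI(
        measure="risk_difference",
        estimate=est,
        se=se,
        ci_low=max(est - mult * se, -1.0),
        ci_high=min(est + mult * se, 1.0),
        level=level,
        scale="identity",
        diagnostics=diag,
    )


def risk_ratio(table: PairedTable, level: float = 0.95) -> EffectWithCI:
    """Paired risk ratio (b + d)/(c + d) with a log-scale Wald CI."""
    bd, cd = table.b + table.d, table.c + table.d
    if bd == 0 or cd == 0:
        margin = "b + d" if bd == 0 else "c + d"
        raise DegenerateInputError(f"risk ratio undefined: zero margin {margin}")
    est = bd / cd
    se = math.sqrt((table.b + table.c) / (bd * cd))
    mult = deviates.ci_multiplier(level, "normal")
    diag = _warn_sparse(table)
    return EffectWithCI(
        measure="risk_ratio",
        estimate=est,
        se=se,
        ci_low=math.exp(math.log(est) - mult * se),
        ci_high=math.exp(math.log(est) + mult * se),
        level=level,
        scale="log",
        diagnostics=diag,
    )


def odds_ratio(table: PairedTable, level: float = 0.95) -> EffectWithCI:
    """Conditional (matched-pairs) odds ratio b/c with a log-scale Wald CI.

    The conditional estimator uses only the discordant pairs, so both b and
    c must be positive.
    """
    b, c = table.b, table.c
    if b == 0 or c == 0:
        raise DegenerateInputError(
            "conditional odds ratio undefined: both discordant cells must be >= 1"
        )
    est = b / c
    se = math.sqrt(1.0 / b + 1.0 / c)
    mult = deviates.ci_multiplier(level, "normal")
    diag = _warn_sparse(table)
    return EffectWithCI(
        measure="odds_ratio",
        estimate=est,
        se=se,
        ci_low=math.exp(math.log(est) - mult * se),
        ci_high=math.exp(math.log(est) + mult * se),
        level=level,
        scale="log",
        diagnostics=diag,
    )


def nnt(rd: EffectWithCI) -> EffectWithCI:
    """Number needed to treat: reciprocal of the risk difference.

    The CI is obtained by inverting the risk-difference CI and reversing
    the limits; it is undefined when that CI spans zero. Estimates are kept
    at full precision here — round to the nearest integer for display.
    """
    if rd.measure != "risk_difference":
        raise DomainError("nnt expects a risk_difference effect")
    if rd.estimate == 0.0:
        raise DegenerateInputError("NNT undefined: risk difference is 0")
    if rd.ci_low <= 0.0 <= rd.ci_high:
        raise DegenerateInputError(
            "NNT confidence interval undefined: risk-difference CI spans 0"
        )
    lo, hi = 1.0 / rd.ci_high, 1.0 / rd.ci_low
    if lo > hi:
        lo, hi = hi, lo
    return EffectWithCI(
        measure="nnt",
        estimate=1.0 / rd.estimate,
        se=rd.se,
        ci_low=lo,
        ci_high=hi,
        level=rd.level,
        scale="identity",
        diagnostics=rd.diagnostics,
    )


def all_effects(table: PairedTable, level: float = 0.95) -> list[EffectWithCI]:
    """Every effect measure computable from the table (skipping undefined ones)."""
    effects: list[EffectWithCI] = []
    rd = risk_difference(table, level)
    effects.append(rd)
    for fn in (risk_ratio, odds_ratio):
        try:
            effects.append(fn(table, level))
        except DegenerateInputError:
            pass
    try:
        effects.append(nnt(rd))
    except DegenerateInputError:
        pass
    return effects
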