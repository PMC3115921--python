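"""Rebuild the paired 2x2 table from reported marginals, n, and p (or OR).

A paired binary comparison is usually published as two marginal proportions,
the number of pairs, and a p-value — which is not enough to compute a CI
directly, because the paired variance depends on the discordant split (b, c).
But the p-value pins the test statistic, and the test statistic together
with the marginal identities gives a solvable linear system in the four
cells. Four schemes, one per reporting situation:

* ``risk_difference`` — both marginals + McNemar/z p-value. From
  z = p_to_z(p) and d_hat = p1 - p2, the null standard error is
  s0 = |d_hat|/z, hence b + c = n^2 s0^2 and c - b = n d_hat.
* ``risk_ratio`` — both marginals + a p-value from the risk-ratio Wald
  test (rare in practice; kept for completeness). With s = |ln(p2/p1)|/z,
  b + c = s^2 n^2 p1 p2 and c - b = n (p1 - p2).
* ``odds_ratio_marginals`` — OR + both marginals (no p needed):
  c = n (p2 - p1) / (OR - 1), b = OR * c.
* ``odds_ratio_pvalue`` — OR + one marginal + p. With s = |ln OR|/z,
  b = (1 + OR)/s^2 and c = (1 + OR)/(OR s^2).

In every scheme the remaining cells follow from the margins:
d = n * p2 - b (or n * p1 - c), a = n - b - c - d. Cells are rounded to
the nearest integer, b and c first (they carry the variance information),
then d from the rounded margin, then a as the remainder so the cells always
sum to n exactly.

When each scheme is fed the exact summaries of a table with b != c, it
recovers that table exactly (the linear system is non-singular); reported
rounding of p and the marginals perturbs cells by at most ~1 in typical
journal precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from . import deviates
from .exceptions import (
    ClampedCellWarning,
    DegenerateInputError,
    DomainError,
    InconsistencyError,
    InfeasibleSummaryError,
    SparseDataWarning,
)
from .paired_table import EffectWithCI, PairedTable, risk_ratio

__all__ = [
    "ReportedBinary",
    "Reconstruction",
    "reconstruct",
    "reconstruct_rd",
    "reconstruct_rr",
    "reconstruct_or_from_marginals",
    "reconstruct_or_from_pvalue",
    "rr_via_rd_route",
]

SCHEMES = ("risk_difference", "risk_ratio", "odds_ratio_marginals", "odds_ratio_pvalue")


@dataclass(frozen=True)
class ReportedBinary:
    """Printed summary of a paired binary comparison.

    Which fields are required depends on ``scheme``:

    * risk_difference / risk_ratio: ``p1_hat``, ``p2_hat``, ``n``, ``p``
    * odds_ratio_marginals: ``or_hat``, ``p1_hat``, ``p2_hat``, ``n``
    * odds_ratio_pvalue: ``or_hat``, ``p``, ``n``, and exactly one marginal
      (named by ``known_marginal``)
    """

    n: int
    scheme: str
    p1_hat: float | None = None
    p2_hat: float | None = None
    p: float | None = None
    or_hat: float | None = None
    known_marginal: str | None = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise DomainError(f"n must be a positive integer, got {self.n!r}")
        if self.scheme not in SCHEMES:
            raise DomainError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        for name in ("p1_hat", "p2_hat"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v!r}")
        missing = [f for f in self._required() if getattr(self, f) is None]
        if missing:
            raise DomainError(
                f"scheme {self.scheme!r} requires missing field(s): {', '.join(missing)}"
            )

    def _required(self) -> tuple[str, ...]:
        if self.scheme in ("risk_difference", "risk_ratio"):
            return ("p1_hat", "p2_hat", "p")
        if self.scheme == "odds_ratio_marginals":
            return ("or_hat", "p1_hat", "p2_hat")
        # odds_ratio_pvalue
        if self.known_marginal not in ("p1", "p2"):
            raise DomainError(
                "odds_ratio_pvalue scheme requires known_marginal 'p1' or 'p2'"
            )
        return ("or_hat", "p", f"{self.known_marginal}_hat")


@dataclass(frozen=True)
class Reconstruction:
    """A reconstructed table plus the raw (pre-rounding) cell solution."""

    table: PairedTable
    raw_cells: tuple[float, float, float, float]
    residual: float
    scheme: str
    diagnostics: tuple[str, ...] = field(default=())

    @property
    def cell_shifts(self) -> tuple[float, float, float, float]:
        """Signed rounding shift per cell (rounded minus raw)."""
        return tuple(r - x for r, x in zip(self.table.cells, self.raw_cells))

    def to_dict(self) -> dict:
        return {
            "table": dict(zip("abcd", self.table.cells)),
            "raw_cells": dict(zip("abcd", self.raw_cells)),
            "residual": self.residual,
            "scheme": self.scheme,
            "diagnostics": list(self.diagnostics),
        }


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _check_p_for_scheme(p: float) -> float:
    if p is not None and p == 1.0:
        raise DegenerateInputError("p = 1 is degenerate: the deviate is 0")
    return p


def _clamp_raw(raw: dict[str, float]) -> tuple[dict[str, float], list[str]]:
    """Clamp slightly negative raw cells; reject clearly infeasible ones."""
    diags: list[str] = []
    clamped = {}
    for name, v in raw.items():
        if v < -0.5:
            raise InfeasibleSummaryError(
                f"raw cell {name} = {v:.4g} < -0.5: reported summaries are "
                "inconsistent with any paired table"
            )
        if v < 0.0:
            warnings.warn(
                f"raw cell {name} = {v:.4g} clamped to 0 (reporting rounding noise)",
                ClampedCellWarning,
                stacklevel=4,
            )
            diags.append(f"clamped cell {name} ({v:.4g} -> 0)")
            v = 0.0
        clamped[name] = v
    return clamped, diags


def _assemble(
    b_raw: float,
    c_raw: float,
    n: int,
    known_marginal_value: float,
    known_marginal: str,
    scheme: str,
    extra_diags: list[str] | None = None,
) -> Reconstruction:
    """Common back end: complete d and a from the known margin, round, validate.

    ``known_marginal`` names which margin ties down d: 'p2' gives
    d = n*p2 - b, 'p1' gives d = n*p1 - c.
    """
    if known_marginal == "p2":
        d_raw = n * known_marginal_value - b_raw
    else:
        d_raw = n * known_marginal_value - c_raw
    a_raw = n - b_raw - c_raw - d_raw

    raw, diags = _clamp_raw({"a": a_raw, "b": b_raw, "c": c_raw, "d": d_raw})
    if extra_diags:
        diags = extra_diags + diags

    b = _round_half_up(raw["b"])
    c = _round_half_up(raw["c"])
    if known_marginal == "p2":
        d = _round_half_up(n * known_marginal_value) - b
    else:
        d = _round_half_up(n * known_marginal_value) - c
    a = n - b - c - d
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise InfeasibleSummaryError(
                f"rounded cell {name} = {v} is negative: summaries infeasible"
            )

    table = PairedTable(a, b, c, d)
    for r in table.sparse_reasons():
        warnings.warn(
            f"sparse/small reconstructed table ({r}); back-calculated CIs "
            "should be read cautiously",
            SparseDataWarning,
            stacklevel=3,
        )
        diags.append(f"sparse: {r}")

    residual = abs((raw["a"] + raw["b"] + raw["c"] + raw["d"]) - n)
    return Reconstruction(
        table=table,
        raw_cells=(raw["a"], raw["b"], raw["c"], raw["d"]),
        residual=residual,
        scheme=scheme,
        diagnostics=tuple(diags),
    )


def reconstruct_rd(
    p1_hat: float, p2_hat: float, n: int, p: float
) -> Reconstruction:
    """Reconstruct the table from both marginals and a McNemar/z p-value.

    Solves b + c = n^2 s0^2 (null-variance identity, s0 = |p1 - p2| / z)
    and c - b = n (p1 - p2), then completes d and a from the margins.
    """
    _check_p_for_scheme(p)
    delta = p1_hat - p2_hat
    if delta == 0.0:
        raise InconsistencyError(
            "marginals are equal (risk difference 0) but p < 1: inconsistent"
        )
    z = deviates.p_to_z(p)
    s0 = abs(delta) / z
    bc = (n * s0) ** 2
    cb = n * delta
    c_raw = (bc + cb) / 2.0
    b_raw = (bc - cb) / 2.0
    return _assemble(b_raw, c_raw, n, p2_hat, "p2", "risk_difference")


def reconstruct_rr(
    p1_hat: float, p2_hat: float, n: int, p: float
) -> Reconstruction:
    """Reconstruct the table from both marginals and a risk-ratio Wald p-value.

    Only valid when the published p came from the risk-ratio standard error —
    rarely the case; McNemar-based p-values should go through
    :func:`reconstruct_rd` (see :func:`rr_via_rd_route`).
    """
    _check_p_for_scheme(p)
    if p1_hat <= 0.0 or p2_hat <= 0.0:
        raise DomainError("risk-ratio scheme requires both marginals > 0")
    if p1_hat == p2_hat:
        raise InconsistencyError("risk ratio 1 (equal marginals) but p < 1: inconsistent")
    z = deviates.p_to_z(p)
    theta = p2_hat / p1_hat
    s = abs(math.log(theta)) / z
    bc = (s * n) ** 2 * p1_hat * p2_hat
    cb = n * (p1_hat - p2_hat)
    c_raw = (bc + cb) / 2.0
    b_raw = (bc - cb) / 2.0
    return _assemble(
        b_raw, c_raw, n, p2_hat, "p2", "risk_ratio",
        extra_diags=["scheme rarely applicable: requires a risk-ratio Wald p-value"],
    )


def reconstruct_or_from_marginals(
    or_hat: float, p1_hat: float, p2_hat: float, n: int
) -> Reconstruction:
    """Reconstruct the table from the odds ratio and both marginals.

    c = n (p2 - p1)/(OR - 1), b = OR * c; no p-value needed.
    """
    if or_hat is None or or_hat <= 0.0:
        raise DomainError(f"odds ratio must be positive, got {or_hat!r}")
    if or_hat == 1.0:
        raise DegenerateInputError(
            "odds ratio 1 leaves the discordant split underdetermined"
        )
    diff = p2_hat - p1_hat
    if diff != 0.0 and (diff > 0) != (or_hat > 1.0):
        raise InfeasibleSummaryError(
            f"sign mismatch: p2 - p1 = {diff:.4g} but OR = {or_hat:.4g}; "
            "no non-negative table matches"
        )
    c_raw = n * diff / (or_hat - 1.0)
    b_raw = or_hat * c_raw
    return _assemble(b_raw, c_raw, n, p2_hat, "p2", "odds_ratio_marginals")


def reconstruct_or_from_pvalue(
    or_hat: float,
    p: float,
    n: int,
    *,
    p1_hat: float | None = None,
    p2_hat: float | None = None,
) -> Reconstruction:
    """Reconstruct the table from the odds ratio, one marginal, and p.

    With s = |ln OR| / z the log-OR Wald identity 1/b + 1/c = s^2 together
    with b/c = OR gives b = (1 + OR)/s^2 and c = (1 + OR)/(OR s^2); the
    known marginal then ties down d.
    """
    if or_hat is None or or_hat <= 0.0:
        raise DomainError(f"odds ratio must be positive, got {or_hat!r}")
    if or_hat == 1.0:
        raise DegenerateInputError("odds ratio 1 gives ln OR = 0: p carries no scale")
    _check_p_for_scheme(p)
    if (p1_hat is None) == (p2_hat is None):
        raise DomainError("give exactly one marginal (p1_hat or p2_hat)")
    z = deviates.p_to_z(p)
    s = abs(math.log(or_hat)) / z
    b_raw = (1.0 + or_hat) / s**2
    c_raw = (1.0 + or_hat) / (or_hat * s**2)
    if p2_hat is not None:
        return _assemble(b_raw, c_raw, n, p2_hat, "p2", "odds_ratio_pvalue")
    return _assemble(b_raw, c_raw, n, p1_hat, "p1", "odds_ratio_pvalue")


def reconstruct(report: ReportedBinary) -> Reconstruction:
    """Dispatch a :class:`ReportedBinary` record to its scheme."""
    if report.scheme == "risk_difference":
        return reconstruct_rd(report.p1_hat, report.p2_hat, report.n, report.p)
    if report.scheme == "risk_ratio":
        return reconstruct_rr(report.p1_hat, report.p2_hat, report.n, report.p)
    if report.scheme == "odds_ratio_marginals":
        return reconstruct_or_from_marginals(
            report.or_hat, report.p1_hat, report.p2_hat, report.n
        )
    return reconstruct_or_from_pvalue(
        report.or_hat, report.p, report.n,
        p1_hat=report.p1_hat if report.known_marginal == "p1" else None,
        p2_hat=report.p2_hat if report.known_marginal == "p2" else None,
    )


def rr_via_rd_route(
    p1_hat: float, p2_hat: float, n: int, p: float, level: float = 0.95
) -> EffectWithCI:
    """Risk ratio CI when the published p-value is McNemar-based.

    Reconstructs the table with the risk-difference scheme, then computes
    the risk ratio and its log-scale Wald CI from the recovered cells. This
    is the recommended default route for risk-ratio recovery, since paired
    binary p-values are almost always McNemar p-values.
    """
    rec = reconstruct_rd(p1_hat, p2_hat, n, p)
    return risk_ratio(rec.table, level)
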