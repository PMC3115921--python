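"""Sensitivity of recovered CIs to the precision of the reported p-value.

A small absolute change in a small p produces a large change in the z or t
deviate, so a p-value printed to one or two significant digits carries real
uncertainty into any back-calculated interval. These helpers sweep p over a
grid (or over the full rounding interval of the printed value) and report
the induced range of confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .continuous import ReportedContinuous, recover_continuous
from .exceptions import PairbackError
from .paired_table import risk_difference
from .reconstruct import ReportedBinary, reconstruct

__all__ = ["SensitivityRow", "SweepResult", "sweep", "digit_perturbation", "rounding_interval"]


@dataclass(frozen=True)
class SensitivityRow:
    """Recovery outcome at one grid p-value."""

    p: float
    ci_low: float | None
    ci_high: float | None
    ok: bool
    scheme: str
    detail: str = ""
    table: tuple[int, int, int, int] | None = None


@dataclass(frozen=True)
class SweepResult:
    """All grid rows plus the CI envelope (min lower, max upper)."""

    rows: tuple[SensitivityRow, ...]
    envelope: tuple[float, float]
    scheme: str
    failures: int = 0

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "envelope": {"ci_low": self.envelope[0], "ci_high": self.envelope[1]},
            "failures": self.failures,
            "rows": [
                {
                    "p": r.p, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "ok": r.ok, "detail": r.detail,
                    "table": None if r.table is None else dict(zip("abcd", r.table)),
                }
                for r in self.rows
            ],
        }


def _grid(p_min: float, p_max: float, step: float) -> list[float]:
    if not 0.0 < p_min <= p_max < 1.0:
        raise PairbackError(f"need 0 < p_min <= p_max < 1, got ({p_min}, {p_max})")
    if step <= 0.0:
        raise PairbackError(f"step must be positive, got {step}")
    n_steps = int(math.floor((p_max - p_min) / step + 1e-9))
    if n_steps + 1 > 10**6:
        raise PairbackError("grid larger than 1e6 points")
    # multiples of step from p_min, immune to accumulation drift
    return [p_min + i * step for i in range(n_steps + 1)]


def _recover_at(report: ReportedContinuous | ReportedBinary, p: float, level: float) -> SensitivityRow:
    if isinstance(report, ReportedContinuous):
        scheme = f"continuous_{report.test}"
        try:
            rec = recover_continuous(
                ReportedContinuous(n=report.n, p=p, test=report.test,
                                   diff=report.mean_diff),
                level,
            )
            return SensitivityRow(p, rec.ci_low, rec.ci_high, True, scheme)
        except PairbackError as exc:
            return SensitivityRow(p, None, None, False, scheme, detail=str(exc))
    # binary: reconstruct (integer-rounded) at this p, then CI from the table
    scheme = report.scheme
    try:
        rec = reconstruct(
            ReportedBinary(
                n=report.n, scheme=report.scheme, p1_hat=report.p1_hat,
                p2_hat=report.p2_hat, p=p, or_hat=report.or_hat,
                known_marginal=report.known_marginal,
            )
        )
        eff = risk_difference(rec.table, level)
        return SensitivityRow(p, eff.ci_low, eff.ci_high, True, scheme,
                              table=rec.table.cells)
    except PairbackError as exc:
        return SensitivityRow(p, None, None, False, scheme, detail=str(exc))


def sweep(
    report: ReportedContinuous | ReportedBinary,
    p_min: float,
    p_max: float,
    step: float,
    level: float = 0.95,
) -> SweepResult:
    """Apply the matching recovery scheme at each grid p in [p_min, p_max].

    For binary reports the table is reconstructed and integer-rounded at
    each grid point before the CI is computed, mirroring what a reader
    applying the scheme by hand at that p would obtain. Grid points where
    the scheme's preconditions fail are recorded as failed rows, not fatal
    errors.
    """
    import warnings as _warnings

    rows = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # per-point diagnostics would repeat
        for p in _grid(p_min, p_max, step):
            rows.append(_recover_at(report, p, level))
    ok = [r for r in rows if r.ok]
    if not ok:
        raise PairbackError("every grid point failed its scheme's preconditions")
    env = (min(r.ci_low for r in ok), max(r.ci_high for r in ok))
    return SweepResult(tuple(rows), env, rows[0].scheme, failures=len(rows) - len(ok))


def rounding_interval(p: float, digits: int) -> tuple[float, float]:
    """The half-open interval of values that round to ``p`` at ``digits`` s.f."""
    if digits not in (1, 2, 3):
        raise PairbackError(f"digits must be 1, 2 or 3, got {digits}")
    if not 0.0 < p < 1.0:
        raise PairbackError(f"p must lie in (0, 1), got {p}")
    exponent = math.floor(math.log10(abs(p)))
    ulp = 10.0 ** (exponent - digits + 1)
    return (p - ulp / 2.0, p + ulp / 2.0)


def digit_perturbation(
    report: ReportedContinuous | ReportedBinary,
    digits: int,
    resolution: float = 1e-4,
    level: float = 0.95,
) -> SweepResult:
    """Sweep over every p consistent with the printed value at ``digits`` s.f.

    Builds the rounding interval of the reported p and sweeps it at the
    given resolution; the envelope bounds the CI uncertainty attributable
    purely to p-value rounding.
    """
    p = report.p
    lo, hi = rounding_interval(p, digits)
    lo = max(lo, resolution)
    return sweep(report, lo, hi - resolution / 2.0, resolution, level)
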