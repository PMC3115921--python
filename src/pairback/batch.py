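"""Batch processing of reported summaries and result serialization.

CSV schema (header)::

    study_id, scheme, mean1, mean2, diff, p1, p2, n, p, or_hat,
    known_marginal, test, level

One study per row; the ``scheme`` column selects the recovery route
(``continuous``, ``risk_difference``, ``risk_ratio``, ``rr_via_rd``,
``odds_ratio_marginals``, ``odds_ratio_pvalue``). Proportions are accepted
as fractions (0.7) or percentages ("70.0%"); the interpretation is logged.
Row-level failures are recorded on the report and never abort the batch.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

from .continuous import ReportedContinuous, recover_continuous
from .exceptions import PairbackError
from .paired_table import EffectWithCI, PairedTable, all_effects
from .reconstruct import ReportedBinary, Reconstruction, reconstruct

log = logging.getLogger("pairback")

__all__ = ["StudyRecord", "RecoveryReport", "parse_proportion", "run_batch", "render"]

BATCH_COLUMNS = (
    "study_id", "scheme", "mean1", "mean2", "diff", "p1", "p2", "n", "p",
    "or_hat", "known_marginal", "test", "level",
)

_SCHEME_ALIASES = {
    "continuous": "continuous",
    "rd": "risk_difference",
    "risk_difference": "risk_difference",
    "rr": "risk_ratio",
    "risk_ratio": "risk_ratio",
    "rr_via_rd": "rr_via_rd",
    "or_marginals": "odds_ratio_marginals",
    "odds_ratio_marginals": "odds_ratio_marginals",
    "or_pvalue": "odds_ratio_pvalue",
    "odds_ratio_pvalue": "odds_ratio_pvalue",
}


def parse_proportion(raw: str | float) -> float:
    """Accept 0.7 or '70.0%' (percentages are divided by 100)."""
    if isinstance(raw, str) and raw.strip().endswith("%"):
        value = float(raw.strip().rstrip("%")) / 100.0
        log.info("interpreted %r as proportion %g", raw, value)
        return value
    return float(raw)


def _pkg_version() -> str:
    try:
        return version("pairback")
    except PackageNotFoundError:
        return "unknown"


@dataclass(frozen=True)
class StudyRecord:
    """One row of the batch schema, normalized."""

    study_id: str
    scheme: str
    fields: dict

    @classmethod
    def from_row(cls, row: dict) -> "StudyRecord":
        study_id = (row.get("study_id") or "").strip() or "<unnamed>"
        raw_scheme = (row.get("scheme") or "").strip()
        scheme = _SCHEME_ALIASES.get(raw_scheme)
        if scheme is None:
            raise PairbackError(f"unknown scheme value {raw_scheme!r}")
        parsed: dict = {}
        for key in ("mean1", "mean2", "diff", "p", "or_hat", "level"):
            v = (row.get(key) or "").strip() if isinstance(row.get(key), str) else row.get(key)
            if v not in (None, ""):
                parsed[key] = float(v)
        for key in ("p1", "p2"):
            v = row.get(key)
            if v not in (None, ""):
                parsed[key] = parse_proportion(v)
        v = row.get("n")
        if v not in (None, ""):
            parsed["n"] = int(float(v))
        km = (row.get("known_marginal") or "").strip()
        if km:
            parsed["known_marginal"] = km
        t = (row.get("test") or "").strip()
        if t:
            parsed["test"] = t
        return cls(study_id=study_id, scheme=scheme, fields=parsed)


@dataclass
class RecoveryReport:
    """Everything recovered for one study, plus diagnostics and provenance."""

    study_id: str
    scheme: str
    ok: bool
    table: PairedTable | None = None
    raw_cells: tuple | None = None
    effects: list[EffectWithCI] = field(default_factory=list)
    continuous: dict | None = None
    diagnostics: list[str] = field(default_factory=list)
    error: str | None = None
    provenance: dict = field(default_factory=lambda: {"package": "pairback",
                                                      "version": _pkg_version()})

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "scheme": self.scheme,
            "ok": self.ok,
            "table": None if self.table is None else dict(zip("abcd", self.table.cells)),
            "raw_cells": None if self.raw_cells is None else list(self.raw_cells),
            "effects": [e.to_dict() for e in self.effects],
            "continuous": self.continuous,
            "diagnostics": list(self.diagnostics),
            "error": self.error,
            "provenance": dict(self.provenance),
        }


def _require(record: StudyRecord, *names: str) -> list:
    missing = [n for n in names if n not in record.fields]
    if missing:
        raise PairbackError("missing field: " + ", ".join(missing))
    return [record.fields[n] for n in names]


def recover_record(record: StudyRecord, *, legacy_196: bool = False) -> RecoveryReport:
    """Run one study record through its recovery route."""
    level = record.fields.get("level", 0.95)
    report = RecoveryReport(study_id=record.study_id, scheme=record.scheme, ok=False)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if record.scheme == "continuous":
                (n, p) = _require(record, "n", "p")
                test = record.fields.get("test", "z")
                rc = ReportedContinuous(
                    n=n, p=p, test=test,
                    mean_1=record.fields.get("mean1"),
                    mean_2=record.fields.get("mean2"),
                    diff=record.fields.get("diff"),
                )
                rec = recover_continuous(rc, level, legacy_196=legacy_196)
                report.continuous = rec.to_dict()
            else:
                rec = _binary_route(record)
                report.table = rec.table
                report.raw_cells = rec.raw_cells
                report.diagnostics.extend(rec.diagnostics)
                report.effects = all_effects(rec.table, level)
        for w in caught:
            report.diagnostics.append(f"{type(w.message).__name__}: {w.message}")
        if legacy_196:
            report.diagnostics.append("legacy 1.96 multiplier in use")
        report.ok = True
    except PairbackError as exc:
        report.error = f"{type(exc).__name__}: {exc}"
        log.warning("study %s failed: %s", record.study_id, report.error)
    return report


def _binary_route(record: StudyRecord) -> Reconstruction:
    f = record.fields
    if record.scheme in ("risk_difference", "rr_via_rd", "risk_ratio"):
        p1, p2, n, p = _require(record, "p1", "p2", "n", "p")
        scheme = "risk_difference" if record.scheme == "rr_via_rd" else record.scheme
        return reconstruct(ReportedBinary(n=n, scheme=scheme, p1_hat=p1, p2_hat=p2, p=p))
    if record.scheme == "odds_ratio_marginals":
        or_hat, p1, p2, n = _require(record, "or_hat", "p1", "p2", "n")
        return reconstruct(ReportedBinary(n=n, scheme=record.scheme,
                                          p1_hat=p1, p2_hat=p2, or_hat=or_hat))
    # odds_ratio_pvalue
    or_hat, p, n = _require(record, "or_hat", "p", "n")
    km = f.get("known_marginal")
    if km not in ("p1", "p2") or km not in f:
        raise PairbackError("missing field: known_marginal (and its proportion)")
    return reconstruct(ReportedBinary(
        n=n, scheme=record.scheme, or_hat=or_hat, p=p, known_marginal=km,
        p1_hat=f.get("p1") if km == "p1" else None,
        p2_hat=f.get("p2") if km == "p2" else None,
    ))


def run_batch(path: str, *, legacy_196: bool = False) -> list[RecoveryReport]:
    """Process a batch CSV; one RecoveryReport per row, failures included."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        log.warning("batch file %s contains no data rows", path)
        return []
    reports = []
    for i, row in enumerate(rows):
        try:
            record = StudyRecord.from_row(row)
        except (PairbackError, ValueError) as exc:
            reports.append(RecoveryReport(
                study_id=row.get("study_id") or f"row {i + 1}",
                scheme=row.get("scheme") or "?", ok=False,
                error=f"rejected: {exc}",
            ))
            continue
        reports.append(recover_record(record, legacy_196=legacy_196))
    return reports


def render(report: RecoveryReport, fmt: str = "json") -> str:
    """Serialize one report as json (full precision), text, or csv."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2)
    if fmt == "text":
        return _render_text(report)
    if fmt == "csv":
        return _render_csv([report])
    raise PairbackError(f"unknown output format {fmt!r}")


def _render_text(report: RecoveryReport) -> str:
    lines = [f"study: {report.study_id}  scheme: {report.scheme}"]
    if report.error:
        lines.append(f"  FAILED: {report.error}")
        return "\n".join(lines)
    if report.table is not None:
        a, b, c, d = report.table.cells
        lines += [
            "  reconstructed 2x2 table (pairs):",
            f"    a = {a:<6d} c = {c}",
            f"    b = {b:<6d} d = {d}",
        ]
    for e in report.effects:
        est = round(e.estimate) if e.measure == "nnt" else f"{e.estimate:.4g}"
        lines.append(
            f"  {e.measure}: {est}  se({e.scale}) = {e.se:.4g}  "
            f"{e.level:.0%} CI ({e.ci_low:.4g}, {e.ci_high:.4g})"
        )
    if report.continuous is not None:
        cdict = report.continuous
        lines.append(
            f"  mean difference: {cdict['mean_diff']:.4g}  se = {cdict['se']:.4g}  "
            f"{cdict['level']:.0%} CI ({cdict['ci_low']:.4g}, {cdict['ci_high']:.4g})  "
            f"sd of differences = {cdict['sd_diff']:.4g}"
        )
    for dmsg in report.diagnostics:
        lines.append(f"  note: {dmsg}")
    return "\n".join(lines)


def _render_csv(reports: list[RecoveryReport]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["study_id", "scheme", "measure", "estimate", "se",
                     "ci_low", "ci_high", "level", "scale", "error"])
    for r in reports:
        if r.error:
            writer.writerow([r.study_id, r.scheme, "", "", "", "", "", "", "", r.error])
            continue
        if r.continuous is not None:
            cdict = r.continuous
            writer.writerow([
                r.study_id, r.scheme, "mean_difference",
                repr(cdict["mean_diff"]), repr(cdict["se"]),
                repr(cdict["ci_low"]), repr(cdict["ci_high"]),
                cdict["level"], "identity", "",
            ])
        for e in r.effects:
            writer.writerow([r.study_id, r.scheme, e.measure, repr(e.estimate),
                             repr(e.se), repr(e.ci_low), repr(e.ci_high),
                             e.level, e.scale, ""])
    return buf.getvalue()


def render_batch(reports: list[RecoveryReport], fmt: str = "json") -> str:
    if fmt == "json":
        return json.dumps([r.to_dict() for r in reports], indent=2)
    if fmt == "csv":
        return _render_csv(reports)
    if fmt == "text":
        return "\n\n".join(_render_text(r) for r in reports)
    raise PairbackError(f"unknown output format {fmt!r}")
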