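"""Trial ingestion and report rendering.

Trials arrive as plain CSV with header ``arm,role,events,person_years``:
exactly one row with role ``control`` and one with role ``experimental``
(the role column fixes orientation, never row order).  Reports render as
human-readable text mirroring the conventional averted-events table
layout (counts to 1 dp, ratios and bounds to 2 dp), as full-precision
round-trippable JSON, or as CSV.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Optional

from .decision import NoninferiorityVerdict
from .estimands import (
    AERResult,
    ArmObservation,
    IntervalEstimate,
    TrialObservation,
    rate_ratio,
)

__all__ = ["TrialCSVError", "AnalysisReport", "read_trial_csv", "render_report", "report_from_json"]


class TrialCSVError(ValueError):
    """Malformed trial CSV."""


_REQUIRED = ("arm", "role", "events", "person_years")


def read_trial_csv(path) -> TrialObservation:
    """Read a two-row trial summary CSV (see module docstring)."""
    arms: dict[str, ArmObservation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrialCSVError(f"{path}: empty file, expected header {','.join(_REQUIRED)}")
        missing = [c for c in _REQUIRED if c not in reader.fieldnames]
        if missing:
            raise TrialCSVError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            role = (row["role"] or "").strip().lower()
            if role not in ("control", "experimental"):
                raise TrialCSVError(
                    f"{path}:{lineno}: role must be 'control' or 'experimental', got {row['role']!r}"
                )
            if role in arms:
                raise TrialCSVError(f"{path}:{lineno}: duplicate role {role!r}")
            try:
                events = int(row["events"])
                person_years = float(row["person_years"])
                arms[role] = ArmObservation(row["arm"].strip(), events, person_years)
            except (TypeError, ValueError) as exc:
                raise TrialCSVError(f"{path}:{lineno}: {exc}") from exc
    for role in ("control", "experimental"):
        if role not in arms:
            raise TrialCSVError(f"{path}: no row with role {role!r}")
    return TrialObservation(control=arms["control"], experimental=arms["experimental"])


@dataclass(frozen=True)
class AnalysisReport:
    """Bundle of everything one `estimate` analysis produced."""

    aer: AERResult
    rr: float
    rr_interval: Optional[IntervalEstimate] = None
    aer_interval: Optional[IntervalEstimate] = None
    verdict: Optional[NoninferiorityVerdict] = None

    def to_dict(self) -> dict:
        t = self.aer.trial

        def _iv(iv: Optional[IntervalEstimate]):
            if iv is None:
                return None
            return {"lower": iv.lower, "upper": iv.upper, "level": iv.level, "method": iv.method}

        return {
            "trial": {
                "control": {
                    "arm": t.control.label,
                    "events": t.control.events,
                    "person_years": t.control.person_time,
                    "incidence_per_100py": t.control.incidence,
                },
                "experimental": {
                    "arm": t.experimental.label,
                    "events": t.experimental.events,
                    "person_years": t.experimental.person_time,
                    "incidence_per_100py": t.experimental.incidence,
                },
            },
            "rate_ratio": {"estimate": self.rr, "interval": _iv(self.rr_interval)},
            "counterfactual": {
                "mode": self.aer.counterfactual.mode,
                "value": self.aer.counterfactual.value,
            },
            "averted_events_ratio": {
                "psi": self.aer.psi,
                "interval": _iv(self.aer_interval),
                "predicted": {
                    "control": self.aer.predicted_control,
                    "experimental": self.aer.predicted_experimental,
                },
                "averted": {
                    "control": self.aer.averted_control,
                    "experimental": self.aer.averted_experimental,
                },
                "warnings": list(self.aer.warnings),
            },
            "noninferiority": None
            if self.verdict is None
            else {
                "scale": self.verdict.scale,
                "margin_or_threshold": self.verdict.margin_or_threshold,
                "bound_used": self.verdict.bound_used,
                "conclusion": self.verdict.conclusion,
                "narrative": self.verdict.narrative,
            },
        }


def _fmt_interval(iv: Optional[IntervalEstimate]) -> str:
    if iv is None:
        return ""
    up = "inf" if math.isinf(iv.upper) else f"{iv.upper:.2f}"
    return f"{iv.lower:.2f}–{up} [{iv.method}]"


def _fmt_count(x: float) -> str:
    """Counts print to 1 dp, but exact integers (e.g. 400) print bare."""
    return f"{x:g}" if float(x).is_integer() else f"{x:.1f}"


def _render_text(rep: AnalysisReport) -> str:
    t = rep.aer.trial
    rows = [
        ("Group", "PYFU", "Observed", "Predicted", "Averted"),
        (
            t.control.label,
            f"{t.control.person_time:g}",
            str(t.control.events),
            _fmt_count(rep.aer.predicted_control),
            _fmt_count(rep.aer.averted_control),
        ),
        (
            t.experimental.label,
            f"{t.experimental.person_time:g}",
            str(t.experimental.events),
            _fmt_count(rep.aer.predicted_experimental),
            _fmt_count(rep.aer.averted_experimental),
        ),
    ]
    widths = [max(len(r[i]) for r in rows) for i in range(5)]
    lines = ["Averted events analysis", "=" * 23, ""]
    cf = rep.aer.counterfactual
    if cf.mode == "placebo_incidence":
        lines.append(f"Counterfactual placebo incidence: {cf.value:g} per 100 PYFU")
    else:
        lines.append(f"Counterfactual control efficacy: {cf.value:g}")
    lines.append("")
    for r in rows:
        lines.append("  ".join(s.ljust(w) for s, w in zip(r, widths)).rstrip())
    lines.append("")
    rr_s = f"Rate ratio (experimental vs control): {rep.rr:.2f}"
    if rep.rr_interval is not None:
        rr_s += f" ({_fmt_interval(rep.rr_interval)})"
    lines.append(rr_s)
    psi_s = f"Averted events ratio: {rep.aer.psi:.3g}"
    if rep.aer_interval is not None:
        psi_s += f" ({_fmt_interval(rep.aer_interval)})"
    lines.append(psi_s)
    for w in rep.aer.warnings:
        lines.append(f"Warning: {w}")
    if rep.verdict is not None:
        lines.append("")
        lines.append(rep.verdict.narrative)
    return "\n".join(lines) + "\n"


def _render_csv(rep: AnalysisReport) -> str:
    t = rep.aer.trial
    out = ["arm,role,events,person_years,predicted,averted"]
    out.append(
        f"{t.control.label},control,{t.control.events},{t.control.person_time:g},"
        f"{rep.aer.predicted_control!r},{rep.aer.averted_control!r}"
    )
    out.append(
        f"{t.experimental.label},experimental,{t.experimental.events},"
        f"{t.experimental.person_time:g},{rep.aer.predicted_experimental!r},"
        f"{rep.aer.averted_experimental!r}"
    )
    return "\n".join(out) + "\n"


def render_report(rep: AnalysisReport, format: str = "text") -> str:
    """Render an analysis bundle as ``text``, ``json`` or ``csv``.

    JSON is canonical (sorted keys, fixed separators) and full precision,
    so parse -> re-render is byte-identical.
    """
    if format == "text":
        return _render_text(rep)
    if format == "json":
        return json.dumps(rep.to_dict(), sort_keys=True, separators=(",", ":")) + "\n"
    if format == "csv":
        return _render_csv(rep)
    raise ValueError(f"format must be 'text', 'json' or 'csv', got {format!r}")


def report_from_json(text: str) -> str:
    """Parse rendered JSON and re-render it canonically (round-trip aid)."""
    return json.dumps(json.loads(text), sort_keys=True, separators=(",", ":")) + "\n"
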