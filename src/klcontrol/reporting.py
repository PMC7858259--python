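"""Serialization of decision reports and sweep results to TSV and JSON.

Numbers are written with 12 significant digits so that written reports
round-trip to the in-memory values at the documented tolerance and are
stable across platforms.  Infinite risks are written as ``inf``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .decision import DecisionReport
from .sweep import CutoffEstimate, SweepResult

__all__ = [
    "format_number",
    "decision_report_frame",
    "write_decision_report",
    "write_sweep_result",
    "cutoff_to_dict",
]

SIG_DIGITS = 12


def format_number(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:.{SIG_DIGITS}g}"


def decision_report_frame(report: DecisionReport) -> pd.DataFrame:
    """One row per policy: name, risk, its two components, selection flag."""
    rows = [{
        "policy": ev.policy_name,
        "risk_bits": ev.risk_bits,
        "expected_utility_term_bits": ev.expected_utility_term,
        "entropy_term_bits": ev.entropy_term,
        "selected": ev.policy_name == report.selected,
    } for ev in report.evaluations]
    return pd.DataFrame(rows)


def _report_dict(report: DecisionReport) -> dict:
    return {
        "evaluations": [{
            "policy": ev.policy_name,
            "risk_bits": ev.risk_bits,
            "expected_utility_term_bits": ev.expected_utility_term,
            "entropy_term_bits": ev.entropy_term,
        } for ev in report.evaluations],
        "selected": report.selected,
        "tie": report.tie,
        "tie_members": list(report.tie_members),
    }


class _FloatEncoder(json.JSONEncoder):
    # json.dump writes full repr / Infinity; round through 12 sig digits
    # and keep "inf" spelled portably
    def default(self, o):  # pragma: no cover - nothing non-standard yet
        return super().default(o)

    def iterencode(self, o, _one_shot=False):
        def convert(x):
            if isinstance(x, float):
                return float(format_number(x)) if math.isfinite(x) else x
            if isinstance(x, dict):
                return {k: convert(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [convert(v) for v in x]
            return x
        return super().iterencode(convert(o), _one_shot)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, cls=_FloatEncoder) + "\n")


def write_decision_report(report: DecisionReport, out_dir, *,
                          stem: str = "decision",
                          formats: tuple = ("tsv", "json")) -> list:
    """Write the report as ``<stem>.tsv`` / ``<stem>.json``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "tsv" in formats:
        frame = decision_report_frame(report)
        path = out_dir / f"{stem}.tsv"
        frame.to_csv(path, sep="\t", index=False,
                     float_format=f"%.{SIG_DIGITS}g")
        written.append(path)
    if "json" in formats:
        path = out_dir / f"{stem}.json"
        _write_json(_report_dict(report), path)
        written.append(path)
    return written


def cutoff_to_dict(cutoff: CutoffEstimate) -> dict:
    return {
        "parameter_value": cutoff.parameter_value,
        "exploit_probability": cutoff.exploit_probability,
        "policy_pair": list(cutoff.policy_pair),
        "residual_bits": cutoff.residual,
    }


def write_sweep_result(result: SweepResult, out_dir, *,
                       stem: str = "sweep",
                       formats: tuple = ("tsv", "json")) -> list:
    """Write plot-ready TSV curves and a JSON structure with the cut-off."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "tsv" in formats:
        frame = pd.DataFrame({result.parameter_name: result.grid})
        for name, curve in result.curves.items():
            frame[f"risk_bits[{name}]"] = curve
        path = out_dir / f"{stem}.tsv"
        frame.to_csv(path, sep="\t", index=False,
                     float_format=f"%.{SIG_DIGITS}g")
        written.append(path)
    if "json" in formats:
        doc = {
            "parameter_name": result.parameter_name,
            "grid": list(result.grid),
            "curves": {k: list(v) for k, v in result.curves.items()},
            "cutoff": (cutoff_to_dict(result.cutoff)
                       if result.cutoff is not None else None),
        }
        path = out_dir / f"{stem}.json"
        _write_json(doc, path)
        written.append(path)
    return written
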