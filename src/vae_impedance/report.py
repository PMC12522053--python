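"""Deterministic JSON report serialization.

Reports are meant to be diffed between runs, so floats are rounded to six
significant digits and keys are emitted sorted: the same recording and
configuration always produce byte-identical report text.
"""

from __future__ import annotations

import json
from typing import Iterable

from .detection import VAEAssessment

__all__ = ["round_floats", "report_dict", "dumps_report", "window_record_lines"]


def round_floats(obj):
    """Recursively round floats to 6 significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v) for v in obj]
    return obj


def report_dict(assessments: Iterable[VAEAssessment]) -> dict:
    windows = [round_floats(a.as_dict()) for a in assessments]
    return {
        "n_windows": len(windows),
        "n_alarm_windows": sum(1 for w in windows if w["alarm"]),
        "max_score": max((w["score"] for w in windows), default=0.0),
        "windows": windows,
    }


def dumps_report(assessments: Iterable[VAEAssessment]) -> str:
    return json.dumps(report_dict(assessments), sort_keys=True, indent=2) + "\n"


def window_record_lines(assessments: Iterable[VAEAssessment]) -> list[str]:
    """One compact JSON line per window (the streaming output format)."""
    return [
        json.dumps(round_floats(a.as_dict()), sort_keys=True, separators=(",", ":"))
        for a in assessments
    ]
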