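"""Report bundling and rendering (JSON + human-readable table)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from pydantic import BaseModel, model_validator

from .stats import ConcordanceReport


class ReportBundle(BaseModel):
    """All per-assay concordance reports plus cohort summary and provenance."""

    reports: dict[str, ConcordanceReport]
    cohort_summary: dict[str, Any] = {}
    provenance: dict[str, Any] = {}

    @model_validator(mode="after")
    def _keys_match_assays(self) -> "ReportBundle":
        for key, rep in self.reports.items():
            if rep.assay != key:
                raise ValueError(f"report under key {key!r} is labelled {rep.assay!r}")
        return self


def render_table(bundle: ReportBundle) -> str:
    """Fixed-width per-assay summary (counts, agreement statistics)."""
    lines = [
        f"{'assay':<10}{'n':>5}{'a':>5}{'b':>5}{'c':>5}{'d':>5}"
        f"{'conc':>8}{'CI':>17}{'sens':>8}{'spec':>8}{'McNemar p':>11}"
    ]
    for name in sorted(bundle.reports):
        r = bundle.reports[name]
        ci = f"{100 * r.concordance_ci.lower:.1f}-{100 * r.concordance_ci.upper:.1f}%"
        lines.append(
            f"{name:<10}{r.n:>5}{r.table.a:>5}{r.table.b:>5}{r.table.c:>5}"
            f"{r.table.d:>5}{100 * r.concordance:>7.1f}%{ci:>17}"
            f"{100 * r.sensitivity:>7.1f}%{100 * r.specificity:>7.1f}%"
            f"{r.mcnemar_p:>11.4g}"
        )
    return "\n".join(lines) + "\n"


def write_report(bundle: ReportBundle, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.json`` (lossless) and ``<path>.txt`` (table).

    Raises on an empty bundle; re-rendering a written bundle is
    idempotent.
    """
    if not bundle.reports:
        raise ValueError("cannot write an empty report bundle")
    base = Path(path)
    json_path = base.with_suffix(".json")
    txt_path = base.with_suffix(".txt")
    json_path.write_text(bundle.model_dump_json(indent=2))
    txt_path.write_text(render_table(bundle))
    return json_path, txt_path


def read_report(path: str | Path) -> ReportBundle:
    return ReportBundle.model_validate(json.loads(Path(path).read_text()))
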