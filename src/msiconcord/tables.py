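"""Tabular (TSV) readers/writers for histograms, profiles, calls and scores."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .bayes import MsiScoreResult
from .ihc import IhcMeasurement
from .models import GENES, LengthHistogram, MarkerProfile


def write_histograms(
    hists_by_sample: Mapping[str, Mapping[str, LengthHistogram]], path: str | Path
) -> None:
    rows = [
        {"sample_id": sid, "marker_id": mid, "repeat_len": l, "read_count": c}
        for sid, hists in hists_by_sample.items()
        for mid, h in hists.items()
        for l, c in sorted(h.counts.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "marker_id", "repeat_len", "read_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_histograms(path: str | Path) -> dict[str, dict[str, LengthHistogram]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, LengthHistogram]] = {}
    for (sid, mid), grp in df.groupby(["sample_id", "marker_id"], sort=True):
        out.setdefault(str(sid), {})[str(mid)] = LengthHistogram(
            marker_id=str(mid),
            counts=dict(zip(grp["repeat_len"].astype(int), grp["read_count"].astype(int))),
        )
    return out


def write_profiles(
    profiles_by_sample: Mapping[str, Sequence[MarkerProfile]], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": sid,
            "marker_id": p.marker_id,
            "depth": p.depth,
            "d": p.d,
            "b": p.b,
            "evaluable": p.evaluable,
        }
        for sid, profiles in profiles_by_sample.items()
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> dict[str, list[MarkerProfile]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[MarkerProfile]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample_id), []).append(
            MarkerProfile(
                marker_id=str(row.marker_id),
                depth=int(row.depth),
                d=float(row.d),
                b=float(row.b),
                evaluable=bool(row.evaluable),
            )
        )
    return out


def write_scores(results: Sequence[MsiScoreResult], path: str | Path) -> None:
    rows = [r.model_dump() for r in results]
    pd.DataFrame(
        rows, columns=["sample_id", "panel_name", "score", "n_markers_used", "call"]
    ).to_csv(path, sep="\t", index=False)


def write_ihc_measurements(
    measurements: Sequence[IhcMeasurement], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            **{g: m.positivity[g] for g in GENES},
            "internal_control_present": m.internal_control_present,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ihc_measurements(path: str | Path) -> list[IhcMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        IhcMeasurement(
            sample_id=str(row["sample_id"]),
            positivity={g: float(row[g]) for g in GENES},
            internal_control_present=bool(row["internal_control_present"]),
        )
        for row in df.to_dict(orient="records")
    ]
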