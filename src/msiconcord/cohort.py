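"""Cohort table I/O (TSV, one sample per row)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .models import SampleRecord

REQUIRED_COLUMNS = [
    "sample_id",
    "carrier_status",
    "gene",
    "variant_class",
    "location",
    "age_at_diagnosis",
    "block_age",
    "dna_conc",
]
OPTIONAL_COLUMNS = ["truth_mmr"]


def read_cohort_table(path: str | Path) -> list[SampleRecord]:
    """Read and validate a cohort TSV.

    ``truth_mmr`` is optional (absent in real-data mode); any missing
    required column raises ``ValueError`` naming it, and rows with
    unknown categories are rejected by validation.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {', '.join(missing)}")
    records = []
    for row in df.to_dict(orient="records"):
        truth = row.get("truth_mmr")
        if truth is not None and pd.isna(truth):
            truth = None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                carrier_status=row["carrier_status"],
                gene=row["gene"],
                variant_class=row["variant_class"],
                location=row["location"],
                age_at_diagnosis=float(row["age_at_diagnosis"]),
                block_age=float(row["block_age"]),
                dna_conc=float(row["dna_conc"]),
                truth_mmr=truth,
            )
        )
    return records


def write_cohort_table(
    samples: Iterable[SampleRecord], path: str | Path, include_truth: bool = True
) -> None:
    cols: Sequence[str] = REQUIRED_COLUMNS + (OPTIONAL_COLUMNS if include_truth else [])
    rows = [s.model_dump(include=set(cols)) for s in samples]
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, sep="\t", index=False)
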