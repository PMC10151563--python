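"""Marker registry: loading, writing and the default synthetic panels.

The three panels mirror the assays under comparison: ``promega5`` holds
the five classical fragment-length markers (BAT-25, BAT-26, NR-21,
NR-24, MONO-27); ``seq24`` and ``seq54`` are sequencing panels of 24 and
54 mononucleotide repeats. The true genomic identities of the
sequencing markers are not modelled — the default registry generates
plausible poly-A/T repeats with reproducible flanks from a fixed
internal seed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import PANEL_SIZES, MarkerDef, Panel

logger = logging.getLogger(__name__)

REGISTRY_COLUMNS = [
    "marker_id",
    "repeat_base",
    "ref_len",
    "left_flank",
    "right_flank",
    "panel_tags",
]

# Canonical repeat lengths of the five fragment-length assay markers.
_PROMEGA5 = [
    ("BAT-25", "A", 25),
    ("BAT-26", "A", 26),
    ("NR-21", "A", 21),
    ("NR-24", "A", 24),
    ("MONO-27", "A", 27),
]

_DEFAULT_REGISTRY_SEED = 714025


def load_marker_registry(path: str | Path) -> list[MarkerDef]:
    """Read a TSV marker registry into validated :class:`MarkerDef` rows.

    An empty file yields an empty list (with a warning); duplicate marker
    ids or malformed bases raise ``ValueError``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("marker registry %s is empty", path)
        return []
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry missing column(s): {', '.join(missing)}")
    markers = []
    for row in df.itertuples(index=False):
        tags = tuple(t for t in str(row.panel_tags).split(",") if t)
        markers.append(
            MarkerDef(
                marker_id=row.marker_id,
                repeat_base=row.repeat_base,
                ref_len=int(row.ref_len),
                left_flank=row.left_flank,
                right_flank=row.right_flank,
                panel_tags=tags,
            )
        )
    ids = [m.marker_id for m in markers]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate marker_id in registry: {sorted(dupes)}")
    return markers


def write_marker_registry(markers: Iterable[MarkerDef], path: str | Path) -> None:
    rows = [
        {
            "marker_id": m.marker_id,
            "repeat_base": m.repeat_base,
            "ref_len": m.ref_len,
            "left_flank": m.left_flank,
            "right_flank": m.right_flank,
            "panel_tags": ",".join(m.panel_tags),
        }
        for m in markers
    ]
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


def _random_flank(rng: np.random.Generator, repeat_base: str, length: int = 10) -> str:
    """Flank with no run of the repeat base longer than 3 and repeat-base-free ends."""
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(rng.choice(bases, size=length))
        run = best = 0
        for ch in seq:
            run = run + 1 if ch == repeat_base else 0
            best = max(best, run)
        if best <= 3 and seq[0] != repeat_base and seq[-1] != repeat_base:
            return seq


def default_registry(seed: int = _DEFAULT_REGISTRY_SEED) -> list[MarkerDef]:
    """Generate the built-in synthetic registry (5 + 24 + 54 markers).

    Marker identities are synthetic stand-ins: repeat lengths are drawn
    uniformly from 7-27 bases and flanks are random anchors, all from a
    fixed seed so every run sees the same registry.
    """
    rng = np.random.default_rng(seed)
    markers: list[MarkerDef] = []
    for marker_id, base, ref_len in _PROMEGA5:
        markers.append(
            MarkerDef(
                marker_id=marker_id,
                repeat_base=base,
                ref_len=ref_len,
                left_flank=_random_flank(rng, base),
                right_flank=_random_flank(rng, base),
                panel_tags=("promega5",),
            )
        )
    for prefix, n, tag in [("CR", 24, "seq24"), ("BL", 54, "seq54")]:
        for i in range(1, n + 1):
            base = rng.choice(["A", "T"])
            markers.append(
                MarkerDef(
                    marker_id=f"{prefix}{i:02d}",
                    repeat_base=str(base),
                    ref_len=int(rng.integers(7, 28)),
                    left_flank=_random_flank(rng, str(base)),
                    right_flank=_random_flank(rng, str(base)),
                    panel_tags=(tag,),
                )
            )
    return markers


def build_panels(markers: Sequence[MarkerDef]) -> dict[str, Panel]:
    """Index markers by panel tag and validate the default panel sizes."""
    by_tag: dict[str, list[str]] = {name: [] for name in PANEL_SIZES}
    for m in markers:
        for tag in m.panel_tags:
            by_tag[tag].append(m.marker_id)
    panels = {}
    for name, ids in by_tag.items():
        if not ids:
            continue
        if len(ids) != PANEL_SIZES[name]:
            raise ValueError(
                f"panel {name} has {len(ids)} markers, expected {PANEL_SIZES[name]}"
            )
        panels[name] = Panel(name=name, marker_ids=tuple(ids))
    return panels


def marker_index(markers: Sequence[MarkerDef]) -> dict[str, MarkerDef]:
    return {m.marker_id: m for m in markers}
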