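"""Reduce amplicon reads or length histograms to per-marker features.

The classifier consumes two features per marker: the deletion frequency
``d`` (fraction of reads strictly shorter than the reference repeat
length — no matched normal, the germline allele is assumed at
reference) and the allelic bias ``b`` (fraction of deleted reads at the
single modal deleted length). Markers below ``min_depth`` reads are
non-evaluable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from Bio import SeqIO

from .models import (
    LengthHistogram,
    MarkerDef,
    MarkerProfile,
    Panel,
    ProfilingConfig,
)

logger = logging.getLogger(__name__)


def extract_repeat_lengths(
    reads: Union[str, Path, Iterable],
    marker: MarkerDef,
) -> Optional[LengthHistogram]:
    """Tally between-flank repeat lengths from FASTQ reads.

    A read counts only if it contains the exact left and right flank
    with nothing but the repeat base between them; all other reads are
    discarded (and the discard count logged). Returns ``None`` when no
    read matched.
    """
    if isinstance(reads, (str, Path)):
        records = SeqIO.parse(str(reads), "fastq")
    else:
        records = iter(reads)
    counts: dict[int, int] = {}
    n_discarded = 0
    for rec in records:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        start = seq.find(marker.left_flank)
        if start < 0:
            n_discarded += 1
            continue
        start += len(marker.left_flank)
        end = seq.find(marker.right_flank, start)
        if end < 0:
            n_discarded += 1
            continue
        between = seq[start:end]
        if between.strip(marker.repeat_base):
            n_discarded += 1
            continue
        counts[len(between)] = counts.get(len(between), 0) + 1
    if n_discarded:
        logger.info("%s: discarded %d reads without clean flanks", marker.marker_id, n_discarded)
    if not counts:
        return None
    return LengthHistogram(marker_id=marker.marker_id, counts=counts)


def profile_marker(
    hist: LengthHistogram,
    marker: MarkerDef,
    config: ProfilingConfig | None = None,
) -> MarkerProfile:
    """Compute (depth, d, b, evaluable) for one marker.

    Ties for the modal deleted length break toward the larger deletion
    (shorter read) so output is deterministic.
    """
    config = config or ProfilingConfig()
    if hist.marker_id != marker.marker_id:
        raise ValueError(
            f"histogram {hist.marker_id} does not match marker {marker.marker_id}"
        )
    depth = hist.depth
    deleted = {l: c for l, c in hist.counts.items() if l < marker.ref_len and c > 0}
    n_del = sum(deleted.values())
    d = n_del / depth
    if n_del:
        modal = min((l for l in deleted), key=lambda l: (-deleted[l], l))
        b = deleted[modal] / n_del
    else:
        b = 0.0
    return MarkerProfile(
        marker_id=marker.marker_id,
        depth=depth,
        d=d,
        b=b,
        evaluable=depth >= config.min_depth,
    )


def profile_sample(
    histograms: Mapping[str, LengthHistogram],
    panel: Panel,
    markers: Mapping[str, MarkerDef],
    config: ProfilingConfig | None = None,
) -> list[MarkerProfile]:
    """One profile per panel marker, in panel order.

    Markers without a histogram yield empty, non-evaluable profiles so
    every downstream consumer sees a full-length, ordered list.
    """
    config = config or ProfilingConfig()
    extra = set(histograms) - set(panel.marker_ids)
    if extra:
        logger.info("ignoring %d histograms outside panel %s", len(extra), panel.name)
    profiles = []
    for mid in panel.marker_ids:
        if mid in histograms:
            profiles.append(profile_marker(histograms[mid], markers[mid], config))
        else:
            profiles.append(
                MarkerProfile(marker_id=mid, depth=0, d=0.0, b=0.0, evaluable=False)
            )
    return profiles
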