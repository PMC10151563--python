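"""The two rule-based assays: fragment-length marker calls and IHC loss.

Fragment-length rule: a secondary allele with >= 20% of reads shifted by
3+ bp from the reference repeat length is unstable; 1-2 bp is only
suggestive (non-evaluable without germline DNA). Sample rule without a
matched normal: 3+ unstable markers = MSI-H. IHC rule: a protein
expressed in <= 10% of tumor cells (with internal control) is lost.
"""

from msiconcord import (
    IhcMeasurement,
    LengthHistogram,
    call_marker_shift,
    classify_promega,
    classify_sample_ihc,
    default_registry,
    marker_index,
)

midx = marker_index(default_registry())

# one unstable (-4 bp), one suggestive (-2 bp), three stable markers
observed = {
    "BAT-25": {25: 1100, 21: 900},
    "BAT-26": {26: 1400, 24: 600},
    "NR-21": {21: 2000},
    "NR-24": {24: 1900, 23: 100},
    "MONO-27": {27: 2000},
}
calls = [
    call_marker_shift(LengthHistogram(marker_id=mid, counts=c), midx[mid])
    for mid, c in observed.items()
]
for c in calls:
    print(f"{c.marker_id:>8}: {c.status}")
res = classify_promega(calls, "demo")
print(f"sample: {res.n_unstable} unstable -> {res.raw_class} "
      f"(pooled: {res.pooled_class})")
# The suggestive BAT-26 trace makes the sample non-evaluable: without
# germline DNA a 2 bp shift cannot be distinguished from a polymorphism.

measurement = IhcMeasurement(
    sample_id="demo",
    positivity={"MLH1": 0.85, "MSH2": 0.03, "MSH6": 0.07, "PMS2": 0.90},
    internal_control_present=True,
)
ihc = classify_sample_ihc(measurement, family_gene="MSH2")
print(f"IHC: lost {sorted(ihc.lost_set)} -> {ihc.sample_status}, "
      f"pattern consistent with MSH2 family: {ihc.pattern_consistent}")
# MSH2 loss drags MSH6 down with it (MutS-alpha heterodimer), exactly the
# pattern expected for an MSH2 family.
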