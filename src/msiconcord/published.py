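"""Published confusion counts from a Lynch-syndrome urothelial cancer
study comparing IHC with three MSI assays.

These frozen counts let the concordance framework be exercised against
the study's reported statistics without any sequence data. Confusion
cells follow the (a, b, c, d) convention of :mod:`msiconcord.stats`
with IHC as reference. Where the study's stratified table disagreed
internally with its prose for the 24-marker assay, the prose counts are
used.
"""

from __future__ import annotations

from .stats import ConfusionTable

#: Fragment-length (Promega-style) assay vs IHC, n=68 evaluable pairs.
PROMEGA_VS_IHC = ConfusionTable(a=45, b=17, c=3, d=3)

#: 24-marker sequencing assay vs IHC, n=72 evaluable pairs.
SEQ24_VS_IHC = ConfusionTable(a=54, b=8, c=1, d=9)

#: 54-marker sequencing assay vs IHC, n=72 evaluable pairs.
SEQ54_VS_IHC = ConfusionTable(a=58, b=4, c=3, d=7)

#: Discordant pairs between the two sequencing panels: six tumors were
#: MSS under the 24-marker panel but MSI-H under the 54-marker panel,
#: none the reverse.
PANEL_DISCORDANT = (6, 0)

#: Published 2x2 cohort contingency tables (rows x columns as noted).
FISHER_TABLES: dict[str, list[list[int]]] = {
    # MMR protein loss vs retained, carriers vs first-degree relatives
    "mmr_loss_carrier_vs_fdr": [[69, 5], [17, 6]],
    # retained vs loss, upper vs lower urinary tract (whole cohort)
    "retained_by_location": [[2, 59], [9, 27]],
    # retained vs loss by tract, first-degree relatives only
    "retained_by_location_fdr": [[1, 14], [5, 3]],
    # retained vs loss by tract, carriers only
    "retained_by_location_carrier": [[1, 45], [4, 24]],
}

CONFUSION_BY_ASSAY: dict[str, ConfusionTable] = {
    "promega": PROMEGA_VS_IHC,
    "seq24": SEQ24_VS_IHC,
    "seq54": SEQ54_VS_IHC,
}
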