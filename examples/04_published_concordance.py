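"""Recompute the published agreement statistics from the bundled counts.

The package ships the study's confusion counts (IHC as reference vs each
MSI assay) and recomputes concordance with Wilson intervals, sensitivity
and specificity with exact Clopper-Pearson intervals, and the exact
McNemar test on the discordant pairs.
"""

from msiconcord import ReportBundle, make_concordance_report, mcnemar_exact, render_table
from msiconcord.published import CONFUSION_BY_ASSAY, FISHER_TABLES, PANEL_DISCORDANT
from msiconcord.stats import fisher_exact_2x2

bundle = ReportBundle(
    reports={
        name: make_concordance_report(ct, name)
        for name, ct in CONFUSION_BY_ASSAY.items()
    }
)
print(render_table(bundle))

b, c = PANEL_DISCORDANT
print(f"24- vs 54-marker panel: {b} vs {c} discordant tumors, "
      f"exact McNemar p = {mcnemar_exact(b, c):.5f}")
for name, table in FISHER_TABLES.items():
    print(f"Fisher exact, {name}: p = {fisher_exact_2x2(table):.3f}")
# The fragment-length assay agrees with IHC for only ~71% of tumors
# (p = 0.003: it systematically under-calls deficiency), while the
# 54-marker sequencing assay reaches 90.3% with no significant asymmetry.
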