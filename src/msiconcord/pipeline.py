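"""End-to-end study runner: simulate -> profile -> train -> classify ->
compare, producing a :class:`~msiconcord.report.ReportBundle`.

This mirrors the study design: a 97-tumor Lynch-syndrome urothelial
cohort is assessed by IHC (reference), a fragment-length five-marker
assay, and sequencing MSI classifiers trained on a separate 50 MSI-H +
52 MSS colorectal reference cohort, once with a 24-marker and once with
a 54-marker panel; per-assay 2x2 concordance and the panel-vs-panel
exact McNemar test are then computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bayes import ClassifierConfig, MsiScoreResult, TrainedClassifier, fit_classifier, score_sample
from .ihc import IhcResult, classify_sample_ihc
from .models import MarkerDef, Panel, ProfilingConfig, SampleRecord, StatsConfig
from .profiling import profile_sample
from .promega import PromegaResult, classify_promega
from .registry import build_panels, default_registry, marker_index
from .report import ReportBundle
from .simulate import (
    SimulationConfig,
    TruthTable,
    apply_dna_qc,
    generate_cohort,
    simulate_ihc,
    simulate_length_histograms,
    simulate_promega_calls,
    simulate_training_cohort,
)
from .stats import build_confusion, compare_panels_mcnemar, make_concordance_report

SEQ_PANELS = ("seq24", "seq54")


@dataclass
class StudyResult:
    samples: list[SampleRecord]
    truth: TruthTable
    excluded: list
    classifiers: dict[str, TrainedClassifier]
    msi_results: dict[str, dict[str, MsiScoreResult]]
    promega_results: dict[str, PromegaResult]
    ihc_results: dict[str, IhcResult]
    bundle: ReportBundle
    panel_comparison: tuple[int, int, float]
    cv_accuracy: Optional[float] = None


def run_study(
    config: SimulationConfig | None = None,
    markers: Optional[list[MarkerDef]] = None,
    stats_config: StatsConfig | None = None,
) -> StudyResult:
    """Run the full synthetic study under ``config`` (seeded, deterministic)."""
    config = config or SimulationConfig()
    stats_config = stats_config or StatsConfig()
    markers = markers if markers is not None else default_registry()
    panels = build_panels(markers)
    midx = marker_index(markers)
    seq_markers = [m for m in markers if any(t in SEQ_PANELS for t in m.panel_tags)]
    union_panel = Panel.model_construct(
        name="seq54", marker_ids=tuple(m.marker_id for m in seq_markers)
    )
    prof_cfg = ProfilingConfig(target_depth=config.depth)

    ss = np.random.SeedSequence(config.seed)
    rng_cohort, rng_train, rng_hist, rng_prom, rng_ihc = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    samples, truth = generate_cohort(config, seq_markers, rng_cohort)
    kept, excluded = apply_dna_qc(samples, config)

    # train one classifier per sequencing panel on the shared reference cohort
    train_hists, train_labels = simulate_training_cohort(config, seq_markers, rng_train)
    classifiers: dict[str, TrainedClassifier] = {}
    train_profiles_by_panel: dict[str, dict] = {}
    for pname in SEQ_PANELS:
        profiles = {
            sid: profile_sample(h, panels[pname], midx, prof_cfg)
            for sid, h in train_hists.items()
        }
        train_profiles_by_panel[pname] = profiles
        classifiers[pname] = fit_classifier(
            profiles, train_labels, pname, ClassifierConfig(), seed=config.seed
        )

    # sequencing assays on the study cohort
    msi_results: dict[str, dict[str, MsiScoreResult]] = {p: {} for p in SEQ_PANELS}
    for s in kept:
        t = truth.samples[s.sample_id]
        if not t.seq_evaluable:
            continue
        hists = simulate_length_histograms(s, t, union_panel, midx, config, rng_hist)
        for pname in SEQ_PANELS:
            profiles = profile_sample(hists, panels[pname], midx, prof_cfg)
            msi_results[pname][s.sample_id] = score_sample(
                profiles, classifiers[pname], s.sample_id
            )

    # fragment-length assay
    promega_results: dict[str, PromegaResult] = {}
    for s in kept:
        t = truth.samples[s.sample_id]
        if not t.promega_evaluable:
            continue
        calls = simulate_promega_calls(s, t, config, rng_prom)
        promega_results[s.sample_id] = classify_promega(calls, s.sample_id)

    # IHC runs on every sample (no DNA requirement)
    ihc_results = {
        s.sample_id: classify_sample_ihc(
            simulate_ihc(s, truth.samples[s.sample_id], config, rng_ihc), s.gene
        )
        for s in samples
    }

    ihc_status = {sid: r.sample_status for sid, r in ihc_results.items()}
    reports = {}
    pooled_by_assay: dict[str, dict[str, str]] = {}
    for assay in ("promega",) + SEQ_PANELS:
        pooled: dict[str, str] = {}
        for sid in ihc_status:
            if assay == "promega":
                res = promega_results.get(sid)
                pooled[sid] = res.pooled_class if res is not None else "NE"
            else:
                sres = msi_results[assay].get(sid)
                if sres is None or sres.call == "NE":
                    pooled[sid] = "NE"
                else:
                    pooled[sid] = (
                        "pooled MSI-H" if sres.call == "MSI-H" else "pooled MSS/MSI-L"
                    )
        pooled_by_assay[assay] = pooled
        table, dropped = build_confusion(ihc_status, pooled)
        reports[assay] = make_concordance_report(table, assay, stats_config, dropped)

    common = [
        sid
        for sid in ihc_status
        if pooled_by_assay["seq24"][sid] != "NE" and pooled_by_assay["seq54"][sid] != "NE"
    ]
    calls24 = {sid: msi_results["seq24"][sid].call for sid in common}
    calls54 = {sid: msi_results["seq54"][sid].call for sid in common}
    panel_cmp = compare_panels_mcnemar(calls24, calls54)

    n_deficient = sum(
        1 for t in truth.samples.values() if t.truth_mmr == "deficient"
    )
    bundle = ReportBundle(
        reports=reports,
        cohort_summary={
            "n_samples": len(samples),
            "n_deficient": n_deficient,
            "n_excluded_dna": len(excluded),
            "n_promega_evaluated": len(promega_results),
            "n_seq_evaluated": len(msi_results["seq54"]),
        },
        provenance={
            "seed": config.seed,
            "depth": config.depth,
            "panel_sizes": {p: len(panels[p]) for p in panels},
            "training": {"MSI-H": config.training_n_msih, "MSS": config.training_n_mss},
        },
    )
    return StudyResult(
        samples=samples,
        truth=truth,
        excluded=excluded,
        classifiers=classifiers,
        msi_results=msi_results,
        promega_results=promega_results,
        ihc_results=ihc_results,
        bundle=bundle,
        panel_comparison=panel_cmp,
    )
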