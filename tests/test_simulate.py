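"""Synthetic cohort generator: marginals, noise model, assay emulation, QC."""

import numpy as np
import pydantic
import pytest

from msiconcord import (
    SampleRecord,
    SimulationConfig,
    apply_dna_qc,
    expected_deletion_frequency,
    generate_cohort,
    simulate_ihc,
    simulate_length_histograms,
    simulate_promega_calls,
)
from msiconcord.simulate import SampleTruth, TruthTable, dropout_probability, stutter_pmf


def _one_sample(samples, truth, status="deficient", gene=None):
    for s in samples:
        t = truth.samples[s.sample_id]
        if t.truth_mmr == status and (gene is None or s.gene == gene):
            return s, t
    raise AssertionError(f"no {status} sample found")


class TestGenerateCohort:
    def test_marginals_exact(self, default_config, seq_markers, rng):
        samples, _ = generate_cohort(default_config, seq_markers, rng)
        assert len(samples) == 97
        genes = {g: sum(s.gene == g for s in samples) for g in ("MLH1", "MSH2", "MSH6", "PMS2")}
        assert genes == {"MLH1": 9, "MSH2": 64, "MSH6": 23, "PMS2": 1}
        assert sum(s.carrier_status == "carrier" for s in samples) == 74
        assert sum(s.location == "renal_pelvis" for s in samples) == 34

    def test_deterministic_given_seed(self, default_config, seq_markers):
        a = generate_cohort(default_config, seq_markers)
        b = generate_cohort(default_config, seq_markers)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_fdr_noncarrier_zero_means_all_fdr_deficient(self, seq_markers):
        cfg = SimulationConfig(seed=3, fdr_noncarrier_prob=0.0)
        samples, truth = generate_cohort(cfg, seq_markers)
        for s in samples:
            if s.carrier_status == "FDR":
                assert truth.samples[s.sample_id].truth_mmr == "deficient"

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(pydantic.ValidationError, match="gene_counts"):
            SimulationConfig(gene_counts={"MLH1": 1, "MSH2": 1, "MSH6": 1, "PMS2": 1})

    def test_proficient_samples_have_no_somatic_alleles(self, default_config, seq_markers):
        _, truth = generate_cohort(default_config, seq_markers)
        for t in truth.samples.values():
            if t.truth_mmr == "proficient":
                assert all(f == 0 for f in t.somatic_fraction.values())

    def test_truth_table_invariant_enforced(self):
        with pytest.raises(pydantic.ValidationError, match="somatic"):
            TruthTable(
                samples={
                    "S1": SampleTruth(
                        truth_mmr="proficient", somatic_fraction={"M": 0.2}
                    )
                }
            )


class TestLengthHistograms:
    def test_no_stutter_proficient_all_reads_at_ref(self, panels, midx, rng):
        cfg = SimulationConfig(seed=1, stutter_rate=0.0, depth=500)
        s = _mk_sample()
        t = SampleTruth(truth_mmr="proficient")
        hists = simulate_length_histograms(s, t, panels["seq24"], midx, cfg, rng)
        for mid, h in hists.items():
            assert h.counts == {midx[mid].ref_len: 500}

    def test_conservation_total_equals_depth(self, panels, midx, fast_config, rng):
        s = _mk_sample()
        t = SampleTruth(
            truth_mmr="deficient",
            somatic_fraction={m: 0.3 for m in panels["seq24"].marker_ids},
            del_size={m: 4 for m in panels["seq24"].marker_ids},
        )
        hists = simulate_length_histograms(s, t, panels["seq24"], midx, fast_config, rng)
        assert all(h.depth == fast_config.depth for h in hists.values())

    def test_closed_form_deletion_frequency_no_stutter(self, panels, midx, rng):
        # purity 0.6 x clonal 0.5 with no stutter: deletion frequency 0.30
        cfg = SimulationConfig(seed=1, stutter_rate=0.0, depth=2000)
        mid = panels["seq24"].marker_ids[0]
        marker = midx[mid]
        assert expected_deletion_frequency(marker.ref_len, 0.30, 4, cfg) == pytest.approx(0.30)
        t = SampleTruth(
            truth_mmr="deficient", somatic_fraction={mid: 0.30}, del_size={mid: 4}
        )
        panel_one = panels["seq24"].model_copy(update={"marker_ids": (mid,)})
        n_del = []
        for _ in range(30):
            h = simulate_length_histograms(_mk_sample(), t, panel_one, midx, cfg, rng)[mid]
            n_del.append(sum(c for l, c in h.counts.items() if l < marker.ref_len))
        exp = 0.30 * cfg.depth
        sd = np.sqrt(cfg.depth * 0.30 * 0.70)
        assert abs(np.mean(n_del) - exp) < 3 * sd / np.sqrt(len(n_del))

    def test_closed_form_matches_simulation_with_stutter(self, panels, midx, rng):
        cfg = SimulationConfig(seed=1, depth=2000)
        mid = panels["seq24"].marker_ids[3]
        marker = midx[mid]
        p = expected_deletion_frequency(marker.ref_len, 0.25, 3, cfg)
        t = SampleTruth(
            truth_mmr="deficient", somatic_fraction={mid: 0.25}, del_size={mid: 3}
        )
        panel_one = panels["seq24"].model_copy(update={"marker_ids": (mid,)})
        h = simulate_length_histograms(_mk_sample(), t, panel_one, midx, cfg, rng)[mid]
        n_del = sum(c for l, c in h.counts.items() if l < marker.ref_len)
        assert abs(n_del - p * cfg.depth) < 3 * np.sqrt(cfg.depth * p * (1 - p))

    def test_stutter_pmf_sums_to_one(self):
        for lam in (0.0, 0.05, 0.3):
            pmf = stutter_pmf(20, lam, 0.1)
            assert sum(pmf.values()) == pytest.approx(1.0)

    def test_effect_size_ordering(self, panels, midx, fast_config, rng):
        """Mean deletion frequency is higher for deficient than proficient tumors."""
        panel = panels["seq24"]
        t_def = SampleTruth(
            truth_mmr="deficient",
            somatic_fraction={m: 0.15 for m in panel.marker_ids},
            del_size={m: 2 for m in panel.marker_ids},
        )
        t_pro = SampleTruth(truth_mmr="proficient")
        h_def = simulate_length_histograms(_mk_sample(), t_def, panel, midx, fast_config, rng)
        h_pro = simulate_length_histograms(_mk_sample(), t_pro, panel, midx, fast_config, rng)
        for mid in panel.marker_ids:
            ref = midx[mid].ref_len
            d_def = sum(c for l, c in h_def[mid].counts.items() if l < ref)
            d_pro = sum(c for l, c in h_pro[mid].counts.items() if l < ref)
            assert d_def > d_pro

    def test_unknown_marker_raises(self, panels, fast_config, rng):
        t = SampleTruth(truth_mmr="proficient")
        with pytest.raises(KeyError):
            simulate_length_histograms(_mk_sample(), t, panels["seq24"], {}, fast_config, rng)


class TestPromegaSimulation:
    def test_binomial_expectation_deficient(self, rng):
        cfg = SimulationConfig(seed=1, marker_instability_prob=0.9, suggestive_prob=0.0)
        s = _mk_sample(gene="MSH2")
        t = SampleTruth(truth_mmr="deficient")
        counts = [
            sum(v == "unstable" for v in simulate_promega_calls(s, t, cfg, rng).values())
            for _ in range(1000)
        ]
        sd = np.sqrt(5 * 0.9 * 0.1)
        assert abs(np.mean(counts) - 4.5) < 3 * sd / np.sqrt(1000)

    def test_proficient_no_false_positives(self, rng):
        cfg = SimulationConfig(seed=1, promega_fp_rate=0.0, suggestive_prob=0.0)
        t = SampleTruth(truth_mmr="proficient")
        calls = simulate_promega_calls(_mk_sample(), t, cfg, rng)
        assert set(calls.values()) == {"stable"}

    def test_no_suggestive_when_disabled(self, rng):
        cfg = SimulationConfig(seed=1, suggestive_prob=0.0)
        t = SampleTruth(truth_mmr="deficient")
        for _ in range(100):
            calls = simulate_promega_calls(_mk_sample(), t, cfg, rng)
            assert "suggestive" not in calls.values()


class TestIhcSimulation:
    def test_deficient_msh2_loses_heterodimer(self, default_config, rng):
        s = _mk_sample(gene="MSH2")
        t = SampleTruth(truth_mmr="deficient")
        below = {"MSH2": 0, "MSH6": 0, "MLH1": 0, "PMS2": 0}
        n = 500
        for _ in range(n):
            m = simulate_ihc(s, t, default_config, rng)
            for protein in below:
                below[protein] += m.positivity[protein] <= 0.10
        assert below["MSH2"] / n > 0.85 and below["MSH6"] / n > 0.85
        assert below["MLH1"] / n < 0.05 and below["PMS2"] / n < 0.05

    def test_proficient_all_retained(self, default_config, rng):
        t = SampleTruth(truth_mmr="proficient")
        n_ok = sum(
            all(pi > 0.10 for pi in simulate_ihc(_mk_sample(), t, default_config, rng).positivity.values())
            for _ in range(500)
        )
        assert n_ok / 500 > 0.95

    def test_missense_retention(self, rng):
        cfg = SimulationConfig(seed=1, missense_retention_prob=1.0)
        s = _mk_sample(gene="MSH6", variant_class="missense")
        t = SampleTruth(truth_mmr="deficient")
        for _ in range(50):
            m = simulate_ihc(s, t, cfg, rng)
            assert all(pi > 0.10 for pi in m.positivity.values())


class TestDnaQc:
    @pytest.mark.parametrize(
        "conc,kept", [(0.5, False), (1.5, True), (1.0, False)]
    )
    def test_threshold_strictly_above(self, default_config, conc, kept):
        samples = [_mk_sample(dna_conc=conc)]
        kept_s, excluded = apply_dna_qc(samples, default_config)
        assert (len(kept_s) == 1) is kept
        if not kept:
            assert excluded[0][1] == "dna_conc"

    def test_negative_concentration_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            _mk_sample(dna_conc=-1.0)

    def test_dropout_monotone_in_block_age(self, default_config):
        ages = np.linspace(0, 60, 50)
        probs = [dropout_probability(a, default_config) for a in ages]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_block_age_dropout_applied_with_rng(self, default_config):
        rng = np.random.default_rng(0)
        samples = [_mk_sample(sample_id=f"S{i}", block_age=80.0) for i in range(50)]
        kept, excluded = apply_dna_qc(samples, default_config, rng)
        assert len(excluded) > len(kept)  # sigmoid(-3 + .08*80) ~ 0.97


def _mk_sample(**kw):
    base = dict(
        sample_id="S1",
        carrier_status="carrier",
        gene="MSH2",
        variant_class="truncating",
        location="bladder",
        age_at_diagnosis=60.0,
        block_age=10.0,
        dna_conc=5.0,
        truth_mmr="deficient",
    )
    base.update(kw)
    return SampleRecord(**base)
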