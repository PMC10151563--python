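"""Synthetic cohort and assay-data generator.

Generates everything the downstream comparison needs without any real
sequencing data: a 97-tumor Lynch-syndrome urothelial cohort with the
study's marginal composition, per-marker read-length histograms with
FFPE/PCR stutter, fragment-length ("Promega-style") marker calls, IHC
tumor-cell positivity fractions, a labelled 50 MSI-H + 52 MSS training
cohort, and DNA-QC / block-age dropout.

Noise model
-----------
A read at a marker starts from either the germline allele (reference
repeat length) or, with probability ``purity x clonal fraction``, a
somatic deleted allele (reference minus a per-marker deletion size).
PCR slippage then shortens the read by ``k ~ Geometric(stutter_rate)``
repeat units (truncated at the allele length), with rare one-base
insertions at one tenth the stutter rate. Deletion-dominated stutter
mirrors the deletion-only focus of the sequencing classifier. Reads per
marker are drawn in one multinomial of size ``depth`` over the induced
length distribution, which is distributionally identical to per-read
sampling.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .ihc import IhcMeasurement, LOSS_PATTERN
from .models import (
    GENES,
    Gene,
    LengthHistogram,
    MarkerDef,
    MmrStatus,
    Panel,
    SampleRecord,
)
from .promega import PROMEGA5_IDS, MarkerStatus


class SimulationConfig(BaseModel):
    """All knobs of the generator, with study-condition defaults.

    Cohort marginals (gene, carrier status, location) default to the
    study composition and are reproduced exactly, not in expectation.
    Instability probabilities and noise levels are simulation knobs, not
    estimates from data.
    """

    n_samples: int = Field(default=97, gt=0)
    gene_counts: dict[Gene, int] = {"MLH1": 9, "MSH2": 64, "MSH6": 23, "PMS2": 1}
    carrier_counts: dict[str, int] = {"carrier": 74, "FDR": 23}
    location_counts: dict[str, int] = {"ureter": 27, "renal_pelvis": 34, "bladder": 36}
    fdr_noncarrier_prob: float = Field(default=0.25, ge=0, le=1)
    sporadic_bladder_prob: float = Field(default=0.1, ge=0, le=1)
    variant_class_probs: dict[str, float] = {
        "truncating": 0.90,
        "missense": 0.05,
        "unknown": 0.05,
    }

    # read-level noise
    depth: int = Field(default=2000, gt=0)
    stutter_rate: float = Field(default=0.05, ge=0, lt=1)
    insertion_ratio: float = Field(default=0.1, ge=0, le=1)
    purity: float = Field(default=0.6, ge=0, le=1)
    somatic_del_mean: dict[Gene, float] = {
        "MLH1": 4.0,
        "MSH2": 4.0,
        "MSH6": 2.0,
        "PMS2": 4.0,
    }
    somatic_del_sd: float = Field(default=1.5, ge=0)
    clonal_fraction_range: tuple[float, float] = (0.4, 0.9)
    instability_attenuation: dict[Gene, float] = {
        "MLH1": 1.0,
        "MSH2": 1.0,
        "MSH6": 0.5,
        "PMS2": 1.0,
    }

    # fragment-length assay emulation; deficient urothelial tumors often show
    # only subtle shifts, so per-marker detection is well below 1 by default
    marker_instability_prob: float = Field(default=0.6, ge=0, le=1)
    promega_fp_rate: float = Field(default=0.02, ge=0, le=1)
    suggestive_prob: float = Field(default=0.05, ge=0, le=1)

    # IHC emulation
    missense_retention_prob: float = Field(default=0.8, ge=0, le=1)
    ihc_loss_beta: tuple[float, float] = (1.5, 40.0)
    ihc_retained_beta: tuple[float, float] = (20.0, 4.0)
    control_absent_prob: float = Field(default=0.02, ge=0, le=1)

    # sample quality
    dna_qc_threshold: float = Field(default=1.0, ge=0)
    dna_lognorm_mean: float = 3.0
    dna_lognorm_sigma: float = 1.6
    block_age_range: tuple[float, float] = (3.0, 40.0)
    diagnosis_age_mean: float = 63.9
    diagnosis_age_sd: float = 12.0
    dropout_intercept: float = -3.0
    dropout_slope: float = 0.08

    # training cohort (colorectal reference set)
    training_n_msih: int = Field(default=50, gt=0)
    training_n_mss: int = Field(default=52, gt=0)

    seed: int = 0

    @model_validator(mode="after")
    def _counts_consistent(self) -> "SimulationConfig":
        for name, counts in [
            ("gene_counts", self.gene_counts),
            ("carrier_counts", self.carrier_counts),
            ("location_counts", self.location_counts),
        ]:
            if sum(counts.values()) != self.n_samples:
                raise ValueError(f"{name} must sum to n_samples={self.n_samples}")
        if abs(sum(self.variant_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("variant_class_probs must sum to 1")
        lo, hi = self.clonal_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("clonal_fraction_range must be within [0,1] and ordered")
        return self


class SampleTruth(BaseModel):
    """Latent ground truth for one sample (never visible to the assays)."""

    truth_mmr: MmrStatus
    promega_evaluable: bool = True
    seq_evaluable: bool = True
    somatic_fraction: dict[str, float] = {}
    del_size: dict[str, int] = {}


class TruthTable(BaseModel):
    samples: dict[str, SampleTruth]

    @model_validator(mode="after")
    def _proficient_have_no_somatic(self) -> "TruthTable":
        for sid, t in self.samples.items():
            if t.truth_mmr == "proficient" and any(
                f > 0 for f in t.somatic_fraction.values()
            ):
                raise ValueError(f"proficient sample {sid} has somatic alleles")
        return self


def rng_from_seed(seed: int) -> np.random.Generator:
    """The package-wide generator contract: NumPy PCG64 via default_rng."""
    return np.random.default_rng(seed)


def dropout_probability(block_age: float, config: SimulationConfig) -> float:
    """Probability a sample is non-evaluable, logistic in block age."""
    return float(expit(config.dropout_intercept + config.dropout_slope * block_age))


def _draw_marker_truth(
    rng: np.random.Generator,
    markers: Sequence[MarkerDef],
    gene: Gene,
    config: SimulationConfig,
) -> tuple[dict[str, float], dict[str, int]]:
    lo, hi = config.clonal_fraction_range
    atten = config.instability_attenuation[gene]
    delta = config.somatic_del_mean[gene]
    fractions, sizes = {}, {}
    for m in markers:
        clonal = rng.uniform(lo, hi) * atten
        fractions[m.marker_id] = config.purity * clonal
        d = int(round(rng.normal(delta, config.somatic_del_sd)))
        sizes[m.marker_id] = int(np.clip(d, 1, m.ref_len - 1))
    return fractions, sizes


def generate_cohort(
    config: SimulationConfig,
    markers: Sequence[MarkerDef],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SampleRecord], TruthTable]:
    """Draw a cohort whose gene/carrier/location marginals match exactly.

    Covariate label vectors are built with exact counts and shuffled
    independently, so marginals are deterministic while the joint is
    random. Ground truth: FDR tumors are MMR-proficient with
    ``fdr_noncarrier_prob`` (non-carrier relatives), carrier bladder
    tumors with ``sporadic_bladder_prob`` (sporadic origin); all other
    tumors are deficient, with per-marker somatic deletion fractions
    attenuated for MSH6.
    """
    rng = rng if rng is not None else rng_from_seed(config.seed)

    def shuffled(counts: Mapping[str, int]) -> list[str]:
        labels = [lab for lab, n in counts.items() for _ in range(n)]
        return list(rng.permutation(labels))

    genes = shuffled(config.gene_counts)
    carriers = shuffled(config.carrier_counts)
    locations = shuffled(config.location_counts)
    vclasses = list(config.variant_class_probs)
    vprobs = list(config.variant_class_probs.values())

    samples: list[SampleRecord] = []
    truths: dict[str, SampleTruth] = {}
    for i in range(config.n_samples):
        sid = f"S{i + 1:03d}"
        gene, carrier, loc = genes[i], carriers[i], locations[i]
        vclass = vclasses[int(rng.choice(len(vclasses), p=vprobs))]
        if carrier == "FDR" and rng.random() < config.fdr_noncarrier_prob:
            status: MmrStatus = "proficient"
        elif (
            carrier == "carrier"
            and loc == "bladder"
            and rng.random() < config.sporadic_bladder_prob
        ):
            status = "proficient"
        else:
            status = "deficient"
        rec = SampleRecord(
            sample_id=sid,
            carrier_status=carrier,
            gene=gene,
            variant_class=vclass,
            location=loc,
            age_at_diagnosis=float(
                np.clip(rng.normal(config.diagnosis_age_mean, config.diagnosis_age_sd), 31, 89)
            ),
            block_age=float(rng.uniform(*config.block_age_range)),
            dna_conc=float(rng.lognormal(config.dna_lognorm_mean, config.dna_lognorm_sigma)),
            truth_mmr=status,
        )
        p_drop = dropout_probability(rec.block_age, config)
        if status == "deficient":
            fractions, sizes = _draw_marker_truth(rng, markers, gene, config)
        else:
            fractions = {m.marker_id: 0.0 for m in markers}
            sizes = {}
        truths[sid] = SampleTruth(
            truth_mmr=status,
            promega_evaluable=bool(rng.random() >= p_drop),
            seq_evaluable=bool(rng.random() >= p_drop),
            somatic_fraction=fractions,
            del_size=sizes,
        )
        samples.append(rec)
    return samples, TruthTable(samples=truths)


def stutter_pmf(
    allele_len: int, stutter_rate: float, insertion_ratio: float
) -> dict[int, float]:
    """Observed-length distribution for one template allele.

    Mass ``stutter_rate * insertion_ratio`` goes to a one-base
    insertion; the rest is spread over deletions of ``k`` bases with
    truncated-geometric weights ``(1 - lam) * lam**k``, ``k <= allele_len``.
    """
    lam = stutter_rate
    p_ins = lam * insertion_ratio
    pmf: dict[int, float] = {}
    if p_ins > 0:
        pmf[allele_len + 1] = p_ins
    if lam == 0:
        pmf[allele_len] = pmf.get(allele_len, 0.0) + (1.0 - p_ins)
        return pmf
    ks = np.arange(allele_len + 1)
    w = (1 - lam) * lam**ks
    w /= w.sum()
    for k, wk in zip(ks, w):
        pmf[allele_len - int(k)] = pmf.get(allele_len - int(k), 0.0) + (1 - p_ins) * float(wk)
    return pmf


def marker_length_pmf(
    ref_len: int,
    somatic_fraction: float,
    del_size: int,
    config: SimulationConfig,
) -> dict[int, float]:
    """Mixture of germline and somatic alleles, each convolved with stutter."""
    germ = stutter_pmf(ref_len, config.stutter_rate, config.insertion_ratio)
    pmf = {length: (1 - somatic_fraction) * p for length, p in germ.items()}
    if somatic_fraction > 0:
        som = stutter_pmf(
            ref_len - del_size, config.stutter_rate, config.insertion_ratio
        )
        for length, p in som.items():
            pmf[length] = pmf.get(length, 0.0) + somatic_fraction * p
    return pmf


def expected_deletion_frequency(
    ref_len: int, somatic_fraction: float, del_size: int, config: SimulationConfig
) -> float:
    """Closed-form P(read length < reference) under the noise model."""
    pmf = marker_length_pmf(ref_len, somatic_fraction, del_size, config)
    return sum(p for length, p in pmf.items() if length < ref_len)


def simulate_length_histograms(
    sample: SampleRecord,
    truth: SampleTruth,
    panel: Panel,
    markers: Mapping[str, MarkerDef],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, LengthHistogram]:
    """One multinomial draw of ``depth`` reads per panel marker."""
    out: dict[str, LengthHistogram] = {}
    for mid in panel.marker_ids:
        if mid not in markers:
            raise KeyError(f"marker {mid} not in registry")
        marker = markers[mid]
        frac = truth.somatic_fraction.get(mid, 0.0)
        dsize = truth.del_size.get(mid, 1)
        pmf = marker_length_pmf(marker.ref_len, frac, dsize, config)
        lengths = sorted(pmf)
        probs = np.array([pmf[l] for l in lengths])
        probs = probs / probs.sum()
        counts = rng.multinomial(config.depth, probs)
        out[mid] = LengthHistogram(
            marker_id=mid,
            counts={l: int(c) for l, c in zip(lengths, counts) if c > 0},
        )
    return out


def simulate_promega_calls(
    sample: SampleRecord,
    truth: SampleTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, MarkerStatus]:
    """Draw per-marker fragment-length statuses for the five-marker panel.

    Deficient tumors go unstable per marker with a gene-attenuated
    probability; proficient tumors at a small false-positive rate; the
    remainder may be drawn 'suggestive' (trace shifts unresolvable
    without germline DNA) with ``suggestive_prob``.
    """
    atten = config.instability_attenuation[sample.gene]
    if truth.truth_mmr == "deficient":
        p_unstable = config.marker_instability_prob * atten
    else:
        p_unstable = config.promega_fp_rate
    calls: dict[str, MarkerStatus] = {}
    for mid in PROMEGA5_IDS:
        if rng.random() < p_unstable:
            calls[mid] = "unstable"
        elif rng.random() < config.suggestive_prob:
            calls[mid] = "suggestive"
        else:
            calls[mid] = "stable"
    return calls


def simulate_ihc(
    sample: SampleRecord,
    truth: SampleTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> IhcMeasurement:
    """Draw per-protein tumor-cell positivity fractions.

    Deficient tumors lose the affected gene's protein plus its
    heterodimer partner (MutS-alpha / MutL-alpha degradation); missense
    variants retain expression with ``missense_retention_prob`` despite
    functional deficiency. Lost proteins draw positivity from a Beta
    concentrated below the 10% scoring cutoff, retained ones from a Beta
    concentrated well above it.
    """
    lost: set[str] = set()
    if truth.truth_mmr == "deficient":
        if not (
            sample.variant_class == "missense"
            and rng.random() < config.missense_retention_prob
        ):
            lost = set(LOSS_PATTERN[sample.gene])
    a_l, b_l = config.ihc_loss_beta
    a_r, b_r = config.ihc_retained_beta
    positivity = {
        protein: float(rng.beta(a_l, b_l) if protein in lost else rng.beta(a_r, b_r))
        for protein in GENES
    }
    return IhcMeasurement(
        sample_id=sample.sample_id,
        positivity=positivity,
        internal_control_present=bool(rng.random() >= config.control_absent_prob),
    )


def apply_dna_qc(
    samples: Sequence[SampleRecord],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, str]]]:
    """Split a cohort into analyzable and excluded samples.

    A sample is kept only if its double-stranded DNA concentration is
    strictly above the threshold (default 1 ng/uL). When an ``rng`` is
    supplied, additional non-evaluability is drawn from the block-age
    logistic (older FFPE blocks drop out more often).
    """
    kept: list[SampleRecord] = []
    excluded: list[tuple[SampleRecord, str]] = []
    for s in samples:
        if s.dna_conc < 0:
            raise ValueError(f"negative DNA concentration for {s.sample_id}")
        if s.dna_conc <= config.dna_qc_threshold:
            excluded.append((s, "dna_conc"))
        elif rng is not None and rng.random() < dropout_probability(s.block_age, config):
            excluded.append((s, "block_age"))
        else:
            kept.append(s)
    return kept, excluded


def simulate_training_cohort(
    config: SimulationConfig,
    markers: Sequence[MarkerDef],
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, LengthHistogram]], dict[str, str]]:
    """Labelled reference cohort (default 50 MSI-H + 52 MSS) for training.

    MSI-H training tumors carry unattenuated somatic deletions at every
    marker (colorectal-like strong instability); MSS tumors carry none.
    Returns per-sample histograms over all given markers and the label map.
    """
    marker_map = {m.marker_id: m for m in markers}
    panel_all = Panel.model_construct(
        name="seq54", marker_ids=tuple(m.marker_id for m in markers)
    )
    hists: dict[str, dict[str, LengthHistogram]] = {}
    labels: dict[str, str] = {}
    for label, n in [("MSI-H", config.training_n_msih), ("MSS", config.training_n_mss)]:
        for i in range(n):
            sid = f"TR-{label}-{i + 1:03d}"
            if label == "MSI-H":
                fractions, sizes = _draw_marker_truth(rng, markers, "MSH2", config)
                truth = SampleTruth(
                    truth_mmr="deficient",
                    somatic_fraction=fractions,
                    del_size=sizes,
                )
            else:
                truth = SampleTruth(
                    truth_mmr="proficient",
                    somatic_fraction={m.marker_id: 0.0 for m in markers},
                )
            rec = SampleRecord(
                sample_id=sid,
                carrier_status="carrier",
                gene="MSH2",
                variant_class="truncating",
                location="bladder",
                age_at_diagnosis=60.0,
                block_age=5.0,
                dna_conc=50.0,
                truth_mmr=truth.truth_mmr,
            )
            hists[sid] = simulate_length_histograms(
                rec, truth, panel_all, marker_map, config, rng
            )
            labels[sid] = label
    return hists, labels


def histograms_to_fastq(
    histograms: Mapping[str, LengthHistogram],
    markers: Mapping[str, MarkerDef],
    path,
) -> int:
    """Write synthetic reads (left flank + repeat + right flank) as FASTQ.

    Returns the number of reads written. Deterministic: reads are
    emitted in marker order, one record per tallied read.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    n = 0
    for mid in sorted(histograms):
        hist = histograms[mid]
        marker = markers[mid]
        for length in sorted(hist.counts):
            seq = marker.left_flank + marker.repeat_base * length + marker.right_flank
            for _ in range(hist.counts[length]):
                n += 1
                rec = SeqRecord(Seq(seq), id=f"{mid}:{n}", description="")
                rec.letter_annotations["phred_quality"] = [40] * len(seq)
                records.append(rec)
    with open(path, "w") as fh:
        seqio_write(records, fh, "fastq")
    return n
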