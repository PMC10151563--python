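"""Naive-Bayes MSI classifier over per-marker (d, b) features.

Each marker gets class-conditional Beta densities for the deletion
frequency ``d`` and the allelic bias ``b``, fitted by method of moments
on a labelled MSI-H / MSS reference cohort. A sample's MSI score is the
summed per-marker log-likelihood ratio (natural logs, equal class
priors):

    S = sum_m [ log f_MSI-H(d_m) - log f_MSS(d_m)
              + log g_MSI-H(b_m) - log g_MSS(b_m) ]

S > 0 calls the sample MSI-H, S <= 0 calls it MSS (the tie at exactly 0
resolves conservatively to MSS); a sample with fewer than
``min_marker_fraction`` of its panel evaluable is non-evaluable (NE).
Because the fit happens on shrunken frequencies, the same epsilon
shrinkage d' = (d*D + eps) / (D + 2*eps) is applied at scoring time.
The score scale depends on these density choices and is not comparable
across classifier implementations.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy.stats import beta as beta_dist

from .models import MarkerProfile

Label = Literal["MSS", "MSI-H"]
Call = Literal["MSS", "MSI-H", "NE"]


class BetaParams(BaseModel):
    alpha: float = Field(gt=0)
    beta: float = Field(gt=0)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


class MarkerModel(BaseModel):
    d_mss: BetaParams
    d_msih: BetaParams
    b_mss: BetaParams
    b_msih: BetaParams


class ClassifierConfig(BaseModel):
    epsilon: float = Field(default=1.0, ge=0, description="shrinkage pseudocount, reads")
    min_marker_fraction: float = Field(default=0.5, ge=0, le=1)
    # floor on the method-of-moments variance: keeps class-conditional Betas
    # moderately concentrated even when a class is nearly constant, which in
    # turn keeps fitted likelihood ratios monotone over the usable d range
    var_floor: float = Field(default=1e-4, gt=0)
    check_monotone: bool = False


class TrainedClassifier(BaseModel):
    panel_name: str
    models: dict[str, MarkerModel]
    config: ClassifierConfig = ClassifierConfig()
    n_msih: int = 0
    n_mss: int = 0
    seed: Optional[int] = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedClassifier":
        return cls.model_validate(json.loads(Path(path).read_text()))


class MsiScoreResult(BaseModel):
    sample_id: str
    panel_name: str
    score: float
    n_markers_used: int
    call: Call


class CvResult(BaseModel):
    accuracy: float
    fold_calls: list[dict[str, str]]


def _shrink(count: float, total: int, eps: float) -> float:
    """eps-shrunk proportion, strictly inside (0, 1) for eps > 0."""
    return (count + eps) / (total + 2 * eps)


def _fit_beta(values: np.ndarray, var_floor: float) -> BetaParams:
    """Method-of-moments Beta fit with floored (and capped) variance."""
    m = float(np.clip(np.mean(values), 1e-4, 1 - 1e-4))
    v = float(np.var(values))
    v = float(np.clip(v, var_floor, 0.95 * m * (1 - m)))
    common = m * (1 - m) / v - 1.0
    return BetaParams(alpha=m * common, beta=(1 - m) * common)


def fit_classifier(
    profiles_by_sample: Mapping[str, Sequence[MarkerProfile]],
    labels: Mapping[str, Label],
    panel_name: str,
    config: ClassifierConfig | None = None,
    seed: Optional[int] = None,
) -> TrainedClassifier:
    """Fit per-marker class-conditional Beta models on a labelled cohort.

    Deletion frequencies are epsilon-shrunk per sample before fitting so
    all-zero markers still yield finite parameters. Bias models use only
    samples with observed deletions (falling back to the uniform
    Beta(1,1) when a class has none). With ``config.check_monotone`` the
    fitted d-densities must yield a log-likelihood ratio that is
    nondecreasing in d across the region between the two class means, so
    the score cannot drop as instability evidence rises through the
    decision boundary; violating fits are rejected.
    """
    config = config or ClassifierConfig()
    classes = set(labels.values())
    if classes != {"MSS", "MSI-H"}:
        raise ValueError(f"training labels must contain both classes, got {classes}")

    by_marker: dict[str, dict[str, list[MarkerProfile]]] = {}
    for sid, profiles in profiles_by_sample.items():
        for p in profiles:
            if p.evaluable:
                by_marker.setdefault(p.marker_id, {"MSS": [], "MSI-H": []})[
                    labels[sid]
                ].append(p)

    marker_ids = sorted(by_marker)
    if not marker_ids:
        raise ValueError("no evaluable markers in training data")
    models: dict[str, MarkerModel] = {}
    eps = config.epsilon
    for mid in marker_ids:
        fits: dict[str, BetaParams] = {}
        for cls_label, ps in by_marker[mid].items():
            if not ps:
                raise ValueError(f"marker {mid} absent from all {cls_label} training samples")
            d_shrunk = np.array([_shrink(p.n_deleted, p.depth, eps) for p in ps])
            fits[f"d_{cls_label}"] = _fit_beta(d_shrunk, config.var_floor)
            with_del = [p for p in ps if p.d > 0]
            if with_del:
                b_shrunk = np.array(
                    [_shrink(p.b * p.n_deleted, p.n_deleted, eps) for p in with_del]
                )
                fits[f"b_{cls_label}"] = _fit_beta(b_shrunk, config.var_floor)
            else:
                fits[f"b_{cls_label}"] = BetaParams(alpha=1.0, beta=1.0)
        model = MarkerModel(
            d_mss=fits["d_MSS"],
            d_msih=fits["d_MSI-H"],
            b_mss=fits["b_MSS"],
            b_msih=fits["b_MSI-H"],
        )
        if config.check_monotone and not _lr_monotone(model.d_msih, model.d_mss):
            raise ValueError(
                f"marker {mid}: fitted d-densities are not monotone in d "
                "over the decision range"
            )
        models[mid] = model

    return TrainedClassifier(
        panel_name=panel_name,
        models=models,
        config=config,
        n_msih=sum(1 for v in labels.values() if v == "MSI-H"),
        n_mss=sum(1 for v in labels.values() if v == "MSS"),
        seed=seed,
    )


def _lr_monotone(msih: BetaParams, mss: BetaParams, n_grid: int = 101) -> bool:
    """True when the log-LR is nondecreasing between the two class means.

    Beta pairs with unequal concentrations are not globally MLR-ordered;
    what the classifier needs is that the score cannot drop as d rises
    through the decision region separating the class means.
    """
    lo, hi = sorted([mss.mean, msih.mean])
    grid = np.linspace(lo, hi, n_grid)
    lr = beta_dist.logpdf(grid, msih.alpha, msih.beta) - beta_dist.logpdf(
        grid, mss.alpha, mss.beta
    )
    return bool(np.all(np.diff(lr) >= -1e-9))


def _log_ratio(x: float, hi: BetaParams, lo: BetaParams) -> float:
    return float(
        beta_dist.logpdf(x, hi.alpha, hi.beta) - beta_dist.logpdf(x, lo.alpha, lo.beta)
    )


def marker_score(profile: MarkerProfile, model: MarkerModel, eps: float) -> float:
    """Log-likelihood-ratio contribution of one evaluable marker.

    The bias term is included only when the marker shows deletions; the
    bias densities were fitted on deletion-bearing samples and carry no
    information otherwise.
    """
    d = _shrink(profile.n_deleted, profile.depth, eps)
    s = _log_ratio(d, model.d_msih, model.d_mss)
    if profile.n_deleted > 0:
        b = _shrink(profile.b * profile.n_deleted, profile.n_deleted, eps)
        s += _log_ratio(b, model.b_msih, model.b_mss)
    return s


def score_sample(
    profiles: Sequence[MarkerProfile],
    classifier: TrainedClassifier,
    sample_id: str = "",
) -> MsiScoreResult:
    """Score one sample: summed marker log-ratios, sign decides the call."""
    unknown = [p.marker_id for p in profiles if p.marker_id not in classifier.models]
    if unknown:
        raise ValueError(
            f"profiles contain markers absent from the classifier: {unknown[:5]}"
        )
    eps = classifier.config.epsilon
    used = [p for p in profiles if p.evaluable]
    n_panel = len(profiles)
    if n_panel == 0 or len(used) < classifier.config.min_marker_fraction * n_panel:
        return MsiScoreResult(
            sample_id=sample_id,
            panel_name=classifier.panel_name,
            score=float("nan"),
            n_markers_used=len(used),
            call="NE",
        )
    score = sum(marker_score(p, classifier.models[p.marker_id], eps) for p in used)
    return MsiScoreResult(
        sample_id=sample_id,
        panel_name=classifier.panel_name,
        score=score,
        n_markers_used=len(used),
        call="MSI-H" if score > 0 else "MSS",
    )


def cross_validate(
    profiles_by_sample: Mapping[str, Sequence[MarkerProfile]],
    labels: Mapping[str, Label],
    panel_name: str,
    k: int = 5,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> CvResult:
    """Stratified k-fold accuracy of the classifier on a labelled cohort."""
    if k < 2:
        raise ValueError("k must be >= 2")
    by_class: dict[str, list[str]] = {"MSS": [], "MSI-H": []}
    for sid in sorted(profiles_by_sample):
        by_class[labels[sid]].append(sid)
    if any(k > len(ids) for ids in by_class.values()):
        raise ValueError("k exceeds the size of a class")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for ids in by_class.values():
        order = list(rng.permutation(ids))
        for i, sid in enumerate(order):
            folds[i % k].append(sid)

    n_correct = 0
    n_total = 0
    fold_calls: list[dict[str, str]] = []
    for fold in folds:
        train_ids = [s for s in profiles_by_sample if s not in set(fold)]
        clf = fit_classifier(
            {s: profiles_by_sample[s] for s in train_ids},
            {s: labels[s] for s in train_ids},
            panel_name,
            config,
        )
        calls = {}
        for sid in fold:
            res = score_sample(profiles_by_sample[sid], clf, sid)
            calls[sid] = res.call
            if res.call != "NE":
                n_total += 1
                n_correct += res.call == labels[sid]
        fold_calls.append(calls)
    return CvResult(
        accuracy=n_correct / n_total if n_total else float("nan"),
        fold_calls=fold_calls,
    )
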