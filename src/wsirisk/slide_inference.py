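"""Slide-level inference.

Fuses the four binary patch predictions into a per-patch fate
(resolved to one class, or eliminated), aggregates fates into per-slide
ratio vectors, and classifies slides as low/high risk with a
Gaussian-process classifier over the ratio features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from wsirisk.synthetic import CLASSES, HIGH_RISK, LOW_RISK

__all__ = [
    "ELIMINATED",
    "GPConfig",
    "RatioVector",
    "SlideClassifier",
    "SlidePrediction",
    "UnclassifiableSlideError",
    "aggregate_patient",
    "compute_ratio_vector",
    "fit_slide_classifier",
    "predict_slide",
    "resolve_patch_label",
]

ELIMINATED = "eliminated"

LOW_RISK_CLASSES = ("punlmp", "low_grade")
HIGH_RISK_CLASSES = ("high_grade", "invasive")


class ValidationError(ValueError):
    pass


class UnclassifiableSlideError(ValueError):
    """Raised when a slide yields no classifiable tissue patches."""


def resolve_patch_label(labels: Sequence[int] | Sequence[bool]) -> str:
    """Fate of one patch from its four binary classifier outputs.

    Exactly one positive label resolves the patch to that class; zero
    positives (all classifiers vote "other") or two or more positives
    (ambiguous) eliminate it. Total on all 16 combinations.
    """
    labels = [bool(v) for v in labels]
    if len(labels) != len(CLASSES):
        raise ValidationError(f"expected {len(CLASSES)} labels, got {len(labels)}")
    if sum(labels) == 1:
        return CLASSES[labels.index(True)]
    return ELIMINATED


@dataclass(frozen=True)
class RatioVector:
    """Per-slide patch-class proportions; the slide classifier's features."""

    slide_id: str
    ratios: Mapping[str, float]  # class -> ratio
    n_patches: int
    n_eliminated: int

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValidationError("ratio vector needs at least one patch")
        if any(r < 0 for r in self.ratios.values()):
            raise ValidationError("negative ratio")
        if sum(self.ratios.values()) > 1 + 1e-9:
            raise ValidationError("class ratios sum above 1")

    @property
    def low_risk_ratio(self) -> float:
        return sum(self.ratios.get(c, 0.0) for c in LOW_RISK_CLASSES)

    @property
    def high_risk_ratio(self) -> float:
        return sum(self.ratios.get(c, 0.0) for c in HIGH_RISK_CLASSES)

    def features(self, feature_mode: str = "combined") -> np.ndarray:
        if feature_mode == "combined":
            return np.array([self.low_risk_ratio, self.high_risk_ratio])
        if feature_mode == "per_class":
            return np.array([self.ratios.get(c, 0.0) for c in CLASSES])
        raise ValidationError(f"unknown feature_mode {feature_mode!r}")


def compute_ratio_vector(
    fates: Sequence[str],
    slide_id: str = "",
    denominator_mode: str = "all",
) -> RatioVector:
    """Ratios of resolved patches per class.

    The default denominator counts every tissue patch entering
    classification, eliminated ones included, so the four ratios plus
    the eliminated fraction sum to exactly 1 (exact rational
    arithmetic on counts).
    """
    fates = list(fates)
    if not fates:
        raise UnclassifiableSlideError(
            f"slide {slide_id!r} produced no classifiable patches"
        )
    unknown = set(fates) - set(CLASSES) - {ELIMINATED}
    if unknown:
        raise ValidationError(f"unknown fates {sorted(unknown)}")
    n_eliminated = sum(f == ELIMINATED for f in fates)
    if denominator_mode == "all":
        denominator = len(fates)
    elif denominator_mode == "resolved":
        denominator = len(fates) - n_eliminated
        if denominator == 0:
            raise UnclassifiableSlideError(
                f"slide {slide_id!r}: all patches eliminated"
            )
    else:
        raise ValidationError(f"unknown denominator_mode {denominator_mode!r}")
    ratios = {
        c: float(Fraction(sum(f == c for f in fates), denominator)) for c in CLASSES
    }
    return RatioVector(
        slide_id=slide_id,
        ratios=ratios,
        n_patches=len(fates),
        n_eliminated=n_eliminated,
    )


@dataclass(frozen=True)
class GPConfig:
    feature_mode: str = "combined"  # or "per_class"
    length_scale: float = 1.0
    n_restarts: int = 2
    seed: int = 0


@dataclass(frozen=True)
class SlidePrediction:
    slide_id: str
    risk: str
    probability_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.probability_high <= 1:
            raise ValidationError("probability outside [0, 1]")


class SlideClassifier:
    """RBF-kernel Gaussian-process binary risk classifier on ratio features."""

    def __init__(self, gpc: GaussianProcessClassifier, config: GPConfig):
        self._gpc = gpc
        self.config = config

    @property
    def n_features(self) -> int:
        return self._gpc.base_estimator_.X_train_.shape[1]

    def predict_probability(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got {features.shape[1]}"
            )
        proba = self._gpc.predict_proba(features)
        high_col = list(self._gpc.classes_).index(HIGH_RISK)
        return proba[:, high_col]

    def kernel_hyperparameters(self) -> dict:
        kernel = self._gpc.kernel_
        return {"kernel": str(kernel), "theta": kernel.theta.tolist()}


def fit_slide_classifier(
    ratio_vectors: Sequence[RatioVector],
    slide_labels: Sequence[str],
    config: GPConfig = GPConfig(),
) -> SlideClassifier:
    """Fit the Gaussian-process slide classifier on training ratios."""
    if len(ratio_vectors) != len(slide_labels):
        raise ValidationError("ratio_vectors and slide_labels length mismatch")
    labels = list(slide_labels)
    for label in labels:
        if label not in (LOW_RISK, HIGH_RISK):
            raise ValidationError(f"unknown slide label {label!r}")
    for risk in (LOW_RISK, HIGH_RISK):
        if labels.count(risk) < 2:
            raise ValidationError(f"need at least 2 slides labeled {risk}")
    x = np.stack([rv.features(config.feature_mode) for rv in ratio_vectors])
    kernel = ConstantKernel(1.0) * RBF(length_scale=config.length_scale)
    gpc = GaussianProcessClassifier(
        kernel=kernel,
        n_restarts_optimizer=config.n_restarts,
        random_state=config.seed,
    )
    gpc.fit(x, np.array(labels))
    return SlideClassifier(gpc, config)


def predict_slide(model: SlideClassifier, ratio_vector: RatioVector) -> SlidePrediction:
    """Risk call for one slide; probability >= 0.5 maps to high risk."""
    prob = float(model.predict_probability(ratio_vector.features(model.config.feature_mode))[0])
    risk = HIGH_RISK if prob >= 0.5 else LOW_RISK
    return SlidePrediction(
        slide_id=ratio_vector.slide_id, risk=risk, probability_high=prob
    )


def aggregate_patient(slide_predictions: Sequence[SlidePrediction]) -> SlidePrediction:
    """Patient-level risk: the maximum high-risk probability over the
    patient's slides, thresholded at 0.5 (ties resolve to high risk)."""
    preds = list(slide_predictions)
    if not preds:
        raise ValidationError("patient has no slide predictions")
    prob = max(p.probability_high for p in preds)
    return SlidePrediction(
        slide_id="|".join(p.slide_id for p in preds),
        risk=HIGH_RISK if prob >= 0.5 else LOW_RISK,
        probability_high=prob,
    )


# ---------------------------------------------------------------------------
# Persistence


def save_slide_classifier(model: SlideClassifier, path) -> None:
    """Pickle the fitted GP next to a JSON sidecar of kernel hyperparameters."""
    import pickle

    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"gpc": model._gpc, "config": model.config}, fh)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(model.kernel_hyperparameters(), indent=2))


def load_slide_classifier(path) -> SlideClassifier:
    import pickle

    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    return SlideClassifier(blob["gpc"], blob["config"])
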