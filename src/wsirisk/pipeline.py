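"""End-to-end orchestration: tile -> classify -> fuse -> ratio -> GP ->
evaluate -> survival, with per-stage artifacts and a reproducible run
manifest. Reruns with the same config and seed are bit-identical."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from wsirisk import __version__
from wsirisk._random import substream_seed
from wsirisk.asap import read_asap_annotations
from wsirisk.config import PipelineConfig, config_hash, save_config
from wsirisk.evaluation import confusion_matrix, classification_metrics, bootstrap_ci
from wsirisk.patch_classifiers import (
    BinaryPatchModel,
    Patch,
    load_model,
    patch_to_features,
    predict_patches,
    save_model,
    train_binary_classifier,
    write_training_log,
)
from wsirisk.slide_inference import (
    SlideClassifier,
    UnclassifiableSlideError,
    aggregate_patient,
    compute_ratio_vector,
    fit_slide_classifier,
    predict_slide,
    resolve_patch_label,
    save_slide_classifier,
)
from wsirisk.survival import (
    NonEstimableError,
    SurvivalRecord,
    cox_fit,
    km_estimate,
    logrank_test,
    median_survival,
)
from wsirisk.synthetic import CLASSES, HIGH_RISK, LOW_RISK
from wsirisk.tiling import extract_patches, label_patches, tissue_mask

logger = logging.getLogger("wsirisk")

__all__ = [
    "PipelineError",
    "load_manifest",
    "slide_features",
    "train_models",
    "infer_slides",
    "evaluate_predictions",
    "survival_analysis",
    "run_pipeline",
]

_PLACEHOLDER = np.zeros((1, 1, 3), dtype=np.uint8)


class PipelineError(RuntimeError):
    pass


def load_manifest(manifest_path) -> pd.DataFrame:
    """Read and validate the slide manifest, failing fast on missing files."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"slide_id", "patient_id", "label", "split", "image"}
    missing = required - set(manifest.columns)
    if missing:
        raise PipelineError(f"manifest missing columns {sorted(missing)}")
    for row in manifest.itertuples(index=False):
        if not Path(row.image).exists():
            raise PipelineError(
                f"stage=manifest: slide image not found: {row.image}"
            )
        xml = getattr(row, "annotations", None)
        if row.split == "train" and xml and not Path(xml).exists():
            raise PipelineError(
                f"stage=manifest: annotation file not found: {xml}"
            )
    return manifest


@dataclass
class SlideFeatures:
    slide_id: str
    features: np.ndarray  # (n_patches, 3, S, S)
    annotation_classes: list[str | None]
    origins: list[tuple[int, int]]


def slide_features(row, tiling_config, with_annotations: bool) -> SlideFeatures:
    """Tile one slide into standardized CNN feature tensors."""
    from PIL import Image

    image = np.asarray(Image.open(row.image).convert("RGB"))
    mask = tissue_mask(image, tiling_config)
    patches = extract_patches(image, mask, tiling_config, slide_id=row.slide_id)
    if with_annotations and getattr(row, "annotations", None):
        regions = read_asap_annotations(row.annotations)
        patches = label_patches(patches, regions)
    if not patches:
        return SlideFeatures(row.slide_id, np.empty((0, 3, 28, 28)), [], [])
    features = np.stack([patch_to_features(p) for p in patches])
    return SlideFeatures(
        slide_id=row.slide_id,
        features=features,
        annotation_classes=[p.annotation_class for p in patches],
        origins=[p.origin for p in patches],
    )


def train_models(
    manifest: pd.DataFrame, config: PipelineConfig, models_dir=None
) -> dict[str, BinaryPatchModel]:
    """Train the four one-vs-rest patch classifiers on the train split."""
    train_rows = manifest[manifest["split"] == "train"]
    if train_rows.empty:
        raise PipelineError("stage=train: no slides in the train split")
    train_cfg = dataclasses.replace(
        config.train, seed=substream_seed(config.seed, "train")
    )
    patches: list[Patch] = []
    features = []
    for row in train_rows.itertuples(index=False):
        sf = slide_features(row, config.tiling, with_annotations=True)
        for cls, origin, feat in zip(sf.annotation_classes, sf.origins, sf.features):
            if cls is None:
                continue
            patches.append(
                Patch(
                    slide_id=sf.slide_id,
                    origin=origin,
                    pixels=_PLACEHOLDER,
                    annotation_class=cls,
                )
            )
            features.append(feat)
        logger.info("tiled %s: %d annotated patches", sf.slide_id, len(features))
    if not patches:
        raise PipelineError("stage=train: no annotated patches in the train split")
    features = np.stack(features)
    models = {}
    for cls in CLASSES:
        logger.info("training one-vs-rest classifier for %s", cls)
        models[cls] = train_binary_classifier(
            patches, cls, train_cfg, features=features
        )
        if models_dir is not None:
            models_dir = Path(models_dir)
            models_dir.mkdir(parents=True, exist_ok=True)
            save_model(models[cls], models_dir / f"model_{cls}.npz")
            write_training_log(models[cls], models_dir / f"train_log_{cls}.csv")
    return models


def load_models(models_dir) -> dict[str, BinaryPatchModel]:
    models_dir = Path(models_dir)
    models = {}
    for cls in CLASSES:
        path = models_dir / f"model_{cls}.npz"
        if not path.exists():
            raise PipelineError(f"stage=infer: missing model checkpoint {path}")
        models[cls] = load_model(path)
    return models


def _slide_ratio_vector(sf: SlideFeatures, models, config: PipelineConfig):
    if len(sf.features) == 0:
        raise UnclassifiableSlideError(f"slide {sf.slide_id!r}: no tissue patches")
    votes = np.stack(
        [
            predict_patches(models[cls], [], features=sf.features)
            >= models[cls].config.positive_threshold
            for cls in CLASSES
        ],
        axis=1,
    )
    fates = [resolve_patch_label(row) for row in votes]
    return compute_ratio_vector(fates, sf.slide_id, config.denominator_mode)


def infer_slides(
    manifest: pd.DataFrame,
    models: dict[str, BinaryPatchModel],
    config: PipelineConfig,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame, SlideClassifier]:
    """Ratio vectors for every slide, GP fit on the train split,
    predictions for all slides. Returns (slide frame, patient frame, GP)."""
    gp_cfg = dataclasses.replace(
        config.gp, seed=substream_seed(config.seed, "gp") % (2**31)
    )
    ratio_vectors = {}
    for row in manifest.itertuples(index=False):
        sf = slide_features(row, config.tiling, with_annotations=False)
        ratio_vectors[row.slide_id] = _slide_ratio_vector(sf, models, config)
        logger.info("ratios computed for %s", row.slide_id)

    train_rows = manifest[manifest["split"] == "train"]
    gp = fit_slide_classifier(
        [ratio_vectors[s] for s in train_rows["slide_id"]],
        list(train_rows["label"]),
        gp_cfg,
    )

    rows = []
    for row in manifest.itertuples(index=False):
        rv = ratio_vectors[row.slide_id]
        pred = predict_slide(gp, rv)
        rows.append(
            {
                "slide_id": row.slide_id,
                "patient_id": row.patient_id,
                "split": row.split,
                "truth": row.label,
                **{f"r_{c}": rv.ratios[c] for c in CLASSES},
                "n_patches": rv.n_patches,
                "n_eliminated": rv.n_eliminated,
                "prob_high": pred.probability_high,
                "risk": pred.risk,
            }
        )
    predictions = pd.DataFrame(rows).sort_values("slide_id").reset_index(drop=True)

    patient_rows = []
    for (patient_id, split), group in predictions.groupby(["patient_id", "split"]):
        preds = [
            predict_slide(gp, ratio_vectors[s]) for s in group["slide_id"]
        ]
        agg = aggregate_patient(preds)
        truth = (
            HIGH_RISK if (group["truth"] == HIGH_RISK).any() else LOW_RISK
        )
        patient_rows.append(
            {
                "patient_id": patient_id,
                "split": split,
                "truth": truth,
                "prob_high": agg.probability_high,
                "risk": agg.risk,
            }
        )
    patients = pd.DataFrame(patient_rows).sort_values("patient_id").reset_index(drop=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        predictions.to_csv(out_dir / "predictions.csv", index=False, float_format="%.12g")
        patients.to_csv(out_dir / "patient_predictions.csv", index=False, float_format="%.12g")
        save_slide_classifier(gp, out_dir / "slide_classifier.pkl")
    return predictions, patients, gp


def evaluate_predictions(
    predictions: pd.DataFrame,
    config: PipelineConfig,
    split: str = "test",
    out_path=None,
) -> dict:
    """Slide-level metrics with bootstrap CIs on the chosen split."""
    rows = predictions[predictions["split"] == split]
    if rows.empty:
        raise PipelineError(f"stage=evaluate: no slides in split {split!r}")
    truths = list(rows["truth"])
    preds = list(rows["risk"])
    report = classification_metrics(confusion_matrix(truths, preds))
    seed = substream_seed(config.seed, "bootstrap")
    cis = {}
    for name in ("weighted_precision", "weighted_recall", "weighted_f1", "accuracy"):
        cis[name] = bootstrap_ci(
            truths, preds, name, iterations=config.bootstrap_iterations, seed=seed
        )
    result = {
        "split": split,
        "n_slides": len(rows),
        "confusion": report.confusion.tolist(),
        "per_class": report.per_class,
        "weighted": report.weighted,
        "accuracy": report.accuracy,
        "bootstrap_ci": cis,
        "bootstrap_iterations": config.bootstrap_iterations,
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, indent=2))
    return result


def survival_analysis(
    patient_predictions: pd.DataFrame,
    survival_csv,
    horizon: float | None = None,
    out_path=None,
    km_dir=None,
) -> dict:
    """KM curves per predicted group, log-rank test, and Cox fit."""
    survival = pd.read_csv(survival_csv)
    merged = patient_predictions.merge(survival, on="patient_id", how="inner")
    if merged.empty:
        raise PipelineError("stage=survival: no patients join the survival table")
    records = {LOW_RISK: [], HIGH_RISK: []}
    for row in merged.itertuples(index=False):
        records[row.risk].append(
            SurvivalRecord(
                patient_id=row.patient_id,
                time=float(row.time_months),
                event=int(row.event),
                group=f"predicted_{'high' if row.risk == HIGH_RISK else 'low'}",
            )
        )
    result: dict = {"n_patients": len(merged), "horizon": horizon}
    curves = {}
    for risk, recs in records.items():
        if recs:
            curve = km_estimate(recs, horizon)
            curves[risk] = curve
            med = median_survival(curve)
            result[f"median_survival_{risk}"] = med if med is not None else "not reached"
            result[f"n_{risk}"] = len(recs)
    if records[LOW_RISK] and records[HIGH_RISK]:
        stat, p = logrank_test(records[LOW_RISK], records[HIGH_RISK])
        result["logrank"] = {"statistic": stat, "p_value": p}
        try:
            cox = cox_fit(records[LOW_RISK] + records[HIGH_RISK])
            result["cox"] = {
                "hazard_ratio": cox.hazard_ratio,
                "ci": [cox.ci_low, cox.ci_high],
                "p_value": cox.p_value,
                "n_events": cox.n_events,
            }
        except NonEstimableError as exc:
            result["cox"] = {"error": str(exc)}
    else:
        result["logrank"] = {"error": "a predicted group is empty"}
    if km_dir is not None:
        km_dir = Path(km_dir)
        km_dir.mkdir(parents=True, exist_ok=True)
        for risk, curve in curves.items():
            curve.as_table().to_csv(km_dir / f"km_{risk}.csv", index=False)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, indent=2))
    return result


def run_pipeline(config: PipelineConfig, manifest_path=None) -> dict:
    """Execute every stage; artifacts land under config.out_dir."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = manifest_path or data_dir / "manifest.csv"
    manifest = load_manifest(manifest_path)

    logger.info("stage=train (%d slides)", (manifest["split"] == "train").sum())
    models = train_models(manifest, config, models_dir=out_dir / "models")

    logger.info("stage=infer (%d slides)", len(manifest))
    predictions, patients, _ = infer_slides(manifest, models, config, out_dir=out_dir)

    logger.info("stage=evaluate")
    metrics = evaluate_predictions(
        predictions, config, split="test", out_path=out_dir / "metrics.json"
    )

    survival_csv = data_dir / "survival.csv"
    survival = None
    if survival_csv.exists():
        logger.info("stage=survival")
        survival = survival_analysis(
            patients[patients["split"] == "test"],
            survival_csv,
            horizon=config.survival_horizon,
            out_path=out_dir / "survival.json",
            km_dir=out_dir / "km",
        )

    run_manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "wsirisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    save_config(config, out_dir / "config.yaml")
    return {
        "predictions": predictions,
        "patients": patients,
        "metrics": metrics,
        "survival": survival,
        "out_dir": out_dir,
    }
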