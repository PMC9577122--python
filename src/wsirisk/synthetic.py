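"""Synthetic pseudo-whole-slide generator.

Produces desk-scale RGB slides with four visually distinguishable
procedural tissue textures on a pink base, white background, optional
saturated marker-ink stripes, box annotations per painted region, a
risk truth label derived from the composition, and linked survival
cohorts whose hazard depends on the risk group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from wsirisk._random import substream

__all__ = [
    "CLASSES",
    "LOW_RISK",
    "HIGH_RISK",
    "HIGH_GRADE_RULE_THRESHOLD",
    "AnnotationRegion",
    "SlideSpec",
    "SlideRecord",
    "CohortSpec",
    "generate_slide",
    "generate_cohort",
    "risk_label_for_composition",
    "make_slide_specs",
    "simulate_dataset",
]

#: The four histologic subtype identifiers, in fixed canonical order.
CLASSES: tuple[str, ...] = ("punlmp", "low_grade", "high_grade", "invasive")

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"

#: Slides whose high-grade + invasive share of tissue area reaches this
#: threshold are labeled high risk.
HIGH_GRADE_RULE_THRESHOLD = 0.05

# Procedural texture parameters: (spot RGB, spot radius, spots per 224x224).
# Spot colors keep HSV saturation below the marker-detection threshold so
# tissue is never mistaken for marker ink.
_TEXTURES: dict[str, tuple[tuple[int, int, int], int, int]] = {
    "punlmp": ((210, 165, 220), 6, 25),
    "low_grade": ((150, 100, 175), 4, 120),
    "high_grade": ((100, 80, 150), 3, 260),
    "invasive": ((120, 88, 80), 2, 420),
}

_TISSUE_BASE = (235, 185, 200)  # pink base under every texture
_MARKER_COLORS = {"green": (10, 190, 60), "blue": (30, 60, 220)}
_MARKER_WIDTH = 24


class ValidationError(ValueError):
    """Raised when a spec violates its invariants."""


@dataclass(frozen=True)
class AnnotationRegion:
    """An axis-aligned annotated box, 0-based half-open pixel coordinates."""

    box: tuple[int, int, int, int]  # (x0, y0, x1, y1)
    class_label: str

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValidationError(f"degenerate region box {self.box}")
        if self.class_label not in CLASSES:
            raise ValidationError(f"unknown class label {self.class_label!r}")

    @property
    def width(self) -> int:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> int:
        return self.box[3] - self.box[1]


@dataclass(frozen=True)
class SlideSpec:
    """Recipe for one synthetic slide."""

    slide_id: str
    width: int
    height: int
    composition: Mapping[str, float]
    background_fraction: float = 0.15
    marker: str | None = None
    seed: int = 0
    patient_id: str | None = None
    min_size: int = 224

    def __post_init__(self) -> None:
        for cls in self.composition:
            if cls not in CLASSES:
                raise ValidationError(f"unknown class {cls!r} in composition")
        if any(f < 0 for f in self.composition.values()):
            raise ValidationError("negative class fraction")
        if not 0 <= self.background_fraction < 1:
            raise ValidationError("background_fraction must be in [0, 1)")
        total = sum(self.composition.values()) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"class fractions + background_fraction must sum to 1, got {total}"
            )
        if self.width < self.min_size or self.height < self.min_size:
            raise ValidationError(
                f"slide {self.width}x{self.height} smaller than minimum size "
                f"{self.min_size}"
            )
        if self.marker is not None and self.marker not in _MARKER_COLORS:
            raise ValidationError(f"unknown marker {self.marker!r}")

    @property
    def tissue_fraction(self) -> float:
        return 1.0 - self.background_fraction


@dataclass
class SlideRecord:
    """A rendered slide with its annotations and ground truth."""

    slide_id: str
    image: np.ndarray  # (H, W, 3) uint8
    regions: list[AnnotationRegion]
    truth_label: str
    patient_id: str
    marker_box: tuple[int, int, int, int] | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic survival cohort."""

    n_patients: int
    high_risk_fraction: float = 0.5
    baseline_hazard: float = 0.01  # events per month, low-risk arm
    hazard_ratio: float = 2.0
    censor_time_max: float = 120.0  # months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if not 0 <= self.high_risk_fraction <= 1:
            raise ValidationError("high_risk_fraction must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard_ratio must be > 0")
        if self.censor_time_max <= 0:
            raise ValidationError("censor_time_max must be > 0")


def risk_label_for_composition(composition: Mapping[str, float]) -> str:
    """Risk truth label as a pure function of the class composition.

    High risk iff the high-grade + invasive share of *tissue* area is at
    least 5%.
    """
    tissue = sum(composition.values())
    if tissue <= 0:
        raise ValidationError("composition has no tissue")
    high = composition.get("high_grade", 0.0) + composition.get("invasive", 0.0)
    return HIGH_RISK if high / tissue >= HIGH_GRADE_RULE_THRESHOLD else LOW_RISK


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def _paint_texture(
    image: np.ndarray,
    box: tuple[int, int, int, int],
    class_label: str,
    rng: np.random.Generator,
) -> None:
    """Paint one class texture into `box` (in place)."""
    x0, y0, x1, y1 = box
    h, w = y1 - y0, x1 - x0
    spot_rgb, radius, density = _TEXTURES[class_label]

    base = np.array(_TISSUE_BASE, dtype=np.float64)
    noise = rng.normal(0.0, 6.0, size=(h, w, 3))
    image[y0:y1, x0:x1] = np.clip(base + noise, 0, 255).astype(np.uint8)

    n_spots = int(round(density * (h * w) / (224.0 * 224.0)))
    if n_spots == 0:
        return
    cy = rng.integers(0, h, size=n_spots)
    cx = rng.integers(0, w, size=n_spots)
    dy, dx = _disk_offsets(radius)
    yy = (cy[:, None] + dy[None, :]).ravel()
    xx = (cx[:, None] + dx[None, :]).ravel()
    keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    image[y0 + yy[keep], x0 + xx[keep]] = np.array(spot_rgb, dtype=np.uint8)


def generate_slide(spec: SlideSpec) -> SlideRecord:
    """Render a slide from its spec; identical spec+seed is bit-identical.

    Layout: tissue occupies a full-height strip on the left, one
    contiguous vertical band per nonzero class fraction; the remainder
    is white background, optionally crossed by a saturated marker-ink
    stripe.
    """
    rng = substream(spec.seed, f"slide:{spec.slide_id}")
    w, h = spec.width, spec.height
    image = np.full((h, w, 3), 255, dtype=np.uint8)

    tissue_width = int(round(spec.tissue_fraction * w))
    regions: list[AnnotationRegion] = []
    # Band edges from cumulative fractions so widths track areas exactly.
    cum = 0.0
    prev_edge = 0
    for cls in CLASSES:
        frac = spec.composition.get(cls, 0.0)
        if frac <= 0:
            continue
        cum += frac
        edge = int(round(cum / spec.tissue_fraction * tissue_width))
        edge = min(edge, tissue_width)
        if edge > prev_edge:
            box = (prev_edge, 0, edge, h)
            _paint_texture(image, box, cls, rng)
            regions.append(AnnotationRegion(box=box, class_label=cls))
        prev_edge = edge

    marker_box = None
    if spec.marker is not None:
        margin = max((w - tissue_width - _MARKER_WIDTH) // 2, 0)
        mx0 = min(tissue_width + margin, w - _MARKER_WIDTH)
        if mx0 > tissue_width:
            marker_box = (mx0, 0, mx0 + _MARKER_WIDTH, h)
            image[:, mx0 : mx0 + _MARKER_WIDTH] = np.array(
                _MARKER_COLORS[spec.marker], dtype=np.uint8
            )

    return SlideRecord(
        slide_id=spec.slide_id,
        image=image,
        regions=regions,
        truth_label=risk_label_for_composition(spec.composition),
        patient_id=spec.patient_id or f"pt_{spec.slide_id}",
        marker_box=marker_box,
    )


def generate_cohort(
    spec: CohortSpec,
    truth_labels: Mapping[str, str] | None = None,
) -> list["SurvivalRecord"]:
    """Draw a survival cohort with group-dependent exponential hazards.

    Event times are exponential with rate `baseline_hazard` (low risk)
    or `baseline_hazard * hazard_ratio` (high risk); censoring times are
    uniform on (0, censor_time_max]; the observed time is the minimum.
    """
    from wsirisk.survival import SurvivalRecord

    rng = substream(spec.seed, "cohort")
    if truth_labels is None:
        n_high = int(round(spec.n_patients * spec.high_risk_fraction))
        ids = [f"patient_{i:05d}" for i in range(spec.n_patients)]
        perm = rng.permutation(spec.n_patients)
        truth_labels = {
            ids[j]: (HIGH_RISK if k < n_high else LOW_RISK)
            for k, j in enumerate(perm)
        }
    records: list[SurvivalRecord] = []
    for patient_id in truth_labels:
        label = truth_labels[patient_id]
        if label not in (LOW_RISK, HIGH_RISK):
            raise ValidationError(f"patient {patient_id} has unknown risk {label!r}")
        rate = spec.baseline_hazard
        if label == HIGH_RISK:
            rate *= spec.hazard_ratio
        event_time = rng.exponential(1.0 / rate)
        censor_time = rng.uniform(0.0, spec.censor_time_max)
        time = min(event_time, censor_time)
        records.append(
            SurvivalRecord(
                patient_id=patient_id,
                time=max(time, 1e-9),
                event=int(event_time <= censor_time),
                group=label,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Dataset assembly


def make_slide_specs(
    n: int,
    width: int = 1024,
    height: int = 1024,
    seed: int = 0,
    prefix: str = "slide",
    start_index: int = 0,
) -> list[SlideSpec]:
    """A balanced plan of slide specs cycling through six archetypes.

    Four pure single-class slides, one mixed slide above the high-grade
    threshold (high risk), and one mixed low-risk slide; markers appear
    on every third slide. Risk classes come out balanced 3:3.
    """
    archetypes: list[dict[str, float]] = [
        {"punlmp": 0.85},
        {"low_grade": 0.85},
        {"high_grade": 0.85},
        {"invasive": 0.85},
        {"low_grade": 0.55, "high_grade": 0.30},
        {"punlmp": 0.45, "low_grade": 0.40},
    ]
    specs = []
    for i in range(n):
        idx = start_index + i
        composition = archetypes[idx % len(archetypes)]
        specs.append(
            SlideSpec(
                slide_id=f"{prefix}_{idx:04d}",
                width=width,
                height=height,
                composition=composition,
                background_fraction=1.0 - sum(composition.values()),
                marker=("green", "blue")[idx % 2] if idx % 3 == 2 else None,
                seed=seed + idx,
            )
        )
    return specs


def simulate_dataset(
    out_dir,
    n_train: int = 60,
    n_test: int = 30,
    width: int = 1024,
    height: int = 1024,
    seed: int = 0,
    cohort: CohortSpec | None = None,
) -> "pd.DataFrame":
    """Write a complete synthetic dataset under `out_dir`.

    Produces slides/*.png, annotations/*.xml (ASAP dialect),
    manifest.csv (slide_id, patient_id, label, split, image, annotations)
    and survival.csv (patient_id, time_months, event). Returns the
    manifest frame.
    """
    import pandas as pd
    from PIL import Image

    from wsirisk.asap import write_asap_annotations

    out_dir = _ensure_dirs(out_dir)
    specs = make_slide_specs(n_train, width, height, seed, prefix="train") + [
        s for s in make_slide_specs(n_test, width, height, seed + 10_000, prefix="test")
    ]
    splits = ["train"] * n_train + ["test"] * n_test

    rows = []
    truth: dict[str, str] = {}
    for spec, split in zip(specs, splits):
        record = generate_slide(spec)
        img_path = out_dir / "slides" / f"{record.slide_id}.png"
        xml_path = out_dir / "annotations" / f"{record.slide_id}.xml"
        Image.fromarray(record.image).save(img_path)
        write_asap_annotations(xml_path, record.regions)
        truth[record.patient_id] = record.truth_label
        rows.append(
            {
                "slide_id": record.slide_id,
                "patient_id": record.patient_id,
                "label": record.truth_label,
                "split": split,
                "image": str(img_path),
                "annotations": str(xml_path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)

    if cohort is None:
        cohort = CohortSpec(n_patients=len(truth), seed=seed)
    records = generate_cohort(cohort, truth_labels=truth)
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_months": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(out_dir / "survival.csv", index=False)
    return manifest


def _ensure_dirs(out_dir):
    from pathlib import Path

    out_dir = Path(out_dir)
    (out_dir / "slides").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    return out_dir
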