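import numpy as np
import pytest

from wsirisk.synthetic import CLASSES, SlideSpec, generate_slide
from wsirisk.tiling import extract_patches, label_patches, tissue_mask


def pure_slide(cls: str, seed: int, size: int = 672, slide_id: str | None = None):
    """A single-class slide with no background, for patch harvesting."""
    spec = SlideSpec(
        slide_id=slide_id or f"{cls}_{seed}",
        width=size,
        height=size,
        composition={cls: 1.0},
        background_fraction=0.0,
        seed=seed,
    )
    return generate_slide(spec)


def harvest_patches(record):
    patches = extract_patches(
        record.image, tissue_mask(record.image), slide_id=record.slide_id
    )
    patches = label_patches(patches, record.regions)
    return [p for p in patches if p.annotation_class]


@pytest.fixture(scope="session")
def texture_corpus():
    """~380 annotated patches, ~96 per class, from 12 pure slides.

    Session-scoped: patch-classifier tests share this corpus to stay
    inside the suite's time budget (the spec's 2000-patch-per-class
    example is exercised at full scale only in the end-to-end
    acceptance run).
    """
    patches = []
    for i, cls in enumerate(CLASSES):
        for s in range(3):
            patches.extend(harvest_patches(pure_slide(cls, seed=100 * i + s)))
    return patches


@pytest.fixture(scope="session")
def texture_features(texture_corpus):
    from wsirisk.patch_classifiers import patch_to_features

    return np.stack([patch_to_features(p) for p in texture_corpus])
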