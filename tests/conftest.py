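import numpy as np
import pytest

from nephroseg import (
    ClassDef,
    ClassSchema,
    LabelMask,
    SectionImage,
    TrainConfig,
    build_model,
    default_schema,
    generate_section,
    train,
)
from nephroseg.synthetic import section_spec


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def injured_section(schema):
    """One 256x256 synthetic section at injury fraction 0.2 with its spec."""
    spec = section_spec(256, 256, injury_fraction=0.2, seed=11)
    img, mask = generate_section(spec, schema)
    return img, mask, spec


@pytest.fixture(scope="session")
def two_class_schema():
    return ClassSchema(
        (
            ClassDef(0, "background", "background", (244, 243, 240)),
            ClassDef(1, "intratubular casts", "pathological", (233, 60, 100)),
        )
    )


def _two_class_tiles(rng, n=4, size=64):
    """Tiles whose left half is background-coloured and right half cast-coloured."""
    tiles = []
    for _ in range(n):
        labels = np.zeros((size, size), dtype=np.uint8)
        labels[:, size // 2 :] = 1
        img = np.empty((size, size, 3), dtype=np.float32)
        img[:, : size // 2] = (244, 243, 240)
        img[:, size // 2 :] = (233, 60, 100)
        img += rng.normal(0, 6, size=(size, size, 1))
        tiles.append(
            (
                SectionImage(np.clip(img, 0, 255).astype(np.uint8)),
                LabelMask(labels),
            )
        )
    return tiles


@pytest.fixture(scope="session")
def toy_trained(two_class_schema):
    """Small model overfit for 200 steps on a linearly separable 2-class set."""
    rng = np.random.Generator(np.random.PCG64(42))
    tiles = _two_class_tiles(rng)
    cfg = TrainConfig(patch_size=(64, 64), batch_size=4, epochs=200, seed=1)
    model = build_model(two_class_schema, width_multiplier=0.5, seed=1)
    model, history = train(model, tiles, cfg)
    return model, history, tiles
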