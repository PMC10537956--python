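"""Class schema and raster container types shared by every pipeline stage.

A kidney section is represented as a paired RGB raster (:class:`SectionImage`)
and an integer label raster (:class:`LabelMask`) bound to a
:class:`ClassSchema` that names the annotation classes, assigns each a role
(background / healthy / pathological) and an overlay colour.

Conventions used throughout the package:

* pixel coordinates are 0-based; pixel intervals are half-open ``[x, x + w)``;
* class ids are contiguous integers starting at 0; id 0 is always background;
* sparsely annotated ground truth marks unlabelled pixels with the
  :data:`UNANNOTATED` sentinel (255), which is never a class id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

#: Sentinel for pixels outside any annotated region. Excluded from training
#: loss, evaluation counts and quantification.
UNANNOTATED: int = 255

Role = Literal["background", "healthy", "pathological"]


@dataclass(frozen=True)
class ClassDef:
    """One annotation class: integer id, name, role and RGB overlay colour."""

    id: int
    name: str
    role: Role
    color: tuple[int, int, int]


@dataclass(frozen=True)
class ClassSchema:
    """Ordered collection of annotation classes.

    Invariants (checked on construction): ids are unique and contiguous from
    0; exactly one class has the background role and it is id 0.
    """

    classes: tuple[ClassDef, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.classes]
        if ids != list(range(len(ids))):
            raise ValueError(f"class ids must be contiguous from 0, got {ids}")
        bg = [c for c in self.classes if c.role == "background"]
        if len(bg) != 1 or bg[0].id != 0:
            raise ValueError("exactly one background class with id 0 is required")
        if UNANNOTATED < len(ids):
            raise ValueError("schema too large: collides with UNANNOTATED sentinel")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __getitem__(self, class_id: int) -> ClassDef:
        return self.classes[class_id]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def id_of(self, name: str) -> int:
        for c in self.classes:
            if c.name == name:
                return c.id
        raise KeyError(name)

    def ids_with_role(self, role: Role) -> tuple[int, ...]:
        return tuple(c.id for c in self.classes if c.role == role)

    @property
    def pathological_ids(self) -> tuple[int, ...]:
        return self.ids_with_role("pathological")

    @property
    def healthy_ids(self) -> tuple[int, ...]:
        return self.ids_with_role("healthy")

    # ---- JSON sidecar -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Write the schema as a JSON sidecar (id, name, role, color)."""
        payload = [
            {"id": c.id, "name": c.name, "role": c.role, "color": list(c.color)}
            for c in self.classes
        ]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassSchema":
        payload = json.loads(Path(path).read_text())
        classes = tuple(
            ClassDef(int(c["id"]), c["name"], c["role"], tuple(int(v) for v in c["color"]))
            for c in sorted(payload, key=lambda c: c["id"])
        )
        return cls(classes)


def default_schema() -> ClassSchema:
    """The 10-class annotation schema for PAS-stained mouse kidney IRI sections.

    Healthy renal structures plus the three acute-injury classes (intratubular
    casts, tubular necrosis, regenerating epithelium). Colours are the overlay
    palette used by the synthetic renderer and heat-styled outputs.
    """
    spec: list[tuple[str, Role, tuple[int, int, int]]] = [
        ("background", "background", (244, 243, 240)),
        ("adipose tissue", "healthy", (250, 226, 233)),
        ("glomeruli", "healthy", (150, 60, 120)),
        ("proximal tubules", "healthy", (226, 134, 155)),
        ("distal tubules/collecting ducts", "healthy", (243, 196, 209)),
        ("stroma", "healthy", (186, 160, 220)),
        ("transitional epithelium", "healthy", (120, 90, 160)),
        ("intratubular casts", "pathological", (233, 60, 100)),
        ("tubular necrosis", "pathological", (150, 120, 110)),
        ("regenerating epithelium", "pathological", (110, 170, 150)),
    ]
    return ClassSchema(tuple(ClassDef(i, n, r, c) for i, (n, r, c) in enumerate(spec)))


@dataclass
class SectionImage:
    """RGB raster of a (sub-)section with physical scale and parent offset."""

    pixels: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float = 0.504
    origin: tuple[int, int] = (0, 0)  # (x, y) in parent full-resolution pixels

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if min(self.pixels.shape[:2]) < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMask:
    """Integer label raster, either at full resolution or the 8x output grid.

    ``downsample_factor`` is 1 for ground truth and 8 for network output; a
    mask cell covers ``factor x factor`` full-resolution pixels.
    """

    labels: np.ndarray  # (H, W) uint8
    downsample_factor: int = 1
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be a positive integer")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def validate_against(self, schema: ClassSchema) -> None:
        """Raise if any label is neither a schema id nor UNANNOTATED."""
        vals = np.unique(self.labels)
        bad = [int(v) for v in vals if v >= schema.n_classes and v != UNANNOTATED]
        if bad:
            raise ValueError(f"labels {bad} not in schema (K={schema.n_classes})")


def class_counts(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Pixel count per class id over ``labels``; UNANNOTATED excluded."""
    flat = labels.ravel()
    flat = flat[flat != UNANNOTATED]
    return np.bincount(flat, minlength=n_classes)[:n_classes]


def ensure_ids(schema: ClassSchema, ids: Iterable[int]) -> tuple[int, ...]:
    ids = tuple(int(i) for i in ids)
    for i in ids:
        if not 0 <= i < schema.n_classes:
            raise ValueError(f"class id {i} not in schema")
    return ids
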