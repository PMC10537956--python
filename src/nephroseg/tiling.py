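"""Raster/annotation I/O, patch grids, rasterization and annotation balancing.

Coordinates are 0-based and pixel intervals half-open ``[x, x + w)``
everywhere. Patch grids support two edge policies:

* ``"clip"`` — edge patches are shrunk so that every pixel of the section is
  covered exactly once (the policy used for quantification and heatmaps,
  where area must be conserved);
* ``"drop-partial"`` — patches that would run past the edge are discarded
  (optionally used when extracting training patches).

Annotations travel as GeoJSON polygons in pixel coordinates with a
``class_name`` property; rasterization fills polygon interiors with the class
id and leaves everything else at the :data:`~nephroseg.schema.UNANNOTATED`
sentinel, because real ground truth annotates regions, not whole slides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
from PIL import Image
from skimage.draw import polygon as _sk_polygon

from .schema import UNANNOTATED, ClassSchema, LabelMask, SectionImage

EdgePolicy = Literal["clip", "drop-partial"]


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


def write_image(image: SectionImage, path: str | Path) -> None:
    """Write an RGB section image as PNG or TIFF (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        Image.fromarray(image.pixels, mode="RGB").save(path)


def read_image(path: str | Path, microns_per_pixel: float = 0.504) -> SectionImage:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    return SectionImage(arr, microns_per_pixel=microns_per_pixel)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as single-channel 8-bit PNG/TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask.labels)
    else:
        Image.fromarray(mask.labels, mode="L").save(path)


def read_mask(path: str | Path, downsample_factor: int = 1) -> LabelMask:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    return LabelMask(arr.astype(np.uint8), downsample_factor=downsample_factor)


# ---------------------------------------------------------------------------
# patch grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Patch:
    x: int
    y: int
    width: int
    height: int


@dataclass(frozen=True)
class PatchGrid:
    """Regular grid of (possibly clipped) patches covering a section."""

    patch_size: tuple[int, int]
    stride: tuple[int, int]
    patches: tuple[Patch, ...]


def make_grid(
    width: int,
    height: int,
    size: tuple[int, int],
    stride: tuple[int, int] | None = None,
    policy: EdgePolicy = "clip",
) -> PatchGrid:
    """Enumerate patch origins on a regular stride grid over a W x H section."""
    pw, ph = size
    sx, sy = stride or size
    if pw < 1 or ph < 1:
        raise ValueError("patch size must be positive")
    if sx < 1 or sy < 1:
        raise ValueError("stride must be positive")
    if width < 1 or height < 1:
        raise ValueError("empty image")
    patches = []
    for y in range(0, height, sy):
        for x in range(0, width, sx):
            w = min(pw, width - x)
            h = min(ph, height - y)
            if (w < pw or h < ph) and policy == "drop-partial":
                continue
            patches.append(Patch(x, y, w, h))
    return PatchGrid((pw, ph), (sx, sy), tuple(patches))


def extract_patches(
    image: SectionImage,
    mask: LabelMask,
    size: tuple[int, int],
    stride: tuple[int, int] | None = None,
    policy: EdgePolicy = "clip",
) -> list[tuple[SectionImage, LabelMask]]:
    """Cut spatially aligned image/mask patches on a regular grid.

    Requires a full-resolution mask so image and mask grids coincide.
    """
    if mask.downsample_factor != 1:
        raise ValueError("extract_patches needs a full-resolution mask")
    if (image.height, image.width) != (mask.height, mask.width):
        raise ValueError("image and mask dimensions differ")
    grid = make_grid(image.width, image.height, size, stride, policy)
    out = []
    for p in grid.patches:
        sl = np.s_[p.y : p.y + p.height, p.x : p.x + p.width]
        out.append(
            (
                SectionImage(
                    image.pixels[sl],
                    microns_per_pixel=image.microns_per_pixel,
                    origin=(p.x, p.y),
                ),
                LabelMask(mask.labels[sl], downsample_factor=1, origin=(p.x, p.y)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """One annotated polygon (closed vertex list, full-resolution pixels)."""

    polygon: tuple[tuple[float, float], ...]
    class_id: int

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("polygons need at least 3 vertices")


@dataclass(frozen=True)
class AnnotationSet:
    regions: tuple[Region, ...]

    def __len__(self) -> int:
        return len(self.regions)

    def counts_by_class(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.regions:
            counts[r.class_id] = counts.get(r.class_id, 0) + 1
        return counts


def write_annotations(ann: AnnotationSet, schema: ClassSchema, path: str | Path) -> None:
    """Write annotations as a GeoJSON FeatureCollection (pixel coordinates)."""
    features = []
    for r in ann.regions:
        ring = [list(v) for v in r.polygon]
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"class_name": schema[r.class_id].name},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}) + "\n"
    )


def read_annotations(path: str | Path, schema: ClassSchema) -> AnnotationSet:
    payload = json.loads(Path(path).read_text())
    regions = []
    for feat in payload["features"]:
        ring = feat["geometry"]["coordinates"][0]
        if ring[0] == ring[-1]:
            ring = ring[:-1]
        cid = schema.id_of(feat["properties"]["class_name"])
        regions.append(Region(tuple((float(x), float(y)) for x, y in ring), cid))
    return AnnotationSet(tuple(regions))


def rasterize_annotations(
    ann: AnnotationSet, width: int, height: int, schema: ClassSchema
) -> LabelMask:
    """Burn polygons into a sparse ground-truth mask.

    Pixels inside a polygon get its class id; pixels in no polygon keep the
    UNANNOTATED sentinel. Later-listed polygons win overlaps. A pixel counts
    as inside when its centre is inside the polygon (out-of-bounds parts are
    clipped).
    """
    labels = np.full((height, width), UNANNOTATED, dtype=np.uint8)
    for r in ann.regions:
        if not 0 <= r.class_id < schema.n_classes:
            raise ValueError(f"invalid class id {r.class_id}")
        xs = np.array([v[0] for v in r.polygon], dtype=float)
        ys = np.array([v[1] for v in r.polygon], dtype=float)
        # skimage's polygon() tests integer lattice points against the polygon;
        # shift by 0.5 so the lattice points are pixel centres.
        rr, cc = _sk_polygon(ys - 0.5, xs - 0.5, shape=(height, width))
        labels[rr, cc] = r.class_id
    return LabelMask(labels, downsample_factor=1)


def balance_annotations(
    ann: AnnotationSet, target_per_class: int, seed: int = 0
) -> AnnotationSet:
    """Subsample over-represented classes to ``target_per_class`` regions.

    Classes with more regions than the target are randomly subsampled
    (seeded); classes with fewer keep everything, matching the balancing of
    sparse manual annotations to a fixed per-class budget. Region order is
    preserved within each class.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    if not ann.regions:
        raise ValueError("empty annotation set")
    rng = np.random.Generator(np.random.PCG64(seed))
    by_class: dict[int, list[int]] = {}
    for i, r in enumerate(ann.regions):
        by_class.setdefault(r.class_id, []).append(i)
    keep: set[int] = set()
    for cid in sorted(by_class):
        idx = by_class[cid]
        if len(idx) > target_per_class:
            chosen = rng.choice(len(idx), size=target_per_class, replace=False)
            keep.update(idx[i] for i in chosen)
        else:
            keep.update(idx)
    return AnnotationSet(tuple(r for i, r in enumerate(ann.regions) if i in keep))
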