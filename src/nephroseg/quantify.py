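"""Whole-section quantification: class areas, injury score, grid heatmaps.

The injury score is the percentage of the kidney surface occupied by the
configured pathological classes: all classified pixels except background are
summed as the section surface, and the score is
``100 * pathological_pixels / surface_pixels``. By default the score classes
are intratubular casts and tubular necrosis; regenerating epithelium is
quantified and reported but excluded from the score because it segments
poorly at realistic scarcity.

Heatmaps use a different denominator on purpose: for each grid patch
(512 x 512 full-resolution pixels by default) the per-class percentage is
taken over *all* pixels of the patch, background included, so a patch at the
section edge reads low even if its little tissue is fully necrotic. Both
conventions are kept deliberately distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import UNANNOTATED, ClassSchema, LabelMask, SectionImage, class_counts, ensure_ids
from .tiling import make_grid


def class_areas(mask: LabelMask, schema: ClassSchema, full_resolution: bool = True) -> dict[int, int]:
    """Pixel count per class; UNANNOTATED positions are excluded.

    With ``full_resolution`` (default) counts from a downsampled mask are
    scaled by ``downsample_factor**2`` so they are comparable to
    full-resolution areas.
    """
    mask.validate_against(schema)
    counts = class_counts(mask.labels, schema.n_classes)
    scale = mask.downsample_factor**2 if full_resolution else 1
    return {c.id: int(counts[c.id]) * scale for c in schema.classes}


@dataclass(frozen=True)
class InjuryScore:
    per_class_pixels: dict[int, int]
    kidney_surface_pixels: int
    per_class_percent: dict[int, float]
    score_percent: float
    score_class_ids: tuple[int, ...]


def injury_score(
    mask: LabelMask,
    schema: ClassSchema,
    score_classes: Iterable[int] | None = None,
) -> InjuryScore:
    """Score a section as the pathological percentage of its kidney surface.

    ``score_classes`` defaults to casts + necrosis and must be a subset of
    the schema's pathological classes. A mask with zero non-background pixels
    is an explicit error, never a silent 0.
    """
    if score_classes is None:
        ids = (schema.id_of("intratubular casts"), schema.id_of("tubular necrosis"))
    else:
        ids = ensure_ids(schema, score_classes)
        patho = set(schema.pathological_ids)
        if not set(ids) <= patho:
            raise ValueError("score classes must be pathological classes")
    areas = class_areas(mask, schema)
    surface = sum(v for cid, v in areas.items() if cid != 0)
    if surface == 0:
        raise ValueError("mask has no non-background pixels; cannot score")
    percents = {
        cid: 100.0 * v / surface for cid, v in areas.items() if cid != 0
    }
    score = sum(percents[c] for c in ids)
    return InjuryScore(
        per_class_pixels=areas,
        kidney_surface_pixels=surface,
        per_class_percent=percents,
        score_percent=float(score),
        score_class_ids=ids,
    )


@dataclass(frozen=True)
class HeatmapPatch:
    x: int  # full-resolution pixel origin
    y: int
    pixel_count: int  # full-resolution pixels in the (possibly clipped) patch
    percent: float


@dataclass(frozen=True)
class HeatmapGrid:
    class_id: int
    patch_size: int  # full-resolution pixels
    patches: tuple[HeatmapPatch, ...]


def heatmap(
    mask: LabelMask,
    schema: ClassSchema,
    class_id: int,
    patch_size: int = 512,
) -> HeatmapGrid:
    """Per-grid-patch percentage of one pathological class.

    ``patch_size`` is in full-resolution pixels and must be a multiple of the
    mask's downsample factor; the grid uses the clip edge policy so every
    mask cell is counted exactly once. Percentages are over the whole patch
    (background in the denominator).
    """
    (cid,) = ensure_ids(schema, [class_id])
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8 full-resolution pixels")
    f = mask.downsample_factor
    if patch_size % f:
        raise ValueError("patch_size must be a multiple of the mask downsample factor")
    cells = patch_size // f
    grid = make_grid(mask.width, mask.height, (cells, cells), policy="clip")
    patches = []
    for p in grid.patches:
        block = mask.labels[p.y : p.y + p.height, p.x : p.x + p.width]
        total = block.size
        pct = 100.0 * float((block == cid).sum()) / total
        patches.append(
            HeatmapPatch(
                x=p.x * f, y=p.y * f, pixel_count=total * f * f, percent=pct
            )
        )
    return HeatmapGrid(class_id=cid, patch_size=patch_size, patches=tuple(patches))


# Blue -> red rendering: 0% maps to deep blue, 100% to red, linearly in RGB.
_DEEP_BLUE = np.array([0.0, 0.0, 143.0])
_RED = np.array([255.0, 0.0, 0.0])


def heatmap_color(percent: float) -> tuple[int, int, int]:
    """Continuous colormap value for one patch percentage (0 -> deep blue,
    100 -> red), interpolated through cyan/yellow like a jet-style ramp."""
    t = np.clip(percent / 100.0, 0.0, 1.0)
    # piecewise-linear jet-like ramp: deep blue, blue, cyan, yellow, red
    stops = np.array(
        [
            [0.0, 0.0, 143.0],
            [0.0, 0.0, 255.0],
            [0.0, 255.0, 255.0],
            [255.0, 255.0, 0.0],
            [255.0, 0.0, 0.0],
        ]
    )
    pos = np.linspace(0.0, 1.0, len(stops))
    rgb = [float(np.interp(t, pos, stops[:, ch])) for ch in range(3)]
    return tuple(int(round(v)) for v in rgb)


def render_heatmap(grid: HeatmapGrid, scale: int = 8) -> SectionImage:
    """Paint the grid as an RGB image, one ``patch_size/scale`` square per patch."""
    if not grid.patches:
        raise ValueError("empty heatmap grid")
    f = max(1, scale)
    w = max(p.x + grid.patch_size for p in grid.patches) // f
    h = max(p.y + grid.patch_size for p in grid.patches) // f
    img = np.zeros((max(h, 1), max(w, 1), 3), dtype=np.uint8)
    cell = max(1, grid.patch_size // f)
    for p in grid.patches:
        img[p.y // f : p.y // f + cell, p.x // f : p.x // f + cell] = heatmap_color(
            p.percent
        )
    return SectionImage(img, microns_per_pixel=1.0)


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------


def score_table(score: InjuryScore, schema: ClassSchema) -> pd.DataFrame:
    rows = []
    for c in schema.classes:
        rows.append(
            {
                "class_id": c.id,
                "class": c.name,
                "role": c.role,
                "pixels": score.per_class_pixels.get(c.id, 0),
                "percent_of_surface": score.per_class_percent.get(c.id, np.nan),
                "in_score": c.id in score.score_class_ids,
            }
        )
    return pd.DataFrame(rows)


def heatmap_table(grid: HeatmapGrid, schema: ClassSchema) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": p.x,
                "y": p.y,
                "class": schema[grid.class_id].name,
                "pixel_count": p.pixel_count,
                "percent": p.percent,
            }
            for p in grid.patches
        ]
    )


def write_heatmap(
    grid: HeatmapGrid, schema: ClassSchema, png_path: str | Path, scale: int = 8
) -> None:
    """Render to PNG plus a JSON sidecar describing the colour legend."""
    import json

    from .tiling import write_image

    img = render_heatmap(grid, scale=scale)
    write_image(img, png_path)
    sidecar = {
        "class": schema[grid.class_id].name,
        "patch_size_px": grid.patch_size,
        "render_scale": scale,
        "colormap": {"0%": "deep blue (0,0,143)", "100%": "red (255,0,0)"},
    }
    Path(png_path).with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")
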