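"""Semi-quantitative FOV grading and comparison with the CNN-based score.

The traditional (Wang-adapted) score grades ten randomly placed fields of
view on a 0-4 ordinal scale by the fraction of damaged tissue in each field
and averages the ten grades. The printed bin edges overlap in the source
protocol; the disjoint, exhaustive reading used here is:

====== ==================
grade  damage fraction
====== ==================
0      exactly 0
1      (0, 0.25]
2      (0.25, 0.50]
3      (0.50, 0.75]
4      (0.75, 1]
====== ==================

FOV damage is area-based: pathological score-class pixels over non-background
pixels within the field. Correlation between the two scorers is Spearman by
default (Pearson on mean ranks, p-value from the t approximation), with
plain Pearson available as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import injury_score
from .schema import ClassSchema, LabelMask, SectionImage, ensure_ids


def grade_fov(damage_fraction: float) -> int:
    """Ordinal 0-4 grade of one field of view from its damaged-area fraction."""
    f = float(damage_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("damage fraction must lie in [0, 1]")
    if f == 0.0:
        return 0
    if f <= 0.25:
        return 1
    if f <= 0.50:
        return 2
    if f <= 0.75:
        return 3
    return 4


@dataclass(frozen=True)
class SemiQuantScore:
    fov_grades: tuple[int, ...]
    mean_grade: float
    fov_origins: tuple[tuple[int, int], ...]
    fov_size: int
    seed: int


def semiquant_score(
    mask: LabelMask,
    schema: ClassSchema,
    n_fov: int = 10,
    fov_size: int = 512,
    seed: int = 0,
    region_mask: np.ndarray | None = None,
    score_classes: Iterable[int] | None = None,
) -> SemiQuantScore:
    """Grade ``n_fov`` randomly placed square fields of view and average.

    FOV origins are drawn uniformly (seeded) among positions whose field
    centre lies on tissue — by default anywhere on the non-background
    footprint; an optional boolean ``region_mask`` (same grid as the mask)
    emulates the pathologist's restriction to particular kidney zones. Per
    field, damage = score-class pixels / non-background pixels; empty fields
    grade 0.
    """
    if score_classes is None:
        ids = (schema.id_of("intratubular casts"), schema.id_of("tubular necrosis"))
    else:
        ids = ensure_ids(schema, score_classes)
    f = mask.downsample_factor
    if fov_size % f:
        raise ValueError("fov_size must be a multiple of the mask downsample factor")
    cells = fov_size // f
    h, w = mask.labels.shape
    if cells > h or cells > w:
        raise ValueError("FOV larger than the section")
    allowed = mask.labels != 0
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != mask.labels.shape:
            raise ValueError("region mask grid mismatch")
        allowed &= region_mask
    # candidate centres: tissue positions whose FOV stays in bounds
    cy, cx = np.nonzero(allowed)
    half = cells // 2
    ok = (cy >= half) & (cy < h - (cells - half)) & (cx >= half) & (cx < w - (cells - half))
    cy, cx = cy[ok], cx[ok]
    if cy.size == 0:
        raise ValueError("no admissible FOV positions in the allowed region")
    rng = np.random.Generator(np.random.PCG64(seed))
    pick = rng.integers(0, cy.size, size=n_fov)
    grades, origins = [], []
    is_patho = np.isin(mask.labels, ids)
    tissue = mask.labels != 0
    for i in pick:
        y0, x0 = int(cy[i] - half), int(cx[i] - half)
        sl = np.s_[y0 : y0 + cells, x0 : x0 + cells]
        tiss = int(tissue[sl].sum())
        frac = float(is_patho[sl].sum()) / tiss if tiss else 0.0
        grades.append(grade_fov(frac))
        origins.append((x0 * f, y0 * f))
    return SemiQuantScore(
        fov_grades=tuple(grades),
        mean_grade=float(np.mean(grades)),
        fov_origins=tuple(origins),
        fov_size=fov_size,
        seed=seed,
    )


@dataclass(frozen=True)
class ScorePair:
    section_id: int | str
    cnn_score_percent: float
    semiquant_mean_grade: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cnn_score_percent <= 100.0:
            raise ValueError("CNN score must lie in [0, 100]")
        if not 0.0 <= self.semiquant_mean_grade <= 4.0:
            raise ValueError("mean grade must lie in [0, 4]")


def correlate(
    pairs: Sequence[ScorePair],
    method: Literal["spearman", "pearson"] = "spearman",
) -> tuple[float, float]:
    """Correlation between the two scorers over a cohort.

    Spearman is the Pearson correlation of average-ranked data (ties get mean
    ranks) with the t-approximation p-value; a constant score vector makes
    the coefficient undefined and raises.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 score pairs")
    x = np.array([p.cnn_score_percent for p in pairs], dtype=float)
    y = np.array([p.semiquant_mean_grade for p in pairs], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("scores must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant score vector: correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def compare_cohort(
    sections: Sequence[tuple[int | str, LabelMask]],
    schema: ClassSchema,
    n_fov: int = 10,
    fov_size: int = 512,
    seed: int = 0,
    score_classes: Iterable[int] | None = None,
    method: Literal["spearman", "pearson"] = "spearman",
) -> tuple[pd.DataFrame, float, float]:
    """Score every section with both scorers and correlate across the cohort.

    ``sections`` pairs an id with a label mask (predicted or ground truth).
    Returns the per-section score table and the (coefficient, p_value) of the
    requested correlation.
    """
    if not sections:
        raise ValueError("empty cohort")
    rows, pairs = [], []
    for i, (sid, mask) in enumerate(sections):
        cnn = injury_score(mask, schema, score_classes=score_classes)
        semi = semiquant_score(
            mask,
            schema,
            n_fov=n_fov,
            fov_size=fov_size,
            seed=seed + i,
            score_classes=score_classes,
        )
        pairs.append(ScorePair(sid, cnn.score_percent, semi.mean_grade))
        rows.append(
            {
                "section_id": sid,
                "cnn_score_percent": cnn.score_percent,
                "semiquant_mean_grade": semi.mean_grade,
                "fov_grades": ",".join(map(str, semi.fov_grades)),
            }
        )
    r, p = correlate(pairs, method=method)
    return pd.DataFrame(rows), r, p
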