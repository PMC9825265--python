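"""Per-cell shape properties and population-level summaries.

Shape definitions
-----------------
* area = pixel count × pixel_size²
* circumference = arc length of the (lightly subsampled) marching-squares
  boundary contour — raw boundary-pixel counts overestimate perimeters
  resolution-dependently and depress circularity
* circularity = 4πA/P², clipped to [0, 1] (a circle is 1)
* aspect_ratio = major/minor axis of the inertia-equivalent ellipse (≥ 1)

Cells touching the image border are flagged: their truncated outlines bias
shape statistics, so they are excluded from population summaries but kept
as nodes for the adjacency network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .io import LabelImage


@dataclass
class CellRecord:
    cell_id: int
    centroid_um: tuple[float, float]  # (row, col) µm
    area_um2: float
    circumference_um: float
    circularity: float
    aspect_ratio: float
    touches_border: bool = False

    def __post_init__(self) -> None:
        if self.area_um2 <= 0 or self.circumference_um <= 0:
            raise ValueError("area and circumference must be positive")
        if not (0 < self.circularity <= 1):
            raise ValueError("circularity must lie in (0, 1]")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")


SHAPE_PROPERTIES = ("area_um2", "circumference_um", "circularity", "aspect_ratio")


def contour_perimeter(mask: np.ndarray, step: int = 3) -> float:
    """Boundary arc length (px) of a mask via marching-squares contours.

    The contour polygon is subsampled every ``step`` vertices before
    summing segment lengths: the raw half-pixel staircase overestimates
    smooth boundaries (a disc by ~6%), while light subsampling keeps
    straight edges exact and brings discs within ~2% of πd.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        pts = contour[::step]
        if not np.array_equal(pts[-1], contour[-1]):
            pts = np.vstack([pts, contour[-1]])
        seg = np.diff(pts, axis=0)
        total += float(np.sqrt((seg ** 2).sum(axis=1)).sum())
    return total


@dataclass
class PopulationSnapshot:
    """One image's worth of morphology: cells plus summary statistics.

    ``summary[prop]`` maps to (mean, population variance, Shannon entropy)
    over non-border cells; entries are None when no measurable cell exists.
    """

    image_id: str
    clone_id: str
    confluency: float
    cells: list[CellRecord]
    summary: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def to_row(self) -> dict[str, float]:
        """Flatten to one table row (for progression assembly)."""
        row: dict[str, float] = {"confluency": self.confluency}
        for prop, stats in self.summary.items():
            for stat, value in stats.items():
                row[f"{prop}_{stat}"] = np.nan if value is None else value
        return row


def measure_cells(img: LabelImage) -> list[CellRecord]:
    """Measure shape properties of every labeled cell.

    One record per label. Border-touching cells are flagged rather than
    dropped so they can still serve as network nodes.
    """
    px = img.pixel_size
    records: list[CellRecord] = []
    nrows, ncols = img.pixels.shape
    for rp in measure.regionprops(img.pixels):
        area = rp.area * px * px
        perimeter = max(contour_perimeter(rp.image), 1.0)  # guard tiny cells
        circ = min(4 * math.pi * area / (perimeter * px) ** 2, 1.0)
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        aspect = max(major / minor, 1.0) if minor > 0 else 1.0
        r0, c0, r1, c1 = rp.bbox
        records.append(CellRecord(
            cell_id=int(rp.label),
            centroid_um=(rp.centroid[0] * px, rp.centroid[1] * px),
            area_um2=float(area),
            circumference_um=float(perimeter * px),
            circularity=float(max(circ, 1e-12)),
            aspect_ratio=float(aspect),
            touches_border=bool(r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols),
        ))
    return records


def shannon_entropy(values, bins: str | int | np.ndarray = "fd") -> float:
    """Shannon entropy H = −Σ p ln p (nats) of the empirical distribution.

    Continuous values are binned (Freedman–Diaconis by default); the
    convention 0·ln 0 = 0 applies. Raises on empty input.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("shannon_entropy requires at least one value")
    if np.ptp(values) == 0:
        return 0.0
    counts, _ = np.histogram(values, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def entropy_from_probabilities(p) -> float:
    """Entropy of an explicit probability vector (must sum to 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("probabilities must be nonempty and sum to 1")
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def snapshot(img: LabelImage) -> PopulationSnapshot:
    """Confluency plus mean/variance/entropy of each shape property.

    Summaries use non-border cells only; with zero measurable cells the
    summaries are marked missing (None) and confluency may still be 0.
    """
    cells = measure_cells(img)
    interior = [c for c in cells if not c.touches_border]
    summary: dict[str, dict[str, float | None]] = {}
    for prop in SHAPE_PROPERTIES:
        vals = np.array([getattr(c, prop) for c in interior], dtype=float)
        if vals.size == 0:
            summary[prop] = {"mean": None, "var": None, "entropy": None}
        else:
            summary[prop] = {
                "mean": float(vals.mean()),
                "var": float(vals.var()),  # population variance
                "entropy": shannon_entropy(vals),
            }
    return PopulationSnapshot(
        image_id=img.image_id,
        clone_id=img.clone_id,
        confluency=img.confluency,
        cells=cells,
        summary=summary,
    )
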