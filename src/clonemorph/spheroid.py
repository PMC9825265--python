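"""3D spheroid invasion quantification from confocal z-stacks.

A 75 µm window of slices from the middle of each spheroid (15 slices at
5 µm spacing) is max-projected, binarized (Otsu), and measured:

* spheroid body shape — area, circularity (4πA/P²), solidity (A / convex
  hull area) of the largest connected component;
* protrusions — connected extensions of the body, found as the residue of
  a morphological opening; each length is the distance from protrusion tip
  to the spheroid centroid;
* disseminated regions — foreground components disconnected from the body
  (cells that migrated away), quantified by area and centroid-to-centroid
  distance from the body.

Six invasion metrics (protrusion count / mean / max length, disseminated
count / mean / max distance) are min–max normalized across the analyzed
clone set and averaged into the composite ``invasion3D`` score in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .io import ZStack
from .morphology import contour_perimeter

INVASION_METRICS = ("n_p", "avg_p", "max_p", "n_c", "avg_c", "max_c")


@dataclass
class SpheroidMeasurement:
    spheroid_id: str
    clone_id: str
    area_um2: float
    circularity: float
    solidity: float
    n_p: int
    protrusion_lengths_um: list[float]
    n_c: int
    region_areas_um2: list[float]
    region_distances_um: list[float]

    def __post_init__(self) -> None:
        if self.n_p != len(self.protrusion_lengths_um):
            raise ValueError("n_p must equal the number of protrusion lengths")
        if self.n_c != len(self.region_distances_um):
            raise ValueError("n_c must equal the number of region distances")
        if not (0 < self.solidity <= 1 + 1e-9):
            raise ValueError("solidity must lie in (0, 1]")

    @property
    def avg_p(self) -> float:
        return float(np.mean(self.protrusion_lengths_um)) if self.protrusion_lengths_um else 0.0

    @property
    def max_p(self) -> float:
        return float(np.max(self.protrusion_lengths_um)) if self.protrusion_lengths_um else 0.0

    @property
    def avg_c(self) -> float:
        return float(np.mean(self.region_distances_um)) if self.region_distances_um else 0.0

    @property
    def max_c(self) -> float:
        return float(np.max(self.region_distances_um)) if self.region_distances_um else 0.0

    def metric_row(self) -> dict[str, float]:
        return {"n_p": float(self.n_p), "avg_p": self.avg_p, "max_p": self.max_p,
                "n_c": float(self.n_c), "avg_c": self.avg_c, "max_c": self.max_c,
                "area_um2": self.area_um2, "circularity": self.circularity,
                "solidity": self.solidity}


@dataclass
class InvasionScore:
    clone_id: str
    invasion3d: float
    normalized: dict[str, float]
    normalization_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Projection and binarization
# ---------------------------------------------------------------------------

def project_stack(stack: ZStack, window_um: float = 75.0,
                  center: int | None = None) -> np.ndarray:
    """Max-intensity projection of the central window of slices.

    Each slice counts as one ``z_spacing`` height increment, so the window
    holds ``window_um / z_spacing`` slices (15 slices at 5 µm span 75 µm).
    ``center=None`` auto-centers on the slice with the most foreground
    after a provisional Otsu threshold.
    """
    n_window = int(round(window_um / stack.z_spacing))
    if stack.n_slices < n_window:
        raise ValueError(f"stack of {stack.n_slices} slices cannot span "
                         f"{window_um} µm at {stack.z_spacing} µm spacing")
    if center is None:
        thresh = filters.threshold_otsu(np.asarray(stack.slices))
        per_slice = (np.asarray(stack.slices) > thresh).sum(axis=(1, 2))
        center = int(np.argmax(per_slice))
    half = n_window // 2
    lo = min(max(center - half, 0), stack.n_slices - n_window)
    return np.max(np.asarray(stack.slices)[lo:lo + n_window], axis=0)


def binarize(projection: np.ndarray, pixel_size: float = 1.0,
             min_area_um2: float = 50.0,
             threshold: float | None = None) -> np.ndarray:
    """Binarize a projected image: global Otsu, speck removal, hole filling.

    Components smaller than ``min_area_um2`` are removed; holes inside the
    largest body are filled. A fixed ``threshold`` overrides Otsu.
    """
    projection = np.asarray(projection, dtype=float)
    if projection.size == 0 or np.ptp(projection) == 0:
        raise ValueError("cannot binarize a blank image")
    t = filters.threshold_otsu(projection) if threshold is None else threshold
    mask = projection > t
    min_px = max(int(round(min_area_um2 / pixel_size ** 2)), 1)
    labeled, n = ndimage.label(mask)
    if n:
        sizes = np.bincount(labeled.ravel())
        sizes[0] = 0
        mask = np.isin(labeled, np.nonzero(sizes >= min_px)[0])
    if not mask.any():
        raise ValueError("binarization produced an empty mask")
    labeled, _ = ndimage.label(mask)
    body_label = np.argmax(np.bincount(labeled[labeled > 0]))
    body_filled = ndimage.binary_fill_holes(labeled == body_label)
    return mask | body_filled


def _main_body(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(body mask, labeled components) with the body = largest component."""
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool))
    if n == 0:
        raise ValueError("mask is empty")
    body_label = np.argmax(np.bincount(labeled[labeled > 0]))
    return labeled == body_label, labeled


# ---------------------------------------------------------------------------
# Shape, protrusions, dissemination
# ---------------------------------------------------------------------------

def measure_spheroid(mask: np.ndarray, pixel_size: float) -> tuple[float, float, float]:
    """(area µm², circularity, solidity) of the main body."""
    body, _ = _main_body(mask)
    rp = measure.regionprops(body.astype(np.uint8))[0]
    area = rp.area * pixel_size ** 2
    perimeter = max(contour_perimeter(body), 1.0)
    circularity = min(4 * math.pi * area / (perimeter * pixel_size) ** 2, 1.0)
    solidity = min(rp.solidity, 1.0)
    return float(area), float(circularity), float(solidity)


def detect_protrusions(mask: np.ndarray, pixel_size: float,
                       core_radius_um: float | None = None,
                       min_protrusion_length_um: float = 20.0) -> tuple[int, list[float]]:
    """Count and measure protrusions of the main body.

    The core is a morphological opening of the body with a disc of
    ``core_radius_um`` (default 0.8 × the body's equivalent radius).
    Candidates are connected components of body − core that touch the
    core; a candidate counts as a protrusion when its radial extent —
    its tip distance to the spheroid centroid minus the core's own maximal
    radial reach — is at least ``min_protrusion_length_um``. The recorded
    length is the tip-to-centroid distance (µm).

    The spheroid centroid is taken from the opened core (the body proper):
    the protrusions themselves would otherwise bias the reference point
    they are measured against.
    """
    body, _ = _main_body(mask)
    area_px = body.sum()
    equiv_radius_um = math.sqrt(area_px / math.pi) * pixel_size
    auto = core_radius_um is None
    if auto:
        core_radius_um = 0.8 * equiv_radius_um
    core_radius_px = max(int(round(core_radius_um / pixel_size)), 1)
    core = morphology.opening(body, morphology.disk(core_radius_px))
    while auto and not core.any() and core_radius_px > 1:
        core_radius_px = max(int(core_radius_px * 0.8), 1)  # shrink until the core survives
        core = morphology.opening(body, morphology.disk(core_radius_px))
    if not core.any():
        raise ValueError("core is empty: core_radius too large for the body")
    centroid = np.array(ndimage.center_of_mass(core))
    core_coords = np.column_stack(np.nonzero(core))
    core_reach_um = float(np.sqrt(((core_coords - centroid) ** 2).sum(axis=1)).max()) * pixel_size

    residue = body & ~core
    labeled, n = ndimage.label(residue)
    core_dilated = ndimage.binary_dilation(core)
    lengths: list[float] = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        if not (comp & core_dilated).any():
            continue  # not attached to the core (raster slivers)
        coords = np.column_stack(np.nonzero(comp))
        tip_um = float(np.sqrt(((coords - centroid) ** 2).sum(axis=1)).max()) * pixel_size
        if tip_um - core_reach_um >= min_protrusion_length_um:
            lengths.append(tip_um)
    lengths.sort()
    return len(lengths), lengths


def detect_dissemination(mask: np.ndarray, pixel_size: float,
                         min_area_um2: float = 50.0) -> tuple[int, list[float], list[float]]:
    """Count disseminated regions and measure their areas and distances.

    Regions are connected components other than the main body with area at
    least ``min_area_um2``; distance is Euclidean centroid-to-centroid from
    the main-body centroid (µm). Returns (n_c, areas, distances) with areas
    and distances ordered by increasing distance.
    """
    body, labeled = _main_body(mask)
    body_centroid = np.array(ndimage.center_of_mass(body))
    body_label = labeled[body][0]
    min_px = min_area_um2 / pixel_size ** 2
    results = []
    for lab in range(1, labeled.max() + 1):
        if lab == body_label:
            continue
        comp = labeled == lab
        area_px = comp.sum()
        if area_px < min_px:
            continue
        centroid = np.array(ndimage.center_of_mass(comp))
        dist = float(np.linalg.norm(centroid - body_centroid)) * pixel_size
        results.append((dist, float(area_px) * pixel_size ** 2))
    results.sort()
    return (len(results),
            [a for _, a in results],
            [d for d, _ in results])


def measure_stack(stack: ZStack, clone_id: str = "", window_um: float = 75.0,
                  min_area_um2: float = 50.0,
                  min_protrusion_length_um: float = 20.0,
                  core_radius_um: float | None = None,
                  threshold: float | None = None) -> SpheroidMeasurement:
    """Full per-stack pipeline: project → binarize → shape/protrusions/regions."""
    projection = project_stack(stack, window_um=window_um)
    mask = binarize(projection, pixel_size=stack.pixel_size,
                    min_area_um2=min_area_um2, threshold=threshold)
    area, circularity, solidity = measure_spheroid(mask, stack.pixel_size)
    n_p, lengths = detect_protrusions(mask, stack.pixel_size,
                                      core_radius_um=core_radius_um,
                                      min_protrusion_length_um=min_protrusion_length_um)
    n_c, areas, distances = detect_dissemination(mask, stack.pixel_size,
                                                 min_area_um2=min_area_um2)
    return SpheroidMeasurement(
        spheroid_id=stack.spheroid_id,
        clone_id=clone_id,
        area_um2=area,
        circularity=circularity,
        solidity=solidity,
        n_p=n_p,
        protrusion_lengths_um=lengths,
        n_c=n_c,
        region_areas_um2=areas,
        region_distances_um=distances,
    )


# ---------------------------------------------------------------------------
# Composite invasion score
# ---------------------------------------------------------------------------

def invasion_score(measurements: list[SpheroidMeasurement]) -> list[InvasionScore]:
    """invasion3D per clone: mean of six min–max normalized invasion metrics.

    Replicate spheroids of one clone are averaged per metric first; each
    metric is then normalized to [0, 1] across the clone set (0 = minimum
    measured value, 1 = maximum) and the six normalized values averaged.
    A metric constant across clones normalizes to 0 with a warning.
    """
    by_clone: dict[str, list[SpheroidMeasurement]] = {}
    for m in measurements:
        by_clone.setdefault(m.clone_id, []).append(m)
    if len(by_clone) < 2:
        raise ValueError("invasion3D normalization requires >= 2 clones")
    clone_means = {
        cid: {k: float(np.mean([m.metric_row()[k] for m in ms])) for k in INVASION_METRICS}
        for cid, ms in by_clone.items()
    }
    bounds = {}
    for k in INVASION_METRICS:
        vals = [clone_means[c][k] for c in clone_means]
        bounds[k] = (min(vals), max(vals))
        if bounds[k][0] == bounds[k][1]:
            warnings.warn(f"invasion metric {k!r} constant across clones; "
                          "normalized value set to 0", stacklevel=2)
    scores = []
    for cid, means in clone_means.items():
        normalized = {}
        for k in INVASION_METRICS:
            lo, hi = bounds[k]
            normalized[k] = 0.0 if hi == lo else (means[k] - lo) / (hi - lo)
        scores.append(InvasionScore(
            clone_id=cid,
            invasion3d=float(np.mean([normalized[k] for k in INVASION_METRICS])),
            normalized=normalized,
            normalization_bounds=bounds,
        ))
    return scores
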