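"""Synthetic fixtures with exact ground truth.

Three generators emulate the pipeline's inputs:

* :func:`generate_population` — a label image of perturbed-ellipse cells
  placed by rejection sampling at controlled confluency, with continuous
  (polygon-based) ground truth for per-cell area, centroid, and the
  adjacency pairs whose planted edge-to-edge gap is below 5 µm.
* :func:`generate_progression` — per-property values along a density axis
  drawn from planted quadratic trends plus Gaussian noise.
* :func:`generate_spheroid_stack` — a fluorescence-like z-stack of a
  spheroid body with radial protrusion arms (capsules) and disseminated
  blobs at planted tip/centroid distances.
* :func:`generate_clone_panel` — growth-variable vectors from a nested
  planted partition (superclasses × subclasses) for clustering tests.

All generators are deterministic given their integer seed. Cells are
represented as continuous polygons (µm coordinates) so areas, centroids
and pairwise boundary gaps have exact values by construction, independent
of rasterization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .io import LabelImage, ZStack

ADJACENCY_GAP_UM = 5.0  # planted-truth adjacency threshold, matches the network builder


# ---------------------------------------------------------------------------
# 2D populations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPopulationSpec:
    """Parameters for one synthetic cell population.

    Two safeguards keep the planted adjacency set unambiguous under
    rasterization. ``gap_exclusion`` rejects placements whose nearest
    boundary gap falls in a band straddling the 5 µm adjacency threshold.
    Additionally, since raster boundary-pixel distances can only inflate a
    continuous gap (pixel centers lie strictly inside the outlines), every
    placement is verified to classify identically in continuous and raster
    space, and rejected otherwise.
    """

    n_cells: int = 100
    image_shape: tuple[int, int] = (512, 512)  # pixels
    pixel_size: float = 1.0  # µm/px
    target_confluency: float | None = None  # stop early once reached
    semi_axis_range: tuple[float, float] = (8.0, 20.0)  # µm
    perturbation: float = 0.08  # relative radial amplitude
    min_gap: float = 2.0  # µm, smallest allowed edge-to-edge spacing
    gap_exclusion: tuple[float, float] = (3.5, 7.0)  # µm band around threshold
    max_attempts_per_cell: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_confluency is not None and not (0 <= self.target_confluency <= 1):
            raise ValueError("target_confluency must be in [0, 1]")
        if min(self.semi_axis_range) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.min_gap <= 0:
            raise ValueError("min_gap must be positive")


@dataclass
class PopulationTruth:
    """Planted ground truth accompanying a generated label image."""

    areas_um2: dict[int, float]  # label -> polygon area
    centroids_um: dict[int, tuple[float, float]]  # label -> (row, col) µm
    adjacency: set[tuple[int, int]]  # label pairs (u < v) with gap < 5 µm
    gaps_um: dict[tuple[int, int], float]  # all pairwise boundary gaps
    polygons: dict[int, Polygon] = field(repr=False, default_factory=dict)


def _perturbed_ellipse(center_um: tuple[float, float], a: float, b: float,
                       angle: float, amplitude: float, rng: np.random.Generator,
                       n_vertices: int = 128) -> Polygon:
    """Polygon of an ellipse with a smooth low-order radial perturbation."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    # 2nd..4th harmonic perturbation keeps the outline convex-ish
    radial = np.ones_like(theta)
    if amplitude > 0:
        for k in (2, 3, 4):
            radial += (amplitude / 3) * rng.uniform(-1, 1) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    x = a * np.cos(theta) * radial
    y = b * np.sin(theta) * radial
    ca, sa = math.cos(angle), math.sin(angle)
    rows = center_um[0] + x * sa + y * ca
    cols = center_um[1] + x * ca - y * sa
    return Polygon(np.column_stack([rows, cols]))


def _rasterize(poly: Polygon, shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.asarray(poly.exterior.coords).T
    return draw_polygon(rows / pixel_size, cols / pixel_size, shape=shape)


def _raster_boundary(rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Boundary pixel coordinates of a rasterized cell (4-connectivity)."""
    filled = set(zip(rr.tolist(), cc.tolist()))
    return np.array([(r, c) for r, c in filled
                     if any((r + dr, c + dc) not in filled
                            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)))],
                    dtype=float)


def generate_population(spec: SyntheticPopulationSpec) -> tuple[LabelImage, PopulationTruth]:
    """Generate a label image plus exact ground truth.

    Raises ``RuntimeError`` when the requested packing is infeasible within
    the bounded rejection budget.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    px = spec.pixel_size
    h_um = shape[0] * px
    w_um = shape[1] * px
    image_area = shape[0] * shape[1] * px ** 2

    pixels = np.zeros(shape, dtype=np.int32)
    polygons: dict[int, Polygon] = {}
    boundary_trees: dict[int, cKDTree] = {}
    lo_band, hi_band = spec.gap_exclusion
    covered = 0.0
    label = 0

    for _ in range(spec.n_cells):
        if spec.target_confluency is not None and covered / image_area >= spec.target_confluency:
            break
        placed = False
        for _attempt in range(spec.max_attempts_per_cell):
            a = rng.uniform(*spec.semi_axis_range)
            b = rng.uniform(*spec.semi_axis_range)
            margin = max(a, b) * (1 + spec.perturbation) + px
            if 2 * margin >= min(h_um, w_um):
                raise RuntimeError("cell axes too large for the image")
            center = (rng.uniform(margin, h_um - margin), rng.uniform(margin, w_um - margin))
            angle = rng.uniform(0, np.pi)
            cand = _perturbed_ellipse(center, a, b, angle, spec.perturbation, rng)
            gaps = {}
            ok = True
            for lab, other in polygons.items():
                gap = cand.distance(other)
                if gap < spec.min_gap or (lo_band < gap < hi_band):
                    ok = False
                    break
                gaps[lab] = gap
            if not ok:
                continue
            rr, cc = _rasterize(cand, shape, px)
            if rr.size == 0:
                continue
            cand_boundary = _raster_boundary(rr, cc)
            cand_tree = cKDTree(cand_boundary)
            # raster distances only inflate continuous gaps, so only planted
            # edges can misclassify; reject placements where they would
            for lab, gap in gaps.items():
                if gap < ADJACENCY_GAP_UM + 2:
                    d = cand_tree.query(boundary_trees[lab].data, k=1)[0].min() * px
                    if (gap < ADJACENCY_GAP_UM) != (d < ADJACENCY_GAP_UM):
                        ok = False
                        break
            if ok:
                label += 1
                polygons[label] = cand
                boundary_trees[label] = cand_tree
                pixels[rr, cc] = label
                covered += cand.area
                placed = True
                break
        if not placed:
            if spec.target_confluency is not None:
                break  # packing saturated below target: return what fits
            raise RuntimeError(
                f"could not place cell {label + 1}/{spec.n_cells} after "
                f"{spec.max_attempts_per_cell} attempts (packing infeasible)")

    truth = PopulationTruth(
        areas_um2={lab: p.area for lab, p in polygons.items()},
        centroids_um={lab: (p.centroid.x, p.centroid.y) for lab, p in polygons.items()},
        adjacency=set(),
        gaps_um={},
        polygons=polygons,
    )
    for u, v in itertools.combinations(sorted(polygons), 2):
        gap = polygons[u].distance(polygons[v])
        truth.gaps_um[(u, v)] = gap
        if gap < ADJACENCY_GAP_UM:
            truth.adjacency.add((u, v))

    img = LabelImage(pixels, spec.pixel_size, image_id=f"synth-seed{spec.seed}")
    return img, truth


def place_discs(centers_um: list[tuple[float, float]], radii_um: list[float],
                image_shape: tuple[int, int], pixel_size: float = 1.0) -> tuple[LabelImage, PopulationTruth]:
    """Deterministically rasterize circular cells at given centers (µm).

    Convenience for boundary fixtures (e.g. two discs with a planted 3 µm
    or 10 µm gap).
    """
    pixels = np.zeros(image_shape, dtype=np.int32)
    polygons: dict[int, Polygon] = {}
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    for i, (c, r) in enumerate(zip(centers_um, radii_um), start=1):
        poly = Polygon(np.column_stack([c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)]))
        polygons[i] = poly
        rr, cc = _rasterize(poly, image_shape, pixel_size)
        pixels[rr, cc] = i
    truth = PopulationTruth(
        areas_um2={i: p.area for i, p in polygons.items()},
        centroids_um={i: (p.centroid.x, p.centroid.y) for i, p in polygons.items()},
        adjacency=set(),
        gaps_um={},
        polygons=polygons,
    )
    for u, v in itertools.combinations(sorted(polygons), 2):
        gap = polygons[u].distance(polygons[v])
        truth.gaps_um[(u, v)] = gap
        if gap < ADJACENCY_GAP_UM:
            truth.adjacency.add((u, v))
    return LabelImage(pixels, pixel_size, image_id="discs"), truth


# ---------------------------------------------------------------------------
# Clone progressions
# ---------------------------------------------------------------------------

def generate_progression(coefficients: dict[str, tuple[float, float, float]],
                         densities: list[float] | np.ndarray,
                         noise_sd: float = 0.0,
                         seed: int = 0) -> tuple[list[dict[str, float]], dict[str, tuple[float, float, float]]]:
    """Draw property values along a confluency axis from planted quadratics.

    ``coefficients[prop] = (c0, c1, c2)`` gives value ``c0 + c1 d + c2 d²``
    at confluency ``d``; observed values add N(0, noise_sd) noise.

    Returns (points, coefficients): points is a list of dicts, one per
    density, each containing ``confluency`` plus every property.
    """
    densities = np.asarray(densities, dtype=float)
    if densities.size and (densities.min() < 0 or densities.max() > 1):
        raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    points = []
    for d in densities:
        row = {"confluency": float(d)}
        for prop, (c0, c1, c2) in coefficients.items():
            row[prop] = float(c0 + c1 * d + c2 * d * d + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0))
        points.append(row)
    return points, dict(coefficients)


# ---------------------------------------------------------------------------
# Spheroid z-stacks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpheroidSpec:
    """Parameters for one synthetic spheroid z-stack.

    Protrusion lengths are tip-to-centroid distances; disseminated
    distances are blob-centroid to body-centroid. Both must exceed
    ``body_radius``.
    """

    body_radius: float = 120.0  # µm
    n_protrusions: int = 0
    protrusion_lengths: tuple[float, ...] = ()
    protrusion_width: float = 24.0  # µm, capsule diameter
    n_disseminated: int = 0
    disseminated_distances: tuple[float, ...] = ()
    disseminated_areas: tuple[float, ...] = ()
    noise_sd: float = 6.0  # intensity units
    foreground: float = 200.0
    background: float = 20.0
    image_shape: tuple[int, int] = (384, 384)
    pixel_size: float = 2.0  # µm/px
    n_slices: int = 15
    z_spacing: float = 5.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.protrusion_lengths) != self.n_protrusions:
            raise ValueError("protrusion_lengths length must equal n_protrusions")
        if len(self.disseminated_distances) != self.n_disseminated:
            raise ValueError("disseminated_distances length must equal n_disseminated")
        if self.disseminated_areas and len(self.disseminated_areas) != self.n_disseminated:
            raise ValueError("disseminated_areas length must equal n_disseminated")
        if any(l <= self.body_radius for l in self.protrusion_lengths):
            raise ValueError("protrusion lengths must exceed body_radius")
        if any(d <= self.body_radius for d in self.disseminated_distances):
            raise ValueError("disseminated distances must exceed body_radius")
        if self.n_slices < 15:
            raise ValueError("need at least 15 slices")


@dataclass
class SpheroidTruth:
    mask: np.ndarray  # planted full cross-section (bool)
    centroid_um: tuple[float, float]
    cross_section_um2: float
    n_protrusions: int
    protrusion_lengths_um: tuple[float, ...]
    n_disseminated: int
    disseminated_distances_um: tuple[float, ...]
    disseminated_areas_um2: tuple[float, ...]


def _disc_mask(shape: tuple[int, int], center_px: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px ** 2


def _capsule_mask(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, half_width_px: float) -> np.ndarray:
    """Pixels within half_width of segment p0-p1 (px coordinates)."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d = p1 - p0
    len2 = float(d @ d)
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / max(len2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dr = rr - (p0[0] + t * d[0])
    dc = cc - (p0[1] + t * d[1])
    return dr * dr + dc * dc <= half_width_px ** 2


def generate_spheroid_stack(spec: SyntheticSpheroidSpec) -> tuple[ZStack, SpheroidTruth]:
    """Generate a spheroid z-stack with planted protrusions and blobs.

    The middle slice carries the full planted cross-section (body + arms +
    blobs); flanking slices carry sphere-profile body discs, so the max
    projection over the central 75 µm window recovers the planted mask.
    Raises ``RuntimeError`` if planted structures would overlap or leave
    the field of view.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    px = spec.pixel_size
    center_px = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])

    reach = max([spec.body_radius, *spec.protrusion_lengths,
                 *[d + math.sqrt(a / math.pi) for d, a in
                   zip(spec.disseminated_distances,
                       spec.disseminated_areas or [400.0] * spec.n_disseminated)]])
    if reach / px >= min(center_px):
        raise RuntimeError("planted structures exceed the field of view")

    # interleave arm and blob directions on a jittered angular grid
    n_dirs = spec.n_protrusions + spec.n_disseminated
    angles = []
    if n_dirs:
        base = rng.uniform(0, 2 * np.pi)
        angles = [base + 2 * np.pi * i / n_dirs for i in range(n_dirs)]
    arm_angles = angles[: spec.n_protrusions]
    blob_angles = angles[spec.n_protrusions:]
    if n_dirs > 1:
        min_sep = 2 * np.pi / n_dirs
        widths = math.asin(min(1, (spec.protrusion_width / 2) / spec.body_radius)) * 2
        if min_sep < widths:
            raise RuntimeError("too many planted structures: arms would overlap")

    body = _disc_mask(shape, tuple(center_px), spec.body_radius / px)
    full = body.copy()
    half_w = (spec.protrusion_width / 2) / px
    for ang, length in zip(arm_angles, spec.protrusion_lengths):
        u = np.array([math.cos(ang), math.sin(ang)])
        # capsule from centroid toward tip; cap radius ends at the tip distance
        tip = center_px + u * (length / px - half_w)
        full |= _capsule_mask(shape, center_px, tip, half_w)

    # asymmetric arms shift the connected body's centroid away from the disc
    # center; dissemination distances are planted from the actual centroid of
    # the body∪arms mask, the reference the measurement stage uses
    body_centroid_px = np.array([c.mean() for c in np.nonzero(full)])

    blob_areas = list(spec.disseminated_areas) or [400.0] * spec.n_disseminated
    blob_masks = []
    for ang, dist, area in zip(blob_angles, spec.disseminated_distances, blob_areas):
        u = np.array([math.cos(ang), math.sin(ang)])
        c = body_centroid_px + u * (dist / px)
        r_px = math.sqrt(area / math.pi) / px
        blob = _disc_mask(shape, tuple(c), r_px)
        if (blob & full).any() or any((blob & b).any() for b in blob_masks):
            raise RuntimeError("planted disseminated blob overlaps another structure")
        blob_masks.append(blob)
    for blob in blob_masks:
        full |= blob

    mid = spec.n_slices // 2
    stack = np.empty((spec.n_slices, *shape), dtype=np.float32)
    for i in range(spec.n_slices):
        z = abs(i - mid) * spec.z_spacing
        if i == mid:
            sl = full
        elif z < spec.body_radius:
            sl = _disc_mask(shape, tuple(center_px), math.sqrt(spec.body_radius ** 2 - z ** 2) / px)
        else:
            sl = np.zeros(shape, dtype=bool)
        plane = np.where(sl, spec.foreground, spec.background).astype(np.float32)
        plane += rng.normal(0, spec.noise_sd, size=shape).astype(np.float32)
        stack[i] = plane

    truth = SpheroidTruth(
        mask=full,
        centroid_um=(body_centroid_px[0] * px, body_centroid_px[1] * px),
        cross_section_um2=float(full.sum()) * px * px,
        n_protrusions=spec.n_protrusions,
        protrusion_lengths_um=tuple(spec.protrusion_lengths),
        n_disseminated=spec.n_disseminated,
        disseminated_distances_um=tuple(spec.disseminated_distances),
        disseminated_areas_um2=tuple(float(b.sum()) * px * px for b in blob_masks),
    )
    zs = ZStack(stack, z_spacing=spec.z_spacing, pixel_size=px,
                spheroid_id=f"synth-spheroid-seed{spec.seed}")
    return zs, truth


# ---------------------------------------------------------------------------
# Planted clone panels (for clustering)
# ---------------------------------------------------------------------------

def generate_clone_panel(n_clones: int = 60, n_super: int = 2, n_sub: int = 3,
                         n_variables: int = 8, separation: float = 4.0,
                         within_sd: float = 1.0, seed: int = 0):
    """Growth-variable vectors from a nested planted partition.

    Superclass centers are ``separation * within_sd * n_sub`` apart,
    subclass centers within a superclass ``separation * within_sd`` apart,
    so between-group separation is ≥ ``separation``× the within-group sd.

    Returns (matrix [n_clones, n_variables], super_labels, sub_labels).
    Sub labels are global (superclass * n_sub + subclass).
    """
    rng = np.random.default_rng(seed)
    per = n_clones // (n_super * n_sub)
    if per < 1:
        raise ValueError("n_clones too small for the requested hierarchy")
    directions = rng.normal(size=(n_super * n_sub + n_super, n_variables))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    rows, super_labels, sub_labels = [], [], []
    for s in range(n_super):
        super_center = directions[s] * separation * within_sd * n_sub * 2
        for b in range(n_sub):
            center = super_center + directions[n_super + s * n_sub + b] * separation * within_sd * 2
            for _ in range(per):
                rows.append(center + rng.normal(0, within_sd, size=n_variables))
                super_labels.append(s)
                sub_labels.append(s * n_sub + b)
    # distribute any remainder over the first groups
    for i in range(n_clones - len(rows)):
        s, b = i % n_super, (i // n_super) % n_sub
        center = (directions[s] * separation * within_sd * n_sub * 2
                  + directions[n_super + s * n_sub + b] * separation * within_sd * 2)
        rows.append(center + rng.normal(0, within_sd, size=n_variables))
        super_labels.append(s)
        sub_labels.append(s * n_sub + b)
    return np.asarray(rows), np.asarray(super_labels), np.asarray(sub_labels)
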