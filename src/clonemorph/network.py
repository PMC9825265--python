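"""Cell adjacency networks and their topology metrics.

Each segmented cell is a node; an edge joins two cells whose minimum
boundary-to-boundary distance (Euclidean, µm, between boundary pixel
centers) is strictly below a threshold (default 5 µm). From the network we
derive degree statistics, average colorability (mean chromatic number over
connected components — a proxy for the maximum achievable packing density),
component statistics, and the box-counting fractal dimension of the
foreground, which together describe cell adhesion, migration and
clustering behavior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import LabelImage
from .morphology import entropy_from_probabilities


@dataclass
class CellNetwork:
    """Graph of cells with centroid (µm) and area (µm²) node attributes."""

    graph: nx.Graph
    pixel_size: float = 1.0
    adjacency_threshold_um: float = 5.0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def components(self) -> list[set]:
        """Connected components, largest first (ties by smallest member id)."""
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), min(c) if c else 0))

    def component_masses(self) -> np.ndarray:
        return np.array([len(c) for c in self.components()], dtype=int)


@dataclass
class NetworkMetrics:
    mean_degree: float
    degree_variance: float
    degree_entropy: float  # nats
    avg_colorability: float
    colorability_exact: bool
    component_number: int
    component_mass_entropy: float  # nats
    largest_component_fraction: float
    fractal_dimension: float | None = None

    def to_row(self, prefix: str = "") -> dict[str, float]:
        return {
            f"{prefix}mean_degree": self.mean_degree,
            f"{prefix}degree_variance": self.degree_variance,
            f"{prefix}degree_entropy": self.degree_entropy,
            f"{prefix}avg_colorability": self.avg_colorability,
            f"{prefix}component_number": float(self.component_number),
            f"{prefix}component_mass_entropy": self.component_mass_entropy,
            f"{prefix}largest_component_fraction": self.largest_component_fraction,
            f"{prefix}fractal_dimension": (np.nan if self.fractal_dimension is None
                                           else self.fractal_dimension),
        }


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of the mask's inner boundary (4-connectivity)."""
    eroded = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    boundary = mask & ~eroded
    if not boundary.any():
        boundary = mask  # single pixels / thin cells
    return np.column_stack(np.nonzero(boundary))


def build_network(img: LabelImage, adjacency_threshold: float = 5.0) -> CellNetwork:
    """Build the cell adjacency network of a label image.

    Edge (u, v) iff the minimum Euclidean distance between boundary pixel
    centers of u and v is strictly less than ``adjacency_threshold`` µm.
    Candidate pairs are pre-filtered by bounding-box separation and the
    exact minimum found with a KD-tree, so the result is identical to the
    brute-force all-pairs computation.
    """
    if adjacency_threshold <= 0:
        raise ValueError("adjacency_threshold must be positive")
    px = img.pixel_size
    g = nx.Graph()
    labels = img.labels
    objects = ndimage.find_objects(img.pixels)
    boundaries: dict[int, np.ndarray] = {}
    trees: dict[int, cKDTree] = {}
    bboxes: dict[int, tuple[int, int, int, int]] = {}

    for lab in labels:
        sl = objects[lab - 1]
        local = img.pixels[sl] == lab
        coords = _boundary_pixels(local)
        coords = coords + np.array([sl[0].start, sl[1].start])
        boundaries[lab] = coords
        trees[lab] = cKDTree(coords)
        bboxes[lab] = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        centroid = ndimage.center_of_mass(img.pixels == lab)
        g.add_node(int(lab),
                   centroid=(centroid[0] * px, centroid[1] * px),
                   area_um2=float(np.count_nonzero(img.pixels == lab)) * px * px)

    thresh_px = adjacency_threshold / px
    labs = list(labels)
    for i, u in enumerate(labs):
        r0u, c0u, r1u, c1u = bboxes[u]
        for v in labs[i + 1:]:
            r0v, c0v, r1v, c1v = bboxes[v]
            dr = max(r0u - r1v + 1, r0v - r1u + 1, 0)
            dc = max(c0u - c1v + 1, c0v - c1u + 1, 0)
            if math.hypot(dr, dc) >= thresh_px + 1e-9:
                continue
            dmin, _ = trees[u].query(boundaries[v], k=1,
                                     distance_upper_bound=thresh_px + 1e-9)
            if np.min(dmin) * px < adjacency_threshold:  # strict
                g.add_edge(int(u), int(v))
    return CellNetwork(g, pixel_size=px, adjacency_threshold_um=adjacency_threshold)


# ---------------------------------------------------------------------------
# Degree and component statistics
# ---------------------------------------------------------------------------

def degree_statistics(net: CellNetwork | nx.Graph) -> tuple[float, float, float]:
    """(mean, population variance, Shannon entropy in nats) of vertex degree.

    Degree entropy uses exact integer-degree bins.
    """
    g = net.graph if isinstance(net, CellNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("degree statistics of an empty network are undefined")
    degs = np.array([d for _, d in g.degree()], dtype=float)
    _, counts = np.unique(degs, return_counts=True)
    entropy = entropy_from_probabilities(counts / counts.sum())
    return float(degs.mean()), float(degs.var()), entropy


def component_statistics(net: CellNetwork | nx.Graph) -> tuple[int, float, float]:
    """(component count, mass-distribution entropy in nats, |c1|/|G|)."""
    g = net.graph if isinstance(net, CellNetwork) else net
    n_nodes = g.number_of_nodes()
    if n_nodes == 0:
        raise ValueError("component statistics of an empty network are undefined")
    masses = np.array(sorted((len(c) for c in nx.connected_components(g)), reverse=True))
    p = masses / n_nodes
    return int(masses.size), entropy_from_probabilities(p), float(masses[0] / n_nodes)


# ---------------------------------------------------------------------------
# Chromatic number / average colorability
# ---------------------------------------------------------------------------

def _greedy_clique(g: nx.Graph) -> int:
    """Size of a greedily grown clique (lower bound on χ)."""
    nodes = sorted(g.nodes, key=lambda n: -g.degree(n))
    best = 0
    for start in nodes[: min(len(nodes), 10)]:
        clique = {start}
        for n in nodes:
            if n not in clique and all(g.has_edge(n, m) for m in clique):
                clique.add(n)
        best = max(best, len(clique))
    return max(best, 1)


def _k_colorable(g: nx.Graph, k: int) -> bool:
    """Backtracking search for a proper k-coloring."""
    nodes = sorted(g.nodes, key=lambda n: -g.degree(n))
    colors: dict = {}

    def assign(idx: int) -> bool:
        if idx == len(nodes):
            return True
        node = nodes[idx]
        used = {colors[m] for m in g[node] if m in colors}
        # symmetry breaking: allow at most one brand-new color
        max_color = max(colors.values(), default=-1)
        for c in range(min(k, max_color + 2)):
            if c not in used:
                colors[node] = c
                if assign(idx + 1):
                    return True
                del colors[node]
        return False

    return assign(0)


def chromatic_number(g: nx.Graph, exact_limit: int = 20) -> tuple[int, bool]:
    """Chromatic number of a connected graph.

    Exact (backtracking over increasing k, starting at a clique lower
    bound) for graphs with at most ``exact_limit`` nodes; otherwise a
    greedy largest-first upper bound, flagged inexact. Returns
    (χ or bound, exact?).
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("chromatic number of the empty graph is undefined")
    if g.number_of_edges() == 0:
        return 1, True
    if n > exact_limit:
        coloring = nx.coloring.greedy_color(g, strategy="largest_first")
        return max(coloring.values()) + 1, False
    lower = _greedy_clique(g)
    k = max(lower, 2)
    while not _k_colorable(g, k):
        k += 1
    return k, True


def average_colorability(net: CellNetwork | nx.Graph, exact_limit: int = 20) -> float:
    """Mean chromatic number over connected components, ⟨χ(G)⟩ = Σχ(c_i)/n.

    Components larger than ``exact_limit`` contribute a greedy upper bound
    and trigger a warning; exactness is also reported by
    :func:`network_metrics`.
    """
    value, exact = _average_colorability_flagged(net, exact_limit)
    if not exact:
        warnings.warn("average colorability includes greedy upper bounds for "
                      f"components larger than {exact_limit} nodes", stacklevel=2)
    return value


def _average_colorability_flagged(net: CellNetwork | nx.Graph,
                                  exact_limit: int = 20) -> tuple[float, bool]:
    g = net.graph if isinstance(net, CellNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("average colorability of an empty network is undefined")
    chis, all_exact = [], True
    for comp in nx.connected_components(g):
        chi, exact = chromatic_number(g.subgraph(comp), exact_limit=exact_limit)
        chis.append(chi)
        all_exact &= exact
    return float(np.mean(chis)), all_exact


# ---------------------------------------------------------------------------
# Box-counting fractal dimension
# ---------------------------------------------------------------------------

def box_counts(mask: np.ndarray, box_sizes) -> np.ndarray:
    """N(ε): number of ε×ε grid boxes (anchored at the origin) hitting S."""
    mask = np.asarray(mask, dtype=bool)
    counts = []
    for eps in box_sizes:
        eps = int(eps)
        pad_r = (-mask.shape[0]) % eps
        pad_c = (-mask.shape[1]) % eps
        padded = np.pad(mask, ((0, pad_r), (0, pad_c)))
        blocks = padded.reshape(padded.shape[0] // eps, eps, padded.shape[1] // eps, eps)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return np.asarray(counts)


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 px up to min(shape)/4."""
    sizes, eps = [], 2
    while eps <= min(shape) // 4:
        sizes.append(eps)
        eps *= 2
    return sizes


def fractal_dimension(mask: np.ndarray, box_sizes=None) -> float:
    """Box-counting dimension: slope of log N(ε) against log(1/ε).

    ``mask`` is the binary set S (here, the rasterized cell foreground).
    Requires a nonempty set and at least 4 box sizes spanning at least one
    decade (factor ≥ 10 between the smallest and largest).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("fractal dimension of the empty set is undefined")
    if box_sizes is None:
        box_sizes = default_box_sizes(mask.shape)
    box_sizes = sorted(int(e) for e in box_sizes)
    if len(box_sizes) < 4 or box_sizes[-1] < 10 * box_sizes[0]:
        raise ValueError("need >= 4 box sizes spanning at least one decade")
    counts = box_counts(mask, box_sizes)
    log_inv_eps = -np.log(np.asarray(box_sizes, dtype=float))
    slope, _ = np.polyfit(log_inv_eps, np.log(counts), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def network_metrics(net: CellNetwork, foreground: np.ndarray | None = None,
                    exact_limit: int = 20) -> NetworkMetrics:
    """All topology metrics of a network (plus Dim_f when a mask is given)."""
    mean_deg, var_deg, h_deg = degree_statistics(net)
    chi, exact = _average_colorability_flagged(net, exact_limit=exact_limit)
    n_comp, h_mass, frac = component_statistics(net)
    fdim = None
    if foreground is not None and np.asarray(foreground).any():
        try:
            fdim = fractal_dimension(foreground)
        except ValueError:
            fdim = None
    return NetworkMetrics(
        mean_degree=mean_deg,
        degree_variance=var_deg,
        degree_entropy=h_deg,
        avg_colorability=chi,
        colorability_exact=exact,
        component_number=n_comp,
        component_mass_entropy=h_mass,
        largest_component_fraction=frac,
        fractal_dimension=fdim,
    )
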