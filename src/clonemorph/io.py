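"""Core data types and readers/writers shared by all pipeline stages.

Conventions
-----------
* Pixel coordinates are (row, col), 0-based. Physical coordinates are
  ``index * pixel_size`` (µm) at pixel centers, with isotropic pixels.
* Label images hold non-negative integers; 0 is background. At ingest,
  labels are relabeled to consecutive positive integers (preserving
  distinctness) so downstream code can index arrays by label.
* Graphs are persisted as GraphML with centroid (µm) and area (µm²)
  node attributes; tables as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import tifffile


@dataclass
class LabelImage:
    """A 2D instance-segmentation mask with physical pixel size.

    Parameters
    ----------
    pixels : ndarray of int, shape (rows, cols)
        Label ids; 0 is background, positive integers are cells.
    pixel_size : float
        µm per pixel (isotropic).
    image_id, clone_id : str
        Opaque identifiers.
    time_h : float or None
        Hours since seeding, if known. Density (confluency), not time,
        is the pipeline's independent variable; time is carried only
        as metadata.
    """

    pixels: np.ndarray
    pixel_size: float
    image_id: str = ""
    clone_id: str = ""
    time_h: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"label image must be 2D, got ndim={self.pixels.ndim}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            if np.any(self.pixels != np.round(self.pixels)):
                raise ValueError("label image must contain integer labels")
            self.pixels = self.pixels.astype(np.int32)
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("label image contains negative values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of positive label ids present in the image."""
        u = np.unique(self.pixels)
        return u[u > 0]

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)

    @property
    def foreground(self) -> np.ndarray:
        return self.pixels > 0

    @property
    def confluency(self) -> float:
        """Fraction of image area covered by cells."""
        return float(np.count_nonzero(self.pixels)) / self.pixels.size

    def relabeled(self) -> "LabelImage":
        """Return a copy with labels mapped to consecutive 1..n (sorted order)."""
        return LabelImage(
            relabel_consecutive(self.pixels),
            self.pixel_size,
            image_id=self.image_id,
            clone_id=self.clone_id,
            time_h=self.time_h,
        )


@dataclass
class ZStack:
    """An ordered stack of 2D intensity slices with physical spacing."""

    slices: np.ndarray  # (n_slices, rows, cols)
    z_spacing: float  # µm between slices
    pixel_size: float  # µm per pixel in-plane
    spheroid_id: str = ""

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("z-stack must be a 3D array (slices, rows, cols)")
        if not self.z_spacing > 0 or not self.pixel_size > 0:
            raise ValueError("z_spacing and pixel_size must be positive")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def depth_um(self) -> float:
        """Physical span from first to last slice center."""
        return (self.n_slices - 1) * self.z_spacing


def relabel_consecutive(pixels: np.ndarray) -> np.ndarray:
    """Map positive labels to consecutive integers 1..n preserving sorted order."""
    pixels = np.asarray(pixels)
    out = np.zeros_like(pixels, dtype=np.int32)
    ids = np.unique(pixels)
    ids = ids[ids > 0]
    for new, old in enumerate(ids, start=1):
        out[pixels == old] = new
    return out


def read_label_image(path: str | Path, pixel_size: float, image_id: str = "",
                     clone_id: str = "", time_h: float | None = None) -> LabelImage:
    """Read a 2D integer TIFF as a :class:`LabelImage`.

    Labels are relabeled to consecutive positive integers (distinctness
    preserved). Raises on non-2D input or negative values.
    """
    arr = tifffile.imread(str(path))
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D label image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if np.any(arr != np.round(arr)):
            raise ValueError(f"{path}: non-integer pixel values cannot be labels")
        arr = arr.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise ValueError(f"{path}: negative values are not valid labels")
    img = LabelImage(arr.astype(np.int64), pixel_size, image_id=image_id or Path(path).stem,
                     clone_id=clone_id, time_h=time_h)
    return img.relabeled()


def write_label_image(img: LabelImage, path: str | Path) -> None:
    """Write the label array as an integer TIFF."""
    arr = img.pixels
    dtype = np.uint16 if (arr.size == 0 or arr.max() < 2**16) else np.int32
    tifffile.imwrite(str(path), arr.astype(dtype))


def read_zstack(path: str | Path, pixel_size: float, z_spacing: float,
                spheroid_id: str = "") -> ZStack:
    """Read a multi-page TIFF as a :class:`ZStack`."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page z-stack, got shape {arr.shape}")
    return ZStack(arr, z_spacing=z_spacing, pixel_size=pixel_size,
                  spheroid_id=spheroid_id or Path(path).stem)


def write_zstack(stack: ZStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack.slices))


def write_network(net, path: str | Path) -> None:
    """Persist a cell network as GraphML.

    Node attributes: centroid (µm, row/col) and area (µm²). Round-trips
    losslessly through :func:`read_network` (attribute values to float
    precision of the GraphML encoding).
    """
    g = nx.Graph()
    graph = net.graph if hasattr(net, "graph") and isinstance(getattr(net, "graph"), nx.Graph) else net
    for node, data in graph.nodes(data=True):
        attrs = {}
        if "centroid" in data:
            attrs["centroid_row_um"] = float(data["centroid"][0])
            attrs["centroid_col_um"] = float(data["centroid"][1])
        for key in ("area_um2",):
            if key in data:
                attrs[key] = float(data[key])
        g.add_node(int(node), **attrs)
    for u, v in graph.edges():
        g.add_edge(int(u), int(v))
    nx.write_graphml(g, str(path))


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML cell network; reconstitutes centroid tuples."""
    g = nx.read_graphml(str(path), node_type=int)
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        attrs = dict(data)
        if "centroid_row_um" in attrs:
            attrs["centroid"] = (attrs.pop("centroid_row_um"), attrs.pop("centroid_col_um"))
        out.add_node(node, **attrs)
    out.add_edges_from((int(u), int(v)) for u, v in g.edges())
    return out
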