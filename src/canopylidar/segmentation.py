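"""Per-layer tree segmentation stand-in: rasterized surface, local-maxima
seeding, watershed crown growing.

This is deliberately simple and deterministic — it exists so the
density-sweep experiment runs end-to-end, not to reproduce any published
crown-delineation method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

from .point_cloud import grid_origin
from .stratification import CanopyLayer


@dataclass
class DetectedTree:
    tree_id: int
    apex_x: float
    apex_y: float
    apex_height: float
    point_ids: np.ndarray
    in_buffer: bool = False

    @property
    def n_points(self) -> int:
        return len(self.point_ids)


@dataclass
class SurfaceGrid:
    origin: Tuple[float, float]
    cell_size: float
    values: np.ndarray  # (ny, nx) surface heights


def rasterize_surface(layer: CanopyLayer, cell: float, smooth_m: float = 0.8) -> SurfaceGrid:
    """Per-cell maximum height; voids filled from the nearest filled cell,
    then lightly smoothed with a Gaussian of ``smooth_m`` metres so the
    amount of smoothing does not depend on the raster resolution."""
    df = layer.points.data
    if len(df) == 0:
        raise ValueError("cannot rasterize an empty layer")
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    z = df["z"].to_numpy(float)
    origin = grid_origin(x, y)
    ix = np.floor((x - origin[0]) / cell).astype(int)
    iy = np.floor((y - origin[1]) / cell).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    values = np.full((ny, nx), -np.inf)
    np.maximum.at(values, (iy, ix), z)
    void = ~np.isfinite(values)
    if void.any():
        _, (jy, jx) = ndimage.distance_transform_edt(void, return_indices=True)
        values = values[jy, jx]
    if min(nx, ny) >= 3 and smooth_m > 0:
        values = ndimage.gaussian_filter(values, sigma=smooth_m / cell, mode="nearest")
    return SurfaceGrid((float(origin[0]), float(origin[1])), cell, values)


def detect_apexes(
    grid: SurfaceGrid, min_height: float = 4.0, min_separation: float = 1.5
) -> List[Tuple[float, float, float]]:
    """Local maxima above ``min_height``, greedily thinned so no two apexes
    are within ``min_separation`` (highest kept).  Returns (x, y, height)."""
    v = grid.values
    footprint = np.ones((3, 3), bool)
    local_max = (v == ndimage.maximum_filter(v, footprint=footprint, mode="nearest")) & (
        v >= min_height
    )
    # plateaus: keep one representative per connected plateau
    labels, n_lab = ndimage.label(local_max)
    apexes = []
    for lab in range(1, n_lab + 1):
        ys, xs = np.nonzero(labels == lab)
        cy, cx = float(ys.mean()), float(xs.mean())
        apexes.append((cx, cy, float(v[ys[0], xs[0]])))
    # greedy thinning, highest first
    apexes.sort(key=lambda a: -a[2])
    kept: List[Tuple[float, float, float]] = []
    sep_cells = min_separation / grid.cell_size
    for ax, ay, ah in apexes:
        if all(math.hypot(ax - kx, ay - ky) >= sep_cells for kx, ky, _ in kept):
            kept.append((ax, ay, ah))
    out = []
    for cx, cy, h in kept:
        out.append(
            (
                grid.origin[0] + (cx + 0.5) * grid.cell_size,
                grid.origin[1] + (cy + 0.5) * grid.cell_size,
                h,
            )
        )
    return out


def grow_crowns(
    grid: SurfaceGrid,
    apexes: List[Tuple[float, float, float]],
    layer: CanopyLayer,
    plot_radius: Optional[float] = None,
) -> List[DetectedTree]:
    """Watershed region growing from apex markers; layer points inherit the
    label of their grid cell.  ``in_buffer`` is set from ``plot_radius`` when
    given (apex farther than the radius from the origin)."""
    if not apexes:
        return []
    markers = np.zeros(grid.values.shape, dtype=int)
    for i, (ax, ay, _) in enumerate(apexes, start=1):
        cx = int((ax - grid.origin[0]) / grid.cell_size)
        cy = int((ay - grid.origin[1]) / grid.cell_size)
        markers[np.clip(cy, 0, markers.shape[0] - 1), np.clip(cx, 0, markers.shape[1] - 1)] = i
    labels = watershed(-grid.values, markers)

    df = layer.points.data
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    ix = np.clip(np.floor((x - grid.origin[0]) / grid.cell_size).astype(int), 0, labels.shape[1] - 1)
    iy = np.clip(np.floor((y - grid.origin[1]) / grid.cell_size).astype(int), 0, labels.shape[0] - 1)
    point_labels = labels[iy, ix]

    trees = []
    for i, (ax, ay, ah) in enumerate(apexes, start=1):
        ids = np.nonzero(point_labels == i)[0]
        in_buf = False
        if plot_radius is not None:
            in_buf = math.hypot(ax, ay) > plot_radius
        trees.append(DetectedTree(i, ax, ay, ah, ids, in_buffer=in_buf))
    return trees


def segment_layer(
    layer: CanopyLayer,
    cell: Optional[float] = None,
    min_height: float = 4.0,
    min_separation: float = 1.5,
    plot_radius: Optional[float] = None,
) -> List[DetectedTree]:
    """Full stand-in segmentation of one canopy layer.

    Default raster cell is max(AFP of the layer, 0.5 m).
    """
    if len(layer.points) == 0:
        return []
    if cell is None:
        d = layer.density or 1.0
        cell = max(1.0 / math.sqrt(max(d, 1e-9)), 0.5)
    grid = rasterize_surface(layer, cell)
    apexes = detect_apexes(grid, min_height=min_height, min_separation=min_separation)
    return grow_crowns(grid, apexes, layer, plot_radius=plot_radius)


def detected_trees_frame(trees: List[DetectedTree]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": [t.tree_id for t in trees],
            "apex_x": [t.apex_x for t in trees],
            "apex_y": [t.apex_y for t in trees],
            "apex_height": [t.apex_height for t in trees],
            "in_buffer": [t.in_buffer for t in trees],
            "n_points": [t.n_points for t in trees],
        }
    )
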