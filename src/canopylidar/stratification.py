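"""Vertical stratification of a height-normalized point cloud into canopy layers.

The routine iteratively peels the top canopy layer: points are binned into a
horizontal grid at the current average footprint (AFP), the 25-cm height
histogram of a circular locale around every grid cell is smoothed with a
Gaussian kernel, the height ranges where its second derivative is negative
(salient ranges) are treated as canopy layers, and the midpoint between the
top range and the one below it becomes the cell's cut height.  The top layer
is removed, the AFP updated from the remainder's density, and the process
repeats until the cloud is empty.

A completed layer lying entirely below ``min_canopy_height`` is flagged as
ground-level vegetation (``is_canopy=False``) rather than a canopy layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .point_cloud import ContractError, PointCloud, grid_origin

logger = logging.getLogger(__name__)


@dataclass
class StratificationParams:
    histogram_bin: float = 0.25
    smoothing_sd: float = 5.0
    locale_factor: float = 6.0
    locale_min_radius: float = 1.5
    min_canopy_height: float = 4.0
    max_layers: int = 10
    min_locale_points: int = 10  # locales with fewer points are degenerate

    def __post_init__(self) -> None:
        for name in ("histogram_bin", "smoothing_sd", "locale_factor",
                     "locale_min_radius", "min_canopy_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class HeightHistogram:
    """Counts (or smoothed densities) on the fixed height lattice anchored at 0."""

    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class ThresholdSurface:
    """Per-grid-cell lower cut heights used to remove one layer."""

    origin: Tuple[float, float]
    cell_size: float
    thresholds: np.ndarray = field(repr=False)  # (ny, nx), NaN where unused


@dataclass
class CanopyLayer:
    points: PointCloud
    threshold_surface: ThresholdSurface
    order_index: int
    starting_height: float
    thickness: float
    density: Optional[float]
    is_canopy: bool


def _bin_index(heights: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor(np.asarray(heights, float) / bin_width).astype(int)


def locale_histogram(
    cloud: PointCloud,
    center: Tuple[float, float],
    radius: float,
    bin_width: float = 0.25,
) -> HeightHistogram:
    """Height histogram of points within horizontal ``radius`` of ``center``."""
    dx = cloud.data["x"].to_numpy() - center[0]
    dy = cloud.data["y"].to_numpy() - center[1]
    z = cloud.z[np.hypot(dx, dy) <= radius]
    if len(z) == 0:
        return HeightHistogram(np.array([0.0, bin_width]), np.zeros(1))
    idx = _bin_index(z, bin_width)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    edges = np.arange(n_bins + 1) * bin_width
    return HeightHistogram(edges, counts)


def smooth_histogram(h: HeightHistogram, sd: float) -> HeightHistogram:
    """Gaussian smoothing (sigma in metres), reflected at the boundaries.

    Total mass is preserved to floating-point accuracy.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    sigma_bins = sd / h.bin_width
    smoothed = gaussian_filter1d(h.counts.astype(float), sigma_bins, mode="reflect", truncate=4.0)
    return HeightHistogram(h.bin_edges.copy(), smoothed)


def second_difference(values: np.ndarray) -> np.ndarray:
    """Central second difference; one-sided copies at the boundaries."""
    d2 = np.empty_like(values, dtype=float)
    if len(values) < 3:
        d2[:] = 0.0
        return d2
    d2[1:-1] = values[2:] - 2.0 * values[1:-1] + values[:-2]
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def salient_ranges(h: HeightHistogram) -> List[Tuple[float, float]]:
    """Maximal height ranges where the smoothed histogram is concave
    (second difference < 0), ordered top-down."""
    mask = second_difference(h.counts) < 0
    ranges: List[Tuple[float, float]] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            ranges.append((float(h.bin_edges[i]), float(h.bin_edges[j + 1])))
            i = j + 1
        i += 1
    return ranges[::-1]


def cell_threshold(ranges: List[Tuple[float, float]]) -> Optional[float]:
    """Cut height from top-down salient ranges.

    Two or more ranges: midpoint between the lower bound of the top range and
    the upper bound of the range below it.  Exactly one range: 0 (the whole
    column is a single layer).  No ranges: None.
    """
    if not ranges:
        return None
    if len(ranges) == 1:
        return 0.0
    return 0.5 * (ranges[0][0] + ranges[1][1])


def _disk_kernel(radius_cells: float) -> np.ndarray:
    k = int(math.floor(radius_cells))
    ax = np.arange(-k, k + 1)
    dx, dy = np.meshgrid(ax, ax)
    return (np.hypot(dx, dy) <= radius_cells).astype(float)


def _iteration_thresholds(
    xy: np.ndarray,
    z: np.ndarray,
    area: float,
    params: StratificationParams,
) -> Tuple[ThresholdSurface, np.ndarray, np.ndarray]:
    """Compute per-cell cut heights for the current remainder of the cloud.

    Returns the threshold surface plus each point's (iy, ix) cell index.
    Locale histograms for all cells are obtained at once by convolving the
    3-D (cell x cell x height-bin) count array with a disk footprint.
    """
    n = len(z)
    pcd = n / area
    afp = 1.0 / math.sqrt(pcd)
    radius = max(params.locale_factor * afp, params.locale_min_radius)
    origin = grid_origin(xy[:, 0], xy[:, 1])
    ix = np.floor((xy[:, 0] - origin[0]) / afp).astype(int)
    iy = np.floor((xy[:, 1] - origin[1]) / afp).astype(int)
    hb = _bin_index(z, params.histogram_bin)
    nx, ny, nb = ix.max() + 1, iy.max() + 1, hb.max() + 1

    counts = np.zeros((ny, nx, nb))
    np.add.at(counts, (iy, ix, hb), 1.0)

    kernel = _disk_kernel(radius / afp)
    locale = fftconvolve(counts, kernel[:, :, None], mode="same", axes=(0, 1))
    locale = np.maximum(locale, 0.0)  # FFT round-off

    sigma_bins = params.smoothing_sd / params.histogram_bin
    smoothed = gaussian_filter1d(locale, sigma_bins, axis=2, mode="reflect", truncate=4.0)

    d2 = np.zeros_like(smoothed)
    if nb >= 3:
        d2[:, :, 1:-1] = smoothed[:, :, 2:] - 2.0 * smoothed[:, :, 1:-1] + smoothed[:, :, :-2]
        d2[:, :, 0] = d2[:, :, 1]
        d2[:, :, -1] = d2[:, :, -2]

    occupied = np.zeros((ny, nx), bool)
    occupied[iy, ix] = True
    oy, ox = np.nonzero(occupied)
    mask = d2[oy, ox, :] < 0  # (C, nb)
    locale_n = locale[oy, ox, :].sum(axis=1)

    thresholds_flat = _thresholds_from_masks(mask, params.histogram_bin)
    thresholds_flat[locale_n < params.min_locale_points] = np.nan

    surface = np.full((ny, nx), np.nan)
    surface[oy, ox] = thresholds_flat

    # cells with no threshold inherit the nearest cell that has one
    have = np.isfinite(thresholds_flat)
    if have.any() and not have.all():
        tree = cKDTree(np.column_stack([ox[have], oy[have]]))
        _, nearest = tree.query(np.column_stack([ox[~have], oy[~have]]))
        surface[oy[~have], ox[~have]] = thresholds_flat[have][nearest]
    elif not have.any():
        # no cell produced a threshold: remove everything as one layer
        surface[oy, ox] = 0.0

    return ThresholdSurface((float(origin[0]), float(origin[1])), afp, surface), iy, ix


def _thresholds_from_masks(mask: np.ndarray, bin_width: float) -> np.ndarray:
    """Vectorized :func:`cell_threshold` over rows of concavity masks."""
    c, b = mask.shape
    cols = np.arange(b)
    prev = np.zeros_like(mask)
    prev[:, 1:] = mask[:, :-1]
    starts = mask & ~prev
    n_runs = starts.sum(axis=1)

    out = np.full(c, np.nan)
    out[n_runs == 1] = 0.0

    multi = n_runs >= 2
    if multi.any():
        m = mask[multi]
        s = starts[multi]
        # start index of the topmost run
        top_start = b - 1 - np.argmax(s[:, ::-1], axis=1)
        # last concave bin strictly below the topmost run = upper end of run 2
        below = np.where(m & (cols[None, :] < top_start[:, None]), cols[None, :], -1)
        prev_end = below.max(axis=1)
        low_of_top = top_start * bin_width
        high_of_second = (prev_end + 1) * bin_width
        out[multi] = 0.5 * (low_of_top + high_of_second)
    return out


def stratify(cloud: PointCloud, params: Optional[StratificationParams] = None) -> List[CanopyLayer]:
    """Partition a height-normalized cloud into top-down canopy layers.

    The union of the returned layers is exactly the input point set.  Layers
    entirely below ``params.min_canopy_height`` have ``is_canopy=False``.
    """
    params = params or StratificationParams()
    if cloud.height_mode != "above_ground":
        raise ContractError("stratify requires a height-normalized (above_ground) cloud")
    area = cloud.area
    if area is None or area <= 0:
        # fall back to the bounding-box footprint
        if len(cloud) == 0:
            return []
        xy = cloud.xy
        area = float(np.ptp(xy[:, 0]) * np.ptp(xy[:, 1]))
        if area <= 0:
            raise ContractError("cannot infer a positive area for the cloud")

    remaining = cloud.data.reset_index(drop=True)
    layers: List[CanopyLayer] = []
    order = 1
    while len(remaining):
        if order > params.max_layers:
            logger.warning("max_layers reached; emitting remainder as one layer")
            layers.append(_make_layer(remaining, None, order, area, params, cloud.height_mode))
            break
        xy = remaining[["x", "y"]].to_numpy(float)
        z = remaining["z"].to_numpy(float)
        surface, piy, pix = _iteration_thresholds(xy, z, area, params)
        cut = surface.thresholds[piy, pix]
        remove = z >= cut
        if not remove.any():
            logger.warning("iteration %d removed no points; emitting remainder", order)
            layers.append(_make_layer(remaining, surface, order, area, params, cloud.height_mode))
            break
        removed = remaining.loc[remove].reset_index(drop=True)
        layers.append(
            _make_layer(
                removed, surface, order, area, params, cloud.height_mode,
                cell_iy=piy[remove], cell_ix=pix[remove],
                cut=cut[remove], z=z[remove],
            )
        )
        remaining = remaining.loc[~remove].reset_index(drop=True)
        order += 1
    return layers


def _make_layer(
    df,
    surface: Optional[ThresholdSurface],
    order: int,
    area: float,
    params: StratificationParams,
    height_mode: str,
    cell_iy: Optional[np.ndarray] = None,
    cell_ix: Optional[np.ndarray] = None,
    cut: Optional[np.ndarray] = None,
    z: Optional[np.ndarray] = None,
) -> CanopyLayer:
    pts = PointCloud(df.reset_index(drop=True), height_mode=height_mode, area=area)
    if cut is not None and len(cut):
        # per-cell starting height = cut; thickness = top removed point - cut
        cells = cell_iy.astype(np.int64) * (cell_ix.max() + 1) + cell_ix
        uniq, inv = np.unique(cells, return_inverse=True)
        cell_cut = np.full(len(uniq), np.inf)
        np.minimum.at(cell_cut, inv, cut)
        cell_top = np.full(len(uniq), -np.inf)
        np.maximum.at(cell_top, inv, z)
        starting = float(np.median(cell_cut))
        thickness = float(np.median(cell_top - cell_cut))
    else:
        zz = df["z"].to_numpy(float)
        starting = float(zz.min()) if len(zz) else 0.0
        thickness = float(zz.max() - zz.min()) if len(zz) else 0.0
    max_h = float(df["z"].max()) if len(df) else 0.0
    if surface is None:
        surface = ThresholdSurface((0.0, 0.0), 1.0, np.zeros((1, 1)))
    return CanopyLayer(
        points=pts,
        threshold_surface=surface,
        order_index=order,
        starting_height=starting,
        thickness=thickness,
        density=len(df) / area,
        is_canopy=max_h >= params.min_canopy_height,
    )


def canopy_layers(layers: List[CanopyLayer]) -> List[CanopyLayer]:
    """The ``is_canopy`` layers, preserving top-down order."""
    return [l for l in layers if l.is_canopy]
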