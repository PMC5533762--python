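"""Point-cloud data model, I/O, DEM construction, height normalization, clipping.

The canonical interchange format is a CSV point table with header columns
``x,y,z,return_number,number_of_returns,pulse_id,point_class`` plus optional
``truth_tree_id,truth_layer``.  LAS 1.2+ reading/writing is available when
:mod:`laspy` is installed; the rest of the pipeline never requires it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

MAX_RETURNS = 4

GROUND = "ground"
VEGETATION = "vegetation"

REQUIRED_COLUMNS = (
    "x",
    "y",
    "z",
    "return_number",
    "number_of_returns",
    "pulse_id",
    "point_class",
)
OPTIONAL_COLUMNS = ("truth_tree_id", "truth_layer", "in_buffer")


class PointTableFormatError(ValueError):
    """Malformed point table (missing columns, inconsistent return metadata)."""


class ContractError(RuntimeError):
    """An operation was called on a cloud that does not satisfy its precondition."""


@dataclass
class PointCloud:
    """A collection of LiDAR returns with shared metadata.

    ``data`` columns: x, y, z (metres), return_number, number_of_returns,
    pulse_id, point_class (``ground``/``vegetation``), optionally
    truth_tree_id, truth_layer, in_buffer.

    ``height_mode`` is ``"elevation"`` for raw clouds and ``"above_ground"``
    after :func:`normalize_heights`.  ``area`` (m²) is set by clipping or may
    be supplied explicitly; density queries require it.
    """

    data: pd.DataFrame
    height_mode: str = "elevation"
    area: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise PointTableFormatError(f"missing required columns: {missing}")
        if self.height_mode not in ("elevation", "above_ground"):
            raise ValueError(f"unknown height_mode {self.height_mode!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def z(self) -> np.ndarray:
        return self.data["z"].to_numpy(dtype=float)

    @property
    def is_ground(self) -> np.ndarray:
        return (self.data["point_class"] == GROUND).to_numpy()

    @property
    def is_first_return(self) -> np.ndarray:
        return (self.data["return_number"] == 1).to_numpy()

    def n_pulses(self) -> int:
        return int(self.data["pulse_id"].nunique())

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask, preserving metadata."""
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def validate(self) -> None:
        """Check per-point and per-pulse return-number invariants."""
        rn = self.data["return_number"].to_numpy()
        nr = self.data["number_of_returns"].to_numpy()
        if len(self) == 0:
            return
        if (rn < 1).any() or (rn > nr).any() or (nr > MAX_RETURNS).any():
            raise PointTableFormatError(
                "return_number must satisfy 1 <= return_number <= "
                f"number_of_returns <= {MAX_RETURNS}"
            )
        grouped = self.data.groupby("pulse_id", sort=False)
        n_unique = grouped["number_of_returns"].nunique()
        if (n_unique > 1).any():
            bad = n_unique[n_unique > 1].index[0]
            raise PointTableFormatError(
                f"pulse {bad!r} has inconsistent number_of_returns"
            )
        dup = grouped["return_number"].apply(lambda s: s.duplicated().any())
        if dup.any():
            bad = dup[dup].index[0]
            raise PointTableFormatError(f"pulse {bad!r} has duplicate return_number")


@dataclass
class ElevationGrid:
    """Regular grid of ground elevations, metres, row-major (iy, ix)."""

    origin: Tuple[float, float]
    cell_size: float
    values: np.ndarray = field(repr=False)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        ix = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y, float) - self.origin[1]) / self.cell_size).astype(int)
        return ix, iy

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Elevation at (x, y); points outside the extent use the nearest cell."""
        ix, iy = self.cell_index(x, y)
        ny, nx = self.values.shape
        outside = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
        if outside.any():
            logger.info("%d point(s) outside DEM extent; using nearest cell", outside.sum())
        ix = np.clip(ix, 0, nx - 1)
        iy = np.clip(iy, 0, ny - 1)
        return self.values[iy, ix]


def grid_origin(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Deterministic grid anchor: floor of the cloud's minimum x/y."""
    return (math.floor(float(np.min(x))), math.floor(float(np.min(y))))


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise PointTableFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PointTableFormatError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int(df.index[bad | df[col].isna()][0]) + 2  # header + 1-based
            raise PointTableFormatError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = df[col].astype(float)
    for col in ("return_number", "number_of_returns"):
        df[col] = df[col].astype(int)
    return df


def _read_las(path: Path) -> pd.DataFrame:
    try:
        import laspy
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading LAS requires the optional 'laspy' dependency "
            "(pip install canopylidar[las])"
        ) from exc
    las = laspy.read(path)
    n = len(las.points)
    cls = np.asarray(las.classification)
    if hasattr(las, "gps_time"):
        pulse_id = pd.factorize(np.asarray(las.gps_time))[0]
    else:  # pragma: no cover - depends on writer
        logger.warning("%s: no GPS time; synthesizing one pulse id per point", path)
        pulse_id = np.arange(n)
    return pd.DataFrame(
        {
            "x": np.asarray(las.x, float),
            "y": np.asarray(las.y, float),
            "z": np.asarray(las.z, float),
            "return_number": np.asarray(las.return_number, int),
            "number_of_returns": np.asarray(las.number_of_returns, int),
            "pulse_id": pulse_id,
            "point_class": np.where(cls == 2, GROUND, VEGETATION),
        }
    )


def read_point_table(path, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from a CSV point table or a LAS file.

    ``format`` is inferred from the suffix when omitted.  The returned cloud
    has ``height_mode="elevation"``; return-number invariants are validated.
    """
    path = Path(path)
    if format is None:
        format = "las" if path.suffix.lower() in (".las", ".laz") else "csv"
    if format == "csv":
        df = _read_csv(path)
    elif format == "las":
        df = _read_las(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    cloud = PointCloud(df, height_mode="elevation")
    cloud.validate()
    return cloud


def write_point_table(cloud: PointCloud, path) -> None:
    """Write the canonical CSV point table (or LAS for .las paths)."""
    path = Path(path)
    if path.suffix.lower() in (".las", ".laz"):
        _write_las(cloud, path)
        return
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in cloud.data.columns]
    cloud.data[cols].to_csv(path, index=False)


def _write_las(cloud: PointCloud, path: Path) -> None:
    try:
        import laspy
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "writing LAS requires the optional 'laspy' dependency "
            "(pip install canopylidar[las])"
        ) from exc
    header = laspy.LasHeader(point_format=1, version="1.2")  # format 1 has GPS time
    header.scales = (0.001, 0.001, 0.001)
    las = laspy.LasData(header)
    df = cloud.data
    las.x = df["x"].to_numpy(float)
    las.y = df["y"].to_numpy(float)
    las.z = df["z"].to_numpy(float)
    las.return_number = df["return_number"].to_numpy(int)
    las.number_of_returns = df["number_of_returns"].to_numpy(int)
    las.classification = np.where(df["point_class"] == GROUND, 2, 5)
    las.gps_time = pd.factorize(df["pulse_id"])[0].astype(float)
    las.write(path)


def read_stem_map(path) -> pd.DataFrame:
    """Read a stem-map CSV: tree_id,x,y,height_m,crown_class."""
    df = pd.read_csv(path)
    missing = [c for c in ("tree_id", "x", "y", "height_m", "crown_class") if c not in df.columns]
    if missing:
        raise PointTableFormatError(f"{path}: stem map missing columns {missing}")
    return df


def build_dem(ground_points: PointCloud, cell_size: float = 1.0) -> ElevationGrid:
    """Grid the ground points into a DEM: per-cell mean elevation, voids
    filled from the nearest filled cell."""
    g = ground_points.select(ground_points.is_ground) if (~ground_points.is_ground).any() else ground_points
    if len(g) < 3:
        raise ContractError("build_dem requires at least 3 ground points")
    x, y, z = g.data["x"].to_numpy(), g.data["y"].to_numpy(), g.z
    origin = grid_origin(x, y)
    ix = np.floor((x - origin[0]) / cell_size).astype(int)
    iy = np.floor((y - origin[1]) / cell_size).astype(int)
    nx, ny = int(ix.max()) + 1, int(iy.max()) + 1
    sums = np.zeros((ny, nx))
    counts = np.zeros((ny, nx))
    np.add.at(sums, (iy, ix), z)
    np.add.at(counts, (iy, ix), 1)
    with np.errstate(invalid="ignore"):
        values = sums / counts
    void = counts == 0
    if void.any():
        # nearest filled cell (Euclidean on cell indices)
        _, (jy, jx) = ndimage.distance_transform_edt(void, return_indices=True)
        values = values[jy, jx]
    return ElevationGrid(origin=origin, cell_size=cell_size, values=values)


def normalize_heights(cloud: PointCloud, dem: ElevationGrid) -> PointCloud:
    """Convert elevations to heights above ground and drop ground returns.

    Negative heights (DEM noise) are clamped to 0.
    """
    if cloud.height_mode != "elevation":
        raise ContractError("normalize_heights expects an elevation-mode cloud")
    keep = ~cloud.is_ground
    df = cloud.data.loc[keep].reset_index(drop=True)
    heights = df["z"].to_numpy() - dem.sample(df["x"].to_numpy(), df["y"].to_numpy())
    n_neg = int((heights < 0).sum())
    if n_neg:
        logger.info("clamped %d negative normalized heights to 0", n_neg)
    df = df.assign(z=np.maximum(heights, 0.0))
    return PointCloud(df, height_mode="above_ground", area=cloud.area)


def clip_circular(
    cloud: PointCloud,
    center: Tuple[float, float],
    radius: float,
    buffer: float = 0.0,
) -> PointCloud:
    """Clip to a circular plot of ``radius`` plus an optional evaluation buffer.

    Points between ``radius`` and ``radius + buffer`` are retained and tagged
    ``in_buffer=True``.  The resulting area is the core plot area pi*r^2.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dx = cloud.data["x"].to_numpy() - center[0]
    dy = cloud.data["y"].to_numpy() - center[1]
    dist = np.hypot(dx, dy)
    keep = dist <= radius + buffer
    df = cloud.data.loc[keep].reset_index(drop=True)
    df = df.assign(in_buffer=dist[keep] > radius)
    return PointCloud(df, height_mode=cloud.height_mode, area=math.pi * radius**2)


def point_density(cloud: PointCloud, first_return_only: bool = False) -> float:
    """Points per square metre (all returns by default)."""
    if cloud.area is None or cloud.area <= 0:
        raise ContractError("point_density requires a cloud with known positive area")
    n = int(cloud.is_first_return.sum()) if first_return_only else len(cloud)
    return n / cloud.area
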