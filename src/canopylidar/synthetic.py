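"""Synthetic multi-layer forest stands and a nadir LiDAR scan simulator.

The generator is the stand-in for a real acquisition: it builds vertically
stacked cohorts of trees with solid-of-revolution crowns, fires nadir pulses
on a jittered grid, and attenuates them stochastically as they pass through
crowns so deeper layers receive geometrically fewer returns (occlusion).
Every vegetation return carries the identity and layer of the crown that
produced it, and the stand ships a stem map, so downstream stratification and
segmentation can be scored against known truth.

All parameters here are ours: the simulator emulates the *premise* of canopy
occlusion, not any particular sensor or forest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .point_cloud import GROUND, VEGETATION, PointCloud

DEFAULT_LAYER_RANGES = [
    (20.0, 26.0),
    (12.0, 17.0),
    (7.0, 11.0),
    (4.0, 6.0),
    (2.0, 3.5),
]


@dataclass
class SyntheticStandConfig:
    plot_radius: float = 15.0
    n_layers: int = 2
    trees_per_layer: Optional[Sequence[int]] = None
    layer_height_ranges: Optional[Sequence[Tuple[float, float]]] = None
    crown_shape: str = "paraboloid"
    crown_radius_range: Tuple[float, float] = (1.5, 3.5)
    crown_base_frac_range: Tuple[float, float] = (0.45, 0.6)  # crown base as a fraction of height
    terrain: str = "flat"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_layers <= 5:
            raise ValueError("n_layers must be in 1..5")
        if self.trees_per_layer is None:
            self.trees_per_layer = [8] * self.n_layers
        if len(self.trees_per_layer) != self.n_layers:
            raise ValueError("trees_per_layer length must equal n_layers")
        if self.layer_height_ranges is None:
            self.layer_height_ranges = DEFAULT_LAYER_RANGES[: self.n_layers]
        ranges = self.layer_height_ranges
        if len(ranges) != self.n_layers:
            raise ValueError("layer_height_ranges length must equal n_layers")
        for k in range(len(ranges) - 1):
            if ranges[k][0] <= ranges[k + 1][1]:
                raise ValueError("layer height ranges must be strictly decreasing")
        if self.crown_shape not in ("paraboloid", "ellipsoid"):
            raise ValueError(f"unknown crown_shape {self.crown_shape!r}")
        if self.terrain not in ("flat", "planar_slope"):
            raise ValueError(f"unknown terrain {self.terrain!r}")


@dataclass
class ScanConfig:
    pulse_density: float = 25.0
    interception_return_prob: float = 0.9
    transmission_prob: float = 0.35
    max_returns: int = 4
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.transmission_prob < 1.0:
            raise ValueError("transmission_prob must lie strictly in (0, 1)")
        if not 0.0 < self.interception_return_prob <= 1.0:
            raise ValueError("interception_return_prob must lie in (0, 1]")


@dataclass
class Tree:
    tree_id: int
    x: float
    y: float
    height: float
    crown_radius: float
    crown_base: float
    layer: int
    crown_class: str


@dataclass
class Stand:
    trees: List[Tree]
    plot_radius: float
    crown_shape: str
    terrain: str
    terrain_slope: float = 0.05  # dz/dx for planar_slope

    def ground_elevation(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.terrain == "flat":
            return np.zeros_like(np.asarray(x, float))
        return self.terrain_slope * np.asarray(x, float)


@dataclass
class SyntheticTruth:
    stem_map: pd.DataFrame
    layer_point_counts: dict


_CROWN_CLASS_BY_LAYER = {1: ("dominant", "codominant"), 2: ("intermediate",)}


def _crown_class(layer: int, rng: np.random.Generator) -> str:
    choices = _CROWN_CLASS_BY_LAYER.get(layer, ("overtopped",))
    return choices[rng.integers(len(choices))]


def generate_stand(config: SyntheticStandConfig) -> Tuple[Stand, pd.DataFrame]:
    """Place trees uniformly within the plot disk, heights uniform per layer.

    Deterministic under ``config.seed``.  Crown overlap is allowed.
    Returns the stand and its stem-map DataFrame
    (tree_id, x, y, height_m, crown_class, layer).
    """
    rng = np.random.default_rng(config.seed)
    trees: List[Tree] = []
    tree_id = 1
    for layer in range(1, config.n_layers + 1):
        n = int(config.trees_per_layer[layer - 1])
        lo, hi = config.layer_height_ranges[layer - 1]
        # uniform positions in the disk via rejection-free polar sampling
        r = config.plot_radius * np.sqrt(rng.random(n))
        phi = rng.random(n) * 2 * math.pi
        heights = rng.uniform(lo, hi, n)
        radii = rng.uniform(*config.crown_radius_range, n)
        base_fracs = rng.uniform(*config.crown_base_frac_range, n)
        for i in range(n):
            trees.append(
                Tree(
                    tree_id=tree_id,
                    x=float(r[i] * math.cos(phi[i])),
                    y=float(r[i] * math.sin(phi[i])),
                    height=float(heights[i]),
                    crown_radius=float(radii[i]),
                    crown_base=float(heights[i] * base_fracs[i]),
                    layer=layer,
                    crown_class=_crown_class(layer, rng),
                )
            )
            tree_id += 1
    stand = Stand(
        trees=trees,
        plot_radius=config.plot_radius,
        crown_shape=config.crown_shape,
        terrain=config.terrain,
    )
    stem_map = pd.DataFrame(
        {
            "tree_id": [t.tree_id for t in trees],
            "x": [t.x for t in trees],
            "y": [t.y for t in trees],
            "height_m": [t.height for t in trees],
            "crown_class": [t.crown_class for t in trees],
            "layer": [t.layer for t in trees],
        }
    )
    return stand, stem_map


def crown_surface_height(tree: Tree, shape: str, r: np.ndarray) -> np.ndarray:
    """Height of the crown surface at horizontal distance ``r`` from the stem.

    Apex at ``tree.height``; the surface falls to ``tree.crown_base`` at the
    crown edge.  NaN outside the crown.
    """
    frac = np.asarray(r, float) / tree.crown_radius
    depth = tree.height - tree.crown_base
    with np.errstate(invalid="ignore"):
        if shape == "paraboloid":
            h = tree.height - depth * frac**2
        else:  # ellipsoid (upper half)
            h = tree.crown_base + depth * np.sqrt(np.maximum(1.0 - frac**2, 0.0))
    return np.where(frac <= 1.0, h, np.nan)


def pulse_grid(plot_radius: float, pulse_density: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid nadir pulse locations covering the plot disk, (n, 2)."""
    spacing = 1.0 / math.sqrt(pulse_density)
    coords = np.arange(-plot_radius, plot_radius, spacing)
    gx, gy = np.meshgrid(coords, coords)
    px = gx.ravel() + rng.random(gx.size) * spacing
    py = gy.ravel() + rng.random(gy.size) * spacing
    inside = px**2 + py**2 <= plot_radius**2
    return np.column_stack([px[inside], py[inside]])


def intercept_hits(stand: Stand, pulses: np.ndarray):
    """All (pulse, crown) interceptions, ordered top-down within each pulse.

    Returns arrays (pulse_idx, z_surface, tree_id, layer) sorted by pulse then
    descending interception height.  Shared by the simulator and by any
    enumeration of per-pulse return probabilities on the same geometry.
    """
    pulse_idx, zs, tids, layers = [], [], [], []
    for tree in stand.trees:
        r = np.hypot(pulses[:, 0] - tree.x, pulses[:, 1] - tree.y)
        inside = r <= tree.crown_radius
        if not inside.any():
            continue
        z = crown_surface_height(tree, stand.crown_shape, r[inside])
        z = z + stand.ground_elevation(pulses[inside, 0], pulses[inside, 1])
        pulse_idx.append(np.nonzero(inside)[0])
        zs.append(z)
        tids.append(np.full(inside.sum(), tree.tree_id))
        layers.append(np.full(inside.sum(), tree.layer))
    if not pulse_idx:
        empty = np.empty(0)
        return empty.astype(int), empty, empty.astype(int), empty.astype(int)
    pulse_idx = np.concatenate(pulse_idx)
    zs = np.concatenate(zs)
    tids = np.concatenate(tids)
    layers = np.concatenate(layers)
    order = np.lexsort((-zs, pulse_idx))
    return pulse_idx[order], zs[order], tids[order], layers[order]


def simulate_scan(stand: Stand, scan: ScanConfig) -> PointCloud:
    """Simulate a nadir LiDAR scan over the stand.

    Each pulse is tested top-down against crown surfaces.  At every
    interception a return is emitted with ``interception_return_prob`` and the
    pulse continues downward with ``transmission_prob``; a ground return is
    emitted if the pulse survives all crowns while the ``max_returns`` budget
    is not exhausted.  Gaussian z-noise is added to every return.

    Output is an elevation-mode :class:`PointCloud` with per-point
    ``truth_tree_id``/``truth_layer`` on vegetation returns.
    """
    rng = np.random.default_rng(scan.seed)
    pulses = pulse_grid(stand.plot_radius, scan.pulse_density, rng)
    n_pulses = len(pulses)
    hp, hz, htid, hlayer = intercept_hits(stand, pulses)

    # Per-hit draws; "reached" = every hit above it in the same pulse transmitted.
    u_ret = rng.random(len(hp)) < scan.interception_return_prob
    transmitted = rng.random(len(hp)) < scan.transmission_prob
    new_pulse = np.ones(len(hp), bool)
    new_pulse[1:] = hp[1:] != hp[:-1]
    reached = _segment_prefix_and(transmitted, new_pulse)

    emit = reached & u_ret
    emit_rank = _segment_cumsum(emit.astype(int), new_pulse)
    emit &= emit_rank <= scan.max_returns

    survives = _segment_all(transmitted | ~reached, new_pulse, hp, n_pulses)
    # pulses with no hits at all trivially reach the ground
    hit_counts = np.bincount(hp, minlength=n_pulses)
    veg_returns_per_pulse = np.bincount(hp[emit], minlength=n_pulses)
    ground_mask = survives & (veg_returns_per_pulse < scan.max_returns)
    ground_mask |= hit_counts == 0

    # assemble vegetation returns
    veg_pulse = hp[emit]
    veg_z = hz[emit] + rng.normal(0.0, scan.noise_sd, emit.sum())
    veg_rank = emit_rank[emit]
    veg_tid = htid[emit]
    veg_layer = hlayer[emit]

    g_idx = np.nonzero(ground_mask)[0]
    g_z = stand.ground_elevation(pulses[g_idx, 0], pulses[g_idx, 1])
    g_z = g_z + rng.normal(0.0, scan.noise_sd, len(g_idx))
    g_rank = veg_returns_per_pulse[g_idx] + 1

    pulse_ids = np.concatenate([veg_pulse, g_idx])
    df = pd.DataFrame(
        {
            "x": np.concatenate([pulses[veg_pulse, 0], pulses[g_idx, 0]]),
            "y": np.concatenate([pulses[veg_pulse, 1], pulses[g_idx, 1]]),
            "z": np.concatenate([veg_z, g_z]),
            "return_number": np.concatenate([veg_rank, g_rank]).astype(int),
            "pulse_id": pulse_ids,
            "point_class": [VEGETATION] * len(veg_pulse) + [GROUND] * len(g_idx),
            "truth_tree_id": np.concatenate(
                [veg_tid.astype(float), np.full(len(g_idx), np.nan)]
            ),
            "truth_layer": np.concatenate(
                [veg_layer.astype(float), np.full(len(g_idx), np.nan)]
            ),
        }
    )
    totals = veg_returns_per_pulse + ground_mask.astype(int)
    df["number_of_returns"] = totals[pulse_ids]
    df = df.sort_values(["pulse_id", "return_number"], kind="stable").reset_index(drop=True)
    return PointCloud(df, height_mode="elevation", area=math.pi * stand.plot_radius**2)


def _segment_prefix_and(values: np.ndarray, new_segment: np.ndarray) -> np.ndarray:
    """Within each segment: out[i] = AND of values[start..i-1] (True at start)."""
    if len(values) == 0:
        return np.empty(0, bool)
    shifted = np.ones(len(values), bool)
    shifted[1:] = values[:-1]
    shifted[new_segment] = True
    # prefix AND <=> zero Falses among shifted values since segment start
    falses = (~shifted).astype(np.int64)
    cum = np.cumsum(falses)
    base = np.maximum.accumulate(np.where(new_segment, cum, np.iinfo(np.int64).min))
    return (cum - base) == 0


def _segment_cumsum(values: np.ndarray, new_segment: np.ndarray) -> np.ndarray:
    """Inclusive cumulative sum restarting at each segment start."""
    cum = np.cumsum(values)
    seg_base = np.maximum.accumulate(np.where(new_segment, cum - values, np.iinfo(np.int64).min))
    return cum - seg_base


def _segment_all(values: np.ndarray, new_segment: np.ndarray, seg_ids: np.ndarray, n_segments: int) -> np.ndarray:
    """Per segment id: AND of values; True for ids with no entries."""
    out = np.ones(n_segments, bool)
    if len(values):
        np.logical_and.at(out, seg_ids, values)
    return out


def uniform_slab_cloud(
    slabs: Sequence[Tuple[float, float, int]],
    radius: float = 15.0,
    seed: int = 0,
) -> PointCloud:
    """Height-normalized cloud of uniform points in horizontal slabs.

    ``slabs`` is a list of (height_min, height_max, n_points); each point's
    ``truth_layer`` is the slab's 1-based index (slabs given top-first).
    Useful as a geometry-free fixture for the stratifier.
    """
    rng = np.random.default_rng(seed)
    frames = []
    pulse_base = 0
    for layer, (lo, hi, n) in enumerate(slabs, start=1):
        r = radius * np.sqrt(rng.random(n))
        phi = rng.random(n) * 2 * math.pi
        frames.append(
            pd.DataFrame(
                {
                    "x": r * np.cos(phi),
                    "y": r * np.sin(phi),
                    "z": rng.uniform(lo, hi, n),
                    "return_number": 1,
                    "number_of_returns": 1,
                    "pulse_id": np.arange(pulse_base, pulse_base + n),
                    "point_class": VEGETATION,
                    "truth_tree_id": np.nan,
                    "truth_layer": float(layer),
                }
            )
        )
        pulse_base += n
    df = pd.concat(frames, ignore_index=True)
    return PointCloud(df, height_mode="above_ground", area=math.pi * radius**2)


def generate_plot_sample(
    n_plots: int,
    stand_config: SyntheticStandConfig,
    scan_config: ScanConfig,
    seed: int = 0,
) -> List[Tuple[PointCloud, SyntheticTruth]]:
    """Independent seeded plots whose layer counts cycle over 1..n_layers.

    Mirrors a field sampling campaign at desk scale: each plot is a fresh
    stand + scan with per-plot sub-seeds derived from ``seed``.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    out: List[Tuple[PointCloud, SyntheticTruth]] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_plots)
    for i in range(n_plots):
        sub = children[i].generate_state(2)
        n_layers = (i % stand_config.n_layers) + 1
        cfg = SyntheticStandConfig(
            plot_radius=stand_config.plot_radius,
            n_layers=n_layers,
            trees_per_layer=list(stand_config.trees_per_layer[:n_layers]),
            layer_height_ranges=list(stand_config.layer_height_ranges[:n_layers]),
            crown_shape=stand_config.crown_shape,
            crown_radius_range=stand_config.crown_radius_range,
            crown_base_frac_range=stand_config.crown_base_frac_range,
            terrain=stand_config.terrain,
            seed=int(sub[0]),
        )
        scan = ScanConfig(
            pulse_density=scan_config.pulse_density,
            interception_return_prob=scan_config.interception_return_prob,
            transmission_prob=scan_config.transmission_prob,
            max_returns=scan_config.max_returns,
            noise_sd=scan_config.noise_sd,
            seed=int(sub[1]),
        )
        stand, stem_map = generate_stand(cfg)
        cloud = simulate_scan(stand, scan)
        layers = cloud.data["truth_layer"].dropna().astype(int)
        counts = layers.value_counts().sort_index().to_dict()
        out.append((cloud, SyntheticTruth(stem_map=stem_map, layer_point_counts=counts)))
    return out
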