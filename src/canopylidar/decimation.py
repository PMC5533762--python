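"""Pulse-preserving point-cloud decimation to a target density.

The protocol: bin first returns into a horizontal grid whose cell width is
the average footprint of the target density, draw one first return uniformly
per occupied cell, and keep *all* returns of the pulses so selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .point_cloud import ContractError, PointCloud, grid_origin

logger = logging.getLogger(__name__)


@dataclass
class DecimationSpec:
    target_pcd: float  # pt/m^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_pcd <= 0:
            raise ValueError("target_pcd must be positive")


def average_footprint(pcd: float) -> float:
    """Grid-cell width holding on average one point: 1/sqrt(pcd)."""
    if pcd <= 0:
        raise ValueError("point density must be positive")
    return 1.0 / math.sqrt(pcd)


def decimate_to_density(cloud: PointCloud, spec: DecimationSpec) -> PointCloud:
    """Thin ``cloud`` toward ``spec.target_pcd`` while preserving pulses.

    One first return is chosen uniformly at random (seeded) per occupied grid
    cell of width ``average_footprint(target_pcd)``; the output is the union
    of all returns of the chosen pulses.  Cells without a first return
    contribute nothing, so realized density can undershoot in sparse areas.
    """
    if cloud.data["pulse_id"].isna().any():
        raise ContractError("decimation requires pulse_id on every point")
    if len(cloud) == 0:
        return cloud.select(np.zeros(0, bool))
    afp = average_footprint(spec.target_pcd)
    first = cloud.is_first_return
    fx = cloud.data["x"].to_numpy()[first]
    fy = cloud.data["y"].to_numpy()[first]
    fpulse = cloud.data["pulse_id"].to_numpy()[first]
    if len(fx) == 0:
        logger.warning("no first returns; decimation output empty")
        return cloud.select(np.zeros(len(cloud), bool))
    origin = grid_origin(cloud.data["x"].to_numpy(), cloud.data["y"].to_numpy())
    ix = np.floor((fx - origin[0]) / afp).astype(np.int64)
    iy = np.floor((fy - origin[1]) / afp).astype(np.int64)
    cell = ix * (iy.max() + 1 - iy.min()) + (iy - iy.min())

    # one uniform draw per occupied cell: shuffle-key trick with per-cell
    # streams spawned from the global seed so selection is order-independent
    order = np.argsort(cell, kind="stable")
    cell_sorted = cell[order]
    boundaries = np.ones(len(cell_sorted), bool)
    boundaries[1:] = cell_sorted[1:] != cell_sorted[:-1]
    cell_ids = np.unique(cell_sorted)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    keys = rng.random(len(cell_sorted))
    # pick the max key within each cell group
    group_index = np.cumsum(boundaries) - 1
    best = np.full(len(cell_ids), -1.0)
    np.maximum.at(best, group_index, keys)
    chosen_sorted = keys == best[group_index]
    # break exact ties (measure zero) by first occurrence
    first_in_group = np.zeros(len(cell_ids), dtype=np.int64)
    np.add.at(first_in_group, group_index, chosen_sorted.astype(np.int64))
    chosen = np.zeros(len(cell_sorted), bool)
    seen = np.zeros(len(cell_ids), bool)
    for i in np.nonzero(chosen_sorted)[0]:
        if not seen[group_index[i]]:
            chosen[i] = True
            seen[group_index[i]] = True
    selected_pulses = set(fpulse[order[chosen]])
    keep = cloud.data["pulse_id"].isin(selected_pulses).to_numpy()
    out = cloud.select(keep)
    if out.area:
        logger.info(
            "decimated %d -> %d points (target %.2f pt/m^2, realized %.2f)",
            len(cloud),
            len(out),
            spec.target_pcd,
            len(out) / out.area,
        )
    return out
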