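"""Desk-scale orchestration of the two experiments.

``run_fraction_survey`` stratifies a batch of plots, collects per-layer point
fractions, and fits the logarithmic-series occlusion model.

``run_density_sweep`` decimates each plot to a series of target densities,
stratifies, segments each canopy layer, and scores overstory (layer-1 stems)
and understory (deeper stems) detection accuracy against the truth stem map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decimation import DecimationSpec, decimate_to_density
from .evaluation import match_trees
from .occlusion import (
    LayerFractionSample,
    LogSeriesModel,
    fit_log_series,
    layer_fractions,
)
from .point_cloud import PointCloud, build_dem, normalize_heights, point_density
from .segmentation import segment_layer
from .stratification import StratificationParams, canopy_layers, stratify
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def prepare_plot(cloud: PointCloud) -> PointCloud:
    """Normalize an elevation-mode plot cloud using a DEM from its own
    ground returns; pass height-normalized clouds through unchanged."""
    if cloud.height_mode == "above_ground":
        return cloud.select(~cloud.is_ground) if cloud.is_ground.any() else cloud
    ground = cloud.select(cloud.is_ground)
    if len(ground) < 3:
        raise PipelineError("plot has fewer than 3 ground returns; cannot build DEM")
    dem = build_dem(ground)
    return normalize_heights(cloud, dem)


def run_fraction_survey(
    plots: Sequence[PointCloud],
    params: Optional[StratificationParams] = None,
    max_n: int = 5,
) -> Tuple[pd.DataFrame, LogSeriesModel]:
    """Stratify every plot, record (n, p_n) fraction samples zero-padded to
    ``max_n``, and fit the log-series model.

    ``p_n`` is computed against each plot's *total* density (all returns,
    ground included) so the ground/low-vegetation share is the remainder.
    Plots with zero canopy layers are recorded but excluded from the fit.
    """
    params = params or StratificationParams()
    rows = []
    fit_samples: List[LayerFractionSample] = []
    for i, plot in enumerate(plots):
        pcd = point_density(plot)
        norm = prepare_plot(plot)
        layers = stratify(norm, params)
        samples = layer_fractions(layers, pcd, max_n=max_n, plot_id=str(i))
        has_canopy = any(l.is_canopy for l in layers)
        for s in samples:
            rows.append({"plot_id": s.plot_id, "n": s.n, "p_n": s.p_n, "used_in_fit": has_canopy})
        if has_canopy:
            fit_samples.extend(samples)
    if not fit_samples:
        raise PipelineError("no plot produced a canopy layer; nothing to fit")
    model = fit_log_series(fit_samples)
    return pd.DataFrame(rows), model


@dataclass
class SweepResult:
    table: pd.DataFrame  # columns: target_pcd, stratum, recall, precision, f_score, n_plots


def _evaluate_stratum(trees, stems: pd.DataFrame):
    """Per-plot (recall, precision, f) with NaN for undefined components.

    A stratum with stems but no detections still has a well-defined recall of
    0 even though precision is undefined.
    """
    if len(stems) == 0:
        return None
    match = match_trees(trees, stems.reset_index(drop=True))
    recall = match.mt / (match.mt + match.oe) if match.mt + match.oe > 0 else np.nan
    precision = match.mt / (match.mt + match.ce) if match.mt + match.ce > 0 else np.nan
    if np.isnan(recall) or np.isnan(precision):
        f = 0.0 if recall == 0.0 else np.nan
    elif recall + precision == 0:
        f = 0.0
    else:
        f = 2 * recall * precision / (recall + precision)
    return recall, precision, f


def run_density_sweep(
    plots: Sequence[Tuple[PointCloud, SyntheticTruth]],
    densities: Sequence[float],
    seed: int = 0,
    params: Optional[StratificationParams] = None,
    min_height: float = 4.0,
) -> SweepResult:
    """Decimate -> stratify -> segment -> evaluate over a density grid.

    Overstory scores match layer-1 detections against layer-1 stems;
    understory scores pool detections from all deeper canopy layers against
    deeper stems.  Rows are means across plots; densities above a plot's
    source density are skipped for that plot.
    """
    params = params or StratificationParams()
    ss = np.random.SeedSequence(seed)
    sub = {
        (pi, d): int(child.generate_state(1)[0])
        for (pi, d), child in zip(
            [(pi, d) for pi in range(len(plots)) for d in densities],
            ss.spawn(len(plots) * len(densities)),
        )
    }
    records = []
    for target in densities:
        per_stratum = {"overstory": [], "understory": []}
        for pi, (cloud, truth) in enumerate(plots):
            source_pcd = point_density(cloud)
            if target > source_pcd:
                logger.info("plot %d: target %.1f above source %.1f; skipped", pi, target, source_pcd)
                continue
            dec = decimate_to_density(cloud, DecimationSpec(target, seed=sub[(pi, target)]))
            if len(dec) == 0:
                continue
            norm = prepare_plot(dec)
            if len(norm) == 0:
                continue
            layers = canopy_layers(stratify(norm, params))
            plot_radius = math.sqrt(cloud.area / math.pi) if cloud.area else None
            over_trees, under_trees = [], []
            for layer in layers:
                trees = segment_layer(
                    layer, min_height=min_height, plot_radius=plot_radius
                )
                if layer.order_index == layers[0].order_index:
                    over_trees = trees
                else:
                    under_trees.extend(trees)
            stems = truth.stem_map
            over = _evaluate_stratum(over_trees, stems[stems["layer"] == 1])
            under = _evaluate_stratum(under_trees, stems[stems["layer"] >= 2])
            if over is not None:
                per_stratum["overstory"].append(over)
            if under is not None:
                per_stratum["understory"].append(under)
        for stratum, scores in per_stratum.items():
            if not scores:
                continue
            arr = np.array(scores, float)  # (n_plots, 3)
            counts = np.isfinite(arr).sum(axis=0)
            means = np.where(
                counts > 0, np.nansum(arr, axis=0) / np.maximum(counts, 1), np.nan
            )
            records.append(
                {
                    "target_pcd": target,
                    "stratum": stratum,
                    "recall": float(means[0]),
                    "precision": float(means[1]),
                    "f_score": float(means[2]),
                    "n_plots": len(scores),
                }
            )
    return SweepResult(pd.DataFrame(records))
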