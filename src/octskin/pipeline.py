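"""End-to-end segmentation: preprocess -> patch CNN -> probability maps ->
graph search -> boundary traces and epidermal thickness."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import boundary_graph, metrics, patchcnn, patchset, preprocess, probmaps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "segment_scan", "SegmentationResult"]


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults that run the whole pipeline end to end on a phantom."""

    preset: str = "cnn-gs-skin"
    step: int = 4
    n_workers: int = 1
    w_min: float = 1e-5
    margin_above: int = 10
    depth_below: int = 300
    despeckle: bool = True
    trace_how: str = "first"
    axial_px_um: float = metrics.METRIC_AXIAL_PX_UM
    seed: int = 0


@dataclass
class SegmentationResult:
    trace_sc: boundary_graph.BoundaryTrace
    trace_dej: boundary_graph.BoundaryTrace
    region: preprocess.TargetRegion
    maps: probmaps.ProbMaps
    et: dict
    timings: dict = field(default_factory=dict)


def segment_scan(
    scan: preprocess.BScan,
    model: patchcnn.PatchCNN,
    config: PipelineConfig | None = None,
    model_path: str | None = None,
) -> SegmentationResult:
    """Segment both boundaries of one B-scan with a trained patch classifier.

    With ``config.n_workers > 1`` a serialized checkpoint path must be given;
    inference is then distributed over worker processes in contiguous chunks.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    scan = preprocess.normalize(scan)
    if config.despeckle:
        scan = preprocess.despeckle(scan)
    air = preprocess.detect_air_boundary(scan)
    region_scan, region = preprocess.crop_target_region(
        scan, air, margin_above=config.margin_above, depth_below=config.depth_below
    )
    timings["preprocess_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    spec = patchset.PatchSpec(patch_size=model.config.input_size,
                              n_model_outputs=model.config.n_outputs)
    centers = patchset.pixel_skip_centers(region_scan.image.shape, config.step)
    pset = patchset.extract_patches_at(region_scan, centers, spec=spec, step=config.step)
    timings["patchset_s"] = time.perf_counter() - t0
    logger.info("target patchset: %d patches at step %d", len(pset), config.step)

    t0 = time.perf_counter()
    if config.n_workers > 1:
        if model_path is None:
            raise ValueError("multi-worker inference needs a serialized model path")
        preds = patchcnn.predict_parallel(model_path, pset, n_workers=config.n_workers)
    else:
        preds = patchcnn.predict_batch(model, pset)
    timings["inference_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    maps = probmaps.assemble_maps(preds, pset.centers, region_scan.image.shape, step=config.step)
    maps = probmaps.infill_kernel(maps)
    params = boundary_graph.WeightParams(w_min=config.w_min)
    tr_sc, tr_dej = boundary_graph.segment_image(maps, params, region=region, how=config.trace_how)
    timings["graph_search_s"] = time.perf_counter() - t0

    try:
        et = metrics.epidermal_thickness(tr_sc.rows, tr_dej.rows, axial_px_um=config.axial_px_um)
    except ValueError:
        logger.warning("%s: DEJ above SC in every column; ET undefined", scan.source_id)
        t_px = tr_dej.rows - tr_sc.rows
        et = {"per_column_px": t_px, "per_column_um": t_px * config.axial_px_um,
              "valid": np.zeros(t_px.shape, dtype=bool),
              "mean_px": float("nan"), "mean_um": float("nan"), "sd_px": float("nan")}
    logger.info(
        "segmented %s: ET %.1f px (%.1f um); timings %s",
        scan.source_id, et["mean_px"], et["mean_um"],
        {k: round(v, 3) for k, v in timings.items()},
    )
    return SegmentationResult(
        trace_sc=tr_sc, trace_dej=tr_dej, region=region, maps=maps, et=et, timings=timings
    )
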