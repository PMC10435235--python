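"""End-to-end kinetics pipeline: movie in, per-cluster lag table out.

Stages run in a fixed order — drift estimation, drift correction,
preprocessing (median filter, top-hat), segmentation (rank threshold, union
mask, area filter), XYT tracking, averaged-trace extraction, and half-rise
kinetics — each logged by name so the ordering is auditable.  Errors raised
inside a stage are re-raised with the stage name attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import kinetics, preprocess, registration, segmentation, tracking
from .io import RESULT_COLUMNS
from .model import (
    ClusterTrack,
    DriftTrace,
    HalfRiseResult,
    PipelineConfig,
    ThresholdSet,
    TwoChannelMovie,
)

logger = logging.getLogger("adhesionlag")

STAGES = (
    "estimate_drift",
    "apply_drift",
    "preprocess",
    "segment",
    "track",
    "traces",
    "kinetics",
)


@dataclass
class PipelineResult:
    """Everything a pipeline run produces."""

    table: pd.DataFrame
    label_volume: np.ndarray
    tracks: list[ClusterTrack]
    half_rise: list[HalfRiseResult]
    drift: DriftTrace
    thresholds: Optional[ThresholdSet]
    stage_log: list[str] = field(default_factory=list)


class PipelineStageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=RESULT_COLUMNS)


def run_pipeline(
    movie: TwoChannelMovie,
    config: Optional[PipelineConfig] = None,
    cell_id: object = 0,
) -> PipelineResult:
    """Run the full kinetics pipeline on one movie.

    Deterministic given the movie and configuration.  An all-zero movie
    yields an empty result table rather than an error.
    """
    config = config or PipelineConfig()
    log: list[str] = []

    def stage(name):
        log.append(name)
        logger.info("stage: %s", name)

    try:
        stage("estimate_drift")
        if movie.n_frames >= 2:
            drift = registration.estimate_drift(movie, channel=config.registration_channel)
        else:
            drift = DriftTrace(displacements_px=np.zeros((movie.n_frames, 2)))
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("estimate_drift", exc) from exc

    try:
        stage("apply_drift")
        corrected = registration.apply_drift(movie, drift)
    except Exception as exc:  # pragma: no cover
        raise PipelineStageError("apply_drift", exc) from exc

    try:
        stage("preprocess")
        pre = preprocess.preprocess(
            corrected,
            median_kernel_px=config.median_kernel_px,
            tophat_radius_px=config.tophat_radius_px,
        )
    except Exception as exc:  # pragma: no cover
        raise PipelineStageError("preprocess", exc) from exc

    try:
        stage("segment")
        thresholds = segmentation.compute_thresholds(
            pre,
            rank=config.threshold_rank,
            fraction=config.threshold_fraction,
            scope=config.threshold_scope,
        )
        masks = segmentation.segment_movie(
            pre,
            thresholds,
            min_area_px=config.min_cluster_area_px,
            noise_floor_sigma=config.noise_floor_sigma,
        )
    except Exception as exc:
        raise PipelineStageError("segment", exc) from exc

    try:
        stage("track")
        label_volume, tracks = tracking.track_clusters(
            masks,
            min_frames=config.min_track_frames,
            connectivity_3d=config.connectivity_3d,
        )
    except Exception as exc:  # pragma: no cover
        raise PipelineStageError("track", exc) from exc

    try:
        stage("traces")
        tracking.extract_all_traces(tracks, label_volume, pre)
    except Exception as exc:  # pragma: no cover
        raise PipelineStageError("traces", exc) from exc

    try:
        stage("kinetics")
        results = []
        rows = []
        times = movie.times_s
        red_idx, green_idx = movie.reference_index, movie.query_index
        for track in tracks:
            hr = kinetics.half_rise_result(
                track.cluster_id,
                track.traces[red_idx],
                track.traces[green_idx],
                times,
                window_frames=config.smoothing_window_frames,
            )
            results.append(hr)
            rows.append(
                {
                    "cell_id": cell_id,
                    "cluster_id": track.cluster_id,
                    "t_half_red_s": hr.t_half_red_s,
                    "t_half_green_s": hr.t_half_green_s,
                    "delta_t_half_s": hr.delta_t_half_s,
                    "area_px_max": track.max_area_px,
                    "n_frames_tracked": track.n_frames_tracked,
                    "valid": hr.valid,
                }
            )
        table = pd.DataFrame(rows, columns=RESULT_COLUMNS) if rows else _empty_table()
    except Exception as exc:  # pragma: no cover
        raise PipelineStageError("kinetics", exc) from exc

    return PipelineResult(
        table=table,
        label_volume=label_volume,
        tracks=tracks,
        half_rise=results,
        drift=drift,
        thresholds=thresholds,
        stage_log=log,
    )
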