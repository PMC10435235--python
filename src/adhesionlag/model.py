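"""Core data model for two-channel adhesion-kinetics analysis.

The central object is :class:`TwoChannelMovie`, an XYT intensity volume with
two fluorescence channels (a red *reference* channel, typically Cas, and a
green *query* channel such as vinculin, integrin, or Crk) plus the physical
calibration needed to convert pixels to micrometres and frames to seconds.

All arrays use the canonical axis order ``(frame, channel, row, col)`` and
0-based, pixel-centre ``(row, col)`` coordinates.  All times live on the grid
``t_k = k * frame_interval_s`` with frame 0 the first acquired frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

#: Pixel size of the TIRF acquisitions the defaults are calibrated for.
DEFAULT_PIXEL_SIZE_UM = 0.16
#: Typical frame interval of the two-colour time-lapse acquisitions (s).
DEFAULT_FRAME_INTERVAL_S = 20.0

REFERENCE = "reference"
QUERY = "query"


def px_area_to_um2(area_px: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a pixel area to µm² (``area_px * pixel_size_um**2``)."""
    return float(area_px) * float(pixel_size_um) ** 2


def px_to_um(length_px: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a pixel length to µm."""
    return float(length_px) * float(pixel_size_um)


def track_duration_s(n_frames: int, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> float:
    """Elapsed time spanned by ``n_frames`` consecutive frames.

    A cluster seen in three frames at a 20 s interval spans 40 s, which is why
    the three-frame persistence filter is equivalent to a >=40 s lifetime cut.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return (int(n_frames) - 1) * float(frame_interval_s)


@dataclass
class TwoChannelMovie:
    """Two-channel time-lapse intensity volume with physical calibration.

    Parameters
    ----------
    data
        Intensity volume of shape ``(n_frames, 2, rows, cols)``.  Any real
        non-negative dtype is accepted; 16-bit unsigned is typical.
    pixel_size_um
        Lateral calibration in µm per pixel.
    frame_interval_s
        Acquisition interval in seconds per frame.
    channel_roles
        Maps ``"reference"`` (red) and ``"query"`` (green) to channel indices.
    bit_depth
        Nominal camera bit depth (metadata only; 16 assumed when unknown).
    """

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    channel_roles: dict = field(default_factory=lambda: {REFERENCE: 0, QUERY: 1})
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"movie data must be (frame, channel, row, col); got shape {self.data.shape}"
            )
        if self.data.shape[1] != 2:
            raise ValueError(f"expected 2 channels, got {self.data.shape[1]}")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be a positive integer")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        roles = set(self.channel_roles)
        if roles != {REFERENCE, QUERY}:
            raise ValueError(f"channel_roles must map exactly {{reference, query}}, got {roles}")
        if set(self.channel_roles.values()) != {0, 1}:
            raise ValueError("channel_roles must map onto channel indices {0, 1}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition times ``t_k = k * frame_interval_s`` in seconds."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s

    @property
    def reference_index(self) -> int:
        return self.channel_roles[REFERENCE]

    @property
    def query_index(self) -> int:
        return self.channel_roles[QUERY]

    def channel(self, index: int) -> np.ndarray:
        """One channel as a ``(frame, row, col)`` stack (a view)."""
        return self.data[:, index]

    def with_data(self, data: np.ndarray) -> "TwoChannelMovie":
        """Copy of this movie carrying new intensity data, same calibration."""
        return dataclasses.replace(self, data=data)

    def swapped_channels(self) -> "TwoChannelMovie":
        """Movie with the reference/query roles exchanged (data untouched)."""
        roles = {
            REFERENCE: self.channel_roles[QUERY],
            QUERY: self.channel_roles[REFERENCE],
        }
        return dataclasses.replace(self, channel_roles=roles)


@dataclass
class PipelineConfig:
    """Tunable parameters of the kinetics pipeline.

    Defaults follow the published quantification rules where they are stated:
    threshold = ``threshold_fraction`` (1/4) of the ``threshold_rank``-th (50th)
    brightest pixel per channel; clusters must exceed ``min_cluster_area_px``
    (20) pixels; tracks must span ``min_track_frames`` (3) frames.  The
    remaining kernel/window sizes are documented package defaults.
    """

    threshold_rank: int = 50
    threshold_fraction: float = 0.25
    threshold_scope: str = "frame"  # "frame" or "dataset"
    min_cluster_area_px: int = 20  # strict: components must EXCEED this area
    noise_floor_sigma: float = 5.0  # robust per-frame floor on thresholds; 0 disables
    min_track_frames: int = 3
    smoothing_window_frames: int = 3
    median_kernel_px: int = 3
    tophat_radius_px: int = 15
    connectivity_3d: int = 26  # 26 (full neighbourhood) or 6 (faces only)
    registration_channel: str = REFERENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.threshold_rank < 1:
            raise ValueError("threshold_rank must be >= 1")
        if self.threshold_scope not in ("frame", "dataset"):
            raise ValueError("threshold_scope must be 'frame' or 'dataset'")
        if self.min_track_frames < 1:
            raise ValueError("min_track_frames must be >= 1")
        if self.min_cluster_area_px < 0:
            raise ValueError("min_cluster_area_px must be >= 0")
        if self.noise_floor_sigma < 0:
            raise ValueError("noise_floor_sigma must be >= 0")
        for name in ("smoothing_window_frames", "median_kernel_px"):
            val = getattr(self, name)
            if val < 1 or val % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {val}")
        if self.tophat_radius_px < 1:
            raise ValueError("tophat_radius_px must be >= 1")
        if self.connectivity_3d not in (6, 26):
            raise ValueError("connectivity_3d must be 6 or 26")
        if self.registration_channel not in (REFERENCE, QUERY):
            raise ValueError("registration_channel must be 'reference' or 'query'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class DriftTrace:
    """Cumulative rigid translation of each frame relative to frame 0.

    ``displacements_px[k]`` is the ``(row, col)`` displacement of frame ``k``'s
    content relative to frame 0; subtracting it re-registers the frame.
    """

    displacements_px: np.ndarray  # (n_frames, 2) as (d_row, d_col)
    metric: Optional[np.ndarray] = None  # per-frame estimation confidence
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.displacements_px = np.asarray(self.displacements_px, dtype=float)
        if self.displacements_px.ndim != 2 or self.displacements_px.shape[1] != 2:
            raise ValueError("displacements_px must have shape (n_frames, 2)")
        if not np.allclose(self.displacements_px[0], 0.0):
            raise ValueError("frame 0 displacement must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.displacements_px.shape[0]


@dataclass
class ThresholdSet:
    """Segmentation thresholds: ``fraction`` x the ``rank``-th brightest pixel.

    ``values`` has shape ``(n_frames, 2)`` for per-frame scope and ``(2,)``
    for dataset scope (one value per channel either way).
    """

    values: np.ndarray
    rank: int
    fraction: float
    scope: str

    def per_frame(self, frame: int) -> np.ndarray:
        """Thresholds (one per channel) applicable to a given frame."""
        if self.scope == "dataset":
            return np.asarray(self.values, dtype=float)
        return np.asarray(self.values[frame], dtype=float)


@dataclass
class ClusterTrack:
    """One tracked XYT connected component.

    ``traces`` holds, per channel, the cluster's *averaged* intensity trace
    over the full movie time axis: the mean over tracked frames of the
    per-frame-mask mean-intensity time series.
    """

    cluster_id: int
    frames: np.ndarray  # sorted distinct frame indices containing the cluster
    max_area_px: int
    traces: Optional[np.ndarray] = None  # (2, n_frames_movie)

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def n_frames_tracked(self) -> int:
        return len(self.frames)


@dataclass
class HalfRiseResult:
    """Per-cluster half-rise times and the recruitment lag Δt½ (green − red)."""

    cluster_id: int
    t_half_red_s: float = np.nan
    t_half_green_s: float = np.nan
    valid_red: bool = False
    valid_green: bool = False
    reason_red: str = ""
    reason_green: str = ""

    @property
    def valid(self) -> bool:
        return self.valid_red and self.valid_green

    @property
    def delta_t_half_s(self) -> float:
        """Lag of the query (green) channel behind the reference (red)."""
        if not self.valid:
            return np.nan
        return self.t_half_green_s - self.t_half_red_s


@dataclass
class CellSummary:
    """Per-cell summary of cluster lags: median with a distribution-free CI."""

    cell_id: object
    n_valid_clusters: int
    median_delta_s: float
    ci95_low_s: float
    ci95_high_s: float
    p_one_sided: float
    ci_degenerate: bool = False  # True when n < 6 forces the full-range CI


@dataclass
class PopulationSummary:
    """Across-cell summary: mean of the per-cell medians with its SEM."""

    n_cells: int
    mean_of_medians_s: float
    sem_s: float
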