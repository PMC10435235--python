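"""Synthetic two-channel TIRF movies and fixed images with known ground truth.

The generator emulates the features of adhesion time-lapse data that the
pipeline must cope with: elongated clusters, channel-specific onset times
with a programmable red-to-green lag, a monotone intensity rise (linear ramp
by default, logistic optionally, with an optional red-channel decay), a
smooth uneven background, rigid stage drift, and Poisson shot noise plus
Gaussian read noise.  The linear ramp gives an analytic half-rise time
``t_half = onset + rise_duration / 2``, so recovery tests have an exact
oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .model import (
    DEFAULT_FRAME_INTERVAL_S,
    DEFAULT_PIXEL_SIZE_UM,
    TwoChannelMovie,
)

DEFAULT_BACKGROUND_PHOTONS = 100.0
DEFAULT_READ_SIGMA = 2.0


def amplitude_for_snr(
    snr: float,
    background_photons: float = DEFAULT_BACKGROUND_PHOTONS,
    read_sigma: float = DEFAULT_READ_SIGMA,
) -> float:
    """Photon amplitude giving a peak SNR under the Poisson+read camera model.

    Solves ``A / sqrt(A + B + sigma_r^2) = snr`` for A, i.e. signal over total
    shot + read noise at the cluster plateau on background B.
    """
    var0 = background_photons + read_sigma**2
    return 0.5 * snr**2 + 0.5 * np.sqrt(snr**4 + 4 * snr**2 * var0)


@dataclass
class ClusterSpec:
    """Geometry and kinetics of one synthetic cluster (an elliptical patch)."""

    center: tuple[float, float]  # (row, col) at frame 0, before drift
    semi_major_px: float
    semi_minor_px: float
    orientation_rad: float
    onset_red_s: float
    lag_s: float

    @property
    def onset_green_s(self) -> float:
        return self.onset_red_s + self.lag_s


@dataclass
class SyntheticMovieSpec:
    """Full description of a synthetic two-channel movie.

    ``amplitude`` and ``rise_duration_s`` are (red, green) pairs in photons
    and seconds.  ``background`` is ``(offset, (g_row, g_col))`` photons with
    a linear gradient per pixel.  ``drift_px_per_frame`` is the rigid
    translation of the whole field between consecutive frames (row, col).
    ``noise=None`` produces the noiseless expected signal (float data).
    """

    image_shape: tuple[int, int] = (128, 128)
    n_frames: int = 60
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    clusters: Sequence[ClusterSpec] = field(default_factory=list)
    rise_duration_s: tuple[float, float] = (120.0, 120.0)
    amplitude: tuple[float, float] = (65.0, 65.0)
    rise_model: str = "ramp"  # "ramp" or "logistic"
    red_decay: Optional[tuple[float, float]] = None  # (start-after-plateau s, half-life s)
    background: tuple[float, tuple[float, float]] = (
        DEFAULT_BACKGROUND_PHOTONS,
        (0.05, 0.08),
    )
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    noise: Optional[tuple[float, float]] = (1.0, DEFAULT_READ_SIGMA)  # (gain, read sigma)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise_model not in ("ramp", "logistic"):
            raise ValueError("rise_model must be 'ramp' or 'logistic'")
        if any(a < 0 for a in self.amplitude):
            raise ValueError("amplitudes must be >= 0")
        duration = (self.n_frames - 1) * self.frame_interval_s
        for c in self.clusters:
            if not (0 <= c.onset_red_s <= duration):
                raise ValueError(
                    f"cluster onset {c.onset_red_s} s outside movie duration {duration} s"
                )
        drift_mag = np.hypot(*self.drift_px_per_frame) * max(self.n_frames - 1, 1)
        if drift_mag >= min(self.image_shape):
            raise ValueError("total drift exceeds the image extent")

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s


@dataclass
class ClusterGroundTruth:
    """True kinetics of one generated cluster, for recovery testing."""

    cluster_id: int
    centroid_path: np.ndarray  # (n_frames, 2) drifted (row, col) positions
    footprint: np.ndarray  # boolean mask in the undrifted frame
    onset_red_s: float
    onset_green_s: float
    t_half_red_s: float
    t_half_green_s: float
    true_lag_s: float
    fully_in_frame: bool = True


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score a pipeline run against the generator."""

    clusters: list[ClusterGroundTruth]
    drift_px: np.ndarray  # (n_frames, 2) cumulative (row, col) displacement
    spec: SyntheticMovieSpec

    @property
    def true_lags_s(self) -> np.ndarray:
        return np.array([c.true_lag_s for c in self.clusters])


def _rise(times: np.ndarray, onset: float, rise_duration: float, model: str) -> np.ndarray:
    """Normalized intensity rise in [0, 1]; midpoint at onset + rise/2."""
    if model == "ramp":
        if rise_duration <= 0:
            return (times >= onset).astype(float)
        return np.clip((times - onset) / rise_duration, 0.0, 1.0)
    # logistic: midpoint at onset + rise/2, ~2% to ~98% over the rise window
    mid = onset + rise_duration / 2.0
    scale = rise_duration / 8.0 if rise_duration > 0 else 1e-9
    return 1.0 / (1.0 + np.exp(-(times - mid) / scale))


def _decay(times: np.ndarray, plateau_s: float, decay: Optional[tuple[float, float]]) -> np.ndarray:
    if decay is None:
        return np.ones_like(times)
    start_after, half_life = decay
    t0 = plateau_s + start_after
    out = np.ones_like(times)
    late = times > t0
    out[late] = 0.5 ** ((times[late] - t0) / half_life)
    return out


def _ellipse_mask(shape: tuple[int, int], cluster: ClusterSpec) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rows - cluster.center[0]
    dc = cols - cluster.center[1]
    c, s = np.cos(cluster.orientation_rad), np.sin(cluster.orientation_rad)
    u = c * dc + s * dr  # along major axis
    v = -s * dc + c * dr
    return (u / cluster.semi_major_px) ** 2 + (v / cluster.semi_minor_px) ** 2 <= 1.0


def generate_movie(spec: SyntheticMovieSpec) -> tuple[TwoChannelMovie, SyntheticGroundTruth]:
    """Render a two-channel movie and its ground truth from a spec.

    The noiseless signal at pixel x, time t is
    ``background(x) + sum_clusters amplitude_ch * rise(t) * footprint(x)``,
    drifted rigidly per frame; Poisson shot noise on the gain-scaled signal
    plus zero-mean Gaussian read noise is then applied, clipped at zero and
    quantized to 16-bit integers.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    times = spec.times_s
    n_frames = spec.n_frames

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    offset, (g_row, g_col) = spec.background
    background = np.clip(offset + g_row * rows + g_col * cols, 0.0, None)

    footprints = [_ellipse_mask(shape, c) for c in spec.clusters]

    # per-cluster, per-channel kinetic time courses
    red_tc, green_tc = [], []
    for c in spec.clusters:
        r = spec.amplitude[0] * _rise(times, c.onset_red_s, spec.rise_duration_s[0], spec.rise_model)
        r = r * _decay(times, c.onset_red_s + spec.rise_duration_s[0], spec.red_decay)
        g = spec.amplitude[1] * _rise(
            times, c.onset_green_s, spec.rise_duration_s[1], spec.rise_model
        )
        red_tc.append(r)
        green_tc.append(g)

    drift = np.cumsum(
        np.vstack([np.zeros((1, 2)), np.tile(spec.drift_px_per_frame, (n_frames - 1, 1))]),
        axis=0,
    )

    clean = np.empty((n_frames, 2, *shape), dtype=float)
    for t in range(n_frames):
        frame_r = background.copy()
        frame_g = background.copy()
        for i, fp in enumerate(footprints):
            if red_tc[i][t] > 0:
                frame_r[fp] += red_tc[i][t]
            if green_tc[i][t] > 0:
                frame_g[fp] += green_tc[i][t]
        if np.any(drift[t] != 0):
            frame_r = ndimage.shift(frame_r, drift[t], order=1, mode="nearest")
            frame_g = ndimage.shift(frame_g, drift[t], order=1, mode="nearest")
        clean[t, 0] = frame_r
        clean[t, 1] = frame_g

    if spec.noise is not None:
        gain, read_sigma = spec.noise
        noisy = rng.poisson(gain * clean).astype(float)
        noisy += rng.normal(0.0, read_sigma, size=noisy.shape)
        data = np.clip(np.rint(noisy), 0, 2**16 - 1).astype(np.uint16)
    else:
        data = clean

    movie = TwoChannelMovie(
        data=data,
        pixel_size_um=spec.pixel_size_um,
        frame_interval_s=spec.frame_interval_s,
    )

    gt_clusters = []
    for i, (c, fp) in enumerate(zip(spec.clusters, footprints)):
        path = np.asarray(c.center, dtype=float)[None, :] + drift
        in_frame = bool(
            np.all(path[:, 0] >= 0)
            and np.all(path[:, 0] <= shape[0] - 1)
            and np.all(path[:, 1] >= 0)
            and np.all(path[:, 1] <= shape[1] - 1)
            and fp.any()
        )
        if not in_frame:
            warnings.warn(f"cluster {i} leaves the field of view", stacklevel=2)
        gt_clusters.append(
            ClusterGroundTruth(
                cluster_id=i,
                centroid_path=path,
                footprint=fp,
                onset_red_s=c.onset_red_s,
                onset_green_s=c.onset_green_s,
                t_half_red_s=c.onset_red_s + spec.rise_duration_s[0] / 2.0,
                t_half_green_s=c.onset_green_s + spec.rise_duration_s[1] / 2.0,
                true_lag_s=c.lag_s,
                fully_in_frame=in_frame,
            )
        )
    return movie, SyntheticGroundTruth(clusters=gt_clusters, drift_px=drift, spec=spec)


def default_cell(
    true_lag_s: float = 60.0,
    snr: Optional[float] = 5.0,
    n_clusters: int = 50,
    seed: int = 0,
    drift_px_per_frame: tuple[float, float] = (0.08, 0.12),
    image_shape: tuple[int, int] = (128, 128),
    n_frames: int = 60,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    rise_duration_s: float = 120.0,
) -> SyntheticMovieSpec:
    """Spec for one simulated spreading cell under the standard conditions.

    Clusters are laid out on a jittered grid (so they stay spatially
    disjoint), with random orientations and red onsets staggered uniformly
    through the usable part of the movie; every cluster carries the same true
    lag.  ``snr=None`` produces the noiseless variant.
    """
    rng = np.random.default_rng(seed)
    margin = 12
    n_side = int(np.ceil(np.sqrt(n_clusters)))
    grid_r = np.linspace(margin, image_shape[0] - margin, n_side)
    grid_c = np.linspace(margin, image_shape[1] - margin, n_side)
    centers = [(r, c) for r in grid_r for c in grid_c][:n_clusters]

    duration = (n_frames - 1) * frame_interval_s
    onset_lo = 2 * frame_interval_s
    onset_hi = duration - true_lag_s - rise_duration_s - 2 * frame_interval_s
    if onset_hi <= onset_lo:
        raise ValueError("movie too short for the requested lag and rise duration")

    clusters = []
    for r, c in centers:
        jitter = rng.uniform(-2.0, 2.0, size=2)
        clusters.append(
            ClusterSpec(
                center=(r + jitter[0], c + jitter[1]),
                semi_major_px=rng.uniform(4.0, 5.0),
                semi_minor_px=rng.uniform(1.8, 2.4),
                orientation_rad=rng.uniform(0, np.pi),
                onset_red_s=rng.uniform(onset_lo, onset_hi),
                lag_s=true_lag_s,
            )
        )
    if snr is None:
        amplitude, noise = 65.0, None
    else:
        amplitude = float(amplitude_for_snr(snr))
        noise = (1.0, DEFAULT_READ_SIGMA)
    return SyntheticMovieSpec(
        image_shape=image_shape,
        n_frames=n_frames,
        frame_interval_s=frame_interval_s,
        clusters=clusters,
        rise_duration_s=(rise_duration_s, rise_duration_s),
        amplitude=(amplitude, amplitude),
        drift_px_per_frame=drift_px_per_frame,
        noise=noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixed-image generator for the line-profile analysis


@dataclass
class ProfileImageTruth:
    """Ground truth for a generated profile image: one entry per adhesion."""

    starts: np.ndarray  # (n, 2) outer-end (row, col) of each sampling line
    directions: np.ndarray  # (n, 2) inward unit vectors
    red_peak_bins: np.ndarray  # axial bin of the red peak along each line
    green_peak_bins: np.ndarray


def generate_profile_image(
    n_adhesions: int = 20,
    peak_offset_px: float = 4.0,
    image_shape: tuple[int, int] = (256, 256),
    sigma_axial_px: float = 3.0,
    sigma_perp_px: float = 1.5,
    amplitude: float = 1000.0,
    background: float = 50.0,
    noise_sigma: float = 0.0,
    red_peak_bin: int = 8,
    peak_bin_jitter: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, ProfileImageTruth]:
    """Render elongated two-channel adhesions with an axial inter-channel offset.

    Each adhesion is a pair of anisotropic Gaussian ridges sharing a major
    axis: the red (reference) peak sits ``red_peak_bin`` (+/- jitter) pixels
    inward of the line start, the green peak ``peak_offset_px`` further
    inward, emulating proteins localised deeper inside the adhesion.  Returns
    a ``(2, rows, cols)`` image and the per-adhesion sampling-line truth.
    """
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    image = np.full((2, *image_shape), background, dtype=float)

    n_side = int(np.ceil(np.sqrt(n_adhesions)))
    margin = 35
    grid_r = np.linspace(margin, image_shape[0] - margin, n_side)
    grid_c = np.linspace(margin, image_shape[1] - margin, n_side)
    centers = [(r, c) for r in grid_r for c in grid_c][:n_adhesions]

    starts, dirs, red_bins, green_bins = [], [], [], []
    for r0, c0 in centers:
        theta = rng.uniform(0, 2 * np.pi)
        d = np.array([np.sin(theta), np.cos(theta)])  # inward unit direction
        rb = red_peak_bin + int(rng.integers(-peak_bin_jitter, peak_bin_jitter + 1))
        gb = rb + peak_offset_px
        start = np.array([r0, c0]) - rb * d  # outer end of the sampling line
        for ch, bin_pos in ((0, rb), (1, gb)):
            peak = start + bin_pos * d
            dr, dc = rows - peak[0], cols - peak[1]
            u = d[0] * dr + d[1] * dc  # axial distance from the peak
            v = -d[1] * dr + d[0] * dc
            image[ch] += amplitude * np.exp(
                -(u**2) / (2 * sigma_axial_px**2) - (v**2) / (2 * sigma_perp_px**2)
            )
        starts.append(start)
        dirs.append(d)
        red_bins.append(rb)
        green_bins.append(gb)

    if noise_sigma > 0:
        image = np.clip(image + rng.normal(0, noise_sigma, image.shape), 0, None)

    truth = ProfileImageTruth(
        starts=np.array(starts),
        directions=np.array(dirs),
        red_peak_bins=np.array(red_bins, dtype=float),
        green_peak_bins=np.array(green_bins, dtype=float),
    )
    return image, truth
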