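"""Axial intensity-profile analysis of fixed two-channel adhesion images.

A sampling line (default 5 px wide x 25 px long, 0.16 µm/px) is placed along
an adhesion's major axis starting at its outer-edge end and pointing inward;
the per-channel profile is the across-width mean at each of the 25 axial
steps.  Profiles from many ROIs are min-max normalized, aligned on the
reference (red/Cas) channel peak by integer-bin shifts, and averaged into a
mean +/- SEM profile per channel, which can be exported as a heat map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .model import DEFAULT_PIXEL_SIZE_UM


@dataclass
class LineProfileSpec:
    """One sampling line: outer-edge start, inward unit direction, geometry."""

    start: tuple[float, float]  # (row, col) of the outer-edge end
    direction: tuple[float, float]  # inward (d_row, d_col); normalized on init
    length_px: int = 25
    width_px: int = 5
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("direction must be non-zero")
        self.direction = tuple(d / norm)
        if self.length_px < 1 or self.width_px < 1:
            raise ValueError("length_px and width_px must be >= 1")

    @property
    def distances_um(self) -> np.ndarray:
        """Distance-from-edge axis: step index x pixel size."""
        return np.arange(self.length_px) * self.pixel_size_um


def sample_line_profile(image: np.ndarray, spec: LineProfileSpec) -> np.ndarray:
    """Per-channel axial profile sampled with bilinear interpolation.

    ``image`` is ``(channels, rows, cols)``.  Each of the ``length_px`` axial
    steps averages ``width_px`` samples taken across the perpendicular
    direction (centred on the axis).  Raises if any sample falls outside the
    image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    d = np.asarray(spec.direction)
    perp = np.array([-d[1], d[0]])
    steps = np.arange(spec.length_px)
    offsets = np.arange(spec.width_px) - (spec.width_px - 1) / 2.0
    # points[s, w] = start + s*d + w_offset*perp
    pts = (
        np.asarray(spec.start)[None, None, :]
        + steps[:, None, None] * d[None, None, :]
        + offsets[None, :, None] * perp[None, None, :]
    )
    rr, cc = pts[..., 0], pts[..., 1]
    if (
        rr.min() < 0
        or cc.min() < 0
        or rr.max() > image.shape[1] - 1
        or cc.max() > image.shape[2] - 1
    ):
        raise ValueError("sampling line exits the image")
    profiles = np.empty((image.shape[0], spec.length_px))
    for ch in range(image.shape[0]):
        samples = ndimage.map_coordinates(
            image[ch], [rr.ravel(), cc.ravel()], order=1, mode="nearest"
        ).reshape(spec.length_px, spec.width_px)
        profiles[ch] = samples.mean(axis=1)
    return profiles


def normalize_profile(profile: np.ndarray) -> np.ndarray:
    """Min-max normalize each channel to [0, 1]; flat channels map to 0."""
    profile = np.asarray(profile, dtype=float)
    out = np.zeros_like(profile)
    for ch in range(profile.shape[0]):
        lo, hi = profile[ch].min(), profile[ch].max()
        if hi > lo:
            out[ch] = (profile[ch] - lo) / (hi - lo)
    return out


@dataclass
class ProfileMatrix:
    """Aligned, normalized profiles across ROIs with per-channel summaries."""

    aligned: np.ndarray  # (n_roi, channels, bins); NaN where shifted out
    shifts: np.ndarray  # integer bin shift applied per ROI
    mean: np.ndarray  # (channels, bins), NaN-aware mean
    sem: np.ndarray  # (channels, bins)
    distances_um: np.ndarray = field(default=None)

    @property
    def n_rois(self) -> int:
        return self.aligned.shape[0]

    def heatmap_matrix(self) -> np.ndarray:
        """Channels x bins matrix of mean normalized intensity."""
        return self.mean


def _shift_with_nan(profile: np.ndarray, shift: int) -> np.ndarray:
    out = np.full_like(profile, np.nan)
    n = profile.shape[-1]
    if shift >= 0:
        out[..., shift:] = profile[..., : n - shift] if shift else profile
    else:
        out[..., :shift] = profile[..., -shift:]
    return out


def align_and_average(
    profiles: Sequence[np.ndarray],
    reference_channel: int = 0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> ProfileMatrix:
    """Normalize, align on the reference-channel peak, and average profiles.

    Each ROI's channels are min-max normalized, then the whole ROI is
    shifted by an integer number of bins so its reference-channel peak lands
    on the modal reference-peak bin across ROIs.  ROIs whose reference
    channel is flat carry no alignment information and are dropped with a
    warning.  Bins vacated by shifting are NaN and excluded from the mean
    and SEM.
    """
    kept = []
    for i, p in enumerate(profiles):
        p = np.asarray(p, dtype=float)
        ref = p[reference_channel]
        if ref.max() == ref.min():
            warnings.warn(f"ROI {i} has a flat reference channel; dropped", stacklevel=2)
            continue
        kept.append(normalize_profile(p))
    if not kept:
        raise ValueError("no usable ROIs (all reference channels flat)")
    stack = np.stack(kept)  # (n, C, bins)
    peaks = np.argmax(stack[:, reference_channel, :], axis=1)
    bins, counts = np.unique(peaks, return_counts=True)
    modal = int(bins[np.argmax(counts)])  # ties resolve to the smallest bin
    shifts = modal - peaks
    aligned = np.stack([_shift_with_nan(p, int(s)) for p, s in zip(stack, shifts)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(aligned, axis=0)
        counts_per_bin = np.sum(np.isfinite(aligned), axis=0)
        std = np.nanstd(aligned, axis=0, ddof=1)
    sem = np.where(counts_per_bin > 1, std / np.sqrt(np.maximum(counts_per_bin, 1)), np.nan)
    distances = np.arange(stack.shape[-1]) * pixel_size_um
    return ProfileMatrix(
        aligned=aligned, shifts=shifts, mean=mean, sem=sem, distances_um=distances
    )


def peak_offset_um(
    matrix: ProfileMatrix, channel_a: int = 0, channel_b: int = 1
) -> float:
    """Mean-profile peak separation (channel_b − channel_a) in µm."""
    pa = int(np.nanargmax(matrix.mean[channel_a]))
    pb = int(np.nanargmax(matrix.mean[channel_b]))
    step = float(matrix.distances_um[1] - matrix.distances_um[0])
    return (pb - pa) * step


def specs_from_labels(
    label_image: np.ndarray,
    inward_point: Optional[tuple[float, float]] = None,
    length_px: int = 25,
    width_px: int = 5,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[LineProfileSpec]:
    """Derive sampling lines from labelled adhesion masks (optional helper).

    Each region's principal axis gives the line direction; the line starts
    at the region end farther from ``inward_point`` (default: image centre,
    a proxy for the cell body) and points toward it, approximating the
    outer-edge-inward convention.
    """
    from skimage.measure import regionprops

    if inward_point is None:
        inward_point = ((label_image.shape[0] - 1) / 2.0, (label_image.shape[1] - 1) / 2.0)
    inward_point = np.asarray(inward_point, dtype=float)
    specs = []
    for region in regionprops(np.asarray(label_image)):
        cy, cx = region.centroid
        theta = region.orientation  # angle of major axis vs row axis
        axis = np.array([np.cos(theta), np.sin(theta)])  # major-axis unit (row, col)
        axis /= np.linalg.norm(axis)
        if np.dot(inward_point - np.array([cy, cx]), axis) < 0:
            axis = -axis
        half = region.axis_major_length / 2.0
        start = np.array([cy, cx]) - axis * half
        specs.append(
            LineProfileSpec(
                start=tuple(start),
                direction=tuple(axis),
                length_px=length_px,
                width_px=width_px,
                pixel_size_um=pixel_size_um,
            )
        )
    return specs


def profiles_to_frame(matrix: ProfileMatrix, channel_names: Optional[list] = None):
    """Tidy per-bin mean +/- SEM table (one row per channel x bin)."""
    import pandas as pd

    n_ch, n_bins = matrix.mean.shape
    names = channel_names or [f"ch{c}" for c in range(n_ch)]
    rows = []
    for c in range(n_ch):
        for b in range(n_bins):
            rows.append(
                {
                    "channel": names[c],
                    "bin": b,
                    "distance_um": matrix.distances_um[b],
                    "mean": matrix.mean[c, b],
                    "sem": matrix.sem[c, b],
                }
            )
    return pd.DataFrame(rows)


def plot_heatmap(matrix: ProfileMatrix, path, channel_names: Optional[list] = None) -> None:
    """Save the mean-profile heat map (channels x distance bins) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_ch = matrix.mean.shape[0]
    fig, ax = plt.subplots(figsize=(6, 0.6 * n_ch + 1.5))
    im = ax.imshow(matrix.mean, aspect="auto", cmap="inferno", interpolation="nearest")
    ax.set_yticks(range(n_ch))
    ax.set_yticklabels(channel_names or [f"ch{c}" for c in range(n_ch)])
    ax.set_xlabel("distance from outer edge (bins)")
    fig.colorbar(im, ax=ax, label="mean normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
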