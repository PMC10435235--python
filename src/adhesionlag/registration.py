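"""Rigid translational drift estimation and correction.

Drift between consecutive frames is estimated by phase correlation on a
single registration channel (the red/reference channel by default, since it
is present earliest in these movies), composed cumulatively, and removed
from both channels identically.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .model import REFERENCE, DriftTrace, TwoChannelMovie


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_drift(
    movie: TwoChannelMovie,
    channel: str = REFERENCE,
    upsample_factor: int = 50,
    min_correlation: float = 0.2,
) -> DriftTrace:
    """Estimate cumulative per-frame drift on one channel.

    Each frame is registered against the previous frame with subpixel phase
    correlation; pairwise shifts are summed into cumulative displacements
    relative to frame 0.  A pairwise shift is accepted only if aligning by
    it yields a frame correlation above ``min_correlation`` and at least the
    unaligned correlation — on frame pairs without real structure, phase
    correlation otherwise returns arbitrary shifts.  Rejected pairs
    contribute zero shift and mark the trace low-confidence.
    """
    if movie.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    stack = np.asarray(movie.channel(movie.channel_roles[channel]), dtype=float)

    shifts = np.zeros((movie.n_frames, 2))
    metric = np.zeros(movie.n_frames)
    low_confidence = False
    for k in range(1, movie.n_frames):
        prev, curr = stack[k - 1], stack[k]
        if prev.std() == 0 or curr.std() == 0:
            low_confidence = True
            continue  # zero pairwise shift
        shift, _, _ = phase_cross_correlation(
            prev, curr, upsample_factor=upsample_factor, normalization=None
        )
        if np.any(shift != 0):
            aligned = ndimage.shift(curr, shift, order=1, mode="nearest")
            r_aligned = _pearson(prev, aligned)
            r_raw = _pearson(prev, curr)
            if r_aligned < min_correlation or r_aligned < r_raw:
                low_confidence = True
                metric[k] = r_aligned
                continue  # unreliable estimate; keep zero shift
            metric[k] = r_aligned
        # phase correlation reports the shift taking curr onto prev; the
        # frame content therefore moved by -shift relative to frame k-1
        shifts[k] = -shift
    cumulative = np.cumsum(shifts, axis=0)
    return DriftTrace(displacements_px=cumulative, metric=metric, low_confidence=low_confidence)


def apply_drift(movie: TwoChannelMovie, drift: DriftTrace) -> TwoChannelMovie:
    """Remove estimated drift: translate each frame by minus its displacement.

    Both channels are translated identically with linear interpolation;
    pixels vacated at the borders are filled with the frame median (which
    avoids creating spurious threshold crossings).  Frames with exactly zero
    displacement are passed through bit-exactly.
    """
    if drift.n_frames != movie.n_frames:
        raise ValueError("drift trace length does not match the movie")
    out = np.array(movie.data, dtype=float, copy=True)
    for k in range(movie.n_frames):
        disp = drift.displacements_px[k]
        if np.all(disp == 0):
            continue
        for ch in range(2):
            frame = np.asarray(movie.data[k, ch], dtype=float)
            fill = float(np.median(frame))
            out[k, ch] = ndimage.shift(frame, -disp, order=1, mode="constant", cval=fill)
    if np.all(drift.displacements_px == 0):
        return movie.with_data(movie.data.copy())
    return movie.with_data(out)
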