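"""Tracking clusters as 3D (XYT) connected components and extracting traces.

Per-frame masks are stacked into an XYT volume and labelled with 3D
connected components, so a cluster is a maximal set of above-threshold
voxels connected across space and time.  Components seen in fewer than the
minimum number of distinct frames (default 3, i.e. >=40 s at a 20 s
interval) are discarded; survivors are relabelled canonically by first
appearance and scanline position, making the output invariant to the input
labelling order.

The per-cluster intensity readout follows the averaged-trace construction:
for every tracked frame f of a cluster, the mask of frame f is used to
measure a full mean-intensity time series over the whole movie, and those
per-frame-mask series are averaged pointwise into a single trace per
channel.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label

from .model import ClusterTrack, TwoChannelMovie

_CONNECTIVITY = {6: 1, 26: 3}


def track_clusters(
    masks: np.ndarray, min_frames: int = 3, connectivity_3d: int = 26
) -> tuple[np.ndarray, list[ClusterTrack]]:
    """Label an XYT mask stack and apply the persistence filter.

    Returns the relabelled ``(frame, row, col)`` integer volume (0 =
    background, labels contiguous ``1..K`` in canonical order) and one
    :class:`ClusterTrack` per surviving component (traces not yet filled).
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3:
        raise ValueError("mask stack must be (frame, row, col)")
    if connectivity_3d not in _CONNECTIVITY:
        raise ValueError("connectivity_3d must be 6 or 26")
    raw = label(masks, connectivity=_CONNECTIVITY[connectivity_3d])
    n_raw = raw.max()
    if n_raw == 0:
        return np.zeros_like(raw), []

    n_cols = masks.shape[2]
    keys = []  # (first_frame, scanline_position, old_label)
    frames_per_label = {}
    for old in range(1, n_raw + 1):
        tt, rr, cc = np.nonzero(raw == old)
        frames = np.unique(tt)
        if len(frames) < min_frames:
            continue
        first = frames[0]
        in_first = tt == first
        scan = int(np.min(rr[in_first] * n_cols + cc[in_first]))
        keys.append((int(first), scan, old))
        frames_per_label[old] = frames
    keys.sort()

    relabelled = np.zeros_like(raw)
    tracks = []
    for new, (_, _, old) in enumerate(keys, start=1):
        sel = raw == old
        relabelled[sel] = new
        areas = sel.sum(axis=(1, 2))
        tracks.append(
            ClusterTrack(
                cluster_id=new,
                frames=frames_per_label[old],
                max_area_px=int(areas.max()),
            )
        )
    return relabelled, tracks


def extract_traces(
    track: ClusterTrack, label_volume: np.ndarray, movie: TwoChannelMovie
) -> np.ndarray:
    """Averaged per-channel intensity trace of one tracked cluster.

    For each tracked frame f, the 2D mask of the cluster in frame f yields a
    mean-intensity series over every movie time point; the cluster trace is
    the pointwise mean of those series.  Shape ``(2, n_frames)``.
    """
    data = np.asarray(movie.data, dtype=float)  # (T, C, Y, X)
    accum = np.zeros((2, movie.n_frames))
    for f in track.frames:
        mask = label_volume[f] == track.cluster_id
        if not mask.any():
            raise ValueError(
                f"cluster {track.cluster_id} has an empty mask in frame {f}"
            )
        rr, cc = np.nonzero(mask)
        accum += data[:, :, rr, cc].mean(axis=2).T  # (C, T)
    return accum / len(track.frames)


def extract_all_traces(
    tracks: list[ClusterTrack], label_volume: np.ndarray, movie: TwoChannelMovie
) -> list[ClusterTrack]:
    """Fill ``traces`` on every track in place; returns the same list."""
    for track in tracks:
        track.traces = extract_traces(track, label_volume, movie)
    return tracks
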