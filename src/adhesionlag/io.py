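"""Movie/image reading and writing and tabular result output.

Movies travel as multi-page TIFF / OME-TIFF hyperstacks.  On read, the axis
layout is taken from the TIFF series metadata when present; otherwise (or
when overridden) ``TCYX`` and ``TYXC`` layouts are accepted.  Result tables
are plain CSV; label volumes are written as 16-bit TIFF.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .model import TwoChannelMovie

RESULT_COLUMNS = [
    "cell_id",
    "cluster_id",
    "t_half_red_s",
    "t_half_green_s",
    "delta_t_half_s",
    "area_px_max",
    "n_frames_tracked",
    "valid",
]


def _to_tcyx(data: np.ndarray, axes: Optional[str]) -> np.ndarray:
    if data.ndim != 4:
        raise ValueError(
            f"expected a 4D (time, channel, row, col) hyperstack; got shape {data.shape}"
        )
    if axes is None:
        # guess: the channel axis is the size-2 axis in position 1 or 3
        if data.shape[1] == 2:
            axes = "TCYX"
        elif data.shape[3] == 2:
            axes = "TYXC"
        else:
            raise ValueError(
                "cannot identify a 2-channel axis; pass axis_order explicitly"
            )
    axes = axes.upper()
    if sorted(axes) != sorted("TCYX"):
        raise ValueError(f"unsupported axis order {axes!r}; expected a permutation of TCYX")
    return np.moveaxis(data, [axes.index(a) for a in "TCYX"], [0, 1, 2, 3])


def load_movie(
    path,
    pixel_size_um: float,
    frame_interval_s: float,
    axis_order: Optional[str] = None,
    bit_depth: int = 16,
) -> TwoChannelMovie:
    """Read a two-channel hyperstack TIFF with its physical calibration.

    Intensities are returned unmodified and channel order is preserved.
    Raises for missing files, movies without exactly two channels, and
    non-positive calibration values.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"movie file not found: {path}")
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("pixel_size_um and frame_interval_s must be positive")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = axis_order or series.axes
    if data.ndim == 3:
        raise ValueError("expected 2 channels, got a single-channel stack")
    data = _to_tcyx(np.asarray(data), axes)
    if data.shape[1] != 2:
        raise ValueError(f"expected 2 channels, got {data.shape[1]}")
    return TwoChannelMovie(
        data=data,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        bit_depth=bit_depth,
    )


def save_movie(movie: TwoChannelMovie, path) -> None:
    """Write a movie as an ImageJ-style TCYX hyperstack (lossless)."""
    data = np.asarray(movie.data)
    if np.issubdtype(data.dtype, np.floating):
        tifffile.imwrite(path, data.astype(np.float32), metadata={"axes": "TCYX"})
    else:
        tifffile.imwrite(path, data, imagej=True, metadata={"axes": "TCYX"})


def write_results(table: pd.DataFrame, path) -> None:
    """Write a ResultTable to CSV (stable column order)."""
    table.loc[:, RESULT_COLUMNS].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_labels(label_volume: np.ndarray, path) -> None:
    """Write a label volume as a 16-bit TIFF stack."""
    vol = np.asarray(label_volume)
    if vol.max() > 2**16 - 1:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(
        path, vol.astype(np.uint16), photometric="minisblack", metadata={"axes": "TYX"}
    )
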