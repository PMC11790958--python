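"""Kymograph construction from tether image series.

The processing chain mirrors the single-molecule analysis it implements:
frames are smoothed with a radius-2 disc median filter, optionally
background-subtracted with a radius-10 white top-hat (used for display
snapshots), and each frame is collapsed into one kymograph column by
summing an 11-pixel band centred on the DNA axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "ImageSeries",
    "Kymograph",
    "median_filter_frame",
    "tophat_subtract",
    "find_axis_column",
    "build_kymograph",
]


@dataclass
class ImageSeries:
    """Time-ordered stack of 2-D fluorescence frames for one tether ROI."""

    frames: np.ndarray  # (n_frames, rows, cols)
    frame_interval: float
    roi_origin: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    #: camera-style baseline added on 16-bit export so that negative
    #: read-noise excursions survive the round trip un-rectified
    TIFF_BASELINE = 100.0

    def to_tiff(self, path) -> None:
        """Write as multi-page 16-bit unsigned TIFF with a baseline offset."""
        data = np.clip(np.round(self.frames + self.TIFF_BASELINE), 0, 65535)
        tifffile.imwrite(
            path,
            data.astype(np.uint16),
            metadata={
                "frame_interval_s": self.frame_interval,
                "baseline": self.TIFF_BASELINE,
            },
        )

    @classmethod
    def from_tiff(
        cls, path, frame_interval: float = 1.0, baseline: float | None = None
    ) -> "ImageSeries":
        """Read a stack; subtracts the stored (or given) baseline offset."""
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            if baseline is None:
                meta = tif.shaped_metadata or tif.imagej_metadata or {}
                if isinstance(meta, (list, tuple)):
                    meta = meta[0] if meta else {}
                baseline = float(meta.get("baseline", 0.0))
        if data.ndim == 2:
            data = data[None]
        return cls(frames=data.astype(float) - baseline, frame_interval=frame_interval)


@dataclass
class Kymograph:
    """Position (rows) x time (columns) intensity matrix for one tether.

    Column ``t`` is the 11-pixel band sum of frame ``t`` (for the default
    ``band_half_width`` of 5); row 0 corresponds to the top tether anchor.
    """

    matrix: np.ndarray
    frame_interval: float
    axis_col: int
    band_half_width: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.matrix.astype(np.float32))

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",")


def median_filter_frame(frame: np.ndarray, radius: int = 2) -> np.ndarray:
    """Disc median filter; ``radius=0`` is the identity.

    The footprint is the discrete Euclidean ball ``x^2 + y^2 <= r^2``
    (boundary ties included), always an odd-sized window.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    frame = np.asarray(frame, dtype=float)
    if radius == 0:
        return frame.copy()
    return ndimage.median_filter(frame, footprint=disk(radius), mode="reflect")


def tophat_subtract(frame: np.ndarray, radius: int = 10) -> np.ndarray:
    """White top-hat background subtraction with a disc structuring element.

    Output = input - morphological opening; non-negative everywhere and
    bounded above by the input.  Structures narrower than the disc (the
    DNA line, the loop punctum) survive; smooth background is removed.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    frame = np.asarray(frame, dtype=float)
    return ndimage.white_tophat(frame, footprint=disk(radius), mode="reflect")


def find_axis_column(series: ImageSeries) -> int:
    """Default DNA-axis estimate: column with maximal summed intensity."""
    return int(np.argmax(series.frames.sum(axis=(0, 1))))


def build_kymograph(
    series: ImageSeries,
    axis_col: int | None = None,
    band_half_width: int = 5,
    median_radius: int | None = None,
    tophat_radius: int | None = None,
) -> Kymograph:
    """Collapse an image series into a kymograph by band summation.

    Parameters
    ----------
    series :
        Input frames.  Per the pipeline default these should already be
        median filtered; pass ``median_radius`` (and optionally
        ``tophat_radius``) to apply the filters here instead.
    axis_col :
        Pixel column of the DNA axis; auto-detected as the column of
        maximal summed intensity when omitted.  The same fixed column is
        used for every frame (no per-frame re-centring).
    band_half_width :
        Half-width of the summation band; the default 5 gives the
        11-pixel band.

    Raises
    ------
    ValueError
        If the band extends outside the frame, identifying the offending
        columns.
    """
    if band_half_width < 0:
        raise ValueError("band_half_width must be >= 0")
    if axis_col is None:
        axis_col = find_axis_column(series)
    n_cols = series.frame_shape[1]
    lo, hi = axis_col - band_half_width, axis_col + band_half_width
    if lo < 0 or hi >= n_cols:
        raise ValueError(
            f"summation band columns {lo}..{hi} fall outside frame "
            f"columns 0..{n_cols - 1} (axis_col={axis_col}, "
            f"band_half_width={band_half_width})"
        )
    frames = series.frames
    if median_radius is not None and median_radius > 0:
        frames = np.stack([median_filter_frame(f, median_radius) for f in frames])
    if tophat_radius is not None:
        frames = np.stack([tophat_subtract(f, tophat_radius) for f in frames])
    matrix = frames[:, :, lo : hi + 1].sum(axis=2).T
    return Kymograph(
        matrix=matrix,
        frame_interval=series.frame_interval,
        axis_col=axis_col,
        band_half_width=band_half_width,
    )
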