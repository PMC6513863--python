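"""Image-stack and ROI input, low-pass filtering, and gray-level quantization.

B-mode ultrasound scans arrive as multi-frame grayscale stacks (multi-page
TIFF or a numbered PNG/BMP series); the tumor region is supplied as a binary
mask image or a closed polygon contour.  All frames are mapped onto a common
internal intensity scale (float64 in [0, 255]) so that one quantization path
serves 8- and 16-bit sources alike.

Conventions
-----------
* arrays are row-major, origin top-left, 0-based;
* masks are boolean arrays congruent with the frame geometry;
* contour vertices are (x=column, y=row) pairs in pixel coordinates;
  rasterization tests pixel *centers* against the polygon with the even-odd
  rule, counting centers on the boundary as inside.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile
from matplotlib.path import Path as _MplPath
from scipy import ndimage

__all__ = [
    "FormatError",
    "ROIValidationError",
    "ScanStack",
    "TumorROI",
    "QuantizedROI",
    "read_scan",
    "write_scan",
    "read_roi",
    "write_mask",
    "rasterize_contour",
    "gaussian_lowpass",
    "quantize",
    "MIN_ROI_PIXELS",
]

#: smallest tumor region accepted for feature computation
MIN_ROI_PIXELS = 16

#: default Gaussian low-pass width (pixels) and kernel truncation (in sigmas)
DEFAULT_SIGMA = 1.0
GAUSSIAN_TRUNCATE = 4.0

#: default gray-level count for run-length quantization
DEFAULT_N_GRAY = 32


class FormatError(ValueError):
    """Unreadable or inconsistent image input."""


class ROIValidationError(ValueError):
    """Mask fails the segmentation sanity rules (empty / fragmented / tiny)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ScanStack:
    """Ordered grayscale frames from one imaging session.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Float64 intensities on the internal [0, 255] scale.
    pixel_spacing : float
        Physical size of one pixel (mm/pixel); defaults to 1.0 when the
        source carries no calibration.
    base_frame_index : int
        Index of the operator-designated best frame.
    """

    frames: np.ndarray
    pixel_spacing: float = 1.0
    base_frame_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n, rows, cols) stack")
        if not 0 <= self.base_frame_index < self.n_frames:
            raise FormatError(
                f"base_frame_index {self.base_frame_index} out of range "
                f"for {self.n_frames} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def base_frame(self) -> np.ndarray:
        return self.frames[self.base_frame_index]


@dataclass
class TumorROI:
    """Binary tumor region tied to one frame geometry.

    The mask must contain at least ``MIN_ROI_PIXELS`` foreground pixels and
    form exactly one 8-connected component — anything else signals a bad
    manual segmentation and is rejected rather than silently propagated.
    """

    mask: np.ndarray
    contour: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ROIValidationError("mask must be 2-D")
        n_fg = int(self.mask.sum())
        if n_fg == 0:
            raise ROIValidationError("empty ROI mask")
        if n_fg < MIN_ROI_PIXELS:
            raise ROIValidationError(
                f"ROI has {n_fg} pixels; at least {MIN_ROI_PIXELS} required"
            )
        _, n_comp = ndimage.label(self.mask, structure=np.ones((3, 3), bool))
        if n_comp != 1:
            raise ROIValidationError(
                f"ROI must be one 8-connected component, found {n_comp}"
            )
        if self.contour is not None:
            self.contour = np.asarray(self.contour, dtype=np.float64)
            if self.contour.ndim != 2 or self.contour.shape[1] != 2:
                raise ROIValidationError("contour must be an (n, 2) array of (x, y)")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class QuantizedROI:
    """Integer gray levels 1..n_gray inside the ROI, 0 outside."""

    levels: np.ndarray
    n_gray: int
    source_min: float
    source_max: float
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.levels > 0


# ---------------------------------------------------------------------------
# reading and writing scans
# ---------------------------------------------------------------------------

_FRAME_EXTS = (".png", ".bmp", ".tif", ".tiff")


def _to_internal(arr: np.ndarray) -> np.ndarray:
    """Map a decoded frame onto the internal float [0, 255] scale."""
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) export of a grayscale image
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) * (255.0 / 65535.0)
    return arr.astype(np.float64)


def _natural_key(name: str) -> list:
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


def read_scan(
    path: str | os.PathLike,
    base_frame_index: int = 0,
    pixel_spacing: float = 1.0,
) -> ScanStack:
    """Read a multi-frame scan from a multi-page TIFF, a single image, or a
    directory of numbered PNG/BMP/TIFF frames (natural sort order).
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        names = sorted(
            (n for n in os.listdir(path) if n.lower().endswith(_FRAME_EXTS)),
            key=_natural_key,
        )
        if not names:
            raise FormatError(f"no image frames found in directory {path!r}")
        frames = [_to_internal(iio.imread(os.path.join(path, n))) for n in names]
    elif path.lower().endswith((".tif", ".tiff")):
        try:
            raw = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc
        raw = raw[None] if raw.ndim == 2 else raw
        frames = [_to_internal(f) for f in raw]
    else:
        try:
            frames = [_to_internal(iio.imread(path))]
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot read image {path!r}: {exc}") from exc

    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent frame shapes in {path!r}: {sorted(shapes)}")
    return ScanStack(
        np.stack(frames), pixel_spacing=pixel_spacing, base_frame_index=base_frame_index
    )


def write_scan(path: str | os.PathLike, stack: ScanStack) -> None:
    """Write a scan as an 8-bit multi-page TIFF (lossless for uint8-valued data)."""
    data = np.clip(np.rint(stack.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(os.fspath(path), data, photometric="minisblack")


def write_mask(path: str | os.PathLike, roi: TumorROI) -> None:
    """Write a mask as a single-page PNG with foreground = 255."""
    iio.imwrite(os.fspath(path), (roi.mask.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# ROI input
# ---------------------------------------------------------------------------


def _on_polygon_edge(points: np.ndarray, vertices: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """True where a point lies within ``tol`` of any polygon edge."""
    on_edge = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        p1, p2 = vertices[i], vertices[(i + 1) % n]
        d = p2 - p1
        den = float(d @ d)
        if den == 0.0:  # repeated vertex
            dist = np.linalg.norm(points - p1, axis=1)
        else:
            t = np.clip(((points - p1) @ d) / den, 0.0, 1.0)
            dist = np.linalg.norm(points - (p1 + t[:, None] * d), axis=1)
        on_edge |= dist <= tol
    return on_edge


def rasterize_contour(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon (x, y vertices) onto a pixel grid.

    A pixel belongs to the region iff its center lies strictly inside the
    polygon under the even-odd rule, or exactly on an edge (half-open
    ambiguity on the boundary is resolved as inside).
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise ROIValidationError("contour needs at least 3 (x, y) vertices")
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    centers = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    # closed=True treats the final vertex as the CLOSEPOLY placeholder, so the
    # first vertex must be repeated to keep every supplied edge
    path = _MplPath(np.vstack([vertices, vertices[:1]]), closed=True)
    inside = path.contains_points(centers) | _on_polygon_edge(centers, vertices)
    return inside.reshape(rows, cols)


def read_roi(path: str | os.PathLike, frame_shape: tuple[int, int]) -> TumorROI:
    """Read a tumor ROI from a mask image (nonzero = foreground) or a CSV of
    contour vertices (two columns: x, y), validating against ``frame_shape``.
    """
    path = os.fspath(path)
    if path.lower().endswith(".csv"):
        vertices = np.loadtxt(path, delimiter=",", ndmin=2)
        mask = rasterize_contour(vertices, frame_shape)
        return TumorROI(mask, contour=vertices)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read mask {path!r}: {exc}") from exc
    if raw.ndim == 3:
        raw = raw[..., 0]
    if raw.shape != tuple(frame_shape):
        raise ROIValidationError(
            f"mask shape {raw.shape} does not match frame shape {tuple(frame_shape)}"
        )
    return TumorROI(raw > 0)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def gaussian_lowpass(
    image: np.ndarray, sigma: float = DEFAULT_SIGMA, truncate: float = GAUSSIAN_TRUNCATE
) -> np.ndarray:
    """Separable Gaussian low-pass filter (reflect boundary handling).

    Reduces the inherent speckle noise of B-mode frames before feature
    computation.  ``sigma=0`` is the identity.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect", truncate=truncate)


def quantize(
    image: np.ndarray, roi: "TumorROI | np.ndarray", n_gray: int = DEFAULT_N_GRAY
) -> QuantizedROI:
    """Quantize in-ROI intensities into ``n_gray`` equal-width bins.

    Bin edges span [min, max] of the in-ROI intensities; the maximum maps to
    level ``n_gray``; a constant region maps to level 1 everywhere.  The
    mapping is monotone in source intensity.  ``roi`` may be a validated
    TumorROI or a plain boolean mask (used for wavelet-subband recomputation,
    where the downsampled mask need not satisfy segmentation rules).
    """
    if n_gray < 2:
        raise ValueError(f"n_gray must be >= 2, got {n_gray}")
    image = np.asarray(image, dtype=np.float64)
    mask = roi.mask if isinstance(roi, TumorROI) else np.asarray(roi, dtype=bool)
    if image.shape != mask.shape:
        raise ROIValidationError("image and ROI mask shapes differ")
    vals = image[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int64)
    if vmax == vmin:
        levels[mask] = 1
    else:
        scaled = (vals - vmin) / (vmax - vmin) * n_gray
        levels[mask] = np.minimum(np.floor(scaled).astype(np.int64) + 1, n_gray)
    return QuantizedROI(levels=levels, n_gray=n_gray, source_min=vmin, source_max=vmax, mask=mask)
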