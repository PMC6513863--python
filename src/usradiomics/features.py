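"""The 284-feature radiomic signature of a segmented tumor region.

The signature concatenates four groups in a fixed, versioned order:

====================  =======  =============================================
group                 count    content
====================  =======  =============================================
morphology            9        shape of the ROI (2-D proxies for the
                               3-D-named quantities, see below)
density               21       first-order intensity statistics inside the
                               ROI after Gaussian low-pass filtering
texture               44       11 gray-level run-length (GLRLM) statistics
                               x 4 directions (0, 45, 90, 135 degrees)
wavelet               210      density + texture recomputed on the four
                               one-level Haar subbands (LL, LH, HL, HH);
                               the canonical ``paper_284`` profile keeps the
                               first 210 of the 260 recomputed values so the
                               total is exactly 284; ``full_334`` keeps all
====================  =======  =============================================

Morphology conventions (the tumor is imaged as a 2-D section, so the
3-D-named features use documented planar proxies): volume = area * spacing^2,
surface area = perimeter * spacing, maximum 3-D diameter = maximum pairwise
distance between boundary pixel centers (Feret diameter), spherical
disproportion = perimeter / (2*pi*r_eq) with r_eq = sqrt(area/pi), and
spherical ratio is its reciprocal.

Five density features are named but not given formulas in the radiomics
literature this bank follows; the definitions used here are:

* ISO-intensity — fraction of ROI pixels within +/-10% of the ROI mean;
* fluctuation mean / STD — mean / STD of |v - local 3x3 mean|;
* mean contrast — (mean_ROI - mean_band) / (mean_ROI + mean_band) against a
  5-pixel outer boundary band;
* contrast — (max - min) / (max + min) over the ROI;
* STD ratio — ROI STD / STD of the 5-pixel outer boundary band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .io_preproc import (
    DEFAULT_N_GRAY,
    DEFAULT_SIGMA,
    MIN_ROI_PIXELS,
    QuantizedROI,
    ROIValidationError,
    TumorROI,
    gaussian_lowpass,
    quantize,
)

__all__ = [
    "MORPHOLOGY_NAMES",
    "DENSITY_NAMES",
    "TEXTURE_STATS",
    "DIRECTIONS",
    "SUBBANDS",
    "PROFILES",
    "GLRLMatrix",
    "SubbandSet",
    "FeatureVector",
    "feature_names",
    "morphology_features",
    "density_features",
    "build_glrlm",
    "glrlm_features",
    "texture_features",
    "wavelet_decompose",
    "wavelet_features",
    "feature_vector",
]

MORPHOLOGY_NAMES = (
    "Volume",
    "Convexity",
    "Max_Radius",
    "Radius_STD",
    "Surface_Area",
    "Compactness",
    "Max_3D_Diameter",
    "Spherical_Disproportion",
    "Spherical_Ratio",
)

DENSITY_NAMES = (
    "Density",
    "Density_STD",
    "Gradient_Mean",
    "Gradient_STD",
    "ISO_Intensity",
    "Fluctuation_Mean",
    "Fluctuation_STD",
    "Mean_Contrast",
    "Contrast",
    "Skewness",
    "Kurtosis",
    "STD_Ratio",
    "Energy",
    "Entropy",
    "Max_Intensity",
    "MAD",
    "Median",
    "Minimum",
    "Range",
    "RMS",
    "Uniformity",
)

TEXTURE_STATS = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
)

DIRECTIONS = (0, 45, 90, 135)
SUBBANDS = ("LL", "LH", "HL", "HH")

#: width (pixels) of the outer boundary band used by Mean_Contrast / STD_Ratio
BOUNDARY_BAND_PX = 5

_TEXTURE_NAMES = tuple(f"{s}_{d}" for s in TEXTURE_STATS for d in DIRECTIONS)
_WAVELET_NAMES_FULL = tuple(
    n
    for sb in SUBBANDS
    for n in (
        [f"{d}_{sb}" for d in DENSITY_NAMES]
        + [f"{s}_{sb}_{theta}" for s in TEXTURE_STATS for theta in DIRECTIONS]
    )
)

#: feature-name profiles; the canonical published layout is ``paper_284``
PROFILES: Mapping[str, tuple[str, ...]] = {
    "paper_284": MORPHOLOGY_NAMES + DENSITY_NAMES + _TEXTURE_NAMES + _WAVELET_NAMES_FULL[:210],
    "full_334": MORPHOLOGY_NAMES + DENSITY_NAMES + _TEXTURE_NAMES + _WAVELET_NAMES_FULL,
}


def feature_names(profile: str = "paper_284") -> tuple[str, ...]:
    """Canonical ordered feature names for a profile."""
    try:
        return PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GLRLMatrix:
    """Gray-level run-length matrix for one direction.

    ``p[i-1, j-1]`` counts maximal runs of quantized level ``i`` (1..n_gray)
    and length ``j`` restricted to in-ROI pixels; out-of-ROI pixels break
    runs.  Invariants: sum(p) = n_runs and sum(j * p) = n_pixels (every ROI
    pixel belongs to exactly one maximal run per direction).
    """

    p: np.ndarray
    theta: int
    n_runs: int
    n_pixels: int


@dataclass
class SubbandSet:
    """One-level 2-D wavelet decomposition with per-subband ROI masks."""

    subbands: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    wavelet: str = "haar"

    def energy(self) -> float:
        return float(sum(np.sum(b.astype(np.float64) ** 2) for b in self.subbands.values()))


@dataclass
class FeatureVector:
    """Ordered, named radiomic signature of one ROI plus provenance."""

    names: tuple[str, ...]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) centers of boundary pixels (foreground with a 4-neighbor
    outside the region or on the image edge)."""
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(mask & ~interior).astype(np.float64)


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 16:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:  # collinear boundary
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def morphology_features(roi: TumorROI, pixel_spacing: float = 1.0) -> dict[str, float]:
    """Nine shape features of the tumor region (planar proxies, see module
    docstring for the conventions behind the 3-D-named quantities)."""
    mask = roi.mask
    if mask.sum() < MIN_ROI_PIXELS:
        raise ROIValidationError("ROI too small for morphology features")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    s = float(pixel_spacing)
    area = float(props.area)
    # Crofton estimator: asymptotically unbiased on smooth rasterized shapes
    # (the chain-code perimeter overestimates disks by ~4%)
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    convex_area = float(props.area_convex)
    centroid = np.asarray(props.centroid)

    boundary = _boundary_points(mask)
    radii = np.linalg.norm(boundary - centroid, axis=1)
    r_eq = np.sqrt(area / np.pi)

    return {
        "Volume": area * s * s,
        "Convexity": area / convex_area,
        "Max_Radius": float(radii.max()) * s,
        "Radius_STD": float(radii.std()) * s,
        "Surface_Area": perimeter * s,
        "Compactness": 4.0 * np.pi * area / perimeter**2,
        "Max_3D_Diameter": _max_pairwise_distance(boundary) * s,
        "Spherical_Disproportion": perimeter / (2.0 * np.pi * r_eq),
        "Spherical_Ratio": (2.0 * np.pi * r_eq) / perimeter,
    }


# ---------------------------------------------------------------------------
# density (first-order) statistics
# ---------------------------------------------------------------------------


def _outer_band(mask: np.ndarray, width: int = BOUNDARY_BAND_PX) -> np.ndarray:
    dilated = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool), iterations=width)
    return dilated & ~mask


def _roi_histogram(vals: np.ndarray, n_bins: int) -> np.ndarray:
    """Normalized n_bins histogram over [min, max] of the values; a constant
    sample concentrates in a single bin."""
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax == vmin:
        q = np.zeros(n_bins)
        q[0] = 1.0
        return q
    counts, _ = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
    return counts / counts.sum()


def density_features(
    image: np.ndarray,
    mask: np.ndarray | TumorROI,
    n_bins: int = DEFAULT_N_GRAY,
) -> dict[str, float]:
    """21 first-order intensity statistics over in-ROI pixels.

    ``image`` should already be low-pass filtered when called from the
    pipeline.  Histogram-based entries (entropy, uniformity) use ``n_bins``
    equal-width bins over the in-ROI intensity range.  Zero-variance regions
    use the conventions: skewness = kurtosis = 0, entropy = 0, uniformity = 1.
    """
    if isinstance(mask, TumorROI):
        mask = mask.mask
    image = np.asarray(image, dtype=np.float64)
    v = image[mask]
    n = v.size
    mean = float(v.mean())
    std = float(v.std())

    gx = ndimage.sobel(image, axis=1, mode="reflect")
    gy = ndimage.sobel(image, axis=0, mode="reflect")
    grad = np.hypot(gx, gy)[mask]

    local_mean = ndimage.uniform_filter(image, size=3, mode="reflect")
    fluct = np.abs(image - local_mean)[mask]

    band = _outer_band(mask)
    band_v = image[band]
    if band_v.size:
        band_mean, band_std = float(band_v.mean()), float(band_v.std())
    else:  # ROI touches every border; no surrounding tissue to compare with
        band_mean, band_std = 0.0, 0.0

    vmin, vmax = float(v.min()), float(v.max())
    q = _roi_histogram(v, n_bins)
    nz = q[q > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    zero_var = std == 0.0
    return {
        "Density": mean,
        "Density_STD": std,
        "Gradient_Mean": float(grad.mean()),
        "Gradient_STD": float(grad.std()),
        "ISO_Intensity": float(np.mean(np.abs(v - mean) <= 0.1 * abs(mean))),
        "Fluctuation_Mean": float(fluct.mean()),
        "Fluctuation_STD": float(fluct.std()),
        "Mean_Contrast": (mean - band_mean) / (mean + band_mean)
        if (mean + band_mean) != 0.0
        else 0.0,
        "Contrast": (vmax - vmin) / (vmax + vmin) if (vmax + vmin) != 0.0 else 0.0,
        "Skewness": 0.0 if zero_var else float(stats.skew(v)),
        "Kurtosis": 0.0 if zero_var else float(stats.kurtosis(v)),
        "STD_Ratio": std / band_std if band_std > 0.0 else 0.0,
        "Energy": float(np.sum(v**2)),
        "Entropy": entropy,
        "Max_Intensity": vmax,
        "MAD": float(np.mean(np.abs(v - mean))),
        "Median": float(np.median(v)),
        "Minimum": vmin,
        "Range": vmax - vmin,
        "RMS": float(np.sqrt(np.mean(v**2))),
        "Uniformity": float(np.sum(q**2)),
    }


# ---------------------------------------------------------------------------
# gray-level run-length texture
# ---------------------------------------------------------------------------


def _sheared(levels: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Place row i at column offset ``offsets[i]`` in a zero canvas, so the
    canvas columns become the image's diagonals; a zero bottom row keeps
    column-to-column raveling from merging runs."""
    h, w = levels.shape
    canvas = np.zeros((h + 1, w + h - 1), dtype=levels.dtype)
    cols = np.arange(w)[None, :] + offsets[:, None]
    canvas[np.arange(h)[:, None], cols] = levels
    return canvas


def _direction_sequence(levels: np.ndarray, theta: int) -> np.ndarray:
    """All scanlines of one direction flattened into a single 1-D sequence
    with zero sentinels between lines (level 0 breaks runs anyway).

    0 deg: rows left-to-right; 90 deg: columns top-to-bottom; 45 deg:
    up-right diagonals; 135 deg: up-left diagonals.  Runs are orientation-
    symmetric, so each line is traversed once.
    """
    h, w = levels.shape
    if theta == 0:
        return np.pad(levels, ((0, 0), (0, 1))).ravel()
    if theta == 90:
        return np.pad(levels.T, ((0, 0), (0, 1))).ravel()
    if theta == 45:
        # column c of the sheared canvas holds pixels (i, c - i): up-right
        return _sheared(levels, np.arange(h)).T.ravel()
    if theta == 135:
        # column c holds pixels (i, c - (h - 1) + i): up-left / down-right
        return _sheared(levels, np.arange(h - 1, -1, -1)).T.ravel()
    raise ValueError(f"direction must be one of {DIRECTIONS}, got {theta}")


def build_glrlm(qroi: QuantizedROI, theta: int) -> GLRLMatrix:
    """Count maximal runs of equal quantized level along one direction.

    Level 0 marks out-of-ROI pixels and breaks runs without contributing any.
    """
    levels = qroi.levels
    n_gray = qroi.n_gray
    j_max = max(levels.shape)
    p = np.zeros((n_gray, j_max), dtype=np.int64)
    seq = _direction_sequence(levels, theta)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [seq.size]))
    run_levels = seq[starts]
    run_lengths = ends - starts
    keep = run_levels > 0
    np.add.at(p, (run_levels[keep] - 1, run_lengths[keep] - 1), 1)
    return GLRLMatrix(
        p=p, theta=theta, n_runs=int(p.sum()), n_pixels=int((levels > 0).sum())
    )


def glrlm_features(glrlm: GLRLMatrix) -> dict[str, float]:
    """The 11 classical run-length statistics (Galloway / Chu) of one matrix:
    SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE."""
    if glrlm.n_runs == 0:
        raise ValueError("empty GLRLM: ROI contributes no runs in this direction")
    p = glrlm.p.astype(np.float64)
    n_r = float(glrlm.n_runs)
    n_p = float(glrlm.n_pixels)
    i = np.arange(1, p.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, p.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "SRE": float((p / j**2).sum() / n_r),
        "LRE": float((p * j**2).sum() / n_r),
        "GLN": float((p.sum(axis=1) ** 2).sum() / n_r),
        "RLN": float((p.sum(axis=0) ** 2).sum() / n_r),
        "RP": n_r / n_p,
        "LGRE": float((p / i**2).sum() / n_r),
        "HGRE": float((p * i**2).sum() / n_r),
        "SRLGE": float((p / (i**2 * j**2)).sum() / n_r),
        "SRHGE": float((p * i**2 / j**2).sum() / n_r),
        "LRLGE": float((p * j**2 / i**2).sum() / n_r),
        "LRHGE": float((p * i**2 * j**2).sum() / n_r),
    }


def texture_features(qroi: QuantizedROI) -> dict[str, float]:
    """All 44 texture features: 11 run-length statistics x 4 directions."""
    out: dict[str, float] = {}
    per_dir = {theta: glrlm_features(build_glrlm(qroi, theta)) for theta in DIRECTIONS}
    for stat in TEXTURE_STATS:
        for theta in DIRECTIONS:
            out[f"{stat}_{theta}"] = per_dir[theta][stat]
    return out


# ---------------------------------------------------------------------------
# wavelet subbands
# ---------------------------------------------------------------------------


def _downsample_mask(mask: np.ndarray) -> np.ndarray:
    """A subband pixel is in-ROI iff any of its 2x2 source pixels is in-ROI."""
    h, w = mask.shape
    hp, wp = h + h % 2, w + w % 2
    padded = np.zeros((hp, wp), dtype=bool)
    padded[:h, :w] = mask
    return padded.reshape(hp // 2, 2, wp // 2, 2).any(axis=(1, 3))


def wavelet_decompose(
    image: np.ndarray, roi: TumorROI | np.ndarray, wavelet: str = "haar"
) -> SubbandSet:
    """One-level 2-D DWT into LL / LH / HL / HH with downsampled ROI masks.

    Haar with periodization mode is orthonormal, so subband energies sum to
    the input energy (to float tolerance) whenever both dimensions are even;
    odd dimensions are handled by a periodic extension that duplicates one
    row/column, giving the ceil(n/2) subband shapes but not exact energy
    conservation.  Subband naming follows (row filter, column filter): LH is
    low-pass along rows, high-pass along columns.
    """
    image = np.asarray(image, dtype=np.float64)
    if min(image.shape) < 8:
        raise ValueError(f"image too small for wavelet decomposition: {image.shape}")
    mask = roi.mask if isinstance(roi, TumorROI) else np.asarray(roi, dtype=bool)
    cA, (cH, cV, cD) = pywt.dwt2(image, wavelet, mode="periodization")
    mask_ds = _downsample_mask(mask)
    subbands = {"LL": cA, "LH": cH, "HL": cV, "HH": cD}
    masks = {sb: mask_ds for sb in SUBBANDS}
    return SubbandSet(subbands=subbands, masks=masks, wavelet=wavelet)


def _rescale_255(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo) * 255.0


def wavelet_features(
    subbands: SubbandSet,
    n_gray: int = DEFAULT_N_GRAY,
    profile: str = "paper_284",
) -> dict[str, float]:
    """Density + texture features recomputed on each subband.

    Each subband is rescaled to [0, 255] (its native coefficient scale is
    arbitrary) before the 21 density and 44 texture features are recomputed
    with the downsampled ROI mask.  The full recomputation yields 65 values
    per subband (260 total, the ``full_334`` profile); ``paper_284`` keeps
    the first 210 in canonical subband order LL, LH, HL, HH.
    """
    out: dict[str, float] = {}
    for sb in SUBBANDS:
        mask = subbands.masks[sb]
        if mask.sum() < 4:
            raise ROIValidationError(f"degenerate downsampled ROI in subband {sb}")
        img = _rescale_255(subbands.subbands[sb])
        dens = density_features(img, mask, n_bins=n_gray)
        for name, val in dens.items():
            out[f"{name}_{sb}"] = val
        qroi = quantize(img, mask, n_gray)
        tex = texture_features(qroi)
        for stat in TEXTURE_STATS:
            for theta in DIRECTIONS:
                out[f"{stat}_{sb}_{theta}"] = tex[f"{stat}_{theta}"]
    names = feature_names(profile)[len(MORPHOLOGY_NAMES) + len(DENSITY_NAMES) + len(_TEXTURE_NAMES):]
    return {n: out[n] for n in names}


# ---------------------------------------------------------------------------
# full signature
# ---------------------------------------------------------------------------


def feature_vector(
    frame: np.ndarray,
    roi: TumorROI,
    *,
    sigma: float = DEFAULT_SIGMA,
    n_gray: int = DEFAULT_N_GRAY,
    pixel_spacing: float = 1.0,
    profile: str = "paper_284",
) -> FeatureVector:
    """Compute the full ordered radiomic signature of one frame + ROI.

    Pipeline: Gaussian low-pass -> morphology / density / quantize+texture /
    wavelet recomputation, concatenated in the canonical group order.
    """
    names = feature_names(profile)
    filtered = gaussian_lowpass(np.asarray(frame, dtype=np.float64), sigma)
    values: dict[str, float] = {}
    values.update(morphology_features(roi, pixel_spacing))
    values.update(density_features(filtered, roi.mask, n_bins=n_gray))
    values.update(texture_features(quantize(filtered, roi, n_gray)))
    values.update(wavelet_features(wavelet_decompose(filtered, roi), n_gray, profile))
    return FeatureVector(
        names=names,
        values=np.array([values[n] for n in names]),
        provenance={"n_gray": n_gray, "sigma": sigma, "profile": profile,
                    "pixel_spacing": pixel_spacing},
    )
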