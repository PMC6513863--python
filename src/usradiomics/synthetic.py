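"""Synthetic ultrasound-like cohorts with planted treatment effects.

The generator emulates the structure of a longitudinal mouse tumor study:
23 subjects in 7 treatment groups, each imaged pre- and post-treatment on
two days (D3 and D6) with ~200 near-identical B-mode frames per scan, plus
tumor sizes at treatment start (x1) and at the endpoint (x2).

Image model
-----------
Frames are multiplicative Rayleigh speckle on a two-level echogenicity map
(tumor brighter than background), clipped to the 8-bit range.  The tumor is
an ellipse whose boundary is perturbed by low-order Fourier modes, giving
nontrivial morphology.  Frames within a scan share one speckle realization
and differ only by i.i.d. additive Gaussian noise and an integer ROI jitter
of at most one pixel, mirroring the near-redundancy of real cine frames.

Planted effect
--------------
Each group carries a response strength in [0, 1], monotone across groups.
Treatment smooths the intra-tumoral speckle field in the post-treatment scan
by an amount proportional to response x ``texture_effect_gain`` — runs of
equal gray level lengthen, so run-length texture statistics shift (LRE up;
SRE, RP, RLN down).  The endpoint size follows
``x2 = x1 * exp(growth_rate * (1 - response) + eps)``, so the tumor-size
increase ratio TSIR = (x2 - x1)/x2 * 100 rises as response falls: responders
keep small tumors, non-responders grow.

Everything is a pure function of the seed: the same configuration and seed
reproduce the cohort bit-for-bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preproc import ScanStack, TumorROI, write_mask, write_scan

__all__ = [
    "SCAN_KEYS",
    "CohortConfig",
    "SyntheticTruth",
    "SubjectData",
    "Cohort",
    "simulate_speckle_frame",
    "simulate_subject_timeline",
    "simulate_cohort",
    "simulate_half_signal_pair",
    "write_cohort",
    "group_sizes",
    "FEATURE_EFFECT_DIRECTION",
]

#: the four scans of one subject, in canonical order
SCAN_KEYS = ("D3_pre", "D3_post", "D6_pre", "D6_post")

#: direction in which post-treatment speckle smoothing moves each run-length
#: family for a responding tumor (post - pre sign, planted ground truth)
FEATURE_EFFECT_DIRECTION = {"LRE": +1, "SRE": -1, "RP": -1, "RLN": -1}

#: Rayleigh scale giving a unit-mean speckle field
_UNIT_MEAN_RAYLEIGH = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and image-model parameters of a synthetic cohort."""

    n_subjects: int = 23
    n_groups: int = 7
    #: per-group response strength in [0, 1]; default is monotone decreasing
    #: across groups (group 1 responds best); None -> linspace(0.9, 0.1)
    group_effect: tuple[float, ...] | None = None
    frames_per_scan: int = 200
    image_size: tuple[int, int] = (128, 128)
    tumor_radius_mean: float = 22.0
    tumor_radius_jitter: float = 3.0
    #: Rayleigh scale of the multiplicative speckle field; the default gives
    #: a unit-mean field so echogenicity levels are preserved on average
    speckle_shape: float = _UNIT_MEAN_RAYLEIGH
    #: how strongly response smooths intra-tumoral speckle post-treatment
    texture_effect_gain: float = 1.0
    #: per-frame additive noise SD (8-bit intensity units)
    noise_sd_frames: float = 2.0
    #: maximum integer frame-to-frame jitter of the imaged section (pixels)
    roi_jitter_px: int = 1
    #: SD of per-subject deviation from the group response
    response_noise_sd: float = 0.05
    #: tumor size link: x1 ~ x1_mean * lognormal, x2 = x1 * exp(growth) * noise
    x1_mean: float = 50.0
    x1_log_sd: float = 0.05
    growth_rate: float = 1.5
    outcome_log_noise_sd: float = 0.15
    background_level: float = 100.0
    tumor_level: float = 140.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_subjects >= self.n_groups >= 1:
            raise ValueError("need n_subjects >= n_groups >= 1")
        if self.frames_per_scan < 1:
            raise ValueError("frames_per_scan must be >= 1")
        for name in ("texture_effect_gain", "noise_sd_frames", "speckle_shape",
                     "response_noise_sd", "outcome_log_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16x16")
        if self.group_effect is not None and len(self.group_effect) != self.n_groups:
            raise ValueError("group_effect length must equal n_groups")

    @property
    def effects(self) -> np.ndarray:
        if self.group_effect is not None:
            return np.asarray(self.group_effect, dtype=np.float64)
        if self.n_groups == 1:
            return np.array([0.5])
        return np.linspace(0.9, 0.1, self.n_groups)


@dataclass
class SyntheticTruth:
    """Planted ground truth: what the pipeline should recover."""

    response: np.ndarray  # per-subject response score in [0, 1]
    x1: np.ndarray
    x2: np.ndarray
    group: np.ndarray  # per-subject group index (0-based)
    feature_effect_direction: dict[str, int] = field(
        default_factory=lambda: dict(FEATURE_EFFECT_DIRECTION)
    )


@dataclass
class SubjectData:
    subject_id: str
    group: int
    scans: dict[str, ScanStack]
    rois: dict[str, TumorROI]
    x1: float
    x2: float


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectData]
    truth: SyntheticTruth

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.subjects],
                "group": [f"G{s.group + 1}" for s in self.subjects],
                "x1": [s.x1 for s in self.subjects],
                "x2": [s.x2 for s in self.subjects],
            }
        )


def group_sizes(n_subjects: int, n_groups: int) -> list[int]:
    """Split subjects as evenly as possible (first groups take the remainder)."""
    base, rem = divmod(n_subjects, n_groups)
    return [base + 1] * rem + [base] * (n_groups - rem)


# ---------------------------------------------------------------------------
# speckle frames
# ---------------------------------------------------------------------------


def simulate_speckle_frame(
    size: tuple[int, int],
    speckle_shape: float = _UNIT_MEAN_RAYLEIGH,
    seed: int | np.random.Generator = 0,
    mean_echogenicity: float = 100.0,
) -> np.ndarray:
    """One fully-developed-speckle frame: a constant echogenicity map under
    multiplicative Rayleigh noise, clipped to [0, 255].

    With the default (unit-mean) Rayleigh scale the expected pixel value is
    ``mean_echogenicity`` up to the small clipping bias; ``speckle_shape -> 0``
    collapses to a constant image.
    """
    if min(size) < 16:
        raise ValueError(f"frame size must be at least 16x16, got {size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field_ = rng.rayleigh(scale=speckle_shape, size=size) if speckle_shape > 0 else np.zeros(size)
    return np.clip(mean_echogenicity * field_, 0.0, 255.0)


def _perturbed_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    aspect: float,
    rotation: float,
    fourier_amp: np.ndarray,
    fourier_phase: np.ndarray,
) -> np.ndarray:
    """Ellipse with low-order Fourier boundary perturbation (star-shaped)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(rotation), np.sin(rotation)
    u = (c * dx + s * dy) / radius
    v = (-s * dx + c * dy) / (radius * aspect)
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    bound = 1.0
    for k, (a, ph) in enumerate(zip(fourier_amp, fourier_phase), start=2):
        bound = bound + a * np.cos(k * theta + ph)
    return rho <= bound


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------


def _render_scan(
    config: CohortConfig,
    echo_map: np.ndarray,
    speckle: np.ndarray,
    mask: np.ndarray,
    smooth_weight: float,
    rng: np.random.Generator,
) -> ScanStack:
    """Render one multi-frame scan from a speckle field and echo map.

    ``smooth_weight`` in [0, 1] blends the intra-tumoral speckle toward its
    Gaussian-smoothed version (the planted treatment effect).
    """
    field_ = speckle
    if smooth_weight > 0:
        smoothed = ndimage.gaussian_filter(speckle, sigma=1.5, mode="reflect")
        field_ = np.where(mask, (1 - smooth_weight) * speckle + smooth_weight * smoothed, speckle)
    base = np.clip(echo_map * field_, 0.0, 255.0)
    frames = np.empty((config.frames_per_scan, *base.shape))
    for k in range(config.frames_per_scan):
        img = base
        if config.roi_jitter_px > 0:
            jit = rng.integers(-config.roi_jitter_px, config.roi_jitter_px + 1, size=2)
            img = np.roll(img, tuple(jit), axis=(0, 1))
        if config.noise_sd_frames > 0:
            img = img + rng.normal(0.0, config.noise_sd_frames, size=img.shape)
        frames[k] = np.clip(np.rint(img), 0, 255)
    return ScanStack(frames, base_frame_index=0)


def _simulate_truth(config: CohortConfig) -> SyntheticTruth:
    rng = np.random.default_rng([config.seed, 999_983])
    sizes = group_sizes(config.n_subjects, config.n_groups)
    group = np.repeat(np.arange(config.n_groups), sizes)
    effects = config.effects
    response = np.clip(
        effects[group] + rng.normal(0.0, config.response_noise_sd, size=config.n_subjects),
        0.0,
        1.0,
    )
    x1 = config.x1_mean * np.exp(rng.normal(0.0, config.x1_log_sd, size=config.n_subjects))
    growth = config.growth_rate * (1.0 - response) + rng.normal(
        0.0, config.outcome_log_noise_sd, size=config.n_subjects
    )
    x2 = x1 * np.exp(growth)
    return SyntheticTruth(response=response, x1=x1, x2=x2, group=group)


def simulate_subject_timeline(
    config: CohortConfig, subject_index: int, truth: SyntheticTruth
) -> SubjectData:
    """Four scans (D3/D6 x pre/post) plus ROIs and tumor sizes for one subject.

    Pre and post scans of one day share the same tumor geometry and speckle
    realization; the post scan applies the response-proportional smoothing,
    so with ``texture_effect_gain = 0`` the pre/post texture is identical up
    to frame noise.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    rng = np.random.default_rng([config.seed, subject_index])
    shape = config.image_size
    response = float(truth.response[subject_index])
    smooth_w = float(np.clip(config.texture_effect_gain * response, 0.0, 1.0))

    center = (
        shape[0] / 2.0 + rng.uniform(-4, 4),
        shape[1] / 2.0 + rng.uniform(-4, 4),
    )
    radius_d3 = max(8.0, rng.normal(config.tumor_radius_mean, config.tumor_radius_jitter))
    aspect = rng.uniform(0.7, 1.0)
    rotation = rng.uniform(0, np.pi)
    amp = rng.uniform(0.0, 0.06, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)

    scans: dict[str, ScanStack] = {}
    rois: dict[str, TumorROI] = {}
    for day, radius in (("D3", radius_d3), ("D6", radius_d3 * 1.15)):
        mask = _perturbed_ellipse_mask(shape, center, radius, aspect, rotation, amp, phase)
        roi = TumorROI(mask)
        echo = np.where(mask, config.tumor_level, config.background_level)
        speckle = (
            rng.rayleigh(scale=config.speckle_shape, size=shape)
            if config.speckle_shape > 0
            else np.ones(shape)
        )
        scans[f"{day}_pre"] = _render_scan(config, echo, speckle, mask, 0.0, rng)
        scans[f"{day}_post"] = _render_scan(config, echo, speckle, mask, smooth_w, rng)
        rois[f"{day}_pre"] = roi
        rois[f"{day}_post"] = roi

    return SubjectData(
        subject_id=f"S{subject_index + 1:02d}",
        group=int(truth.group[subject_index]),
        scans=scans,
        rois=rois,
        x1=float(truth.x1[subject_index]),
        x2=float(truth.x2[subject_index]),
    )


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort bundle (all scans, masks, sizes, groups, truth)."""
    truth = _simulate_truth(config)
    subjects = [
        simulate_subject_timeline(config, i, truth) for i in range(config.n_subjects)
    ]
    return Cohort(config=config, subjects=subjects, truth=truth)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> str:
    """Write a cohort as a directory tree.

    Per subject and scan: a multi-page 8-bit TIFF of frames and a PNG mask;
    plus ``manifest.csv`` (subject, group, x1, x2, per-scan paths) and
    ``truth.csv`` (planted response).  Returns the manifest path.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        sdir = os.path.join(out_dir, subj.subject_id)
        os.makedirs(sdir, exist_ok=True)
        row: dict[str, object] = {
            "subject": subj.subject_id,
            "group": f"G{subj.group + 1}",
            "x1": subj.x1,
            "x2": subj.x2,
        }
        for key in SCAN_KEYS:
            scan_path = os.path.join(sdir, f"{key}.tif")
            mask_path = os.path.join(sdir, f"mask_{key.split('_')[0]}.png")
            write_scan(scan_path, subj.scans[key])
            if not os.path.exists(mask_path):
                write_mask(mask_path, subj.rois[key])
            row[f"scan_{key}"] = os.path.relpath(scan_path, out_dir)
            row[f"mask_{key}"] = os.path.relpath(mask_path, out_dir)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    truth = cohort.truth
    pd.DataFrame(
        {
            "subject": [s.subject_id for s in cohort.subjects],
            "group": [f"G{g + 1}" for g in truth.group],
            "response": truth.response,
            "x1": truth.x1,
            "x2": truth.x2,
        }
    ).to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return manifest_path


def load_cohort(manifest_path: str | os.PathLike) -> list[dict]:
    """Read a written cohort back as a list of per-subject records with
    ScanStacks and TumorROIs (paths resolved relative to the manifest)."""
    from .io_preproc import read_roi, read_scan

    manifest_path = os.fspath(manifest_path)
    root = os.path.dirname(manifest_path)
    manifest = pd.read_csv(manifest_path)
    records = []
    for _, row in manifest.iterrows():
        rec: dict[str, object] = {
            "subject": row["subject"],
            "group": row["group"],
            "x1": float(row["x1"]),
            "x2": float(row["x2"]),
            "scans": {},
            "rois": {},
        }
        for key in SCAN_KEYS:
            scan = read_scan(os.path.join(root, row[f"scan_{key}"]))
            roi = read_roi(os.path.join(root, row[f"mask_{key}"]), scan.frame_shape)
            rec["scans"][key] = scan
            rec["rois"][key] = roi
        records.append(rec)
    return records


def replace_config(config: CohortConfig, **kwargs) -> CohortConfig:
    """Return a copy of the config with fields replaced (dataclasses.replace)."""
    return replace(config, **kwargs)


def simulate_half_signal_pair(
    n_subjects: int = 23,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outcome plus two planted half-signal features for fusion experiments.

    Draws a cohort outcome from the standard size link, normalizes its TSIR
    to [0, 1], and returns two features that each carry half the outcome
    signal plus independent Gaussian noise:

        F_i = y / 2 + eps_i,   eps_i ~ N(0, noise_sd), independent.

    The default noise level makes each single feature's correlation with the
    outcome land in the strong-but-imperfect range, so the equal-weight
    fusion (which halves the noise variance) typically beats both singles —
    the setting the fusion-gain experiments probe.

    Returns ``(y, f1, f2)``.
    """
    cfg = CohortConfig(n_subjects=n_subjects, n_groups=min(7, n_subjects), seed=seed)
    truth = _simulate_truth(cfg)
    tsir = (truth.x2 - truth.x1) / truth.x2 * 100.0
    y = (tsir - tsir.min()) / (tsir.max() - tsir.min())
    rng = np.random.default_rng([seed, 424_243])
    f1 = y / 2.0 + rng.normal(0.0, noise_sd, size=n_subjects)
    f2 = y / 2.0 + rng.normal(0.0, noise_sd, size=n_subjects)
    return y, f1, f2
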