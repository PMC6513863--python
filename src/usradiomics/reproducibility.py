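"""Feature reproducibility across the frames of one ultrasound scan.

A scan is a stack of near-identical frames; the operator designates one
*base frame*.  The full feature signature is recomputed on every frame with
the same tumor mask, and agreement between the base frame and each other
frame is summarized as a mean correlation coefficient with its SD and a 95%
normal-approximation confidence interval (mean +/- 1.96 * SD / sqrt(m) over
the m base-vs-other comparisons).

Two defensible readings of "per-feature correlation across frames" exist,
and both are provided:

* ``vector`` mode (default, single scan): for each frame k, the Pearson r
  between the base frame's full feature vector and frame k's vector, plus a
  per-feature leave-one-feature-out contribution to the mean r (how much the
  overall agreement drops when that feature is removed).  Pearson r is
  invariant to any affine rescaling of the vectors, so no normalization is
  needed before comparing.
* ``cohort`` mode (requires several subjects' scans): for each feature, the
  Pearson r *across subjects* between base-frame values and frame-k values,
  averaged over k — a true per-feature reproducibility coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureVector, feature_vector
from .io_preproc import ScanStack, TumorROI
from .markers import pearson_r

__all__ = [
    "ReproducibilityReport",
    "frame_feature_series",
    "reproducibility_stats",
]


@dataclass
class ReproducibilityReport:
    """Frame-agreement summary for one scan (or one cohort of scans)."""

    mode: str
    n_frames: int
    mean_r: float
    sd: float
    ci_low: float
    ci_high: float
    per_feature: pd.DataFrame  # vector: loo_contribution; cohort: mean_r/sd/ci

    def __post_init__(self) -> None:
        if not -1.0 <= self.mean_r <= 1.0:
            raise ValueError("mean correlation outside [-1, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("confidence bounds out of order")


def frame_feature_series(
    scan: ScanStack,
    roi: TumorROI,
    **feature_kwargs,
) -> pd.DataFrame:
    """Recompute the full feature vector on every frame of a scan.

    Returns a features x frames DataFrame (columns are frame indices); the
    base frame index is recorded in ``df.attrs['base_frame_index']``.  The
    same ROI mask is applied to every frame (the tumor is segmented once per
    scan).
    """
    if scan.n_frames < 2:
        raise ValueError("reproducibility analysis needs at least 2 frames")
    vectors: list[FeatureVector] = [
        feature_vector(scan.frames[k], roi, **feature_kwargs)
        for k in range(scan.n_frames)
    ]
    df = pd.DataFrame(
        {k: vec.values for k, vec in enumerate(vectors)},
        index=list(vectors[0].names),
    )
    df.attrs["base_frame_index"] = scan.base_frame_index
    return df


def _ci(mean: float, sd: float, m: int) -> tuple[float, float]:
    half = 1.96 * sd / np.sqrt(m)
    return mean - half, mean + half


def _vector_mode(series: pd.DataFrame, base: int) -> ReproducibilityReport:
    frames = [c for c in series.columns if c != base]
    b = series[base].to_numpy(dtype=np.float64)
    d = b.size

    # running raw moments let the leave-one-feature-out r come out in O(1)
    rs = np.empty(len(frames))
    loo = np.zeros((d, len(frames)))
    for col, k in enumerate(frames):
        v = series[k].to_numpy(dtype=np.float64)
        sx, sy = b.sum(), v.sum()
        sxx, syy, sxy = (b * b).sum(), (v * v).sum(), (b * v).sum()
        rs[col] = pearson_r(b, v)
        n1 = d - 1
        vx = n1 * (sxx - b * b) - (sx - b) ** 2
        vy = n1 * (syy - v * v) - (sy - v) ** 2
        num = n1 * (sxy - b * v) - (sx - b) * (sy - v)
        with np.errstate(invalid="ignore", divide="ignore"):
            loo[:, col] = num / np.sqrt(vx * vy)

    mean_r = float(rs.mean())
    sd = float(rs.std())
    ci_low, ci_high = _ci(mean_r, sd, len(frames))
    with np.errstate(invalid="ignore"):
        loo_mean = np.nanmean(loo, axis=1)
    per_feature = pd.DataFrame(
        {"loo_contribution": mean_r - loo_mean}, index=series.index
    )
    return ReproducibilityReport(
        mode="vector",
        n_frames=series.shape[1],
        mean_r=mean_r,
        sd=sd,
        ci_low=min(ci_low, 1.0) if sd == 0 else ci_low,
        ci_high=ci_high,
        per_feature=per_feature,
    )


def _cohort_mode(
    series_list: list[pd.DataFrame], bases: list[int]
) -> ReproducibilityReport:
    if len(series_list) < 3:
        raise ValueError("cohort mode needs at least 3 subjects' scans")
    n_frames = min(s.shape[1] for s in series_list)
    feats = series_list[0].index
    base_vals = np.stack(
        [s[b].to_numpy() for s, b in zip(series_list, bases)]
    )  # subjects x features
    rows = []
    for fi, name in enumerate(feats):
        rs = []
        for k in range(n_frames):
            if k in bases:  # comparing a base frame with itself is trivial
                continue
            x = base_vals[:, fi]
            y = np.array([s[k].to_numpy()[fi] for s in series_list])
            if x.min() == x.max() or y.min() == y.max():
                continue
            rs.append(pearson_r(x, y))
        if rs:
            m = float(np.mean(rs))
            s_ = float(np.std(rs))
            lo, hi = _ci(m, s_, len(rs))
            rows.append((name, m, s_, lo, hi))
    if not rows:
        raise ValueError("no feature admits a cross-subject correlation")
    per_feature = pd.DataFrame(
        rows, columns=["feature", "mean_r", "sd", "ci_low", "ci_high"]
    ).set_index("feature")
    mean_r = float(per_feature["mean_r"].mean())
    sd = float(per_feature["mean_r"].std(ddof=0))
    lo, hi = _ci(mean_r, sd, len(per_feature))
    return ReproducibilityReport(
        mode="cohort",
        n_frames=n_frames,
        mean_r=mean_r,
        sd=sd,
        ci_low=lo,
        ci_high=hi,
        per_feature=per_feature,
    )


def reproducibility_stats(
    series: pd.DataFrame | list[pd.DataFrame],
    mode: str = "vector",
    base_index: int | list[int] | None = None,
) -> ReproducibilityReport:
    """Summarize base-frame vs other-frame feature agreement.

    ``series`` is one features x frames DataFrame (``vector`` mode) or a list
    of them, one per subject (``cohort`` mode).  ``base_index`` defaults to
    the value recorded by :func:`frame_feature_series`.
    """
    if mode == "vector":
        if not isinstance(series, pd.DataFrame):
            raise ValueError("vector mode expects a single features x frames frame")
        if series.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        base = series.attrs.get("base_frame_index", 0) if base_index is None else base_index
        return _vector_mode(series, base)
    if mode == "cohort":
        if isinstance(series, pd.DataFrame):
            raise ValueError("cohort mode expects a list of per-subject series")
        bases = (
            [s.attrs.get("base_frame_index", 0) for s in series]
            if base_index is None
            else list(base_index)
        )
        return _cohort_mode(series, bases)
    raise ValueError("mode must be 'vector' or 'cohort'")
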