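"""Longitudinal feature pools and the tumor-size-increase-ratio outcome.

Four pools are assembled per cohort: the pre-treatment signature on each of
day 3 and day 6 (``prior_D3``, ``prior_D6``) and the post-minus-pre
difference on each day (``diff_D3``, ``diff_D6``).  Differences are taken on
raw feature values; each pool is then min-max normalized per feature across
subjects so that every entry lies in [0, 1] (a constant column maps to all
zeros, with a warning).  Note Pearson correlation is invariant to this
scaling — normalization matters only for the fused marker's value range.

The treatment-efficacy ground truth is the tumor size increase ratio

    TSIR = (x2 - x1) / x2 * 100

with x1 the size at treatment start (day 3) and x2 the endpoint size
(day 10).  The denominator is the *endpoint* size: growth asymptotes at
+100% while shrinkage is unboundedly negative.  TSIR is normalized to [0, 1]
across the cohort before correlation analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "POOL_KINDS",
    "FeaturePool",
    "OutcomeTable",
    "compute_tsir",
    "minmax_normalize",
    "build_pools",
]

POOL_KINDS = ("prior_D3", "diff_D3", "prior_D6", "diff_D6")


@dataclass
class FeaturePool:
    """Subjects x features matrix for one pool kind, min-max normalized.

    ``norm_min`` / ``norm_max`` record the per-feature pre-normalization
    range so raw values can be recovered.
    """

    kind: str
    data: pd.DataFrame
    norm_min: pd.Series = field(repr=False, default=None)
    norm_max: pd.Series = field(repr=False, default=None)


@dataclass
class OutcomeTable:
    """Per-subject outcome: sizes, TSIR (percent), normalized TSIR, group."""

    table: pd.DataFrame  # columns: x1, x2, TSIR, TSIR_norm, group

    @property
    def tsir_norm(self) -> pd.Series:
        return self.table["TSIR_norm"]


def compute_tsir(x1: float | np.ndarray, x2: float | np.ndarray) -> float | np.ndarray:
    """Tumor size increase ratio in percent: (x2 - x1) / x2 * 100."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if np.any(x2 <= 0):
        raise ValueError("endpoint tumor size x2 must be positive")
    if np.any(x1 <= 0):
        raise ValueError("starting tumor size x1 must be positive")
    out = (x2 - x1) / x2 * 100.0
    return float(out) if out.ndim == 0 else out


def minmax_normalize(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Map values onto [0, 1] by (v - min) / (max - min).

    A constant vector maps to all zeros and emits a warning (it carries no
    cross-subject information).
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn("constant vector normalized to all zeros", stacklevel=2)
        out = np.zeros_like(arr)
    else:
        out = (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def _normalize_pool(kind: str, raw: pd.DataFrame) -> FeaturePool:
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    span = hi - lo
    const = span == 0
    n_const = int(const.sum())
    if n_const:
        log.warning("pool %s: %d constant feature column(s) mapped to 0", kind, n_const)
    safe_span = span.replace(0, 1.0)
    data = (raw - lo) / safe_span
    data.loc[:, const] = 0.0
    return FeaturePool(kind=kind, data=data, norm_min=lo, norm_max=hi)


def build_pools(
    features: dict[str, dict[str, pd.Series]],
    sizes: dict[str, tuple[float, float]],
    groups: dict[str, str] | None = None,
) -> tuple[dict[str, FeaturePool], OutcomeTable]:
    """Assemble the four normalized pools and the outcome table.

    Parameters
    ----------
    features
        ``{subject: {scan_key: feature Series}}`` with scan keys
        ``D3_pre, D3_post, D6_pre, D6_post``.  Subjects missing any of the
        four scans are excluded with a logged reason.
    sizes
        ``{subject: (x1, x2)}`` tumor sizes at treatment start and endpoint.
    groups
        optional ``{subject: label}``.
    """
    required = ("D3_pre", "D3_post", "D6_pre", "D6_post")
    kept = []
    for subj in features:
        missing = [k for k in required if k not in features[subj]]
        if missing or subj not in sizes:
            log.warning("subject %s excluded: missing %s", subj,
                        missing or "tumor sizes")
            continue
        kept.append(subj)
    if len(kept) < 2:
        raise ValueError("need at least 2 complete subjects to build pools")

    def frame(key: str) -> pd.DataFrame:
        return pd.DataFrame({s: features[s][key] for s in kept}).T

    raw = {
        "prior_D3": frame("D3_pre"),
        "diff_D3": frame("D3_post") - frame("D3_pre"),
        "prior_D6": frame("D6_pre"),
        "diff_D6": frame("D6_post") - frame("D6_pre"),
    }
    pools = {kind: _normalize_pool(kind, raw[kind]) for kind in POOL_KINDS}

    x1 = np.array([sizes[s][0] for s in kept])
    x2 = np.array([sizes[s][1] for s in kept])
    tsir = compute_tsir(x1, x2)
    table = pd.DataFrame(
        {
            "x1": x1,
            "x2": x2,
            "TSIR": tsir,
            "TSIR_norm": minmax_normalize(tsir),
            "group": [groups.get(s, "") if groups else "" for s in kept],
        },
        index=kept,
    )
    return pools, OutcomeTable(table)
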