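"""Correlation-based marker selection and equal-weight feature fusion.

Workflow per feature pool: rank features by Pearson correlation with the
normalized tumor-size-increase ratio, keep the top k (default 5), compute
the k x k inter-feature correlation matrix, pick the least-correlated pair
among the top k (redundancy reduction), and fuse it with an equal-weight
mean, F_new = (F1 + F2) / 2.  P-values comparing each feature's correlation
with the top feature's use the Hotelling–Williams test for two dependent
correlations sharing one variable (the outcome), with n - 3 degrees of
freedom.

Correlation strengths are labeled with the conventional interpretation
bands: |r| >= 0.70 very strong, 0.40–0.69 strong, 0.30–0.39 moderate,
0.20–0.29 weak, 0.01–0.19 negligible, 0 none (sign-aware; magnitudes are
rounded to two decimals before lookup, and band edges are inclusive at the
lower magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .pools import FeaturePool, OutcomeTable

__all__ = [
    "MarkerReport",
    "PoolMarkerResult",
    "pearson_r",
    "rank_top_k",
    "dependent_corr_pvalue",
    "select_fusion_pair",
    "fuse_equal_weight",
    "interpret_r",
    "analyze_pool",
    "group_distribution",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation via the raw-moment form

        r = [n*sum(xy) - sum(x)*sum(y)] /
            sqrt([n*sum(x^2) - sum(x)^2] * [n*sum(y^2) - sum(y)^2])

    Requires n >= 3 and both vectors non-constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((n * sxy - sx * sy) / np.sqrt(vx * vy))


def rank_top_k(
    pool: FeaturePool | pd.DataFrame,
    outcome: OutcomeTable | pd.Series | np.ndarray,
    k: int = 5,
    mode: str = "signed",
) -> pd.DataFrame:
    """Rank features by correlation with the outcome and keep the top ``k``.

    ``mode='signed'`` ranks by r descending (positive correlates first, the
    published behavior); ``mode='abs'`` ranks by |r| descending.  Constant
    feature columns are skipped (their correlation is undefined).  Ties are
    broken by canonical feature order.  Returns a DataFrame with columns
    ``feature`` and ``r`` ordered best-first.
    """
    if mode not in ("signed", "abs"):
        raise ValueError("mode must be 'signed' or 'abs'")
    data = pool.data if isinstance(pool, FeaturePool) else pool
    y = np.asarray(outcome.tsir_norm if isinstance(outcome, OutcomeTable) else outcome,
                   dtype=np.float64)
    if len(data) != y.size:
        raise ValueError("pool and outcome are not aligned")
    rows = []
    for idx, name in enumerate(data.columns):
        col = data[name].to_numpy()
        if col.min() == col.max():
            continue
        rows.append((name, pearson_r(col, y), idx))
    if not rows:
        raise ValueError("no non-constant features to rank")
    key = (lambda t: (-abs(t[1]), t[2])) if mode == "abs" else (lambda t: (-t[1], t[2]))
    rows.sort(key=key)
    top = rows[: min(k, len(rows))]
    return pd.DataFrame({"feature": [t[0] for t in top], "r": [t[1] for t in top]})


def dependent_corr_pvalue(r1j: float, r1k: float, rjk: float, n: int) -> float:
    """Two-sided p-value for H0: rho(y, xj) = rho(y, xk) on the same sample.

    Hotelling–Williams t-test for two dependent correlations with one
    overlapping variable; t has n - 3 degrees of freedom:

        t = (r1j - r1k) * sqrt( (n-1)(1+rjk) /
              ( 2 * (n-1)/(n-3) * |R| + rbar^2 * (1-rjk)^3 ) )

    with |R| = 1 - r1j^2 - r1k^2 - rjk^2 + 2*r1j*r1k*rjk and
    rbar = (r1j + r1k)/2.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    for name, r in (("r1j", r1j), ("r1k", r1k), ("rjk", rjk)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    if r1j == r1k:
        return 1.0
    det = 1.0 - r1j**2 - r1k**2 - rjk**2 + 2.0 * r1j * r1k * rjk
    rbar = 0.5 * (r1j + r1k)
    denom = 2.0 * (n - 1) / (n - 3) * det + rbar**2 * (1.0 - rjk) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation configuration")
    t = (r1j - r1k) * np.sqrt((n - 1) * (1.0 + rjk) / denom)
    return float(2.0 * stats.t.sf(abs(t), df=n - 3))


def select_fusion_pair(
    top_features: list[str] | pd.DataFrame, pool: FeaturePool | pd.DataFrame
) -> tuple[str, str, float]:
    """Pick the least-redundant pair among the top features.

    Returns the pair (F1, F2) minimizing the absolute pairwise correlation
    over all C(k, 2) candidates, plus that correlation; ties go to the
    lexicographically earliest pair in ranked order.
    """
    if isinstance(top_features, pd.DataFrame):
        top_features = list(top_features["feature"])
    if len(top_features) < 2:
        raise ValueError("need at least 2 features to select a pair")
    data = pool.data if isinstance(pool, FeaturePool) else pool
    best: tuple[str, str, float] | None = None
    for fa, fb in combinations(top_features, 2):
        r = pearson_r(data[fa].to_numpy(), data[fb].to_numpy())
        if best is None or abs(r) < abs(best[2]):
            best = (fa, fb, r)
    return best


def fuse_equal_weight(
    f1_values: np.ndarray | pd.Series, f2_values: np.ndarray | pd.Series
) -> np.ndarray | pd.Series:
    """Equal-weight fusion marker: F_new = (F1 + F2) / 2."""
    a = np.asarray(f1_values, dtype=np.float64)
    b = np.asarray(f2_values, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("fusion inputs must have equal length")
    fused = (a + b) / 2.0
    if isinstance(f1_values, pd.Series):
        return pd.Series(fused, index=f1_values.index, name="F_new")
    return fused


_BANDS = (
    (0.70, "very strong"),
    (0.40, "strong"),
    (0.30, "moderate"),
    (0.20, "weak"),
    (0.01, "negligible"),
)


def interpret_r(r: float) -> str:
    """Conventional strength label for a correlation coefficient."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    mag = round(abs(r), 2)
    if mag == 0.0:
        return "no relationship"
    sign = "positive" if r > 0 else "negative"
    for lo, label in _BANDS:
        if mag >= lo:
            return f"{label} {sign}"
    return "no relationship"


# ---------------------------------------------------------------------------
# per-pool analysis
# ---------------------------------------------------------------------------


@dataclass
class PoolMarkerResult:
    """Selection + fusion outcome for one feature pool."""

    kind: str
    top: pd.DataFrame  # feature, r, p_vs_top, interpretation
    corr_matrix: pd.DataFrame  # k x k inter-feature correlations
    pair: tuple[str, str]
    pair_r: float
    fused: pd.Series
    fused_r: float
    fused_p_vs_top: float


@dataclass
class MarkerReport:
    """Marker analysis over all pools of one cohort."""

    pools: dict[str, PoolMarkerResult]
    n: int


def analyze_pool(
    pool: FeaturePool,
    outcome: OutcomeTable,
    k: int = 5,
    mode: str = "signed",
) -> PoolMarkerResult:
    """Full marker analysis of one pool: rank, compare, select, fuse."""
    y = outcome.tsir_norm.to_numpy()
    n = y.size
    top = rank_top_k(pool, outcome, k=k, mode=mode)
    names = list(top["feature"])
    data = pool.data[names]

    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for fa, fb in combinations(names, 2):
        r = pearson_r(data[fa].to_numpy(), data[fb].to_numpy())
        corr.loc[fa, fb] = corr.loc[fb, fa] = r

    r_top = float(top["r"].iloc[0])
    p_vs_top = [np.nan]
    for i in range(1, len(names)):
        p_vs_top.append(
            dependent_corr_pvalue(
                r_top, float(top["r"].iloc[i]), float(corr.iloc[0, i]), n
            )
        )
    top = top.assign(
        p_vs_top=p_vs_top, interpretation=[interpret_r(r) for r in top["r"]]
    )

    f1, f2, pair_r = select_fusion_pair(names, pool)
    fused = fuse_equal_weight(pool.data[f1], pool.data[f2])
    fused_r = pearson_r(fused.to_numpy(), y)
    r_fused_top = pearson_r(fused.to_numpy(), pool.data[names[0]].to_numpy())
    fused_p = (
        1.0
        if fused_r == r_top
        else dependent_corr_pvalue(fused_r, r_top, r_fused_top, n)
    )
    return PoolMarkerResult(
        kind=pool.kind,
        top=top,
        corr_matrix=corr,
        pair=(f1, f2),
        pair_r=pair_r,
        fused=fused,
        fused_r=fused_r,
        fused_p_vs_top=fused_p,
    )


def group_distribution(
    pool: FeaturePool, feature: str, groups: pd.Series
) -> pd.DataFrame:
    """Long-format per-group values of one feature (boxplot-ready)."""
    vals = pool.data[feature]
    return pd.DataFrame(
        {"subject": vals.index, "group": groups.loc[vals.index].to_numpy(),
         "value": vals.to_numpy()}
    ).sort_values(["group", "subject"], ignore_index=True)
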