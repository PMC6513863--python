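"""Independent brute-force oracles used to validate the feature bank.

Everything here is deliberately written as naive enumeration, separate from
the package's vectorized implementations.
"""

import numpy as np

_DIR_STEPS = {0: (0, 1), 45: (-1, 1), 90: (1, 0), 135: (-1, -1)}


def brute_force_glrlm(levels: np.ndarray, theta: int, n_gray: int) -> np.ndarray:
    """Enumerate maximal runs pixel-by-pixel along one direction.

    A run of level ``lev`` starts at (r, c) when the predecessor pixel along
    the direction is absent or different; its length is counted by walking
    forward.  Level 0 (outside the ROI) never contributes.
    """
    dr, dc = _DIR_STEPS[theta]
    h, w = levels.shape
    p = np.zeros((n_gray, max(h, w)), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            lev = levels[r, c]
            if lev == 0:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w and levels[pr, pc] == lev:
                continue  # not the start of a maximal run
            length = 0
            rr, cc = r, c
            while 0 <= rr < h and 0 <= cc < w and levels[rr, cc] == lev:
                length += 1
                rr += dr
                cc += dc
            p[lev - 1, length - 1] += 1
    return p


def brute_force_glrlm_stats(p: np.ndarray, n_pixels: int) -> dict[str, float]:
    """The 11 run-length statistics computed by explicit double loops."""
    n_r = p.sum()
    acc = {k: 0.0 for k in
           ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE")}
    for i0 in range(p.shape[0]):
        for j0 in range(p.shape[1]):
            cnt = p[i0, j0]
            if cnt == 0:
                continue
            i, j = i0 + 1, j0 + 1
            acc["SRE"] += cnt / j**2
            acc["LRE"] += cnt * j**2
            acc["LGRE"] += cnt / i**2
            acc["HGRE"] += cnt * i**2
            acc["SRLGE"] += cnt / (i**2 * j**2)
            acc["SRHGE"] += cnt * i**2 / j**2
            acc["LRLGE"] += cnt * j**2 / i**2
            acc["LRHGE"] += cnt * i**2 * j**2
    out = {k: v / n_r for k, v in acc.items()}
    out["GLN"] = sum(p[i0, :].sum() ** 2 for i0 in range(p.shape[0])) / n_r
    out["RLN"] = sum(p[:, j0].sum() ** 2 for j0 in range(p.shape[1])) / n_r
    out["RP"] = n_r / n_pixels
    return out


def pearson_mean_centered(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook mean-centered covariance form of Pearson r."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
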