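"""Independent brute-force oracles used by the test suite.

Each function re-derives an estimator or rule from first principles with a
different implementation route than the package (explicit summation loops,
exhaustive enumeration, dense scans) so agreement is evidence, not
tautology.
"""

import numpy as np

Z95 = 1.959964
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def ivw_oracle(bx, by, sy):
    """Weighted regression through the origin by explicit sums."""
    w = 1.0 / np.asarray(sy) ** 2
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se_fixed = np.sum(w * bx**2) ** -0.5
    q_resid = np.sum(w * (by - beta * bx) ** 2)
    scale = np.sqrt(q_resid / (len(bx) - 1))
    return beta, se_fixed, se_fixed * max(1.0, scale)


def egger_oracle(bx, by, sy):
    """Weighted regression with intercept via explicit 2x2 normal equations.

    Applies the bx >= 0 re-orientation first, mirroring the convention.
    Returns (intercept, slope, se_intercept, se_slope) with the residual
    scale floored at 1 and J-2 denominator df.
    """
    bx, by, sy = (np.asarray(a, float) for a in (bx, by, sy))
    s = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * s, by * s
    w = 1.0 / sy**2
    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx**2), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    alpha = (swxx * swy - swx * swxy) / det
    beta = (sw * swxy - swx * swy) / det
    resid = by - alpha - beta * bx
    scale = np.sqrt(np.sum(w * resid**2) / (len(bx) - 2))
    infl = max(1.0, scale)
    se_a = np.sqrt(swxx / det) * infl
    se_b = np.sqrt(sw / det) * infl
    return alpha, beta, se_a, se_b


def weighted_median_oracle(theta, w):
    """Interpolated weighted median by an explicit scan (w need not sum 1)."""
    w = np.asarray(w, float) / np.sum(w)
    order = np.argsort(theta, kind="mergesort")
    th = np.asarray(theta, float)[order]
    ws = w[order]
    p = np.cumsum(ws) - ws / 2.0
    if 0.5 <= p[0]:
        return th[0]
    if 0.5 >= p[-1]:
        return th[-1]
    k = int(np.searchsorted(p, 0.5))
    f = (0.5 - p[k - 1]) / (p[k] - p[k - 1])
    return th[k - 1] + f * (th[k] - th[k - 1])


def mode_oracle(theta, w, phi=1.0, grid_points=512):
    """Dense-scan density maximisation over the standard grid definition."""
    theta = np.asarray(theta, float)
    w = np.asarray(w, float) / np.sum(w)
    j = len(theta)
    s = np.std(theta, ddof=1)
    mad = np.median(np.abs(theta - np.median(theta))) / 0.6745
    h = phi * 0.9 * min(s, mad) * j ** (-0.2)
    if h <= 0:
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_points)
    best_x, best_d = grid[0], -np.inf
    for x in grid:
        d = float(np.sum(w * np.exp(-0.5 * ((x - theta) / h) ** 2)))
        if d > best_d:
            best_x, best_d = x, d
    return float(best_x)


def cochran_q_oracle(bx, by, sy):
    theta = np.asarray(by, float) / np.asarray(bx, float)
    v = (np.asarray(sy, float) / np.asarray(bx, float)) ** 2
    mu = np.sum(theta / v) / np.sum(1.0 / v)
    return float(np.sum((theta - mu) ** 2 / v))


def clump_oracle(records, ld_lookup, r2_max, window_bp):
    """Exhaustive greedy clumping over (variant_id, chr, pos, pval) tuples.

    ``ld_lookup(a, b)`` returns pairwise r². Independent loop-based
    re-implementation of the greedy rule.
    """
    remaining = sorted(records, key=lambda r: (r[3], r[1], r[2], r[0]))
    kept = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top[0])
        survivors = []
        for r in remaining:
            same_chr = r[1] == top[1]
            near = abs(r[2] - top[2]) <= window_bp
            if same_chr and near and ld_lookup(top[0], r[0]) >= r2_max:
                continue
            survivors.append(r)
        remaining = survivors
    return set(kept)


def harmonize_oracle(e_ea, e_oa, o_ea, o_oa, by, eafx, eafy,
                     palindrome_handling="resolve_by_eaf", band=0.08,
                     allow_strand_flip=True):
    """Enumerated rule table for one exposure/outcome allele configuration.

    Returns (action, harmonized_by). Written as flat case enumeration over
    the allele configurations, independently of the package's branching.
    """
    pal = _COMP[e_ea] == e_oa
    if pal:
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return "dropped_mismatch", None
        if palindrome_handling == "drop_all":
            return "dropped_palindromic", None
        if (o_ea, o_oa) == (e_oa, e_ea):
            by, eafy = -by, 1 - eafy
        if np.isnan(eafx) or np.isnan(eafy):
            return "dropped_palindromic", None
        if abs(eafx - 0.5) <= band and abs(eafy - 0.5) <= band:
            return "dropped_palindromic", None
        flipped = (o_ea, o_oa) == (e_oa, e_ea)
        if (eafx < 0.5) != (eafy < 0.5):
            by = -by
            flipped = not flipped
        return ("kept_flipped" if flipped else "kept_same"), by
    if (o_ea, o_oa) == (e_ea, e_oa):
        return "kept_same", by
    if (o_ea, o_oa) == (e_oa, e_ea):
        return "kept_flipped", -by
    if allow_strand_flip:
        if (_COMP[o_ea], _COMP[o_oa]) == (e_ea, e_oa):
            return "kept_strand_flipped", by
        if (_COMP[o_oa], _COMP[o_ea]) == (e_ea, e_oa):
            return "kept_strand_flipped", -by
    return "dropped_mismatch", None
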