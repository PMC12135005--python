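"""Independent brute-force oracles used by the test suite.

These re-derive the quantities the package computes, by exhaustive scanning
or numeric optimization, sharing no code with the implementation paths they
check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def scan_side(H, a, b, f, step):
    """First index in direction ``step`` from f where rows a and b differ."""
    j = f + step
    while 0 <= j < H.shape[1]:
        if H[a, j] != H[b, j]:
            return j
        j += step
    return -1


def tract_lengths(positions, L, f, lj, rj):
    lp = positions[f] - 1 if lj < 0 else positions[f] - positions[lj]
    rp = L - positions[f] if rj < 0 else positions[rj] - positions[f]
    return lp, rp


def brute_singleton_msh(H, positions, L, f, c, exclude=()):
    """Best partner for haplotype c: all partners, all sites, max total tract.

    Ties go to the lowest partner index. Returns (partner, lj, rj)."""
    best = None
    for b in range(H.shape[0]):
        if b == c or b in exclude:
            continue
        lj = scan_side(H, c, b, f, -1)
        rj = scan_side(H, c, b, f, +1)
        lp, rp = tract_lengths(positions, L, f, lj, rj)
        if best is None or lp + rp > best[0]:
            best = (lp + rp, b, lj, rj)
    return best[1], best[2], best[3]


def brute_allele_tract(H, f, carriers):
    """Per-side nearest site where any pair of carriers differs."""
    lj = rj = -1
    for j in range(f - 1, -1, -1):
        if len({int(H[c, j]) for c in carriers}) > 1:
            lj = j
            break
    for j in range(f + 1, H.shape[1]):
        if len({int(H[c, j]) for c in carriers}) > 1:
            rj = j
            break
    return lj, rj


def numeric_tc_mle(n_list, s_list, t_max=1e9):
    """Numerically maximize l(t) = sum(n) ln t - 2 t sum(S) over t > 0."""
    n_tot = float(np.sum(n_list))
    s_tot = float(np.sum(s_list))

    def neg_ll(log_t):
        t = np.exp(log_t)
        return -(n_tot * np.log(t) - 2.0 * t * s_tot)

    res = minimize_scalar(
        neg_ll, bounds=(np.log(1e-9), np.log(t_max)), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(np.exp(res.x))


def piecewise_linear(x, xs, ys):
    """Independent piecewise-linear interpolation with terminal clamping."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= x <= xs[i + 1]:
            w = (x - xs[i]) / (xs[i + 1] - xs[i])
            return ys[i] * (1 - w) + ys[i + 1] * w
    raise AssertionError("unreachable")
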