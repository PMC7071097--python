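"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive per-pixel loops, explicit
bit-string transition counting, scipy reference morphology and O(n^2) rank
statistics, so they share no code path with the package implementation.
"""

import math

import numpy as np
from scipy import ndimage as ndi


def lbp_oracle(patch, n_points=8, radius=1.0, tie_eps=1e-10):
    """Naive LBP riu2 labels + neighbor variance via explicit loops.

    Uses the documented convention: neighbor p at angle 2*pi*p/P, offset
    (-R sin, +R cos), bilinear interpolation of the differences from the
    center, s(x) = 1 iff x >= -tie_eps.
    """
    patch = np.asarray(patch, dtype=float)
    m = int(math.ceil(radius))
    h, w = patch.shape
    labels = np.zeros((h - 2 * m, w - 2 * m), dtype=int)
    variances = np.zeros((h - 2 * m, w - 2 * m), dtype=float)
    for i in range(m, h - m):
        for j in range(m, w - m):
            c = patch[i, j]
            deltas = []
            for p in range(n_points):
                theta = 2.0 * math.pi * p / n_points
                dr = -radius * math.sin(theta)
                dc = radius * math.cos(theta)
                if abs(dr - round(dr)) < 1e-9:
                    dr = round(dr)
                if abs(dc - round(dc)) < 1e-9:
                    dc = round(dc)
                r0, c0 = math.floor(dr), math.floor(dc)
                fr, fc = dr - r0, dc - c0
                acc = 0.0
                for (oy, ox, wgt) in (
                    (r0, c0, (1 - fr) * (1 - fc)),
                    (r0, c0 + 1, (1 - fr) * fc),
                    (r0 + 1, c0, fr * (1 - fc)),
                    (r0 + 1, c0 + 1, fr * fc),
                ):
                    if wgt == 0.0:
                        continue
                    acc += wgt * (patch[i + oy, j + ox] - c)
                deltas.append(acc)
            bits = [1 if d >= -tie_eps else 0 for d in deltas]
            transitions = sum(
                bits[p] != bits[(p + 1) % n_points] for p in range(n_points)
            )
            labels[i - m, j - m] = sum(bits) if transitions <= 2 else n_points + 1
            mu = sum(deltas) / n_points
            variances[i - m, j - m] = sum((d - mu) ** 2 for d in deltas) / n_points
    return labels, variances


def disc_footprint_oracle(n):
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return (yy * yy + xx * xx) <= n * n


def opening_oracle(image, n):
    """scipy reference grayscale opening with the disc footprint."""
    if n == 0:
        return np.asarray(image, dtype=float).copy()
    fp = disc_footprint_oracle(n)
    ero = ndi.grey_erosion(np.asarray(image, float), footprint=fp, mode="reflect")
    return ndi.grey_dilation(ero, footprint=fp, mode="reflect")


def closing_oracle(image, n):
    if n == 0:
        return np.asarray(image, dtype=float).copy()
    fp = disc_footprint_oracle(n)
    dil = ndi.grey_dilation(np.asarray(image, float), footprint=fp, mode="reflect")
    return ndi.grey_erosion(dil, footprint=fp, mode="reflect")


def spectrum_oracle(image, bounds, sizes, op="opening"):
    """Per-level window volumes -> normalized consecutive differences."""
    top, left, h, w = bounds
    fn = opening_oracle if op == "opening" else closing_oracle
    vols = np.array([fn(image, int(n))[top:top + h, left:left + w].sum() for n in sizes])
    diffs = vols[:-1] - vols[1:] if op == "opening" else vols[1:] - vols[:-1]
    return diffs / vols[0]


def auc_rank_oracle(prob, labels):
    """O(n^2) pairwise rank statistic: P(score_pos > score_neg), ties half."""
    prob = np.asarray(prob, float)
    labels = np.asarray(labels, int)
    pos = prob[labels == 1]
    neg = prob[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
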