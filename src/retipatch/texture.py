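"""Rotation-invariant uniform local binary patterns and the variance-weighted
LBPV histogram.

The texture descriptor used for retinal patches is the LBPV histogram: each
pixel receives a rotation-invariant uniform LBP label (riu2 coding) computed
from ``P`` neighbors sampled on a circle of radius ``R``, and contributes the
local population variance of those neighbors (VAR) — instead of a unit count —
to the bin of its label.  The result is a ``P + 2``-dimensional, gray-shift
invariant descriptor of local contrast structure.

Conventions
-----------
* Neighbor ``p`` sits at angle ``2*pi*p/P`` on the circle, at image offset
  ``(-R*sin, +R*cos)`` in (row, col); non-integer positions are sampled by
  bilinear interpolation.
* The sign function of the thresholding step is ``s(x) = 1 iff x >= 0``; a
  tolerance of ``1e-10`` is applied so an interpolated neighbor numerically
  equal to the center counts as ``>=``.
* Interpolation acts on the *differences* ``v - g_c`` rather than on raw
  values, which makes labels and VAR exactly invariant under additive gray
  shifts whenever the inputs and the shift are exactly representable.
* Labels exist only where the full circular neighborhood fits inside the
  raster: the valid region excludes a border of ``ceil(R)`` pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: equality tolerance for the s(g_p - g_c) >= 0 comparison
TIE_EPS = 1e-10


@dataclass(frozen=True)
class LBPConfig:
    """Parameters of the circular LBP neighborhood.

    Attributes
    ----------
    n_points : int
        Number of samples ``P`` on the circle (>= 4).
    radius : float
        Circle radius ``R`` in pixels (> 0).
    """

    n_points: int = 8
    radius: float = 1.0

    #: maximum number of 0/1 transitions for a pattern to count as uniform
    UNIFORMITY: int = 2

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError(f"n_points must be >= 4, got {self.n_points}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")

    @property
    def n_labels(self) -> int:
        """Number of distinct riu2 labels: P + 2 (0..P uniform, P+1 non-uniform)."""
        return self.n_points + 2

    @property
    def margin(self) -> int:
        """Border width (pixels) where the neighborhood does not fit."""
        return int(math.ceil(self.radius))


@dataclass
class LBPVHistogram:
    """Variance-weighted LBP histogram of a patch.

    ``bins[k]`` holds the total VAR mass of pixels labeled ``k``; length is
    ``P + 2``.  If ``normalized``, the bins sum to 1 (or are all zero for a
    constant patch).
    """

    bins: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if np.any(self.bins < 0):
            raise ValueError("LBPV bins must be nonnegative")


def riu2_code(bits: np.ndarray) -> int:
    """riu2 label of one circular bit pattern.

    ``bits`` is the length-``P`` 0/1 string ``s(g_p - g_c)``.  Patterns with at
    most 2 circular transitions map to their popcount (0..P); all others
    collapse to the single non-uniform label ``P + 1``.
    """
    bits = np.asarray(bits, dtype=int)
    transitions = int(np.sum(bits != np.roll(bits, -1)))
    if transitions <= LBPConfig.UNIFORMITY:
        return int(bits.sum())
    return bits.size + 1


def _neighbor_deltas(patch: np.ndarray, config: LBPConfig) -> np.ndarray:
    """Sample ``g_p - g_c`` for every valid pixel.

    Returns an array of shape ``(P, H - 2m, W - 2m)`` with ``m = ceil(R)``.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise ValueError("patch must be a 2-D raster")
    m = config.margin
    h, w = patch.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise ValueError(
            f"patch of shape {patch.shape} is smaller than the "
            f"{2 * m + 1}x{2 * m + 1} circular neighborhood"
        )
    center = patch[m:h - m, m:w - m]
    out = np.empty((config.n_points, h - 2 * m, w - 2 * m), dtype=float)
    for p in range(config.n_points):
        theta = 2.0 * math.pi * p / config.n_points
        dr = -config.radius * math.sin(theta)
        dc = config.radius * math.cos(theta)
        # snap near-integer offsets to kill sin/cos rounding fuzz
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        r0, c0 = math.floor(dr), math.floor(dc)
        fr, fc = dr - r0, dc - c0
        acc = np.zeros_like(center)
        for (oy, ox, wgt) in (
            (r0, c0, (1 - fr) * (1 - fc)),
            (r0, c0 + 1, (1 - fr) * fc),
            (r0 + 1, c0, fr * (1 - fc)),
            (r0 + 1, c0 + 1, fr * fc),
        ):
            if wgt == 0.0:
                continue
            block = patch[m + oy:h - m + oy, m + ox:w - m + ox]
            acc += wgt * (block - center)
        out[p] = acc
    return out


def _labels_from_deltas(deltas: np.ndarray) -> np.ndarray:
    bits = deltas >= -TIE_EPS
    transitions = np.zeros(deltas.shape[1:], dtype=np.int64)
    p_count = deltas.shape[0]
    for p in range(p_count):
        transitions += bits[p] != bits[(p + 1) % p_count]
    ones = bits.sum(axis=0)
    return np.where(transitions <= LBPConfig.UNIFORMITY, ones, p_count + 1).astype(np.int64)


def lbp_riu2(patch: np.ndarray, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Per-pixel riu2 LBP labels over the valid region of ``patch``.

    Returns an integer raster of shape ``(H - 2m, W - 2m)`` with values in
    ``[0, P + 1]``.
    """
    return _labels_from_deltas(_neighbor_deltas(patch, config))


def local_variance(patch: np.ndarray, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Per-pixel population variance VAR of the P circular neighbors.

    The mean is taken over the same P neighbors (the center is excluded) and
    the divisor is P.  VAR is invariant to additive gray shifts.
    """
    deltas = _neighbor_deltas(patch, config)
    mu = deltas.mean(axis=0)
    return ((deltas - mu) ** 2).mean(axis=0)


def lbp_var_maps(
    image: np.ndarray, config: LBPConfig = LBPConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Compute the label and VAR rasters in one sampling pass.

    Used by the feature pipeline to evaluate a whole conditioned image once;
    for any pixel whose neighborhood fits inside a patch window, slicing the
    image-level maps is identical to the per-patch computation.
    """
    deltas = _neighbor_deltas(image, config)
    labels = _labels_from_deltas(deltas)
    mu = deltas.mean(axis=0)
    var = ((deltas - mu) ** 2).mean(axis=0)
    return labels, var


def histogram_from_maps(
    labels: np.ndarray,
    var: np.ndarray,
    config: LBPConfig = LBPConfig(),
    normalize: bool = True,
) -> LBPVHistogram:
    """Accumulate an LBPV histogram from precomputed label/VAR rasters."""
    bins = np.bincount(
        np.asarray(labels).ravel(),
        weights=np.asarray(var, dtype=float).ravel(),
        minlength=config.n_labels,
    )
    if normalize:
        total = bins.sum()
        if total > 0:
            bins = bins / total
    return LBPVHistogram(bins=bins, normalized=normalize)


def lbpv_histogram(
    patch: np.ndarray,
    config: LBPConfig = LBPConfig(),
    normalize: bool = True,
) -> LBPVHistogram:
    """LBPV histogram of one patch.

    Bin ``k`` accumulates ``VAR(i, j)`` over all valid pixels whose riu2 label
    is ``k``; with ``normalize`` the histogram is divided by its total mass
    (constant patches, whose mass is zero, stay all-zero).
    """
    deltas = _neighbor_deltas(patch, config)
    labels = _labels_from_deltas(deltas)
    mu = deltas.mean(axis=0)
    var = ((deltas - mu) ** 2).mean(axis=0)
    return histogram_from_maps(labels, var, config, normalize=normalize)
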