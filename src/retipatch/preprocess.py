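"""Data conditioning for fundus images.

Four concerns are handled before any descriptor is computed, in a fixed,
recorded order:

1. **Resolution normalization** — images are only ever downscaled to a common
   target size; a local *maximum* filter precedes resampling so small bright
   lesions survive (a *minimum* filter when the lesions of interest are dark).
2. **Color normalization** — a per-channel affine map inside the field of view
   brings each image to reference mean (and optionally std) statistics,
   compensating white-balance drift between acquisitions.
3. **Vessel segmentation** — a conservative morphological detector (black
   top-hat + Otsu, capped at 30% of the FOV); an externally computed mask may
   be supplied instead.
4. **Vessel inpainting** — vessels are treated as missing data and restored by
   harmonic interpolation from the surrounding retina, so that background
   texture descriptors are not dominated by vasculature.

The conditioned output is the inpainted green channel (the RGB channel with
the best lesion/background contrast) together with the FOV and optic-disc
masks and a provenance record of the applied steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .granulometry import closing as morph_closing

logger = logging.getLogger(__name__)

#: fraction of the FOV a vessel mask may cover at most
VESSEL_FRACTION_CAP = 0.30


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    ``reference_mean``/``reference_std`` are per-channel targets for color
    normalization (None disables the respective matching); ``lesion_polarity``
    selects the extremum filter protecting bright or dark lesions during
    downscaling.
    """

    target_width: int | None = None
    target_height: int | None = None
    extremum_filter_size: int = 3
    lesion_polarity: str = "bright"
    reference_mean: tuple[float, float, float] | None = None
    reference_std: tuple[float, float, float] | None = None
    inpaint_method: str = "harmonic"
    tophat_radius: int = 6

    def __post_init__(self) -> None:
        if self.extremum_filter_size < 1 or self.extremum_filter_size % 2 == 0:
            raise ValueError("extremum_filter_size must be odd and >= 1")
        if self.lesion_polarity not in ("bright", "dark"):
            raise ValueError("lesion_polarity must be 'bright' or 'dark'")
        for dim in (self.target_width, self.target_height):
            if dim is not None and dim < 1:
                raise ValueError("target dimensions must be >= 1")


@dataclass
class ConditionedImage:
    """Single-channel conditioned raster plus masks and provenance."""

    green: np.ndarray
    fov_mask: np.ndarray
    od_mask: np.ndarray
    provenance: list[str] = field(default_factory=list)
    vessel_mask: np.ndarray | None = None


def estimate_fov_mask(image: np.ndarray) -> np.ndarray:
    """Heuristic FOV: luminance above 5% of max, largest component, holes filled."""
    image = np.asarray(image, dtype=float)
    lum = image.mean(axis=-1) if image.ndim == 3 else image
    rough = lum > 0.05 * lum.max()
    labels, n = ndi.label(rough)
    if n == 0:
        return rough
    largest = np.argmax(ndi.sum_labels(rough, labels, index=np.arange(1, n + 1))) + 1
    return ndi.binary_fill_holes(labels == largest)


def estimate_od_mask(green: np.ndarray, fov_mask: np.ndarray, radius_fraction: float = 0.07) -> np.ndarray:
    """Approximate optic-disc mask: brightest disc-shaped region by matched
    filtering with a uniform disc kernel.  A coarse stand-in for a dedicated
    disc segmenter — callers with a real mask should pass it instead."""
    green = np.asarray(green, dtype=float)
    r = max(3, int(round(radius_fraction * min(green.shape))))
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    kernel = (yy**2 + xx**2 <= r * r).astype(float)
    kernel /= kernel.sum()
    response = ndi.convolve(green, kernel, mode="nearest")
    interior = ndi.binary_erosion(fov_mask, iterations=r) if fov_mask.any() else fov_mask
    response = np.where(interior, response, -np.inf)
    cy, cx = np.unravel_index(np.argmax(response), response.shape)
    yy, xx = np.ogrid[: green.shape[0], : green.shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= (1.15 * r) ** 2


def normalize_resolution(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Extremum-filter then bilinearly resample to the target dimensions.

    The max (bright polarity) or min (dark polarity) filter dilates small
    lesions before resampling so they are not averaged away; upscaling is
    refused.  With target dims equal to (or unset for) the source, only the
    extremum filter is applied.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    th = config.target_height if config.target_height is not None else h
    tw = config.target_width if config.target_width is not None else w
    if th > h or tw > w:
        raise ValueError(f"refusing to upscale {h}x{w} to {th}x{tw}")
    size = config.extremum_filter_size
    filt = ndi.maximum_filter if config.lesion_polarity == "bright" else ndi.minimum_filter
    if image.ndim == 3:
        filtered = np.stack([filt(image[..., c], size=size) for c in range(image.shape[-1])], axis=-1)
        out_shape = (th, tw, image.shape[-1])
    else:
        filtered = filt(image, size=size)
        out_shape = (th, tw)
    if (th, tw) == (h, w):
        return filtered
    return resize(filtered, out_shape, order=1, anti_aliasing=False, preserve_range=True)


def normalize_color(
    image: np.ndarray,
    fov_mask: np.ndarray,
    reference_mean,
    reference_std=None,
) -> np.ndarray:
    """Affine per-channel map inside the FOV to reference statistics.

    Matches the mean (and the std when given) of every channel over FOV
    pixels, clips to [0, 1] and leaves pixels outside the FOV untouched.  A
    channel with zero within-FOV variance falls back to a mean shift.
    """
    image = np.asarray(image, dtype=float)
    if not fov_mask.any():
        raise ValueError("FOV mask is empty")
    single = image.ndim == 2
    work = image[..., None] if single else image.copy()
    ref_mean = np.atleast_1d(np.asarray(reference_mean, dtype=float))
    ref_std = None if reference_std is None else np.atleast_1d(np.asarray(reference_std, dtype=float))
    out = work.copy()
    for c in range(work.shape[-1]):
        vals = work[..., c][fov_mask]
        mu, sd = vals.mean(), vals.std()
        if ref_std is not None and sd > 1e-12:
            scaled = (work[..., c] - mu) * (ref_std[c] / sd) + ref_mean[c]
        else:
            if ref_std is not None:
                logger.info("channel %d has zero FOV variance; mean-shift only", c)
            scaled = work[..., c] + (ref_mean[c] - mu)
        out[..., c] = np.where(fov_mask, np.clip(scaled, 0.0, 1.0), work[..., c])
    return out[..., 0] if single else out


def segment_vessels(
    green: np.ndarray,
    fov_mask: np.ndarray,
    radius: int = 6,
) -> np.ndarray:
    """Conservative vessel mask: black top-hat with a disc SE + Otsu threshold.

    The black top-hat (closing minus image) responds to thin dark structures;
    the threshold is raised to the 70th percentile of the in-FOV response if
    Otsu would flag more than 30% of the FOV.  Structureless images yield an
    empty mask.
    """
    green = np.asarray(green, dtype=float)
    if green.shape != fov_mask.shape:
        raise ValueError("green and fov_mask shapes differ")
    tophat = morph_closing(green, radius) - green
    vals = tophat[fov_mask]
    if vals.size == 0 or vals.max() - vals.min() < 1e-6:
        return np.zeros_like(fov_mask)
    thr = threshold_otsu(vals)
    mask = (tophat > thr) & fov_mask
    allowed = int(VESSEL_FRACTION_CAP * fov_mask.sum())
    if mask.sum() > allowed:
        # keep only the strongest responses (top-k inside the FOV)
        fy, fx = np.nonzero(fov_mask)
        order = np.argpartition(vals, -allowed)[-allowed:]
        mask = np.zeros_like(fov_mask)
        mask[fy[order], fx[order]] = True
    return mask


def inpaint_vessels(
    green: np.ndarray,
    vessel_mask: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> np.ndarray:
    """Harmonic fill of vessel pixels by iterated 4-neighbor averaging.

    Masked pixels are relaxed to the discrete-Laplace equilibrium of their
    surroundings (Jacobi iteration to ``tol``); unmasked pixels are returned
    untouched and the result never leaves the observed value range.
    """
    green = np.asarray(green, dtype=float)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if green.shape != vessel_mask.shape:
        raise ValueError("green and vessel_mask shapes differ")
    if not vessel_mask.any():
        return green.copy()
    if vessel_mask.all() or (~vessel_mask).sum() == 0:
        raise ValueError("vessel mask covers the whole raster; nothing to interpolate from")
    lo, hi = green.min(), green.max()
    out = green.copy()
    out[vessel_mask] = green[~vessel_mask].mean()
    for _ in range(max_iter):
        padded = np.pad(out, 1, mode="edge")
        nb = 0.25 * (padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:])
        delta = np.abs(nb[vessel_mask] - out[vessel_mask]).max()
        out[vessel_mask] = nb[vessel_mask]
        if delta < tol:
            break
    return np.clip(out, lo, hi)


def dataset_reference_stats(images, fov_masks) -> tuple[np.ndarray, np.ndarray]:
    """Median per-channel FOV mean/std across a dataset — the default color
    normalization target when no explicit reference is configured."""
    means, stds = [], []
    for img, fov in zip(images, fov_masks):
        img = np.asarray(img, dtype=float)
        vals = img[fov]
        means.append(vals.mean(axis=0))
        stds.append(vals.std(axis=0))
    return np.median(np.asarray(means), axis=0), np.median(np.asarray(stds), axis=0)


def condition(
    image: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
    fov_mask: np.ndarray | None = None,
    od_mask: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
) -> ConditionedImage:
    """Run the full conditioning pipeline on one RGB image.

    Fixed order: resolution normalization, color normalization, vessel
    segmentation (skipped when a mask is supplied), inpainting, green-channel
    extraction.  Masks are resampled (nearest neighbor) alongside the image;
    missing masks are estimated heuristically (FOV) or left empty (optic
    disc).  The provenance list records the steps actually applied, in order.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("condition() expects an RGB raster")
    provenance: list[str] = []
    if fov_mask is None:
        fov_mask = estimate_fov_mask(image)
        provenance.append("estimate_fov_mask")
    fov_mask = np.asarray(fov_mask, dtype=bool)
    od_mask = (
        np.zeros(image.shape[:2], dtype=bool) if od_mask is None else np.asarray(od_mask, dtype=bool)
    )

    h, w = image.shape[:2]
    th = config.target_height if config.target_height is not None else h
    tw = config.target_width if config.target_width is not None else w
    image = normalize_resolution(image, config)
    provenance.append(f"normalize_resolution[{config.lesion_polarity}]")
    if (th, tw) != (h, w):
        fov_mask = resize(fov_mask.astype(float), (th, tw), order=0, preserve_range=True) > 0.5
        od_mask = resize(od_mask.astype(float), (th, tw), order=0, preserve_range=True) > 0.5
        if vessel_mask is not None:
            vessel_mask = (
                resize(np.asarray(vessel_mask, float), (th, tw), order=0, preserve_range=True) > 0.5
            )

    if config.reference_mean is not None:
        image = normalize_color(image, fov_mask, config.reference_mean, config.reference_std)
        provenance.append("normalize_color")

    green = image[..., 1]
    if vessel_mask is None:
        vessel_mask = segment_vessels(green, fov_mask, radius=config.tophat_radius)
        provenance.append("segment_vessels")
    vessel_mask = np.asarray(vessel_mask, dtype=bool) & fov_mask
    if vessel_mask.any():
        green = inpaint_vessels(green, vessel_mask)
        provenance.append(f"inpaint_vessels[{config.inpaint_method}]")
    provenance.append("extract_green")
    logger.info("conditioned image: %s", " -> ".join(provenance))
    return ConditionedImage(
        green=green,
        fov_mask=fov_mask,
        od_mask=od_mask,
        provenance=provenance,
        vessel_mask=vessel_mask,
    )
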