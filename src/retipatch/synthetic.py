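"""Synthetic fundus-like images with pixel-accurate ground truth.

The generator emulates the gross photometric structure of a retinal
photograph as seen by the downstream descriptors, not its photorealism: a
roughly circular field of view (FOV) on a near-black background, a smooth
greenish background with radial vignetting and a per-image brightness offset,
dark curvilinear vessels radiating from a bright optic disc, and three lesion
classes with binary ground-truth masks:

* exudates — small *bright* blobs with irregular edges (unions of jittered
  ellipses clipped between a core and a bounding disc),
* microaneurysms — small *dark* round spots,
* hemorrhages — larger dark blobs with blurred edges.

Each lesion raises (bright) or lowers (dark) the green channel by at least
half of ``lesion_contrast`` everywhere inside its mask, before sensor noise
is added; this is the signal the texture/granulometry descriptors must pick
up.  All randomness flows from ``rng_seed``: the same seed reproduces the
sample bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi


class LesionPlacementError(RuntimeError):
    """Raised when lesions cannot be placed inside the FOV after bounded retries."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic fundus generator.

    ``lesion_size_range`` is the (min, max) lesion *diameter* in pixels;
    ``lesion_contrast`` is the green-channel offset (in [0, 1] gray levels)
    applied inside lesions; ``noise_sigma`` is the per-channel Gaussian sensor
    noise added last.
    """

    image_width: int = 512
    image_height: int = 512
    fov_radius_fraction: float = 0.95
    n_exudates: int = 6
    n_microaneurysms: int = 4
    n_hemorrhages: int = 2
    lesion_size_range: tuple[float, float] = (6.0, 14.0)
    lesion_contrast: float = 0.5
    vessel_count: int = 8
    noise_sigma: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exudates, self.n_microaneurysms, self.n_hemorrhages) < 0:
            raise ValueError("lesion counts must be >= 0")
        lo, hi = self.lesion_size_range
        if lo > hi or lo <= 0:
            raise ValueError(f"invalid lesion_size_range {self.lesion_size_range}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 < self.fov_radius_fraction <= 1):
            raise ValueError("fov_radius_fraction must lie in (0, 1]")
        if self.image_width < 32 or self.image_height < 32:
            raise ValueError("image must be at least 32x32")


@dataclass
class SyntheticSample:
    """One generated image with aligned ground-truth masks.

    ``bright_mask`` marks exudate pixels, ``dark_mask`` microaneurysm and
    hemorrhage pixels; the two are disjoint, lie inside the FOV and outside
    the optic disc.  ``vessel_mask`` / ``vessel_centerline`` describe the
    drawn vessel strokes, and ``green_clean`` is the green channel before
    noise injection (useful for contrast audits).
    """

    image: np.ndarray
    fov_mask: np.ndarray
    od_mask: np.ndarray
    bright_mask: np.ndarray
    dark_mask: np.ndarray
    vessel_mask: np.ndarray
    vessel_centerline: np.ndarray
    green_clean: np.ndarray
    config: SyntheticConfig


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    field = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _bezier_points(p0, p1, p2, n: int = 256) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    return np.rint(pts).astype(int)


def _draw_vessels(
    rng: np.random.Generator,
    shape: tuple[int, int],
    od_center: np.ndarray,
    fov_radius: float,
    center: np.ndarray,
    count: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Dark curvilinear strokes from the optic disc toward the FOV rim.

    Returns (stroke mask, centerline mask).  These exist to exercise vessel
    segmentation and the inpainting contract, not to model real vasculature.
    """
    h, w = shape
    centerline = np.zeros(shape, dtype=bool)
    for _ in range(count):
        ang = rng.uniform(0, 2 * np.pi)
        reach = rng.uniform(0.55, 0.95) * fov_radius
        p2 = center + reach * np.array([np.sin(ang), np.cos(ang)])
        mid = (od_center + p2) / 2
        perp = np.array([-(p2 - od_center)[1], (p2 - od_center)[0]])
        norm = np.linalg.norm(perp)
        if norm > 0:
            perp /= norm
        p1 = mid + rng.uniform(-0.25, 0.25) * np.linalg.norm(p2 - od_center) * perp
        pts = _bezier_points(od_center, p1, p2)
        valid = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
        pts = pts[valid]
        centerline[pts[:, 0], pts[:, 1]] = True
    stroke = ndi.binary_dilation(centerline, structure=ndi.generate_binary_structure(2, 2))
    return stroke, centerline


def _local_disc(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _ellipse(shape, center, a, b, theta) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    y = yy - center[0]
    x = xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _exudate_shape(rng: np.random.Generator, shape, center, radius: float, min_radius: float):
    """Irregular bright blob: jittered ellipses clipped between a core disc
    (radius >= the configured minimum, bounding the area from below) and the
    bounding disc of the sampled radius (bounding it from above)."""
    core = max(min_radius, 0.7 * radius)
    mask = _local_disc(shape, center, core)
    for _ in range(int(rng.integers(2, 5))):
        a = rng.uniform(0.6 * radius, radius)
        b = rng.uniform(0.5 * radius, 0.9 * radius)
        jitter = rng.uniform(-0.3 * radius, 0.3 * radius, size=2)
        mask |= _ellipse(shape, center + jitter, a, b, rng.uniform(0, np.pi))
    mask &= _local_disc(shape, center, radius)
    return mask


def _place_lesions(
    rng: np.random.Generator,
    spec: list[tuple[str, float]],
    shape: tuple[int, int],
    center: np.ndarray,
    fov_radius: float,
    od_center: np.ndarray,
    od_radius: float,
    vessel_mask: np.ndarray,
    min_radius: float,
    max_retries: int = 200,
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Place lesions with mutual separation, inside the FOV, clear of the
    optic disc and the vessel strokes.  Raises LesionPlacementError when a
    lesion cannot be placed within ``max_retries`` draws."""
    placed: list[tuple[str, np.ndarray, float]] = []  # (kind, center, radius)
    out: list[tuple[str, np.ndarray, np.ndarray]] = []
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for kind, radius in spec:
        ok = False
        for _ in range(max_retries):
            rho = np.sqrt(rng.uniform(0, 1)) * (fov_radius - radius - 6)
            ang = rng.uniform(0, 2 * np.pi)
            c = center + rho * np.array([np.sin(ang), np.cos(ang)])
            if np.linalg.norm(c - od_center) <= od_radius + radius + 4:
                continue
            if any(
                np.linalg.norm(c - pc) <= radius + pr + 6 for _, pc, pr in placed
            ):
                continue
            near = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= (radius + 2) ** 2
            if vessel_mask[near].any():
                continue
            placed.append((kind, c, radius))
            if kind == "exudate":
                mask = _exudate_shape(rng, shape, c, radius, min_radius)
            elif kind == "microaneurysm":
                mask = _local_disc(shape, c, radius)
            else:  # hemorrhage
                mask = _local_disc(shape, c, radius * 0.8)
                for _ in range(int(rng.integers(1, 3))):
                    jitter = rng.uniform(-0.3 * radius, 0.3 * radius, size=2)
                    mask |= _ellipse(
                        shape, c + jitter,
                        rng.uniform(0.6, 1.0) * radius,
                        rng.uniform(0.5, 0.9) * radius,
                        rng.uniform(0, np.pi),
                    )
                mask &= _local_disc(shape, c, radius)
            out.append((kind, mask, c))
            ok = True
            break
        if not ok:
            raise LesionPlacementError(
                f"could not place {kind} of radius {radius:.1f} after {max_retries} tries "
                "(too many lesions for the FOV area?)"
            )
    return out


def _lesion_field(masks: np.ndarray, blur_sigma: float, floor: float) -> np.ndarray:
    """Soft lesion intensity profile, guaranteed >= ``floor`` inside the mask."""
    field = ndi.gaussian_filter(masks.astype(float), blur_sigma)
    return np.where(masks, np.maximum(field, floor), field)


def generate_sample(config: SyntheticConfig) -> SyntheticSample:
    """Generate one fundus-like image with consistent ground-truth masks.

    Deterministic for a fixed ``rng_seed``.  Raises
    :class:`LesionPlacementError` if the requested lesions do not fit.
    """
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_height, config.image_width
    shape = (h, w)
    center = np.array([h / 2.0, w / 2.0])
    fov_radius = config.fov_radius_fraction * min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    dist = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
    fov_mask = dist <= fov_radius

    # smooth background: base level + vignette + low-frequency mottle
    base = 0.45 + rng.uniform(-0.05, 0.05)
    vignette = 1.0 - 0.30 * (dist / fov_radius) ** 2
    green = base * vignette + 0.02 * _smooth_field(rng, shape, min(h, w) / 8.0)

    # optic disc: one bright disc off-center
    od_ang = rng.choice([0.0, np.pi]) + rng.uniform(-0.25, 0.25)
    od_center = center + 0.55 * fov_radius * np.array([np.sin(od_ang) * 0.3, np.cos(od_ang)])
    od_radius = 0.14 * fov_radius
    od_dist = np.sqrt((yy - od_center[0]) ** 2 + (xx - od_center[1]) ** 2)
    od_profile = np.clip(1.0 - (od_dist / od_radius) ** 2, 0.0, 1.0)
    green = green + 0.22 * ndi.gaussian_filter(od_profile, 2.0)
    od_mask = od_dist <= od_radius

    # vessels
    vessel_mask, vessel_centerline = _draw_vessels(
        rng, shape, od_center, fov_radius, center, config.vessel_count
    )
    vessel_field = ndi.gaussian_filter(vessel_mask.astype(float), 0.7)
    peak = vessel_field.max()
    if peak > 0:
        vessel_field /= peak
    green = green - 0.18 * vessel_field

    # lesions
    lo, hi = config.lesion_size_range
    spec: list[tuple[str, float]] = []
    spec += [("exudate", rng.uniform(lo, hi) / 2.0) for _ in range(config.n_exudates)]
    spec += [
        ("microaneurysm", rng.uniform(lo, lo + 0.3 * (hi - lo)) / 2.0)
        for _ in range(config.n_microaneurysms)
    ]
    spec += [("hemorrhage", rng.uniform(hi, 1.5 * hi) / 2.0) for _ in range(config.n_hemorrhages)]
    lesions = _place_lesions(
        rng, spec, shape, center, fov_radius, od_center, od_radius,
        vessel_mask, min_radius=lo / 2.0,
    )
    bright_mask = np.zeros(shape, dtype=bool)
    dark_mask = np.zeros(shape, dtype=bool)
    for kind, mask, _c in lesions:
        if kind == "exudate":
            bright_mask |= mask
        else:
            dark_mask |= mask

    bright_field = _lesion_field(bright_mask, 0.6, 0.55)
    dark_field = _lesion_field(dark_mask, 0.8, 0.55)
    green = green + config.lesion_contrast * bright_field
    green = green - config.lesion_contrast * dark_field

    red = 0.10 + 1.35 * green + config.lesion_contrast * (0.8 * bright_field - 0.4 * dark_field)
    blue = 0.30 * green

    rgb = np.stack([red, green, blue], axis=-1)
    rgb = np.where(fov_mask[..., None], rgb, 0.02)
    rgb = np.clip(rgb, 0.0, 1.0)
    green_clean = rgb[..., 1].copy()

    if config.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, config.noise_sigma, rgb.shape)
        rgb = np.clip(rgb, 0.0, 1.0)

    assert not (bright_mask & dark_mask).any()
    assert not (bright_mask & od_mask).any() and not (dark_mask & od_mask).any()
    assert bool(((bright_mask | dark_mask) & ~fov_mask).sum() == 0)
    return SyntheticSample(
        image=rgb,
        fov_mask=fov_mask,
        od_mask=od_mask,
        bright_mask=bright_mask,
        dark_mask=dark_mask,
        vessel_mask=vessel_mask,
        vessel_centerline=vessel_centerline,
        green_clean=green_clean,
        config=config,
    )


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """``n`` independent per-image seeds derived from one base seed (< 2**31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n, dtype=np.uint64)]


def generate_dataset(
    n_pathological: int,
    n_healthy: int,
    config: SyntheticConfig = SyntheticConfig(),
    base_seed: int = 0,
) -> list[SyntheticSample]:
    """A mixed dataset: ``n_pathological`` images with the configured lesion
    counts followed by ``n_healthy`` lesion-free images, each generated from
    an independent seed derived from ``base_seed``."""
    seeds = derive_seeds(base_seed, n_pathological + n_healthy)
    samples = []
    for i, seed in enumerate(seeds):
        if i < n_pathological:
            cfg = dataclasses.replace(config, rng_seed=seed)
        else:
            cfg = dataclasses.replace(
                config, rng_seed=seed, n_exudates=0, n_microaneurysms=0, n_hemorrhages=0
            )
        samples.append(generate_sample(cfg))
    return samples


def save_sample(sample: SyntheticSample, outdir: str | Path, stem: str) -> dict:
    """Write the image and masks as PNGs; returns the manifest record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"image": f"{stem}_image.png"}
    iio.imwrite(outdir / paths["image"], (sample.image * 255).round().astype(np.uint8))
    for name in ("fov_mask", "od_mask", "bright_mask", "dark_mask", "vessel_mask"):
        paths[name] = f"{stem}_{name}.png"
        iio.imwrite(outdir / paths[name], getattr(sample, name).astype(np.uint8) * 255)
    return {
        "stem": stem,
        "paths": paths,
        "rng_seed": sample.config.rng_seed,
        "n_exudates": sample.config.n_exudates,
        "n_microaneurysms": sample.config.n_microaneurysms,
        "n_hemorrhages": sample.config.n_hemorrhages,
        "lesion_contrast": sample.config.lesion_contrast,
    }


def write_manifest(records: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps({"samples": records}, indent=2))


def read_manifest(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())["samples"]
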