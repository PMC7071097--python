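"""Dense overlapping patch grids with FOV/optic-disc exclusion.

The image is scanned with a sliding ``Nw x Nw`` window displaced by
``(dx, dy)`` pixels (default 64x64 with 50% overlap); every window that
touches retinal tissue (intersects the FOV) and avoids the optic disc
becomes one sample, identified by its central pixel.  Ground-truth labels
come from a lesion mask: a patch is *pathological* when its window contains
at least ``min_lesion_pixels`` lesion pixels (default 1).

Windows are anchored so they fit entirely inside the raster (no partial
border windows); coordinates are 0-based ``(row, col)`` and windows are
half-open ``[top, top+Nw) x [left, left+Nw)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

HEALTHY = 0
PATHOLOGICAL = 1
UNLABELED = -1

_LABEL_NAMES = {HEALTHY: "healthy", PATHOLOGICAL: "pathological", UNLABELED: "unlabeled"}


@dataclass(frozen=True)
class GridConfig:
    """Sliding-window geometry and labeling rule."""

    window_size: int = 64
    step: tuple[int, int] = (32, 32)  # (dx, dy) displacement in pixels
    min_lesion_pixels: int = 1

    def __post_init__(self) -> None:
        dx, dy = self.step
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not (0 < dx <= self.window_size and 0 < dy <= self.window_size):
            raise ValueError("step components must lie in (0, window_size]")
        if self.min_lesion_pixels < 1:
            raise ValueError("min_lesion_pixels must be >= 1")


@dataclass(frozen=True)
class Patch:
    """One window: center pixel, bounds and ground-truth label."""

    center: tuple[int, int]
    bounds: tuple[int, int, int, int]  # (top, left, height, width)
    label: int = UNLABELED
    source_image_id: str = ""

    @property
    def label_name(self) -> str:
        return _LABEL_NAMES[self.label]


@dataclass
class PatchGrid:
    """Row-major list of kept patches over one image."""

    patches: list[Patch]
    image_shape: tuple[int, int]
    config: GridConfig

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patches], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": p.source_image_id,
                    "center_row": p.center[0],
                    "center_col": p.center[1],
                    "top": p.bounds[0],
                    "left": p.bounds[1],
                    "label": p.label_name,
                }
                for p in self.patches
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _window_sums(mask: np.ndarray, nw: int) -> np.ndarray:
    """Sum of ``mask`` over every top-left anchored ``nw x nw`` window,
    via a summed-area table."""
    sat = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=sat[1:, 1:])
    return (
        sat[nw:, nw:] - sat[:-nw, nw:] - sat[nw:, :-nw] + sat[:-nw, :-nw]
    )


def build_grid(
    image_shape: tuple[int, int],
    fov_mask: np.ndarray,
    od_mask: np.ndarray | None,
    config: GridConfig = GridConfig(),
    image_id: str = "",
) -> PatchGrid:
    """Enumerate the kept windows of the sliding-window grid.

    A window is kept iff it intersects the FOV and contains no optic-disc
    pixel.  Patches are ordered row-major by center.  Raises ``ValueError``
    when no window survives (empty FOV or total disc exclusion).
    """
    h, w = image_shape
    nw = config.window_size
    dx, dy = config.step
    fov_mask = np.asarray(fov_mask, dtype=bool)
    if fov_mask.shape != (h, w):
        raise ValueError("fov_mask shape does not match image_shape")
    if od_mask is None:
        od_mask = np.zeros((h, w), dtype=bool)
    od_mask = np.asarray(od_mask, dtype=bool)
    if od_mask.shape != (h, w):
        raise ValueError("od_mask shape does not match image_shape")
    if h < nw or w < nw:
        raise ValueError(f"image {image_shape} smaller than the {nw}x{nw} window")
    if not fov_mask.any():
        raise ValueError("empty FOV mask: no retinal texture to process")

    fov_sums = _window_sums(fov_mask, nw)
    od_sums = _window_sums(od_mask, nw)
    tops = np.arange(0, h - nw + 1, dy)
    lefts = np.arange(0, w - nw + 1, dx)
    patches = []
    for top in tops:
        for left in lefts:
            if fov_sums[top, left] == 0 or od_sums[top, left] > 0:
                continue
            patches.append(
                Patch(
                    center=(int(top + nw // 2), int(left + nw // 2)),
                    bounds=(int(top), int(left), nw, nw),
                    source_image_id=image_id,
                )
            )
    if not patches:
        raise ValueError("no patch survives the FOV/optic-disc exclusion rules")
    return PatchGrid(patches=patches, image_shape=(h, w), config=config)


def label_patches(
    grid: PatchGrid, lesion_mask: np.ndarray, config: GridConfig | None = None
) -> PatchGrid:
    """Assign healthy/pathological labels from a ground-truth lesion mask.

    A patch is pathological iff its window contains at least
    ``min_lesion_pixels`` lesion pixels.
    """
    cfg = config if config is not None else grid.config
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != grid.image_shape:
        raise ValueError("lesion_mask shape does not match the grid's image shape")
    sums = _window_sums(lesion_mask, cfg.window_size)
    labeled = [
        replace(
            p,
            label=PATHOLOGICAL
            if sums[p.bounds[0], p.bounds[1]] >= cfg.min_lesion_pixels
            else HEALTHY,
        )
        for p in grid.patches
    ]
    return PatchGrid(patches=labeled, image_shape=grid.image_shape, config=cfg)
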