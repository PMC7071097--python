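"""Per-patch feature assembly: LBPV and pattern-spectrum blocks.

A feature vector is the concatenation of named blocks:

* ``lbpv`` — the normalized LBPV histogram (length ``P + 2``),
* ``ps_gamma_b`` / ``ps_phi_b`` — opening / closing pattern spectrum with the
  isotropic disc SE (length ``nmax // s``),
* ``ps_gamma_l`` / ``ps_phi_l`` — the angular (line-SE) counterparts, either
  averaged over the four directions (same length as the isotropic block) or
  concatenated per angle.

Morphological pyramids and the LBP/VAR rasters are computed once per image
and shared by all patches.  Feature standardization is *not* performed here:
each committee base classifier z-scores columns with its own training-fold
statistics (a per-block standardization, since blocks occupy disjoint column
ranges).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .granulometry import (
    MorphPyramid,
    SEFamily,
    build_pyramid,
    one_sided_spectrum,
)
from .patches import PatchGrid
from .preprocess import ConditionedImage
from .texture import LBPConfig, histogram_from_maps, lbp_var_maps

KNOWN_BLOCKS = ("lbpv", "ps_gamma_b", "ps_gamma_l", "ps_phi_b", "ps_phi_l")

#: the full descriptor ablated in the study: texture + all four morphological blocks
FULL_BLOCKS = ("lbpv", "ps_gamma_b", "ps_gamma_l", "ps_phi_b", "ps_phi_l")


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered block list plus per-block configuration."""

    blocks: tuple[str, ...] = FULL_BLOCKS
    lbp: LBPConfig = LBPConfig()
    se_disc: SEFamily = SEFamily(shape="disc")
    se_line: SEFamily = SEFamily(shape="line")
    angular_combine: str = "mean"
    normalize_lbpv: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("FeatureSpec requires at least one block")
        for b in self.blocks:
            if b not in KNOWN_BLOCKS:
                raise ValueError(f"unknown feature block {b!r}")
        if self.angular_combine not in ("mean", "concat"):
            raise ValueError("angular_combine must be 'mean' or 'concat'")

    def block_length(self, block: str) -> int:
        if block == "lbpv":
            return self.lbp.n_labels
        n_sizes = self.se_disc.nmax // self.se_disc.step
        if block in ("ps_gamma_b", "ps_phi_b"):
            return n_sizes
        n_sizes_l = self.se_line.nmax // self.se_line.step
        if self.angular_combine == "concat":
            return n_sizes_l * len(self.se_line.angles)
        return n_sizes_l

    @property
    def n_features(self) -> int:
        return sum(self.block_length(b) for b in self.blocks)

    def schema(self) -> list[tuple[str, int]]:
        """Column provenance: (block, within-block index) per feature column."""
        return [(b, i) for b in self.blocks for i in range(self.block_length(b))]


@dataclass
class _ImageContext:
    """Per-image precomputations shared by all patches."""

    labels: np.ndarray | None = None
    var: np.ndarray | None = None
    pyramids: dict = dc_field(default_factory=dict)


def _prepare_context(green: np.ndarray, spec: FeatureSpec) -> _ImageContext:
    ctx = _ImageContext()
    if "lbpv" in spec.blocks:
        ctx.labels, ctx.var = lbp_var_maps(green, spec.lbp)
    if "ps_gamma_b" in spec.blocks:
        ctx.pyramids["gamma_b"] = build_pyramid(green, "opening", spec.se_disc)
    if "ps_phi_b" in spec.blocks:
        ctx.pyramids["phi_b"] = build_pyramid(green, "closing", spec.se_disc)
    if "ps_gamma_l" in spec.blocks:
        ctx.pyramids["gamma_l"] = [
            build_pyramid(green, "opening", spec.se_line, angle=a) for a in spec.se_line.angles
        ]
    if "ps_phi_l" in spec.blocks:
        ctx.pyramids["phi_l"] = [
            build_pyramid(green, "closing", spec.se_line, angle=a) for a in spec.se_line.angles
        ]
    return ctx


def _angular_block(pyrs: list[MorphPyramid], bounds, combine: str) -> np.ndarray:
    spectra = [one_sided_spectrum(p, bounds) for p in pyrs]
    if combine == "concat":
        return np.concatenate(spectra)
    return np.mean(spectra, axis=0)


def _patch_vector(ctx: _ImageContext, spec: FeatureSpec, bounds) -> np.ndarray:
    top, left, height, width = bounds
    parts = []
    for block in spec.blocks:
        if block == "lbpv":
            # valid pixels of this patch are those whose neighborhood fits in
            # the window: interior margin m; image-level maps are offset by m.
            m = spec.lbp.margin
            lab = ctx.labels[top:top + height - 2 * m, left:left + width - 2 * m]
            var = ctx.var[top:top + height - 2 * m, left:left + width - 2 * m]
            hist = histogram_from_maps(lab, var, spec.lbp, normalize=spec.normalize_lbpv)
            parts.append(hist.bins)
        elif block == "ps_gamma_b":
            parts.append(one_sided_spectrum(ctx.pyramids["gamma_b"], bounds))
        elif block == "ps_phi_b":
            parts.append(one_sided_spectrum(ctx.pyramids["phi_b"], bounds))
        elif block == "ps_gamma_l":
            parts.append(_angular_block(ctx.pyramids["gamma_l"], bounds, spec.angular_combine))
        elif block == "ps_phi_l":
            parts.append(_angular_block(ctx.pyramids["phi_l"], bounds, spec.angular_combine))
    vec = np.concatenate(parts)
    if vec.shape[0] != spec.n_features:
        raise ValueError(
            f"feature blocks produced {vec.shape[0]} columns, schema expects {spec.n_features}"
        )
    return vec


def extract_features(
    conditioned: ConditionedImage,
    grid: PatchGrid,
    spec: FeatureSpec = FeatureSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (one row per kept patch, grid order) + aligned labels."""
    ctx = _prepare_context(np.asarray(conditioned.green, dtype=float), spec)
    rows = [_patch_vector(ctx, spec, p.bounds) for p in grid.patches]
    return np.asarray(rows), grid.labels


def save_features(path: str | Path, X: np.ndarray, y: np.ndarray, spec: FeatureSpec) -> None:
    """NPZ feature matrix + JSON column schema next to it."""
    path = Path(path)
    np.savez_compressed(path, X=X, y=y)
    schema_path = path.with_suffix(".schema.json")
    schema_path.write_text(json.dumps({"columns": spec.schema(), "blocks": list(spec.blocks)}))


def load_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.load(Path(path))
    return data["X"], data["y"]
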