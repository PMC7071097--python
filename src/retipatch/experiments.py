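"""End-to-end synthetic experiments: generation -> conditioning -> features
-> committee cross-validation.

These wire the full screening pipeline together on the synthetic generator's
output, mirroring the bright-lesion study protocol at a reduced problem
size: a mixed set of pathological (exudate-bearing) and healthy images,
64x64 patches with (32, 32) displacement, the full texture+morphology
descriptor, and image-grouped 5-fold cross-validation of the balanced
committee.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .committee import CommitteeConfig, crossvalidate
from .features import FeatureSpec, extract_features
from .patches import GridConfig, build_grid, label_patches
from .preprocess import PreprocessConfig, condition, dataset_reference_stats
from .synthetic import SyntheticConfig, SyntheticSample, generate_dataset

logger = logging.getLogger(__name__)


def condition_sample(
    sample: SyntheticSample,
    pre_config: PreprocessConfig = PreprocessConfig(),
):
    """Condition a synthetic sample using its ground-truth FOV/OD masks."""
    return condition(
        sample.image, pre_config, fov_mask=sample.fov_mask, od_mask=sample.od_mask
    )


def sample_features(
    sample: SyntheticSample,
    image_id: str,
    pre_config: PreprocessConfig = PreprocessConfig(),
    grid_config: GridConfig = GridConfig(),
    feature_spec: FeatureSpec = FeatureSpec(),
    lesion_polarity: str = "bright",
):
    """Features and labels for all kept patches of one synthetic image."""
    cond = condition_sample(sample, pre_config)
    grid = build_grid(
        cond.green.shape, cond.fov_mask, cond.od_mask, grid_config, image_id=image_id
    )
    lesion_mask = sample.bright_mask if lesion_polarity == "bright" else sample.dark_mask
    grid = label_patches(grid, lesion_mask)
    X, y = extract_features(cond, grid, feature_spec)
    return X, y, grid


def dataset_features(
    samples: list[SyntheticSample],
    pre_config: PreprocessConfig = PreprocessConfig(),
    grid_config: GridConfig = GridConfig(),
    feature_spec: FeatureSpec = FeatureSpec(),
    lesion_polarity: str = "bright",
):
    """Stacked features, labels and image-group ids for a dataset.

    When the preprocessing config carries no color reference, the median
    per-channel FOV statistics of the dataset itself are used (each image is
    normalized toward the dataset's typical appearance).
    """
    if pre_config.reference_mean is None:
        ref_mean, ref_std = dataset_reference_stats(
            [s.image for s in samples], [s.fov_mask for s in samples]
        )
        pre_config = dataclasses.replace(
            pre_config, reference_mean=tuple(ref_mean), reference_std=tuple(ref_std)
        )
    xs, ys, gs = [], [], []
    for i, sample in enumerate(samples):
        image_id = f"img{i:03d}"
        X, y, _grid = sample_features(
            sample, image_id, pre_config, grid_config, feature_spec, lesion_polarity
        )
        xs.append(X)
        ys.append(y)
        gs.append(np.full(len(y), i))
        logger.info("image %s: %d patches, %d pathological", image_id, len(y), int(y.sum()))
    return np.vstack(xs), np.concatenate(ys), np.concatenate(gs)


def run_patch_classification_experiment(
    n_pathological: int = 12,
    n_healthy: int = 8,
    image_size: int = 512,
    lesion_contrast: float = 0.5,
    classifier_kinds: tuple[str, ...] = ("rbf_svm", "random_forest"),
    n_seeds: int = 3,
    base_seed: int = 0,
    k_folds: int = 5,
    optimize_delta: bool = False,
    synthetic_overrides: dict | None = None,
) -> dict:
    """Scaled-down bright-lesion screening experiment on synthetic images.

    Images and features are generated once from ``base_seed``; the K-fold
    partition and committee permutations (the stochastic elements of the
    protocol) are repeated for ``n_seeds`` seeds and metrics averaged.
    Returns per-classifier fold tables and seed-mean summary metrics.
    """
    syn_kwargs = dict(
        image_width=image_size,
        image_height=image_size,
        n_exudates=8,
        n_microaneurysms=0,
        n_hemorrhages=0,
        lesion_contrast=lesion_contrast,
    )
    syn_kwargs.update(synthetic_overrides or {})
    syn_config = SyntheticConfig(**syn_kwargs)
    samples = generate_dataset(n_pathological, n_healthy, syn_config, base_seed=base_seed)
    X, y, groups = dataset_features(samples)
    results: dict = {
        "n_patches": int(len(y)),
        "n_pathological_patches": int(y.sum()),
        "classifiers": {},
    }
    for kind in classifier_kinds:
        tables = []
        for s in range(n_seeds):
            cfg = CommitteeConfig(
                classifier_kind=kind,
                k_folds=k_folds,
                rng_seed=base_seed + 1000 * s + 1,
                optimize_delta=optimize_delta,
            )
            table = crossvalidate(X, y, groups, cfg)
            table.insert(0, "seed", cfg.rng_seed)
            tables.append(table)
        all_folds = pd.concat(tables, ignore_index=True)
        folds_only = all_folds[~all_folds["fold"].isin(["mean", "std"])]
        results["classifiers"][kind] = {
            "table": all_folds,
            "mean_auc": float(folds_only["auc"].mean()),
            "std_auc": float(folds_only["auc"].std(ddof=1)),
            "mean_accuracy": float(folds_only["accuracy"].mean()),
            "mean_sensitivity": float(folds_only["sensitivity"].mean()),
            "mean_specificity": float(folds_only["specificity"].mean()),
            "mean_delta": float(folds_only["delta"].mean()),
        }
    return results
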