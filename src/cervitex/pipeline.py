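"""End-to-end convenience: tiles -> feature tables -> trained models -> report.

Glue used by the command-line interface, the test suite and the
reproduction script; each step simply chains the public module functions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from cervitex.classifier import DIVERGENCES, TrainedClassifier, train_classifier
from cervitex.image_io import GrayImage, new_manifest, split_train_test, tile_image
from cervitex.reporting import EvaluationReport, build_report
from cervitex.synthetic import SyntheticConfig, generate_gray_images
from cervitex.texture import FeatureMatrix, GLCMConfig, feature_matrix
from cervitex.wavelets import WAVELET_FAMILIES, WaveletSpec


def tile_images(images: Sequence[GrayImage]) -> list[GrayImage]:
    """Four quadrant tiles per source image, in source order."""
    tiles: list[GrayImage] = []
    for img in images:
        tiles.extend(tile_image(img))
    return tiles


def extract_features(tiles: Sequence[GrayImage],
                     families: Sequence[str] = WAVELET_FAMILIES,
                     config: GLCMConfig = GLCMConfig(),
                     level: int = 3) -> pd.DataFrame:
    """Feature table: one row per (tile, wavelet family), 40 feature columns."""
    rows = []
    for fam in families:
        spec = WaveletSpec(family=fam, level=level)
        for tile in tiles:
            fm: FeatureMatrix = feature_matrix(tile, spec, config)
            row = {"source_id": fm.source_id, "tile_index": fm.tile_index,
                   "modality": fm.modality, "label": fm.label, "family": fam}
            row.update(zip(FeatureMatrix.column_names(), fm.flatten()))
            rows.append(row)
    return pd.DataFrame(rows)


def split_feature_table(features: pd.DataFrame, seed: int,
                        by_source: bool = False
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified half/half split of a feature table at the tile level.

    The split is drawn once on the distinct (source_id, tile_index) tiles via
    the manifest splitter, then joined onto every per-family feature row, so
    all 16 families share the same train/test tiles.
    """
    tiles = features[["modality", "label", "source_id", "tile_index"]
                     ].drop_duplicates()
    manifest = new_manifest([
        {"path": "", "modality": r.modality, "label": r.label,
         "source_id": r.source_id, "tile_index": r.tile_index,
         "split": "unassigned"} for r in tiles.itertuples()])
    assigned = split_train_test(manifest, seed=seed, by_source=by_source)
    key = ["modality", "source_id", "tile_index"]
    merged = features.merge(assigned[key + ["split"]], on=key, how="left")
    return (merged[merged["split"] == "train"].drop(columns="split"),
            merged[merged["split"] == "test"].drop(columns="split"))


def train_all(train_features: pd.DataFrame,
              families: Sequence[str] = WAVELET_FAMILIES,
              divergences: Sequence[str] = DIVERGENCES,
              R: int = 10, alpha: float = 1.0,
              ) -> dict[tuple[str, str], TrainedClassifier]:
    """One classifier per (wavelet family, divergence type)."""
    models = {}
    for fam in families:
        sub = train_features[train_features["family"] == fam]
        for div in divergences:
            models[(fam, div)] = train_classifier(sub, div, family=fam,
                                                  R=R, alpha=alpha)
    return models


def run_synthetic_experiment(cfg: SyntheticConfig, modality: str,
                             families: Sequence[str] = WAVELET_FAMILIES,
                             divergences: Sequence[str] = DIVERGENCES,
                             split_seed: int | None = None,
                             glcm: GLCMConfig = GLCMConfig(),
                             ) -> EvaluationReport:
    """Generate, tile, split, extract, train and evaluate in one call."""
    images = generate_gray_images(cfg, modality)
    tiles = tile_images(images)
    features = extract_features(tiles, families=families, config=glcm)
    train_f, test_f = split_feature_table(
        features, seed=cfg.seed if split_seed is None else split_seed)
    models = train_all(train_f, families=families, divergences=divergences)
    return build_report(models, test_f, modality=modality,
                        families=families, algorithms=divergences)


def mean_per_class_recall(report: EvaluationReport) -> float:
    """Grand mean of the full-precision per-class recall grid, percent."""
    return float(np.mean(report.rates))
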