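"""Model fitting and cohort encoding: the offline database-building phase.

Per training set, the pipeline fits (1) a PCA reduction on a random sample
of raw ROI patches, (2) a GMM vocabulary (or k-means vocabulary for the
bag-of-words baseline) on a random sample of reduced descriptors, and then
encodes every case into a normalized signature.  All sampling uses seeds
derived deterministically from the global config seed, and draws only from
the cases it is given — evaluation code passes training folds only, so
test-fold pixels can never leak into the fitted models.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from ._logging import stage_timer
from .config import PipelineConfig, stage_seed
from .data import TumorCase
from .encoders import (
    GmmModel,
    ImageSignature,
    build_signature,
    fit_bow_vocabulary,
    fit_gmm,
)
from .metric import MetricModel
from .patches import PcaModel, apply_pca, extract_patches, fit_pca
from .roi import augment_tumor_region

__all__ = [
    "FeatureModels",
    "RunManifest",
    "fit_feature_models",
    "encode_cases",
    "save_models",
    "load_models",
]

_SCHEMA_VERSION = 1


@dataclass
class FeatureModels:
    """Fitted per-training-set models: PCA plus GMM or k-means vocabulary."""

    pca: PcaModel
    vocabulary: GmmModel | np.ndarray  # GmmModel (fv) or (K, d) centroids (bow)
    config: PipelineConfig


@dataclass
class RunManifest:
    """Everything needed to re-run a result bit-identically on one platform."""

    config: dict
    seed: int
    model_path: str | None = None
    data_dir: str | None = None
    outputs: dict | None = None
    timestamp: str = ""

    def save(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["timestamp"] = payload["timestamp"] or time.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        Path(path).write_text(json.dumps(payload, indent=2))


def _roi_coords(case: TumorCase, config: PipelineConfig) -> np.ndarray:
    roi = augment_tumor_region(case.tumor_mask, config.R)
    rows, cols = np.nonzero(roi.mask)
    return np.column_stack([rows, cols])


def _sample_patches(
    cases: Sequence[TumorCase],
    config: PipelineConfig,
    n_sample: int,
    seed: int,
    pca: PcaModel | None = None,
) -> np.ndarray:
    """Uniform random sample of (optionally PCA-reduced) ROI patches."""
    coords = [_roi_coords(c, config) for c in cases]
    counts = np.array([len(c) for c in coords])
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    take = min(n_sample, total)
    chosen = np.sort(rng.choice(total, size=take, replace=False))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    blocks = []
    for i, case in enumerate(cases):
        local = chosen[(chosen >= offsets[i]) & (chosen < offsets[i + 1])] - offsets[i]
        if local.size == 0:
            continue
        ps = extract_patches(case.image, coords[i][local], config.W)
        if pca is not None:
            ps = apply_pca(pca, ps)
        blocks.append(ps.descriptors)
    return np.vstack(blocks)


def fit_feature_models(
    cases: Sequence[TumorCase], config: PipelineConfig
) -> FeatureModels:
    """Fit PCA and the visual vocabulary on (training) cases only."""
    with stage_timer("fit_pca"):
        raw = _sample_patches(
            cases, config, config.pca_sample_size, stage_seed(config.seed, "pca")
        )
        pca = fit_pca(raw, config.pca_variance)
    with stage_timer(f"fit_vocabulary[{config.encoder}]"):
        reduced = _sample_patches(
            cases, config, config.gmm_sample_size, stage_seed(config.seed, "gmm"),
            pca=pca,
        )
        vocab_seed = stage_seed(config.seed, "vocab")
        if config.encoder == "fv":
            vocabulary: GmmModel | np.ndarray = fit_gmm(reduced, config.K, vocab_seed)
        else:
            vocabulary = fit_bow_vocabulary(reduced, config.K, vocab_seed)
    return FeatureModels(pca=pca, vocabulary=vocabulary, config=config)


def encode_cases(
    cases: Sequence[TumorCase], models: FeatureModels
) -> np.ndarray:
    """Stack the signatures of ``cases`` into an (n, F) matrix."""
    with stage_timer(f"encode[{len(cases)} cases]"):
        sigs = [
            build_signature(c, models.config, models.pca, models.vocabulary).values
            for c in cases
        ]
    return np.vstack(sigs)


def save_models(
    path: str | Path, models: FeatureModels, metric: MetricModel | None = None
) -> None:
    """Persist fitted models (PCA + vocabulary + optional metric) to HDF5."""
    import yaml

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["encoder"] = models.config.encoder
        f.attrs["config_yaml"] = yaml.safe_dump(asdict(models.config))
        g = f.create_group("pca")
        g.create_dataset("mean", data=models.pca.mean)
        g.create_dataset("components", data=models.pca.components)
        g.attrs["explained_fraction"] = models.pca.explained_fraction
        if models.config.encoder == "fv":
            g = f.create_group("gmm")
            g.create_dataset("weights", data=models.vocabulary.weights)
            g.create_dataset("means", data=models.vocabulary.means)
            g.create_dataset("variances", data=models.vocabulary.variances)
        else:
            f.create_dataset("bow_vocabulary", data=models.vocabulary)
        if metric is not None:
            g = f.create_group("metric")
            g.create_dataset("L", data=metric.L)
            g.create_dataset("eigenvalues", data=metric.eigenvalues)
            g.attrs["lambda_reg"] = metric.lambda_reg


def load_models(path: str | Path) -> tuple[FeatureModels, MetricModel | None]:
    import yaml

    with h5py.File(path, "r") as f:
        if int(f.attrs["schema_version"]) != _SCHEMA_VERSION:
            raise ValueError("unsupported model file schema version")
        config = PipelineConfig(**yaml.safe_load(f.attrs["config_yaml"]))
        pca = PcaModel(
            mean=np.asarray(f["pca/mean"]),
            components=np.asarray(f["pca/components"]),
            explained_fraction=float(f["pca"].attrs["explained_fraction"]),
        )
        if config.encoder == "fv":
            vocabulary: GmmModel | np.ndarray = GmmModel(
                weights=np.asarray(f["gmm/weights"]),
                means=np.asarray(f["gmm/means"]),
                variances=np.asarray(f["gmm/variances"]),
            )
        else:
            vocabulary = np.asarray(f["bow_vocabulary"])
        metric = None
        if "metric" in f:
            metric = MetricModel(
                L=np.asarray(f["metric/L"]),
                lambda_reg=float(f["metric"].attrs["lambda_reg"]),
                eigenvalues=np.asarray(f["metric/eigenvalues"]),
            )
    return FeatureModels(pca=pca, vocabulary=vocabulary, config=config), metric
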