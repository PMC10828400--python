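"""Gradient-boosted tree classification with leakage-safe cross-validation.

Training builds the AAP/AAT antigenicity scales from the given dataset,
encodes every peptide, and fits an XGBoost ensemble. In cross-validation
the scales are rebuilt from the k−1 training folds only, never from the
held-out fold: the scales are label-derived statistics, and building them
on the full data would leak test labels into the features.

Fitted models travel as a bundle directory — the serialized ensemble, the
exact scales and encoder configuration used, the ordered feature-name list
(hash-checked on load), and a fingerprint of the training data — so a
loaded model reproduces its predictions bit-for-bit and refuses
mismatched feature schemas.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xgboost as xgb
from xgboost import XGBClassifier

from epiboost.antigen_scales import (
    KmerScale,
    build_scale,
    count_kmers,
    load_scale,
    save_scale,
)
from epiboost.evaluation import METRIC_COLUMNS, MetricsReport, score_predictions
from epiboost.feature_encoding import EncoderConfig, encode_dataset
from epiboost.peptide_data import EpitopeDataset, FoldAssignment, stratified_folds

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "CVReport",
    "ModelBundleError",
    "train",
    "predict",
    "cross_validate",
    "grid_search",
    "save_model",
    "load_model",
    "default_grid",
]

_BUNDLE_SCHEMA = 1


class ModelBundleError(ValueError):
    """A persisted model bundle is missing pieces or fails integrity checks."""


@dataclass(frozen=True)
class ModelConfig:
    """XGBoost hyperparameters (desk-scale defaults; no values are published
    for this problem, so the grid in :func:`default_grid` is the standard
    small sweep)."""

    n_estimators: int = 200
    max_depth: int = 6
    learning_rate: float = 0.1
    subsample: float = 0.8
    colsample: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be positive")
        for name in ("learning_rate", "subsample", "colsample"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def to_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "subsample": self.subsample,
            "colsample": self.colsample,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def default_grid() -> list[ModelConfig]:
    """max_depth {3,6} × learning_rate {0.05,0.1} × n_estimators {100,300}."""
    return [
        ModelConfig(n_estimators=n, max_depth=d, learning_rate=lr)
        for d in (3, 6)
        for lr in (0.05, 0.1)
        for n in (100, 300)
    ]


@dataclass
class TrainedModel:
    booster: xgb.Booster
    feature_names: list[str]
    encoder_config: EncoderConfig
    aap: KmerScale
    aat: KmerScale
    model_config: ModelConfig
    training_fingerprint: str


@dataclass
class CVReport:
    """Per-fold metrics plus their mean/std, with the scales each fold used."""

    fold_reports: list[MetricsReport]
    mean: MetricsReport
    std: MetricsReport
    folds: FoldAssignment
    encoder_config: EncoderConfig
    model_config: ModelConfig
    fold_aap: list[KmerScale]
    fold_aat: list[KmerScale]

    def table(self) -> str:
        """CV table in fixed column order Pre, Sn, F1, ACC, MCC, AUROC."""
        header = "fold\t" + "\t".join(c.upper() for c in METRIC_COLUMNS)
        lines = [header]
        for i, rep in enumerate(self.fold_reports):
            lines.append(
                f"{i}\t" + "\t".join(f"{rep.as_dict()[c]:.4f}" for c in METRIC_COLUMNS)
            )
        for tag, rep in (("mean", self.mean), ("std", self.std)):
            lines.append(
                f"{tag}\t" + "\t".join(f"{rep.as_dict()[c]:.4f}" for c in METRIC_COLUMNS)
            )
        return "\n".join(lines)


def _fingerprint(dataset: EpitopeDataset) -> str:
    h = hashlib.sha256()
    for p in dataset:
        h.update(f"{p.id}\t{p.sequence}\t{p.label}\n".encode())
    return h.hexdigest()


def _make_xgb(config: ModelConfig, n_jobs: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        colsample_bytree=config.colsample,
        random_state=config.seed,
        n_jobs=n_jobs,
        tree_method="hist",
        eval_metric="logloss",
    )


def build_scales(
    dataset: EpitopeDataset, pseudocount: float = 1.0
) -> tuple[KmerScale, KmerScale]:
    """AAP (k=2) and AAT (k=3) scales from one labeled dataset."""
    dataset.require_both_classes()
    aap = build_scale(count_kmers(dataset, 2), pseudocount)
    aat = build_scale(count_kmers(dataset, 3), pseudocount)
    return aap, aat


def train(
    dataset: EpitopeDataset,
    provider,
    encoder_config: EncoderConfig | None = None,
    model_config: ModelConfig | None = None,
    pseudocount: float = 1.0,
    n_jobs: int = 1,
) -> TrainedModel:
    """Build scales from the full given dataset, encode, and fit.

    Deterministic for a fixed seed with ``n_jobs=1`` (the default).
    """
    encoder_config = encoder_config or EncoderConfig()
    model_config = model_config or ModelConfig()
    dataset.require_both_classes()
    aap, aat = build_scales(dataset, pseudocount)
    matrix = encode_dataset(dataset, aap, aat, provider, encoder_config)
    clf = _make_xgb(model_config, n_jobs)
    clf.fit(matrix.values, matrix.labels_array())
    return TrainedModel(
        booster=clf.get_booster(),
        feature_names=matrix.names,
        encoder_config=encoder_config,
        aap=aap,
        aat=aat,
        model_config=model_config,
        training_fingerprint=_fingerprint(dataset),
    )


def predict(model: TrainedModel, dataset: EpitopeDataset, provider) -> np.ndarray:
    """Per-peptide epitope probability in [0,1] using the model's stored scales."""
    if model.encoder_config.embedding == "on":
        if provider is None:
            raise ValueError("model expects an embedding provider")
        if provider.dim != model.encoder_config.embedding_dim:
            raise ValueError(
                f"provider dim {provider.dim} != model embedding dim "
                f"{model.encoder_config.embedding_dim}"
            )
    matrix = encode_dataset(
        dataset, model.aap, model.aat, provider, model.encoder_config
    )
    if matrix.names != model.feature_names:
        raise ValueError("feature schema mismatch between model and encoded data")
    # binary:logistic booster: predict() returns the positive-class probability
    return np.asarray(
        model.booster.predict(xgb.DMatrix(matrix.values)), dtype=float
    )


def cross_validate(
    dataset: EpitopeDataset,
    provider,
    encoder_config: EncoderConfig | None = None,
    model_config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    pseudocount: float = 1.0,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold CV with per-fold scale building (no label leakage)."""
    encoder_config = encoder_config or EncoderConfig()
    model_config = model_config or ModelConfig()
    dataset.require_both_classes()
    folds = stratified_folds(dataset, k, seed)
    fold_reports: list[MetricsReport] = []
    fold_aap: list[KmerScale] = []
    fold_aat: list[KmerScale] = []
    for fold in range(k):
        train_set = dataset.subset(folds.train_indices(fold), f"{dataset.name}/train{fold}")
        test_set = dataset.subset(folds.fold_indices(fold), f"{dataset.name}/test{fold}")
        model = train(
            train_set, provider, encoder_config, model_config, pseudocount
        )
        scores = predict(model, test_set, provider)
        fold_reports.append(
            score_predictions(scores, test_set.labels(), threshold=threshold)
        )
        fold_aap.append(model.aap)
        fold_aat.append(model.aat)
    values = {
        m: np.array([rep.as_dict()[m] for rep in fold_reports])
        for m in METRIC_COLUMNS
    }
    mean = MetricsReport(**{m: float(values[m].mean()) for m in METRIC_COLUMNS})
    std = MetricsReport(**{m: float(values[m].std(ddof=0)) for m in METRIC_COLUMNS})
    return CVReport(
        fold_reports=fold_reports,
        mean=mean,
        std=std,
        folds=folds,
        encoder_config=encoder_config,
        model_config=model_config,
        fold_aap=fold_aap,
        fold_aat=fold_aat,
    )


def grid_search(
    dataset: EpitopeDataset,
    provider,
    encoder_config: EncoderConfig | None = None,
    grid: list[ModelConfig] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[ModelConfig, list[tuple[ModelConfig, CVReport]]]:
    """CV every config; best = highest mean AUROC, ties by mean ACC, then
    first-in-grid."""
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    results: list[tuple[ModelConfig, CVReport]] = []
    best_idx = 0
    best_key = (-np.inf, -np.inf)
    for i, config in enumerate(grid):
        report = cross_validate(
            dataset, provider, encoder_config, config, k=k, seed=seed
        )
        results.append((config, report))
        key = (report.mean.auroc, report.mean.acc)
        if key > best_key:  # strict: first-in-grid wins ties
            best_key = key
            best_idx = i
    return grid[best_idx], results


def _names_hash(names: list[str]) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model bundle directory: ensemble JSON + scales + metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model.booster.save_model(str(path / "ensemble.json"))
    save_scale(model.aap, path / "aap.tsv")
    save_scale(model.aat, path / "aat.tsv")
    meta = {
        "schema_version": _BUNDLE_SCHEMA,
        "feature_names": model.feature_names,
        "feature_names_sha256": _names_hash(model.feature_names),
        "encoder_config": model.encoder_config.to_dict(),
        "model_config": model.model_config.to_dict(),
        "training_fingerprint": model.training_fingerprint,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    """Load a bundle; verifies schema version, files, and feature-list hash."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ModelBundleError(f"{path}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != _BUNDLE_SCHEMA:
        raise ModelBundleError(
            f"{path}: bundle schema {meta.get('schema_version')!r} not supported"
        )
    names = meta["feature_names"]
    if _names_hash(names) != meta.get("feature_names_sha256"):
        raise ModelBundleError(f"{path}: feature-name list fails integrity check")
    for fname in ("ensemble.json", "aap.tsv", "aat.tsv"):
        if not (path / fname).exists():
            raise ModelBundleError(f"{path}: missing bundle file {fname}")
    model_config = ModelConfig.from_dict(meta["model_config"])
    booster = xgb.Booster()
    booster.load_model(str(path / "ensemble.json"))
    return TrainedModel(
        booster=booster,
        feature_names=list(names),
        encoder_config=EncoderConfig.from_dict(meta["encoder_config"]),
        aap=load_scale(path / "aap.tsv"),
        aat=load_scale(path / "aat.tsv"),
        model_config=model_config,
        training_fingerprint=meta["training_fingerprint"],
    )
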