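"""Model training, data splitting, cross-validation and bootstrapping.

Training minimises mean-squared error (regression) or binary cross-entropy
(classification) with the adaptive-moment optimiser; early stopping halts
when the monitored validation metric has not improved for ``patience``
consecutive epochs, and the best-epoch parameters are restored.

Cross-validation follows a Monte-Carlo scheme: five independent seeded
70/15/15 train/validation/test splits, the per-split model selected by the
best validation R^2. Bootstrapped evaluation (for small classification
sets) resamples the training pool with replacement, validates on the
out-of-bag samples, selects the best epoch by validation AUC and averages
metrics across iterations.

All randomness (splits, resampling, initialisation, batch order) derives
from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor
from .featurize import (InteractionSample, LigandGraph, ProteinGraph,
                        ProteinStructure, build_ligand_graph,
                        build_protein_graph)
from .metrics import MetricReport, compute_report
from .model import CPIModel, ModelConfig
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "GraphCache", "split_indices", "train_model",
    "crossvalidate", "bootstrap_evaluate", "TrainResult",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 5e-5
    max_epochs: int = 100
    patience: int = 5
    folds: int = 5
    split_ratio: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    monitor: str = "loss"        # "loss" | "r2" | "auc" on the validation set
    early_stopping: bool = True

    def __post_init__(self):
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.split_ratio}")
        if self.early_stopping and self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class GraphCache:
    """Featurized graphs keyed by protein reference / SMILES string."""

    proteins: dict[str, ProteinGraph] = field(default_factory=dict)
    ligands: dict[str, LigandGraph] = field(default_factory=dict)

    @classmethod
    def build(cls, samples: list[InteractionSample],
              structures: dict[str, ProteinStructure],
              cutoff_angstrom: float = 8.0) -> "GraphCache":
        cache = cls()
        for s in samples:
            if s.protein_ref not in cache.proteins:
                cache.proteins[s.protein_ref] = build_protein_graph(
                    structures[s.protein_ref], cutoff_angstrom)
            if s.smiles not in cache.ligands:
                cache.ligands[s.smiles] = build_ligand_graph(s.smiles)
        return cache

    def pair(self, sample: InteractionSample) -> tuple[ProteinGraph, LigandGraph]:
        return self.proteins[sample.protein_ref], self.ligands[sample.smiles]


def split_indices(n: int, ratios: tuple[float, float, float],
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded random train/val/test partition of range(n)."""
    perm = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def _sample_loss(model: CPIModel, sample: InteractionSample,
                 cache: GraphCache) -> Tensor:
    pg, lg = cache.pair(sample)
    raw, _ = model.forward(pg, lg)
    y = float(sample.label)
    if model.config.task == "regression":
        return (raw - y) ** 2
    # numerically stable binary cross-entropy on the logit:
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    z = raw
    return z.relu() - z * y + (1.0 + (-(z.relu() * 2.0 - z)).exp()).log()


def _predictions(model: CPIModel, samples: list[InteractionSample],
                 cache: GraphCache) -> np.ndarray:
    return np.array([model.predict(*cache.pair(s)) for s in samples])


def _monitor_value(monitor: str, report: MetricReport, loss: float) -> float:
    """Higher is better."""
    if monitor == "loss":
        return -loss
    if monitor == "r2":
        return report.r2 if report.r2 is not None else -np.inf
    if monitor == "auc":
        return report.auc if report.auc is not None else -np.inf
    raise ValueError(f"unknown monitor {monitor!r}")


@dataclass
class TrainResult:
    model: CPIModel
    report: MetricReport            # validation report at the best epoch
    best_epoch: int
    history: list[dict]             # per-epoch train loss / val metrics


def train_model(model: CPIModel, samples: list[InteractionSample],
                cache: GraphCache, config: TrainConfig,
                val_samples: list[InteractionSample] | None = None
                ) -> TrainResult:
    """Train in place and return the best-epoch result.

    If ``val_samples`` is None, samples carrying ``split_tag`` "train"/"val"
    define the two pools.
    """
    if val_samples is None:
        train_pool = [s for s in samples if s.split_tag in (None, "train")]
        val_pool = [s for s in samples if s.split_tag == "val"]
    else:
        train_pool, val_pool = samples, val_samples
    if not train_pool or not val_pool:
        raise ValueError("empty train or validation split")

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, lr=config.learning_rate)
    best_value, best_epoch, best_params = -np.inf, -1, None
    stale = 0
    history: list[dict] = []
    val_truth = np.array([s.label for s in val_pool])

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_pool))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train_pool[i] for i in order[start:start + config.batch_size]]
            optimizer.zero_grad()
            total = None
            for s in batch:
                loss = _sample_loss(model, s, cache)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(batch))
            total.backward()
            optimizer.step(model.trainable)
            epoch_loss += total.item() * len(batch)
        epoch_loss /= len(train_pool)

        val_pred = _predictions(model, val_pool, cache)
        report = compute_report(val_pred, val_truth, model.config.task)
        if model.config.task == "regression":
            val_loss = float(np.mean((val_pred - val_truth) ** 2))
        else:
            eps = 1e-12
            val_loss = float(-np.mean(
                val_truth * np.log(val_pred + eps)
                + (1 - val_truth) * np.log(1 - val_pred + eps)))
        value = _monitor_value(config.monitor, report, val_loss)
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "val_loss": val_loss, "val": report.to_dict()})
        logger.info("epoch %d train_loss=%.5f val_loss=%.5f", epoch,
                    epoch_loss, val_loss)
        if value > best_value or best_params is None:
            best_value, best_epoch = value, epoch
            best_params = {k: v.data.copy() for k, v in model.params.items()}
            best_report = report
            stale = 0
        else:
            stale += 1
            if config.early_stopping and stale >= config.patience:
                break

    for k, v in best_params.items():
        model.params[k].data = v
    return TrainResult(model, best_report, best_epoch, history)


def evaluate(model: CPIModel, samples: list[InteractionSample],
             cache: GraphCache) -> MetricReport:
    pred = _predictions(model, samples, cache)
    truth = np.array([s.label for s in samples])
    return compute_report(pred, truth, model.config.task)


def crossvalidate(samples: list[InteractionSample], cache: GraphCache,
                  model_config: ModelConfig, config: TrainConfig,
                  checkpoint_dir: str | None = None
                  ) -> tuple[list[MetricReport], dict]:
    """Monte-Carlo cross-validation: ``folds`` seeded random 70/15/15
    splits; per-split the best-validation-R^2 (or monitored metric) model is
    evaluated on the held-out test split.

    With ``checkpoint_dir`` set, each fold's best model is saved under
    ``<checkpoint_dir>/fold<k>/best.npz``.
    """
    if config.folds < 2:
        raise ValueError("folds must be >= 2")
    if len(samples) < config.folds:
        raise ValueError("dataset smaller than the number of folds")
    reports: list[MetricReport] = []
    for fold in range(config.folds):
        fold_seed = config.seed * 1000 + fold
        rng = np.random.default_rng(fold_seed)
        tr, va, te = split_indices(len(samples), config.split_ratio, rng)
        model = CPIModel.new(model_config, seed=fold_seed + 1)
        monitor = config.monitor
        if model_config.task == "regression" and monitor == "loss":
            monitor = "r2"   # best validation R^2 selects the fold model
        result = train_model(model, [samples[i] for i in tr], cache,
                             replace(config, seed=fold_seed, monitor=monitor),
                             val_samples=[samples[i] for i in va])
        reports.append(evaluate(result.model, [samples[i] for i in te], cache))
        logger.info("fold %d: test metrics %s", fold, reports[-1].to_dict())
        if checkpoint_dir is not None:
            from pathlib import Path

            result.model.save(Path(checkpoint_dir) / f"fold{fold}" / "best.npz")
    summary = _summarize(reports)
    return reports, summary


def _summarize(reports: list[MetricReport]) -> dict:
    keys = ("rmse", "r2", "auc", "accuracy", "precision", "recall")
    out = {}
    for key in keys:
        values = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if values:
            out[f"{key}_mean"] = float(np.mean(values))
            out[f"{key}_sd"] = float(np.std(values))
    return out


def bootstrap_evaluate(samples: list[InteractionSample], cache: GraphCache,
                       model_config: ModelConfig, config: TrainConfig,
                       iterations: int = 100,
                       base_model: CPIModel | None = None
                       ) -> tuple[MetricReport, dict]:
    """Bootstrapped evaluation for small classification sets.

    Each iteration resamples the training pool with replacement (same
    size), validates on the out-of-bag samples, picks the best epoch by
    validation AUC, and the final report averages metrics over iterations.
    Iterations whose out-of-bag pool is single-class are skipped and
    counted. When ``base_model`` is given it is cloned per iteration
    (fine-tuning); otherwise a fresh model is initialised.
    """
    if model_config.task != "classification":
        raise ValueError("bootstrap evaluation is defined for classification")
    rng = np.random.default_rng(config.seed)
    reports, skipped = [], 0
    n = len(samples)
    for it in range(iterations):
        idx = rng.integers(0, n, size=n)
        oob = sorted(set(range(n)) - set(idx.tolist()))
        train_pool = [samples[i] for i in idx]
        val_pool = [samples[i] for i in oob]
        labels = {s.label for s in val_pool}
        if len(val_pool) == 0 or len(labels) < 2:
            skipped += 1
            logger.info("bootstrap iteration %d skipped (single-class "
                        "out-of-bag pool)", it)
            continue
        if base_model is not None:
            model = base_model.clone()
        else:
            model = CPIModel.new(model_config, seed=int(rng.integers(2**31)))
        result = train_model(
            model, train_pool, cache,
            replace(config, seed=int(rng.integers(2**31)), monitor="auc"),
            val_samples=val_pool)
        reports.append(result.report)
    if not reports:
        raise ValueError("all bootstrap iterations were skipped")
    averaged = MetricReport(n=n)
    for key in ("rmse", "r2", "auc", "accuracy", "precision", "recall",
                "re_pre_threshold"):
        values = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if values:
            setattr(averaged, key, float(np.mean(values)))
    detail = {"iterations": len(reports), "skipped": skipped,
              "auc_values": [r.auc for r in reports]}
    return averaged, detail
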