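"""Leave-one-out cross-validation with nested hyperparameter selection.

Each of the n samples serves once as the held-out test set (all of its
spectra); a second sample is drawn at random from the remainder as the
validation set used only to pick hyperparameters.  Per fold, one network per
grid point (10 learning rates x 4 minimum deltas by default) is trained on
the remaining n-2 samples' spectra, the grid point with the highest
validation accuracy wins (ties broken by lowest validation loss), and the
winning network predicts the test sample's spectra.  Aggregated predictions
over all folds give the confusion matrix and the accuracy
n_correct / n_total.

Two sensitivity experiments reuse the machinery with fixed hyperparameters
(learning rate 0.005, minimum delta 0.001): per-wavelength-window LOOCV with
a one-way ANOVA / Fisher's LSD comparison of per-fold accuracies, and a
resolution sweep over 15 reduction factors K spaced logarithmically between
10 and 1000.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import spectra as sp
from .cnn import (CLASS_LABELS, NetworkSpec, TrainedModel,
                  TrainingConfig, predict_classes, train_population)

logger = logging.getLogger(__name__)

CLASS_TO_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


class LeakageError(RuntimeError):
    """A test or validation spectrum appeared in a training set."""


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    test_sample_id: str
    validation_sample_id: str
    training_sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.test_sample_id == self.validation_sample_id \
                or self.test_sample_id in self.training_sample_ids \
                or self.validation_sample_id in self.training_sample_ids:
            raise ValueError("fold split leaks test/validation samples")


@dataclass(frozen=True)
class HyperGrid:
    learning_rates: tuple[float, ...] = tuple(
        np.geomspace(1e-4, 1e-2, 10))
    min_deltas: tuple[float, ...] = (0.001, 0.003, 0.005, 0.007)

    def __post_init__(self) -> None:
        if len(self.learning_rates) == 0 or len(self.min_deltas) == 0:
            raise ValueError("hyperparameter grid must be non-empty")
        if np.any(np.diff(self.learning_rates) <= 0):
            raise ValueError("learning rates must be strictly increasing")

    def points(self) -> list[tuple[float, float]]:
        return [(lr, md) for lr in self.learning_rates
                for md in self.min_deltas]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (3, 3), rows true class, columns predicted

    @classmethod
    def from_predictions(cls, y_true: np.ndarray,
                         y_pred: np.ndarray) -> "ConfusionMatrix":
        from sklearn.metrics import confusion_matrix
        m = confusion_matrix(y_true, y_pred, labels=[0, 1, 2])
        return cls(counts=m)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))


def accuracy(confusion: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    if confusion.n_total == 0:
        raise ValueError("empty confusion matrix")
    return confusion.n_correct / confusion.n_total


@dataclass
class FoldResult:
    fold: FoldSplit
    chosen_learning_rate: float
    chosen_min_delta: float
    validation_accuracy: float
    validation_loss: float
    test_true: np.ndarray
    test_pred: np.ndarray

    @property
    def test_accuracy(self) -> float:
        return float(np.mean(self.test_true == self.test_pred))


@dataclass
class LOOCVReport:
    folds: list[FoldResult]
    confusion: ConfusionMatrix

    @property
    def per_fold_accuracies(self) -> np.ndarray:
        return np.array([f.test_accuracy for f in self.folds])

    @property
    def aggregate_accuracy(self) -> float:
        return accuracy(self.confusion)

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        acc = self.per_fold_accuracies
        return float(acc.std(ddof=1)) if acc.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "aggregate_accuracy": self.aggregate_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion_matrix": self.confusion.counts.tolist(),
            "folds": [{
                "fold_index": f.fold.fold_index,
                "test_sample": f.fold.test_sample_id,
                "validation_sample": f.fold.validation_sample_id,
                "learning_rate": f.chosen_learning_rate,
                "min_delta": f.chosen_min_delta,
                "validation_accuracy": f.validation_accuracy,
                "validation_loss": f.validation_loss,
                "test_accuracy": f.test_accuracy,
            } for f in self.folds],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class SpectraDataset:
    """Preprocessed spectra plus per-sample class labels.

    ``X`` holds one preprocessed (concatenated) spectrum per row;
    ``sample_ids[i]`` names row i's source sample, and ``sample_classes``
    maps each sample id to 'low' / 'medium' / 'high'.
    """

    X: np.ndarray
    sample_ids: np.ndarray
    sample_classes: dict[str, str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        missing = set(np.unique(self.sample_ids)) - set(self.sample_classes)
        if missing:
            raise ValueError(f"samples without class labels: {sorted(missing)}")

    @property
    def unique_samples(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.sample_ids.tolist()))

    def y(self) -> np.ndarray:
        return np.array([CLASS_TO_INDEX[self.sample_classes[s]]
                         for s in self.sample_ids])

    def rows_for(self, sample_ids) -> np.ndarray:
        return np.isin(self.sample_ids, list(sample_ids))

    def downsampled(self, K: float) -> "SpectraDataset":
        return SpectraDataset(sp.downsample_array(self.X, K),
                              self.sample_ids, self.sample_classes)


def make_loocv_folds(sample_ids, seed: int = 0) -> list[FoldSplit]:
    """One fold per sample as test, with a random validation sample."""
    ids = list(dict.fromkeys(sample_ids))
    if len(ids) < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    rng = np.random.default_rng(seed)
    folds = []
    for i, test in enumerate(ids):
        rest = [s for s in ids if s != test]
        val = rest[int(rng.integers(len(rest)))]
        train = tuple(s for s in rest if s != val)
        folds.append(FoldSplit(i, test, val, train))
    return folds


def _select_best(results: list[dict]) -> dict:
    """Highest validation accuracy; ties resolved by lowest validation loss."""
    best = results[0]
    for r in results[1:]:
        if (r["validation_accuracy"] > best["validation_accuracy"]
            or (r["validation_accuracy"] == best["validation_accuracy"]
                and r["validation_loss"] < best["validation_loss"])):
            best = r
    return best


def _fold_seed(seed: int, fold_index: int, grid_index: int) -> int:
    return int(np.random.SeedSequence(
        [seed & 0x7FFFFFFF, fold_index, grid_index]).generate_state(1)[0]
        & 0x7FFFFFFF)


def _check_leakage(dataset: SpectraDataset, fold: FoldSplit,
                   train_mask: np.ndarray) -> None:
    held_out = dataset.rows_for([fold.test_sample_id,
                                 fold.validation_sample_id])
    if np.any(train_mask & held_out):
        raise LeakageError(
            f"fold {fold.fold_index}: test/validation spectra present in the "
            "training set")


def grid_search_fold(fold: FoldSplit, dataset: SpectraDataset,
                     grid: HyperGrid, net_spec: NetworkSpec = NetworkSpec(),
                     base_config: TrainingConfig = TrainingConfig(),
                     seed: int = 0) -> tuple[TrainingConfig, TrainedModel,
                                             dict]:
    """Train one network per grid point; return the winning config and model.

    Validation accuracy is computed on the validation sample's spectra after
    restoring the best (minimum-training-loss) weights; the highest accuracy
    wins, with ties broken by the lowest validation loss.
    """
    points = grid.points()
    train_mask = dataset.rows_for(fold.training_sample_ids)
    _check_leakage(dataset, fold, train_mask)
    val_mask = dataset.rows_for([fold.validation_sample_id])
    y = dataset.y()
    Xtr, ytr = dataset.X[train_mask], y[train_mask]
    Xval, yval = dataset.X[val_mask], y[val_mask]

    configs = [replace(base_config, learning_rate=lr, min_delta=md,
                       seed=_fold_seed(seed, fold.fold_index, gi))
               for gi, (lr, md) in enumerate(points)]
    trained_models = train_population(
        dataset.X.shape[1], net_spec, configs, Xtr, ytr,
        perm_seed=_fold_seed(seed, fold.fold_index, len(points)))
    results = []
    for cfg, trained in zip(configs, trained_models):
        pred, _ = predict_classes(trained, Xval)
        results.append({
            "config": cfg,
            "model": trained,
            "validation_accuracy": float(np.mean(pred == yval)),
            "validation_loss": trained.network.loss(Xval, yval),
        })
    best = _select_best(results)
    logger.info("fold %d: lr=%.5g min_delta=%.3g val_acc=%.3f",
                fold.fold_index, best["config"].learning_rate,
                best["config"].min_delta, best["validation_accuracy"])
    return best["config"], best["model"], best


def run_loocv(dataset: SpectraDataset,
              grid: HyperGrid = HyperGrid(),
              net_spec: NetworkSpec = NetworkSpec(),
              base_config: TrainingConfig = TrainingConfig(),
              downsample_K: float | None = None,
              seed: int = 0) -> LOOCVReport:
    """Nested LOOCV over all samples; aggregate confusion matrix and report.

    ``downsample_K`` optionally reduces spectral resolution (factor-K linear
    interpolation) before training.  A hard :class:`LeakageError` is raised if
    any held-out spectrum would enter a training set.
    """
    y_all = dataset.y()
    if np.unique(y_all).size < 1 or dataset.X.shape[0] == 0:
        raise ValueError("empty dataset")
    if downsample_K is not None:
        dataset = dataset.downsampled(downsample_K)
    folds = make_loocv_folds(dataset.unique_samples, seed=seed)
    y = dataset.y()
    fold_results = []
    all_true, all_pred = [], []
    for fold in folds:
        cfg, model, best = grid_search_fold(fold, dataset, grid, net_spec,
                                            base_config, seed=seed)
        test_mask = dataset.rows_for([fold.test_sample_id])
        pred, _ = predict_classes(model, dataset.X[test_mask])
        fold_results.append(FoldResult(
            fold=fold,
            chosen_learning_rate=cfg.learning_rate,
            chosen_min_delta=cfg.min_delta,
            validation_accuracy=best["validation_accuracy"],
            validation_loss=best["validation_loss"],
            test_true=y[test_mask],
            test_pred=pred,
        ))
        all_true.append(y[test_mask])
        all_pred.append(pred)
    confusion = ConfusionMatrix.from_predictions(np.concatenate(all_true),
                                                 np.concatenate(all_pred))
    return LOOCVReport(folds=fold_results, confusion=confusion)


# ---------------------------------------------------------------------------
# sensitivity experiments
# ---------------------------------------------------------------------------

FIXED_SESSION_CONFIG = TrainingConfig(learning_rate=0.005, min_delta=0.001)

STUDY_WINDOWS_NM = ((500.0, 700.0), (700.0, 900.0), (900.0, 1100.0))


def fisher_lsd(groups: list[np.ndarray], alpha: float = 0.05):
    """One-way ANOVA plus Fisher's least-significant-difference pairs.

    Pairwise t statistics use the ANOVA's pooled mean-square error with
    N - g degrees of freedom.  Returns (F, p, significant pair index tuples).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0, ()
    F, p = stats.f_oneway(*arrays)
    if np.isnan(F):
        F, p = 0.0, 1.0
    n_total = sum(a.size for a in arrays)
    df_within = n_total - len(arrays)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / df_within
    sig = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a, b = arrays[i], arrays[j]
            if mse == 0:
                different = a.mean() != b.mean()
                pij = 0.0 if different else 1.0
            else:
                t = abs(a.mean() - b.mean()) / np.sqrt(
                    mse * (1.0 / a.size + 1.0 / b.size))
                pij = 2.0 * stats.t.sf(t, df_within)
            if pij < alpha:
                sig.append((i, j))
    return float(F), float(p), tuple(sig)


def wavelength_sensitivity_experiment(
        records, sample_classes: dict[str, str],
        net_spec: NetworkSpec = NetworkSpec(),
        train_config: TrainingConfig = FIXED_SESSION_CONFIG,
        windows=STUDY_WINDOWS_NM,
        filter_spec: sp.FilterSpec = sp.FilterSpec(),
        downsample_K: float | None = None,
        seed: int = 0) -> dict:
    """Per-wavelength-window LOOCV accuracies with an ANOVA/LSD comparison.

    ``records`` are raw per-fiber spectra; each window is cut per fiber
    before concatenation, then a fixed-hyperparameter LOOCV (single-point
    grid) runs per window.  Returns per-window reports, per-fold accuracy
    lists, and the Fisher's LSD comparison at alpha = 0.05.
    """
    grid = HyperGrid(learning_rates=(train_config.learning_rate,),
                     min_deltas=(train_config.min_delta,))
    reports = {}
    for window in windows:
        X, sids = sp.preprocess_dataset(records, filter_spec, window=window,
                                        downsample_K=downsample_K)
        ds = SpectraDataset(X, sids, sample_classes)
        reports[window] = run_loocv(ds, grid, net_spec, train_config,
                                    seed=seed)
    acc_lists = [reports[w].per_fold_accuracies for w in windows]
    F, p, sig = fisher_lsd(acc_lists, alpha=0.05)
    return {
        "windows": tuple(windows),
        "reports": reports,
        "per_fold_accuracies": acc_lists,
        "mean_accuracies": [float(a.mean()) for a in acc_lists],
        "F_statistic": F,
        "p_value": p,
        "significant_pairs": sig,
    }


def resolution_scale_schedule(n_scales: int = 15, k_min: float = 10.0,
                              k_max: float = 1000.0) -> np.ndarray:
    """K values spaced logarithmically between k_min and k_max inclusive."""
    return np.geomspace(k_min, k_max, n_scales)


def resolution_sensitivity_experiment(
        dataset: SpectraDataset,
        net_spec: NetworkSpec = NetworkSpec(),
        train_config: TrainingConfig = FIXED_SESSION_CONFIG,
        scales: np.ndarray | None = None,
        seed: int = 0) -> pd.DataFrame:
    """Fixed-hyperparameter LOOCV per resolution-reduction factor K.

    Returns a table with one row per K: mean and SD of per-fold accuracies
    and the aggregate accuracy.  Raises if a K leaves the spectra shorter
    than the network's minimum input length.
    """
    if scales is None:
        scales = resolution_scale_schedule()
    grid = HyperGrid(learning_rates=(train_config.learning_rate,),
                     min_deltas=(train_config.min_delta,))
    rows = []
    for K in scales:
        try:
            report = run_loocv(dataset, grid, net_spec, train_config,
                               downsample_K=float(K), seed=seed)
        except Exception as err:  # re-raise naming the failing scale
            raise RuntimeError(
                f"resolution factor K={K:.4g} failed: {err}") from err
        rows.append({"K": float(K),
                     "mean_accuracy": report.mean_accuracy,
                     "sd_accuracy": report.sd_accuracy,
                     "aggregate_accuracy": report.aggregate_accuracy})
    return pd.DataFrame(rows)
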