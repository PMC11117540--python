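"""Stratified 10-fold cross-validation, classification metrics, KW screening.

Metrics (positive class = alcoholic = label 1): sensitivity, specificity,
precision, accuracy and F1 are reported as percentages rounded to one
decimal; Cohen's kappa stays on its natural [-1, 1] scale. Folds are
stratified so that 240 balanced samples give the 216-train / 24-test split
per fold with 12 + 12 test samples per class. Per-feature class contrast
can be screened with the Kruskal-Wallis rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifiers import ClassifierConfig, predict, train
from .selection import ensemble_select

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "METRIC_NAMES",
    "stratified_kfold",
    "compute_metrics",
    "kruskal_wallis",
    "run_cv",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "f1", "kappa")


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn,
            self.tn + other.tn, self.fp + other.fp,
        )


@dataclass
class CVReport:
    folds: list[ConfusionCounts]
    mean_metrics: dict[str, float]
    fold_sizes: list[tuple[int, int]]  # (train, test) per fold
    fold_metrics: list[dict[str, float]] = field(default_factory=list)
    selected_per_fold: list[list[int]] = field(default_factory=list)

    @property
    def pooled(self) -> ConfusionCounts:
        c = ConfusionCounts(0, 0, 0, 0)
        for f in self.folds:
            c = c + f
        return c


def stratified_kfold(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Seeded stratified partition: list of k disjoint test-index arrays.

    Indices are shuffled within each class and dealt into k folds so every
    fold's class ratio is within one sample of the global ratio.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"k={k} exceeds the size of class {cls!r} ({idx.size} samples)"
            )
        rng.shuffle(idx)
        for fold_id, chunk in enumerate(np.array_split(idx, k)):
            folds[fold_id].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, decimals: int | None = 1) -> dict[str, float]:
    """The six metrics from a confusion table.

    Percentages (sensitivity, specificity, precision, accuracy, F1) are
    rounded to ``decimals`` places (None = no rounding); kappa is reported
    on [-1, 1].
    """
    n = c.total
    if n == 0:
        raise ValueError("empty confusion table")
    sens = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_div(c.tn, c.tn + c.fp, "specificity")
    prec = _safe_div(c.tp, c.tp + c.fp, "precision")
    acc = (c.tp + c.tn) / n
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1")
    p_o = acc
    p_e = ((c.tp + c.fn) * (c.tp + c.fp) + (c.tn + c.fp) * (c.tn + c.fn)) / n**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    out = {
        "sensitivity": sens * 100.0,
        "specificity": spec * 100.0,
        "precision": prec * 100.0,
        "accuracy": acc * 100.0,
        "f1": f1 * 100.0,
        "kappa": kappa,
    }
    if decimals is not None:
        out = {
            k: round(v, decimals if k != "kappa" else 3) for k, v in out.items()
        }
    return out


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value for two or more value groups.

    Identical data in every group (zero rank variance) is reported as
    H = 0, p = 1.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig,
    k: int = 10,
    seed: int = 0,
    select_k: int | None = None,
    select_mode: str = "ensemble",
    select_in_fold: bool = True,
    select_weights=None,
) -> CVReport:
    """Stratified k-fold evaluation of one classifier configuration.

    If ``select_k`` is given, ensemble feature selection to ``select_k``
    features runs inside each training fold (default) so the test fold never
    influences the chosen subset; ``select_in_fold=False`` instead selects
    once on the full matrix before splitting (the optimistic variant some
    study protocols imply).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    folds = stratified_kfold(y, k=k, seed=seed)
    all_idx = np.arange(y.size)

    global_sel: list[int] | None = None
    if select_k is not None and not select_in_fold:
        global_sel = ensemble_select(
            X, y, k=select_k, mode=select_mode, weights=select_weights
        ).selected

    confusions: list[ConfusionCounts] = []
    fold_sizes: list[tuple[int, int]] = []
    fold_metrics: list[dict[str, float]] = []
    selected_per_fold: list[list[int]] = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        if select_k is not None:
            sel = (
                ensemble_select(
                    X_tr, y_tr, k=select_k, mode=select_mode, weights=select_weights
                ).selected
                if select_in_fold
                else global_sel
            )
            selected_per_fold.append(list(sel))
            X_tr, X_te = X_tr[:, sel], X_te[:, sel]
        model = train(config, X_tr, y_tr)
        pred, _ = predict(model, X_te)
        c = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (y_te == 1))),
            fn=int(np.sum((pred == 0) & (y_te == 1))),
            tn=int(np.sum((pred == 0) & (y_te == 0))),
            fp=int(np.sum((pred == 1) & (y_te == 0))),
        )
        confusions.append(c)
        fold_sizes.append((train_idx.size, test_idx.size))
        fold_metrics.append(compute_metrics(c, decimals=None))

    mean_metrics = {
        name: round(
            float(np.mean([fm[name] for fm in fold_metrics])),
            1 if name != "kappa" else 3,
        )
        for name in METRIC_NAMES
    }
    return CVReport(
        folds=confusions,
        mean_metrics=mean_metrics,
        fold_sizes=fold_sizes,
        fold_metrics=fold_metrics,
        selected_per_fold=selected_per_fold,
    )
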