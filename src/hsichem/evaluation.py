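"""Data partitioning and model-evaluation metrics.

Regression metrics follow the standard chemometric definitions:

    R^2  = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RMSE = sqrt( sum (yhat_i - y_i)^2 / n )
    RPD  = sigma_y / RMSEP

with the 1/n denominator in RMSE and the population SD of the prediction
partition's reference values in RPD.  Classification metrics (accuracy,
precision, recall, F1, Cohen's kappa) come from the confusion matrix with
one-vs-rest collapse and macro averaging; kappa uses

    K = (Po - Pe) / (1 - Pe),  Po = trace/total,
    Pe = sum_i (row_i * col_i) / total^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplitPlan",
    "RegressionMetrics",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "stratified_split",
    "kfold_indices",
    "regression_metrics",
    "confusion_matrix",
    "classification_metrics",
    "classification_report_grid",
    "quantification_report",
]


@dataclass(frozen=True)
class SplitPlan:
    """Partition fractions (must sum to 1) plus the seed that fixes the draw."""

    fractions: tuple[float, ...] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("partition fractions must sum to 1")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("partition fractions must be positive")


def _largest_remainder(n: int, fractions) -> np.ndarray:
    quotas = np.asarray(fractions) * n
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    short = n - counts.sum()
    for j in np.argsort(-rem, kind="stable")[:short]:
        counts[j] += 1
    return counts


def stratified_split(labels, plan: SplitPlan = SplitPlan()) -> list[np.ndarray]:
    """Per-class proportional allocation (largest-remainder rounding), seeded.

    Returns one sorted index array per partition; partitions are disjoint and
    exhaustive.  Raises when a class is too small to appear in every
    partition.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(plan.seed)
    k = len(plan.fractions)
    parts: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} samples; cannot fill {k} partitions"
            )
        counts = _largest_remainder(idx.size, plan.fractions)
        if counts.min() == 0:            # force representation in every partition
            for j in np.where(counts == 0)[0]:
                donor = int(np.argmax(counts))
                counts[donor] -= 1
                counts[j] += 1
        rng.shuffle(idx)
        start = 0
        for j, c in enumerate(counts):
            parts[j].extend(idx[start : start + c].tolist())
            start += c
    return [np.sort(np.array(p)) for p in parts]


def kfold_indices(n: int, k: int, seed: int = 0, stratify=None) -> list[np.ndarray]:
    """Seeded folds of near-equal size (difference <= 1), optionally stratified."""
    if k > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    if stratify is None:
        idx = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(idx, k)]
    stratify = np.asarray(stratify)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(stratify):
        idx = np.where(stratify == cls)[0]
        rng.shuffle(idx)
        for i, sample in enumerate(idx):       # round-robin keeps sizes near-equal
            folds[(offset + i) % k].append(int(sample))
        offset += idx.size
    return [np.sort(np.array(f)) for f in folds]


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    sd_reference: float

    @property
    def rpd(self) -> float:
        """sigma_y / RMSE; undefined (raises) for an error-free prediction."""
        if self.rmse == 0:
            raise ValueError("RPD undefined: RMSE is zero")
        return self.sd_reference / self.rmse


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero-variance reference values: R^2 and RPD undefined")
    resid = y_pred - y_true
    ss_res = float(resid @ resid)
    return RegressionMetrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(ss_res / y_true.size)),
        sd_reference=float(y_true.std()),      # population SD (n denominator)
    )


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_matrix(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Counts[i, j] = samples of true class i predicted as class j."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = tuple(np.unique(np.concatenate([y_true, y_pred])))
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    per_class: pd.DataFrame = field(repr=False, default=None)


def classification_metrics(
    cm: ConfusionMatrix, average: str = "macro"
) -> ClassificationMetrics:
    """Accuracy, one-vs-rest precision/recall/F1 (macro by default) and kappa."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    row = counts.sum(axis=1)       # support (true counts per class)
    col = counts.sum(axis=0)       # predicted counts per class
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    if average == "macro":
        w = np.full(len(tp), 1.0 / len(tp))
    elif average == "weighted":
        w = row / total
    else:
        raise ValueError("average must be 'macro' or 'weighted'")
    po = tp.sum() / total
    pe = float(row @ col) / total**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": row},
        index=list(cm.classes),
    )
    return ClassificationMetrics(
        accuracy=float(po),
        precision=float(precision @ w),
        recall=float(recall @ w),
        f1=float(f1 @ w),
        kappa=float(kappa),
        per_class=per_class,
    )


def classification_report_grid(
    spectra,
    labels,
    chains,
    specs,
    plan: SplitPlan = SplitPlan(),
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Chain x model accuracy grid over train/validation/test splits plus CV.

    Mirrors the layout of a pre-processing comparison table: one row per
    (model, data-set) pair, one column per chain.
    """
    from .models import train_classifier

    spectra = np.asarray(spectra, dtype=float)
    labels = np.asarray(labels)
    train, val, test = stratified_split(labels, plan)
    rows = {}
    for spec in specs:
        for chain in chains:
            model = train_classifier(spectra[train], labels[train], spec, chain=chain)
            accs = {}
            for part, idx in (("Training", train), ("Validation", val), ("Test", test)):
                pred = model.predict(spectra[idx])
                cmx = confusion_matrix(labels[idx], pred)
                accs[part] = 100.0 * classification_metrics(cmx).accuracy
            # k-fold CV accuracy on the full set
            correct = 0
            for fold in kfold_indices(len(labels), cv_folds, seed, stratify=labels):
                rest = np.setdiff1d(np.arange(len(labels)), fold)
                m = train_classifier(spectra[rest], labels[rest], spec, chain=chain)
                correct += int((m.predict(spectra[fold]) == labels[fold]).sum())
            accs["Cross-validation"] = 100.0 * correct / len(labels)
            for part, acc in accs.items():
                rows.setdefault((spec.kind, part), {})[chain.name] = round(acc, 2)
    df = pd.DataFrame(rows).T
    df.index.names = ["model", "data_set"]
    return df


def quantification_report(results: list[dict]) -> pd.DataFrame:
    """Assemble calibration/prediction rows into the standard results table.

    Each entry carries: constituent, model, selection method, EW count, and
    the calibration/prediction metric objects.
    """
    rows = []
    for r in results:
        cal, pred = r["calibration"], r["prediction"]
        rows.append(
            {
                "constituent": r["constituent"],
                "model": r["model"],
                "selection": r["selection"],
                "n_ews": r["n_ews"],
                "Rc2": round(cal.r2, 4),
                "RMSEC": round(cal.rmse, 4),
                "Rp2": round(pred.r2, 4),
                "RMSEP": round(pred.rmse, 4),
                "RPD": round(pred.rpd, 4),
            }
        )
    return pd.DataFrame(rows)
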