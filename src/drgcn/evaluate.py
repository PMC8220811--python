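"""K-fold cross-validation with AUROC / AUPRC reporting.

Cases are shuffled once under the run seed and partitioned into k folds; a
fresh CNN is trained per fold on the other k-1 folds and scored on the held-
out fold.  The headline numbers are the arithmetic means of the per-fold
AUROC and AUPRC ("fold-mean"); pooled out-of-fold metrics are computed
alongside.  AUROC is the trapezoidal area under the ROC curve, equal to the
Mann-Whitney probability that a positive outscores a negative (ties counted
half).  AUPRC is the step-wise (non-interpolated) area under the precision-
recall curve, whose chance baseline is the positive prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .errors import InvalidInputError, UndefinedMetricError
from .features import SampleFeatureTensor
from .nn import CNNConfig, build_model, predict_proba, train

logger = logging.getLogger(__name__)


@dataclass
class FoldCurves:
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation metrics."""

    fold_auroc: list[float]
    fold_auprc: list[float]
    mean_auroc: float
    mean_auprc: float
    fold_assignments: dict[str, int]
    seed: int
    pooled_auroc: float | None = None
    pooled_auprc: float | None = None
    curves: list[FoldCurves] = field(default_factory=list)
    fold_train_ids: list[list[str]] = field(default_factory=list)
    fold_test_ids: list[list[str]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.fold_auroc)


def kfold_split(
    case_ids: Sequence[str], k: int = 10, seed: int = 0
) -> dict[str, int]:
    """Shuffle cases and partition into k folds of size floor(m/k) or ceil(m/k).

    The first ``m mod k`` folds receive the extra case.  Deterministic under
    the seed; folds are disjoint and cover all cases.
    """
    case_ids = [str(c) for c in case_ids]
    m = len(case_ids)
    if k < 2:
        raise InvalidInputError(f"k must be >= 2, got {k}")
    if m < k:
        raise InvalidInputError(f"cannot split {m} cases into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    base, extra = divmod(m, k)
    assignment: dict[str, int] = {}
    pos = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        for idx in order[pos : pos + size]:
            assignment[case_ids[idx]] = fold
        pos += size
    return assignment


def compute_auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (trapezoidal / Mann-Whitney)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise InvalidInputError(f"labels {y.shape} vs scores {s.shape}")
    if np.unique(y).size < 2:
        raise UndefinedMetricError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(y, s))


def compute_auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise InvalidInputError(f"labels {y.shape} vs scores {s.shape}")
    if not np.any(y == 1):
        raise UndefinedMetricError("AUPRC undefined: no positive labels")
    return float(average_precision_score(y, s))


def cross_validate(
    features: SampleFeatureTensor | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    cnn_config: CNNConfig,
    k: int = 10,
    seed: int = 0,
    case_ids: Sequence[str] | None = None,
    max_reshuffles: int = 10,
) -> CVResult:
    """Run shuffled k-fold cross-validation of the CNN classifier.

    Each fold trains a freshly initialized model on the k-1 training folds
    only (the held-out fold never touches fitting).  If a shuffle leaves some
    training fold single-class, the split is redrawn with an incremented seed
    (logged).  Per-fold ROC and PR coordinates are retained for export.
    """
    if isinstance(features, SampleFeatureTensor):
        x = features.values
        ids = list(features.sample_ids) if case_ids is None else [str(c) for c in case_ids]
    else:
        x = np.asarray(features)
        ids = (
            [str(c) for c in case_ids]
            if case_ids is not None
            else [f"case_{i}" for i in range(x.shape[0])]
        )
    y = np.asarray(labels, dtype=np.int64)
    if y.shape[0] != x.shape[0] or len(ids) != x.shape[0]:
        raise InvalidInputError("features, labels and case ids must agree in length")
    if np.unique(y).size < 2:
        raise UndefinedMetricError("cross-validation needs both classes present")

    split_seed = seed
    for attempt in range(max_reshuffles):
        assignment = kfold_split(ids, k=k, seed=split_seed)
        fold_of = np.array([assignment[c] for c in ids])
        ok = all(np.unique(y[fold_of != f]).size == 2 for f in range(k))
        if ok:
            break
        logger.warning(
            "split seed %d left a single-class training fold; reshuffling", split_seed
        )
        split_seed += 1
    else:
        raise UndefinedMetricError(
            f"no valid split found in {max_reshuffles} reshuffles"
        )

    fold_auroc: list[float] = []
    fold_auprc: list[float] = []
    curves: list[FoldCurves] = []
    train_ids: list[list[str]] = []
    test_ids: list[list[str]] = []
    oof_scores = np.full(y.shape[0], np.nan)
    for f in range(k):
        tr = fold_of != f
        te = fold_of == f
        cfg = replace(cnn_config, seed=cnn_config.seed + f)
        model = build_model(cfg, tuple(x.shape[1:]))
        fitted = train(model, x[tr], y[tr], cfg)
        probs = predict_proba(fitted, x[te])
        scores = probs[:, 1]  # positive class = metastasis
        oof_scores[te] = scores
        if np.unique(y[te]).size == 2:
            fold_auroc.append(compute_auroc(y[te], scores))
            fold_auprc.append(compute_auprc(y[te], scores))
            fpr, tpr, _ = roc_curve(y[te], scores)
            prec, rec, _ = precision_recall_curve(y[te], scores)
            curves.append(FoldCurves(fpr=fpr, tpr=tpr, precision=prec, recall=rec))
        else:
            logger.warning("fold %d is single-class in the test split; skipped", f)
        train_ids.append([c for c, keep in zip(ids, tr) if keep])
        test_ids.append([c for c, keep in zip(ids, te) if keep])

    if not fold_auroc:
        raise UndefinedMetricError("every test fold was single-class")
    return CVResult(
        fold_auroc=fold_auroc,
        fold_auprc=fold_auprc,
        mean_auroc=float(np.mean(fold_auroc)),
        mean_auprc=float(np.mean(fold_auprc)),
        fold_assignments=assignment,
        seed=seed,
        pooled_auroc=compute_auroc(y, oof_scores),
        pooled_auprc=compute_auprc(y, oof_scores),
        curves=curves,
        fold_train_ids=train_ids,
        fold_test_ids=test_ids,
    )


def export_results(result: CVResult, outdir: str | Path, plot: bool = True) -> None:
    """Write metrics TSV, per-fold curve CSVs and summary plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "metrics.tsv", "w") as fh:
        fh.write("fold\tauroc\tauprc\n")
        for f, (a, p) in enumerate(zip(result.fold_auroc, result.fold_auprc)):
            fh.write(f"{f}\t{a:.6f}\t{p:.6f}\n")
        fh.write(f"mean\t{result.mean_auroc:.6f}\t{result.mean_auprc:.6f}\n")
    for f, c in enumerate(result.curves):
        with open(outdir / f"roc_fold{f}.csv", "w") as fh:
            fh.write("fpr,tpr\n")
            for a, b in zip(c.fpr, c.tpr):
                fh.write(f"{a:.6f},{b:.6f}\n")
        with open(outdir / f"pr_fold{f}.csv", "w") as fh:
            fh.write("recall,precision\n")
            for a, b in zip(c.recall, c.precision):
                fh.write(f"{a:.6f},{b:.6f}\n")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
        for f, c in enumerate(result.curves):
            axes[0].plot(c.fpr, c.tpr, alpha=0.6, lw=1)
            axes[1].plot(c.recall, c.precision, alpha=0.6, lw=1)
        axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
        axes[0].set(xlabel="FPR", ylabel="TPR",
                    title=f"ROC (mean AUROC {result.mean_auroc:.3f})")
        axes[1].set(xlabel="recall", ylabel="precision",
                    title=f"PR (mean AUPRC {result.mean_auprc:.3f})")
        fig.tight_layout()
        fig.savefig(outdir / "curves.png", dpi=120)
        plt.close(fig)
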