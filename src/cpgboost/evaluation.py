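"""Evaluation metrics and the feature-analysis experiment drivers.

Eight measurements are reported for every model: accuracy, precision,
sensitivity (SE), specificity (SP), F-score, Matthews correlation
coefficient, AUC (ROC) and AUPR.  The thresholded metrics follow the
standard confusion-matrix formulas; any zero denominator yields 0 by
convention (flagged in the report).  AUC/AUPR are computed with
scikit-learn's estimators (trapezoidal ROC, step-wise precision-recall).

Two experiment drivers reproduce the package's feature analyses on any
dataset: the skip-k distance-decay experiment (how fast neighbor
information decays with neighbor rank) and the importance-ranked top-k
feature sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import FeatureMatrix, ModelConfig, TrainedModel, predict, train
from .positional import skip_k_feature_names, skip_k_matrix
from .profiles import MultiCellDataset, SplitSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Confusion:
    """Binary confusion counts (positive class = methylated)."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvalReport:
    """The eight measurements plus the underlying confusion counts.

    ``degenerate`` lists the metrics whose denominator was zero and which
    were therefore set to 0 by convention.
    """

    Acc: float
    Precision: float
    SE: float
    SP: float
    Fscore: float
    MCC: float
    AUC: float = float("nan")
    AUPR: float = float("nan")
    confusion: Confusion | None = None
    degenerate: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        out = {k: getattr(self, k)
               for k in ("Acc", "Precision", "SE", "SP", "Fscore", "MCC", "AUC", "AUPR")}
        if self.confusion is not None:
            out.update({k: getattr(self.confusion, k) for k in ("TP", "TN", "FP", "FN")})
        return out


def confusion(labels: np.ndarray, states: np.ndarray) -> Confusion:
    """Confusion counts of predicted binary states against labels."""
    y = np.asarray(labels).astype(np.int64)
    p = np.asarray(states).astype(np.int64)
    if y.shape != p.shape:
        raise ValueError("labels and states must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and states must be binary")
    return Confusion(
        TP=int(((y == 1) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(c: Confusion) -> EvalReport:
    """Thresholded metrics from confusion counts; zero denominators give 0."""
    if c.n < 1:
        raise ValueError("empty confusion matrix")
    degenerate: list[str] = []
    acc = (c.TP + c.TN) / c.n
    precision = _ratio(c.TP, c.TP + c.FP, "Precision", degenerate)
    se = _ratio(c.TP, c.TP + c.FN, "SE", degenerate)
    sp = _ratio(c.TN, c.TN + c.FP, "SP", degenerate)
    fscore = _ratio(2 * precision * se, precision + se, "Fscore", degenerate)
    mcc_den = math.sqrt(
        float(c.TP + c.FP) * float(c.TN + c.FN) * float(c.TP + c.FN) * float(c.TN + c.FP)
    )
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC", degenerate)
    if degenerate:
        logger.debug("zero-denominator metrics set to 0: %s", degenerate)
    return EvalReport(Acc=acc, Precision=precision, SE=se, SP=sp,
                      Fscore=fscore, MCC=mcc, confusion=c,
                      degenerate=tuple(degenerate))


def auc_roc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal over the full threshold set)."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def auc_pr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (step integration)."""
    return float(average_precision_score(np.asarray(labels), np.asarray(scores)))


def evaluate(labels: np.ndarray, scores: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Full report from probability scores: thresholded metrics at
    ``threshold`` plus AUC/AUPR."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    states = (scores >= threshold).astype(np.int8)
    base = metrics(confusion(labels, states))
    return EvalReport(**{**base.__dict__,
                         "AUC": auc_roc(labels, scores),
                         "AUPR": auc_pr(labels, scores)})


# ---------------------------------------------------------------------------
# Experiment drivers


def _skip_k_table(dataset: MultiCellDataset, chroms, k: int, mode: str):
    """Pooled skip-k feature rows over all cells for the given chromosomes."""
    Xs, ys = [], []
    kwargs = {"k1": k} if mode == "rank_pair" else {"k2": k}
    for cell in dataset.cells:
        for chrom in chroms:
            pos_arr, state_arr = cell.labeled(chrom)
            if len(pos_arr) == 0:
                continue
            Xs.append(skip_k_matrix(cell, chrom, pos_arr, mode=mode, **kwargs))
            ys.append(state_arr)
    if not Xs:
        raise ValueError("no labeled sites on the requested chromosomes")
    names = skip_k_feature_names(k1=k, k2=k, mode=mode)
    X = pd.DataFrame(np.vstack(Xs), columns=names)
    y = pd.Series(np.concatenate(ys).astype(np.int8), name="label")
    return FeatureMatrix(X.set_index(pd.RangeIndex(len(X))), y,
                         {c: "pos" for c in names})


def skip_k_experiment(
    dataset: MultiCellDataset,
    k_values,
    split: SplitSpec,
    mode: str = "rank_pair",
    cfg: ModelConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one model per neighbor rank k on skip-k features only.

    Rows are pooled over all cells; train/test chromosomes come from
    ``split``.  Returns a table with one row per k and the eight
    measurements on the test partition.
    """
    if cfg is None:
        cfg = ModelConfig(threads=1)
    rows = []
    for k in k_values:
        train_fm = _skip_k_table(dataset, split.train_chroms, k, mode)
        test_fm = _skip_k_table(dataset, split.test_chroms, k, mode)
        model = train(train_fm, ModelConfig(**{**cfg.__dict__, "seed": seed}))
        scores = predict(model, test_fm)
        report = evaluate(test_fm.y.to_numpy(), scores)
        rows.append({"k": k, **report.to_dict()})
    return pd.DataFrame(rows).set_index("k")


def topk_sweep(
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    importance: pd.Series,
    k_list,
    cfg: ModelConfig | None = None,
) -> pd.DataFrame:
    """Retrain on the top-k most important columns for each k.

    ``importance`` is a split-count Series (descending; ties by name, as
    produced by ``aggregate_importance``).  Reports the eight measurements
    on the held-out matrix per dimension k.
    """
    if cfg is None:
        cfg = ModelConfig(threads=1)
    ranked = [c for c in importance.index if c in train_fm.X.columns]
    rows = []
    for k in k_list:
        k = int(min(k, len(ranked)))
        cols = ranked[:k]
        model = train(train_fm.select_columns(cols), cfg)
        scores = predict(model, test_fm.select_columns(cols))
        report = evaluate(test_fm.y.to_numpy(), scores)
        rows.append({"dimension": k, **report.to_dict()})
    return pd.DataFrame(rows).set_index("dimension")


def report_table(reports: dict) -> pd.DataFrame:
    """Tabulate {name: EvalReport} into a tidy frame."""
    return pd.DataFrame({name: rep.to_dict() for name, rep in reports.items()}).T
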