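"""Cross-validation protocols, metrics and disease-query candidate ranking.

Four protocols are provided: leave-one-out over known positives, k-fold
over positives, and the two cold-start tests in which entire disease rows
(horizontal) or microbe columns (vertical) are withheld.  In every round
the GIP similarities and the heterogeneous graph are rebuilt from the
masked training matrix, so held-out labels never reach the model through
similarity profiles.  Masked positives are treated as negatives in the
training loss, the standard matrix-completion convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score

from .config import RunConfig
from .datatypes import (
    AssociationMatrix,
    SampleSets,
    ScoreMatrix,
    SimilarityMatrix,
)

__all__ = [
    "EvalResult",
    "RankedCandidates",
    "auc",
    "threshold_metrics",
    "loocv",
    "kfold_cv",
    "horizontal_test",
    "vertical_test",
    "rank_candidates",
]

# optional audit hook: called with (fold_id, A_train, test_positive_cells)
RoundCallback = Callable[[int, AssociationMatrix, list], None]

_METRICS = ("auc", "f1", "accuracy", "sensitivity", "specificity")


@dataclass
class EvalResult:
    """Per-fold and aggregate metrics for one protocol run."""

    protocol: str
    per_fold: list
    threshold: float
    mean: dict = field(init=False)
    sd: dict = field(init=False)

    def __post_init__(self) -> None:
        keys = self.per_fold[0].keys() if self.per_fold else _METRICS
        self.mean = {
            k: float(np.mean([f[k] for f in self.per_fold])) for k in keys
        }
        self.sd = {
            k: float(np.std([f[k] for f in self.per_fold], ddof=1))
            if len(self.per_fold) > 1 else 0.0
            for k in keys
        }

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "threshold": self.threshold,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
        }


@dataclass(frozen=True)
class RankedCandidates:
    """Top-ranked previously unknown microbes for one query disease."""

    disease_id: str
    entries: tuple  # (microbe_id, score, rank), scores non-increasing


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at a fixed decision threshold.

    F1 is defined as 0 when there are no positive predictions.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(labels) if len(labels) else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * sens / (precision + sens)) if precision + sens else 0.0
    return {"f1": f1, "accuracy": acc, "sensitivity": sens, "specificity": spec}


def _fold_metrics(scores, labels, threshold) -> dict:
    out = {"auc": auc(scores, labels)}
    out.update(threshold_metrics(scores, labels, threshold))
    return out


def loocv(
    A: AssociationMatrix,
    config: RunConfig,
    fd: SimilarityMatrix | None = None,
    fm: SimilarityMatrix | None = None,
    on_round: RoundCallback | None = None,
) -> EvalResult:
    """Leave-one-out over known positives with one pooled AUC.

    Each known association is zeroed in a training copy; the model is
    refit from scratch and the held-out pair's score is pooled (as a
    positive) with that round's scores of all never-associated pairs
    (negatives).  A single global AUC over all rounds is reported.
    """
    positives = list(zip(*np.nonzero(A.values == 1)))
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least two known associations")
    zero_cells = A.values == 0
    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    for r, (i, j) in enumerate(positives):
        masked = A.values.copy()
        masked[i, j] = 0.0
        A_train = A.with_values(masked)
        if on_round is not None:
            on_round(r, A_train, [(int(i), int(j))])
        scores = _fit_predict_values(A_train, config, fd, fm)
        pooled_scores.append(float(scores[i, j]))
        pooled_labels.append(1)
        pooled_scores.extend(scores[zero_cells].tolist())
        pooled_labels.extend([0] * int(zero_cells.sum()))
    global_auc = auc(pooled_scores, pooled_labels)
    fold = {"auc": global_auc}
    fold.update(threshold_metrics(pooled_scores, pooled_labels, config.threshold))
    return EvalResult("loocv", [fold], config.threshold)


def kfold_cv(
    A: AssociationMatrix,
    config: RunConfig,
    k: int = 5,
    seed: int = 0,
    fd: SimilarityMatrix | None = None,
    fm: SimilarityMatrix | None = None,
    on_round: RoundCallback | None = None,
) -> EvalResult:
    """k-fold cross-validation over known positives.

    Positives are partitioned into k seeded folds (sizes differing by at
    most one); each fold is zeroed for training and its held-out positives
    are scored against all never-associated pairs.
    """
    positives = np.array(list(zip(*np.nonzero(A.values == 1))))
    if len(positives) < k:
        raise ValueError(f"{k}-fold CV needs at least {k} known associations")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds = np.array_split(order, k)
    zero_cells = A.values == 0
    neg_scores_cells = np.nonzero(zero_cells)
    per_fold = []
    for fid, fold_idx in enumerate(folds):
        held = positives[fold_idx]
        masked = A.values.copy()
        masked[held[:, 0], held[:, 1]] = 0.0
        A_train = A.with_values(masked)
        if on_round is not None:
            on_round(fid, A_train, [(int(i), int(j)) for i, j in held])
        scores = _fit_predict_values(A_train, config, fd, fm)
        s = np.concatenate([
            scores[held[:, 0], held[:, 1]],
            scores[neg_scores_cells],
        ])
        y = np.concatenate([
            np.ones(len(held)), np.zeros(len(neg_scores_cells[0]))
        ])
        per_fold.append(_fold_metrics(s, y, config.threshold))
    return EvalResult("kfold", per_fold, config.threshold)


def _fit_predict_values(A_train, config, fd, fm, samples=None) -> np.ndarray:
    from .pipeline import fit_predict

    return fit_predict(A_train, config, fd=fd, fm=fm, samples=samples).values


def horizontal_test(
    A: AssociationMatrix,
    config: RunConfig,
    fraction: float = 0.2,
    seed: int = 0,
    n_repeats: int = 5,
    fd: SimilarityMatrix | None = None,
    fm: SimilarityMatrix | None = None,
    on_round: RoundCallback | None = None,
) -> EvalResult:
    """Disease cold-start test: whole rows withheld from training.

    A seeded ``fraction`` of disease rows is fully zeroed in the training
    matrix; every cell of the held-out rows is scored against its true
    label.  Repeated ``n_repeats`` times with derived seeds; mean and sd
    over repeats are reported.  A draw whose held-out rows contain no
    positive is resampled.
    """
    nd = A.n_diseases
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n_held = max(1, int(round(fraction * nd)))
    if n_held >= nd:
        raise ValueError("fraction would hold out every disease row")
    rng = np.random.default_rng(seed)
    per_fold = []
    for rep in range(n_repeats):
        for _ in range(100):
            held_rows = rng.choice(nd, size=n_held, replace=False)
            if A.values[held_rows].sum() > 0:
                break
        else:
            raise ValueError("could not draw a held-out set containing a positive")
        masked = A.values.copy()
        masked[held_rows] = 0.0
        A_train = A.with_values(masked)
        test_cells = [
            (int(i), int(j)) for i in held_rows for j in range(A.n_microbes)
            if A.values[i, j] == 1
        ]
        if on_round is not None:
            on_round(rep, A_train, test_cells)
        # held-out rows are excluded from the training loss entirely: the
        # model must not be taught that their cells are negatives
        train_rows = np.setdiff1d(np.arange(nd), held_rows)
        train_cells = SampleSets(
            frozenset((int(i), int(j)) for i in train_rows
                      for j in np.nonzero(masked[i] == 1)[0]),
            frozenset((int(i), int(j)) for i in train_rows
                      for j in np.nonzero(masked[i] == 0)[0]),
        )
        scores = _fit_predict_values(A_train, config, fd, fm, train_cells)
        s = scores[held_rows].ravel()
        y = A.values[held_rows].ravel()
        per_fold.append(_fold_metrics(s, y, config.threshold))
    return EvalResult("horizontal", per_fold, config.threshold)


def vertical_test(
    A: AssociationMatrix,
    config: RunConfig,
    fraction: float = 0.2,
    seed: int = 0,
    n_repeats: int = 5,
    fd: SimilarityMatrix | None = None,
    fm: SimilarityMatrix | None = None,
    on_round: RoundCallback | None = None,
) -> EvalResult:
    """Microbe cold-start test: whole columns withheld from training.

    Implemented as the horizontal protocol on the transposed association
    matrix with the disease/microbe roles (and their functional-similarity
    inputs) swapped, so the two protocols mirror each other exactly.
    """
    A_t = AssociationMatrix(A.values.T, A.microbe_ids, A.disease_ids)
    result = horizontal_test(
        A_t, config, fraction=fraction, seed=seed, n_repeats=n_repeats,
        fd=fm, fm=fd, on_round=on_round,
    )
    result.protocol = "vertical"
    return result


def rank_candidates(
    scores: ScoreMatrix,
    A: AssociationMatrix,
    disease_id: str,
    top_k: int = 20,
) -> RankedCandidates:
    """Top-k previously unknown microbes for one disease, by score.

    Microbes already associated with the query disease are excluded; ties
    are broken by input microbe order (stable sort).
    """
    if disease_id not in A.disease_ids:
        raise KeyError(f"unknown disease id {disease_id!r}")
    i = A.disease_ids.index(disease_id)
    unknown = [j for j in range(A.n_microbes) if A.values[i, j] == 0]
    if top_k > len(unknown):
        raise ValueError(
            f"top_k={top_k} exceeds the {len(unknown)} unknown pairs for "
            f"{disease_id!r}"
        )
    row = scores.values[i]
    order = sorted(unknown, key=lambda j: -row[j])  # stable: ties keep input order
    entries = tuple(
        (A.microbe_ids[j], float(row[j]), rank + 1)
        for rank, j in enumerate(order[:top_k])
    )
    return RankedCandidates(disease_id, entries)
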