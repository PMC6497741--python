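"""Leave-one-out cross-validation and rank-based ROC/AUC.

Three LOOCV regimes:

global
    Remove one known association at a time, refit on the remaining
    network, and rank the held-out pair among all pairs unknown in the
    full dataset (plus itself).
isolated disease
    Remove a disease's entire association row, refit, and rank each of
    its true miRNAs among that disease's non-associated miRNAs (plus the
    held-out one).  Only the disease-similarity channel can score such a
    row.
new miRNA
    The column-wise mirror, rescued only by the miRNA-similarity
    channel.

Each held-out positive contributes one fold.  A fold's rank (1-based,
ties share the average rank) is converted to a percentile
``p = (rank - 0.5) / candidates``; the ROC sweeps a threshold t over
[0, 1] with ``TPR(t) = fraction of folds with p <= t`` and
``FPR(t) = t``, so the area under the curve is exactly
``1 - mean(p)``.  Being rank-based, the AUC is invariant to any strictly
monotone transform of the scores, so no cross-fold score calibration is
assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .containers import (
    BipartiteAssociation,
    FamilyAnnotation,
    SimilarityMatrix,
)
from .model import BHCN, BHCNParams

__all__ = [
    "FoldResult",
    "roc_auc",
    "loocv_global",
    "loocv_isolated_disease",
    "loocv_new_mirna",
]


@dataclass(frozen=True)
class FoldResult:
    """Outcome of ranking one held-out positive.

    ``rank`` is 1-based among ``candidates`` scored pairs (ties get the
    average rank), so ``1 <= rank <= candidates``.
    """

    held_out: tuple[str, str] | str
    rank: float
    candidates: int

    def __post_init__(self):
        if not 1.0 <= self.rank <= self.candidates:
            raise ValueError(
                f"rank {self.rank} outside [1, {self.candidates}]"
            )

    @property
    def percentile(self) -> float:
        return (self.rank - 0.5) / self.candidates


def _average_rank(candidate_scores: np.ndarray, held_out_score: float) -> float:
    """1-based descending rank of the held-out score, averaging ties.

    ``candidate_scores`` must include the held-out score itself.
    """
    greater = int((candidate_scores > held_out_score).sum())
    equal = int((candidate_scores == held_out_score).sum())
    return greater + (equal + 1) / 2.0


def roc_auc(folds: list[FoldResult]) -> tuple[pd.DataFrame, float]:
    """Pool fold percentiles into a ROC curve and its exact area.

    Returns a DataFrame of (FPR, TPR) points (with both sides of every
    jump, so trapezoidal integration over the points is exact) and the
    AUC ``1 - mean(percentile)``.
    """
    if not folds:
        raise ValueError("cannot compute a ROC curve from zero folds")
    p = np.array([f.percentile for f in folds])
    n = len(p)
    fpr_pts = [0.0]
    tpr_pts = [float((p <= 0.0).sum()) / n]
    for v in np.unique(p):
        below = float((p < v).sum()) / n
        at_or_below = float((p <= v).sum()) / n
        fpr_pts += [float(v), float(v)]
        tpr_pts += [below, at_or_below]
    fpr_pts.append(1.0)
    tpr_pts.append(1.0)
    roc = pd.DataFrame({"FPR": fpr_pts, "TPR": tpr_pts})
    auc = float(1.0 - p.mean())
    return roc, auc


def _as_model(model: BHCN | BHCNParams | None) -> BHCN:
    if model is None:
        return BHCN()
    if isinstance(model, BHCNParams):
        return model.to_estimator()
    return clone(model)


def _fit_scores(
    train: BipartiteAssociation,
    sm: SimilarityMatrix | None,
    sd: SimilarityMatrix | None,
    fam: FamilyAnnotation | None,
    model: BHCN,
) -> np.ndarray:
    fitted = clone(model).fit(
        train,
        mirna_similarity=sm,
        disease_similarity=sd,
        family=fam,
    )
    return fitted.scores_.matrix


def loocv_global(
    assoc: BipartiteAssociation,
    sm: SimilarityMatrix | None = None,
    sd: SimilarityMatrix | None = None,
    fam: FamilyAnnotation | None = None,
    model: BHCN | BHCNParams | None = None,
) -> tuple[list[FoldResult], pd.DataFrame, float]:
    """Single-association-removal LOOCV.

    For every known pair, the pair is removed, the model refit on the
    remaining network (all association-derived quantities — degrees,
    co-neighbor counts, clamping, and the functional disease similarity
    where the scenario reconstructs it — are recomputed), and the
    held-out pair is ranked among the dataset's unknown pairs plus
    itself.
    """
    model = _as_model(model)
    if assoc.n_associations < 2:
        raise ValueError("global LOOCV needs at least 2 known associations")
    unknown_mask = assoc.matrix == 0
    folds: list[FoldResult] = []
    for i, j in np.argwhere(assoc.matrix == 1):
        train_mat = assoc.matrix.copy()
        train_mat[i, j] = 0
        scores = _fit_scores(assoc.with_matrix(train_mat), sm, sd, fam, model)
        candidate_scores = np.append(scores[unknown_mask], scores[i, j])
        rank = _average_rank(candidate_scores, scores[i, j])
        folds.append(
            FoldResult(
                held_out=(assoc.disease_ids[i], assoc.mirna_ids[j]),
                rank=rank,
                candidates=candidate_scores.size,
            )
        )
    roc, auc = roc_auc(folds)
    return folds, roc, auc


def loocv_isolated_disease(
    assoc: BipartiteAssociation,
    sm: SimilarityMatrix | None = None,
    sd: SimilarityMatrix | None = None,
    fam: FamilyAnnotation | None = None,
    model: BHCN | BHCNParams | None = None,
) -> tuple[list[FoldResult], pd.DataFrame, float]:
    """Whole-row-removal LOOCV simulating isolated diseases.

    Each disease with at least one association has its entire row
    removed; each of its true miRNAs is then ranked among the disease's
    non-associated miRNAs plus itself.
    """
    model = _as_model(model)
    deg_d = assoc.matrix.sum(axis=1)
    if int((deg_d > 0).sum()) < 2:
        raise ValueError(
            "isolated-disease LOOCV needs at least 2 diseases with associations"
        )
    folds: list[FoldResult] = []
    for i in np.flatnonzero(deg_d > 0):
        train_mat = assoc.matrix.copy()
        train_mat[i, :] = 0
        scores = _fit_scores(assoc.with_matrix(train_mat), sm, sd, fam, model)
        negatives = np.flatnonzero(assoc.matrix[i] == 0)
        for j in np.flatnonzero(assoc.matrix[i] == 1):
            candidate_scores = np.append(scores[i, negatives], scores[i, j])
            rank = _average_rank(candidate_scores, scores[i, j])
            folds.append(
                FoldResult(
                    held_out=(assoc.disease_ids[i], assoc.mirna_ids[j]),
                    rank=rank,
                    candidates=candidate_scores.size,
                )
            )
    roc, auc = roc_auc(folds)
    return folds, roc, auc


def loocv_new_mirna(
    assoc: BipartiteAssociation,
    sm: SimilarityMatrix | None = None,
    sd: SimilarityMatrix | None = None,
    fam: FamilyAnnotation | None = None,
    model: BHCN | BHCNParams | None = None,
) -> tuple[list[FoldResult], pd.DataFrame, float]:
    """Whole-column-removal LOOCV simulating new miRNAs.

    The column-wise mirror of :func:`loocv_isolated_disease`.
    """
    model = _as_model(model)
    deg_m = assoc.matrix.sum(axis=0)
    if int((deg_m > 0).sum()) < 2:
        raise ValueError(
            "new-miRNA LOOCV needs at least 2 miRNAs with associations"
        )
    folds: list[FoldResult] = []
    for j in np.flatnonzero(deg_m > 0):
        train_mat = assoc.matrix.copy()
        train_mat[:, j] = 0
        scores = _fit_scores(assoc.with_matrix(train_mat), sm, sd, fam, model)
        negatives = np.flatnonzero(assoc.matrix[:, j] == 0)
        for i in np.flatnonzero(assoc.matrix[:, j] == 1):
            candidate_scores = np.append(scores[negatives, j], scores[i, j])
            rank = _average_rank(candidate_scores, scores[i, j])
            folds.append(
                FoldResult(
                    held_out=(assoc.disease_ids[i], assoc.mirna_ids[j]),
                    rank=rank,
                    candidates=candidate_scores.size,
                )
            )
    roc, auc = roc_auc(folds)
    return folds, roc, auc
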