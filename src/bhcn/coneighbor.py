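"""Bipartite co-neighbor counting and the eight local structural indexes.

In a bipartite disease-miRNA network two nodes of different classes never
share a common neighbor, so the classical common-neighbor link-prediction
indexes do not apply directly.  The co-neighbor construction replaces the
common-neighbor count with the number of *simple paths of three edges*
``d_i -> m' -> d' -> m_j`` joining a disease to a miRNA (all four nodes
distinct).  That count, ``NCN``, is then normalized by the endpoint
degrees under one of eight local indexes (CN, Salton, Jaccard, Sørensen,
HPI, HDI, LHN1, PA) to give the initial association score.
"""

from __future__ import annotations

import numpy as np

from .containers import BipartiteAssociation, ScoreMatrix, degrees

__all__ = ["INDEXES", "count_simple_paths3", "initial_score"]

#: The eight local structural indexes, canonical capitalization.
INDEXES = ("CN", "Salton", "Jaccard", "Sorensen", "HPI", "HDI", "LHN1", "PA")

_INDEX_ALIASES = {name.lower(): name for name in INDEXES}
_INDEX_ALIASES["sørensen"] = "Sorensen"


def normalize_index_name(index: str) -> str:
    """Canonicalize an index name (case-insensitive); raise on unknown."""
    key = str(index).lower()
    if key not in _INDEX_ALIASES:
        raise ValueError(
            f"unknown index {index!r}; valid indexes are {', '.join(INDEXES)}"
        )
    return _INDEX_ALIASES[key]


def count_simple_paths3(assoc: BipartiteAssociation) -> ScoreMatrix:
    """Count simple length-3 paths between every disease-miRNA pair.

    ``NCN(i,j)`` is the number of paths ``d_i -> m' -> d' -> m_j`` with
    all four nodes distinct.  Computed in closed form: the walk count
    ``A A^T A`` counts every length-3 walk; a walk is non-simple only
    when it reuses the edge ``(d_i, m_j)`` (as ``m' = m_j`` or
    ``d' = d_i``), which requires ``A(i,j) = 1``, and there are exactly
    ``deg(d_i) + deg(m_j) - 1`` such degenerate walks.
    """
    a = assoc.matrix.astype(np.int64)
    walks = a @ a.T @ a
    deg_d, deg_m = degrees(assoc)
    correction = a * (deg_d[:, None] + deg_m[None, :] - 1)
    ncn = walks - correction
    return ScoreMatrix(assoc.disease_ids, assoc.mirna_ids, ncn)


def initial_score(
    assoc: BipartiteAssociation,
    ncn: ScoreMatrix,
    index: str = "HPI",
    clamp: bool = True,
) -> ScoreMatrix:
    """Normalize co-neighbor counts into initial association scores.

    With ``dd = deg(d_i)``, ``dm = deg(m_j)`` and ``N = NCN(i,j)``:

    ========  =======================
    CN        ``N``
    Salton    ``N / sqrt(dd * dm)``
    Jaccard   ``N / (dd + dm)``
    Sorensen  ``2 N / (dd + dm)``
    HPI       ``N / min(dd, dm)``
    HDI       ``N / max(dd, dm)``
    LHN1      ``N / (dd * dm)``
    PA        ``N * dd * dm``
    ========  =======================

    A pair with no co-neighbor (``N = 0``) or a zero denominator scores
    0.  With ``clamp=True`` every known pair (``AS(i,j) = 1``) is then
    overwritten with the global maximum of the score matrix (1 if the
    matrix is all zero), so training positives dominate the ranking
    before similarity propagation.
    """
    index = normalize_index_name(index)
    n = ncn.matrix.astype(float)
    deg_d, deg_m = degrees(assoc)
    dd = deg_d[:, None].astype(float)
    dm = deg_m[None, :].astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        if index == "CN":
            score = n
        elif index == "Salton":
            score = n / np.sqrt(dd * dm)
        elif index == "Jaccard":
            score = n / (dd + dm)
        elif index == "Sorensen":
            score = 2.0 * n / (dd + dm)
        elif index == "HPI":
            score = n / np.minimum(dd, dm)
        elif index == "HDI":
            score = n / np.maximum(dd, dm)
        elif index == "LHN1":
            score = n / (dd * dm)
        else:  # PA
            score = n * dd * dm

    # zero rule: no co-neighbor, or an isolated endpoint, scores 0
    score = np.where((n > 0) & (dd > 0) & (dm > 0), score, 0.0)

    if clamp:
        known = assoc.matrix == 1
        if known.any():
            top = score.max()
            score = np.where(known, top if top > 0 else 1.0, score)

    return ScoreMatrix(assoc.disease_ids, assoc.mirna_ids, score)
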