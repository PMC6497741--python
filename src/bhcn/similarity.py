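"""Similarity-network reconstruction.

Two fused similarity networks feed the secondary scoring stage:

* the miRNA network ``SIM``, which reweights the functional similarity
  ``SM`` by family co-membership — same-family pairs keep their full
  functional similarity while cross-family pairs are down-weighted:

  ``SIM(i,j) = SM(i,j) * (alpha + (1 - alpha) * SM_fam(i,j))``

* the disease network ``SDD``, a convex blend of the association-derived
  functional similarity ``SDAS`` and the precomputed semantic similarity
  ``SD``:

  ``SDAS(i,j) = comm(i,j) / (deg(d_i) + deg(d_j))`` (0 when no shared
  miRNA), and ``SDD(i,j) = beta * SDAS(i,j) + (1 - beta) * SD(i,j)``.

Both fused matrices get a unit diagonal after fusion: self-similarity is
defined as maximal so the self-term of the secondary propagation carries
each pair's initial score through unchanged (``SDAS`` alone would give a
diagonal of 0.5 for any associated disease).
"""

from __future__ import annotations

import numpy as np

from .containers import BipartiteAssociation, SimilarityMatrix, degrees

__all__ = [
    "fuse_mirna_similarity",
    "disease_functional_similarity",
    "fuse_disease_similarity",
]


def _check_weight(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


def _check_same_labels(a: SimilarityMatrix, b: SimilarityMatrix) -> None:
    if a.ids != b.ids:
        raise ValueError(
            "similarity matrices have mismatched labels: "
            f"{a.ids[:3]}... vs {b.ids[:3]}..."
        )


def fuse_mirna_similarity(
    sm: SimilarityMatrix, fam: SimilarityMatrix, alpha: float = 0.5
) -> SimilarityMatrix:
    """Fuse miRNA functional similarity with family co-membership.

    Same-family pairs keep ``SM`` unchanged; different-family pairs are
    scaled by ``alpha``.  The diagonal is forced to 1 after fusion.
    """
    alpha = _check_weight(alpha, "alpha")
    _check_same_labels(sm, fam)
    fused = sm.matrix * (alpha + (1.0 - alpha) * fam.matrix)
    fused = 0.5 * (fused + fused.T)
    np.fill_diagonal(fused, 1.0)
    return SimilarityMatrix(sm.ids, fused)


def disease_functional_similarity(assoc: BipartiteAssociation) -> SimilarityMatrix:
    """Association-derived disease functional similarity ``SDAS``.

    ``SDAS(i,j)`` is the number of miRNAs associated with both diseases
    divided by the sum of the two disease degrees, or 0 when the diseases
    share no miRNA.  Entries lie in [0, 0.5].
    """
    a = assoc.matrix.astype(float)
    comm = a @ a.T
    deg_d, _ = degrees(assoc)
    denom = deg_d[:, None] + deg_d[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sdas = np.where((comm > 0) & (denom > 0), comm / np.maximum(denom, 1), 0.0)
    return SimilarityMatrix(assoc.disease_ids, sdas)


def fuse_disease_similarity(
    sdas: SimilarityMatrix, sd: SimilarityMatrix, beta: float = 0.5
) -> SimilarityMatrix:
    """Blend functional and semantic disease similarity into ``SDD``.

    ``beta`` weights the association-derived component; the diagonal is
    forced to 1 after fusion.
    """
    beta = _check_weight(beta, "beta")
    _check_same_labels(sdas, sd)
    fused = beta * sdas.matrix + (1.0 - beta) * sd.matrix
    fused = 0.5 * (fused + fused.T)
    np.fill_diagonal(fused, 1.0)
    return SimilarityMatrix(sdas.ids, fused)
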