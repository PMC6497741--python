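"""Labeled matrix containers for the bipartite disease-miRNA network.

The package works on three kinds of labeled matrices:

* :class:`BipartiteAssociation` — the Boolean training network ``AS`` with
  diseases on the rows and miRNAs on the columns.
* :class:`SimilarityMatrix` — a symmetric square matrix of pairwise
  similarities (disease semantic similarity ``SD``, miRNA functional
  similarity ``SM``, or any of the fused matrices derived from them).
* :class:`ScoreMatrix` — a real-valued disease x miRNA matrix of predicted
  association scores.

One orientation is enforced everywhere: diseases index rows, miRNAs index
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteAssociation",
    "SimilarityMatrix",
    "FamilyAnnotation",
    "ScoreMatrix",
    "degrees",
    "family_matrix",
]

_SYMMETRY_TOL = 1e-9


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what} labels: {sorted(set(dups))}")
    return labels


@dataclass(frozen=True)
class BipartiteAssociation:
    """Boolean disease x miRNA association matrix ``AS``.

    ``matrix[i, j] == 1`` iff disease ``disease_ids[i]`` is known to be
    associated with miRNA ``mirna_ids[j]``.
    """

    disease_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        d = _check_unique(self.disease_ids, "disease")
        m = _check_unique(self.mirna_ids, "miRNA")
        a = np.asarray(self.matrix)
        if a.shape != (len(d), len(m)):
            raise ValueError(
                f"association matrix shape {a.shape} does not match "
                f"{len(d)} diseases x {len(m)} miRNAs"
            )
        if a.size and not np.isin(a, (0, 1)).all():
            bad = np.argwhere(~np.isin(a, (0, 1)))[0]
            raise ValueError(
                f"association matrix must be Boolean; entry "
                f"({d[bad[0]]!r}, {m[bad[1]]!r}) = {a[tuple(bad)]!r}"
            )
        object.__setattr__(self, "disease_ids", tuple(d))
        object.__setattr__(self, "mirna_ids", tuple(m))
        object.__setattr__(self, "matrix", a.astype(np.int8))

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_associations(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.disease_ids), columns=list(self.mirna_ids)
        )

    def with_matrix(self, matrix: np.ndarray) -> "BipartiteAssociation":
        """Return a copy carrying ``matrix`` with the same labels."""
        return BipartiteAssociation(self.disease_ids, self.mirna_ids, matrix)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric square similarity matrix with labeled axes.

    Entries are expected in [0, 1]; symmetry is enforced to 1e-9.
    """

    ids: tuple[str, ...]
    matrix: np.ndarray
    check_range: bool = field(default=True, compare=False)

    def __post_init__(self):
        labels = _check_unique(self.ids, "similarity")
        a = np.asarray(self.matrix, dtype=float)
        n = len(labels)
        if a.shape != (n, n):
            raise ValueError(f"similarity matrix must be {n}x{n}, got {a.shape}")
        if a.size and not np.isfinite(a).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if a.size:
            asym = np.abs(a - a.T).max()
            if asym > _SYMMETRY_TOL:
                i, j = np.unravel_index(np.argmax(np.abs(a - a.T)), a.shape)
                raise ValueError(
                    f"similarity matrix is asymmetric at ({labels[i]!r}, "
                    f"{labels[j]!r}): {a[i, j]} vs {a[j, i]}"
                )
            if self.check_range and (
                a.min() < -_SYMMETRY_TOL or a.max() > 1 + _SYMMETRY_TOL
            ):
                raise ValueError(
                    f"similarity entries must lie in [0, 1]; "
                    f"range is [{a.min()}, {a.max()}]"
                )
        object.__setattr__(self, "ids", tuple(labels))
        object.__setattr__(self, "matrix", a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Restrict/reorder to ``ids``, which must all be present."""
        ids = [str(x) for x in ids]
        missing = [x for x in ids if x not in set(self.ids)]
        if missing:
            raise KeyError(f"labels missing from similarity matrix: {missing}")
        dropped = set(self.ids) - set(ids)
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} similarity labels absent from the "
                f"association matrix: {sorted(dropped)[:5]}...",
                stacklevel=2,
            )
        pos = {x: k for k, x in enumerate(self.ids)}
        idx = np.array([pos[x] for x in ids], dtype=int)
        return SimilarityMatrix(tuple(ids), self.matrix[np.ix_(idx, idx)],
                                check_range=self.check_range)


@dataclass(frozen=True)
class FamilyAnnotation:
    """miRNA -> family assignment.

    miRNAs absent from :attr:`assignments` form singleton families of
    their own.
    """

    assignments: Mapping[str, str]

    def family_of(self, mirna: str) -> str:
        # singleton sentinel is the miRNA's own name, which cannot collide
        # with a real family across two unlisted miRNAs
        return self.assignments.get(mirna, f"__singleton__{mirna}")


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued disease x miRNA score matrix."""

    disease_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        d = _check_unique(self.disease_ids, "disease")
        m = _check_unique(self.mirna_ids, "miRNA")
        a = np.asarray(self.matrix, dtype=float)
        if a.shape != (len(d), len(m)):
            raise ValueError(
                f"score matrix shape {a.shape} does not match labels "
                f"({len(d)}, {len(m)})"
            )
        if a.size and not np.isfinite(a).all():
            raise ValueError("score matrix contains non-finite entries")
        object.__setattr__(self, "disease_ids", tuple(d))
        object.__setattr__(self, "mirna_ids", tuple(m))
        object.__setattr__(self, "matrix", a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.disease_ids), columns=list(self.mirna_ids)
        )

    def to_long(self) -> pd.DataFrame:
        """Long-form (disease, miRNA, score) table sorted by score descending."""
        df = self.to_frame().stack().rename("score").reset_index()
        df.columns = ["disease", "mirna", "score"]
        return df.sort_values(
            ["score", "disease", "mirna"], ascending=[False, True, True]
        ).reset_index(drop=True)


def degrees(assoc: BipartiteAssociation) -> tuple[np.ndarray, np.ndarray]:
    """Node degrees in the bipartite network.

    Returns ``(disease_degrees, mirna_degrees)``: the number of miRNAs
    associated with each disease (row sums of ``AS``) and the number of
    diseases associated with each miRNA (column sums).
    """
    a = assoc.matrix
    return a.sum(axis=1).astype(np.int64), a.sum(axis=0).astype(np.int64)


def family_matrix(
    fam: FamilyAnnotation, mirna_ids: Sequence[str]
) -> SimilarityMatrix:
    """Boolean family co-membership matrix ``SM_fam``.

    ``SM_fam[i, j] = 1`` iff miRNAs ``i`` and ``j`` belong to the same
    family (unannotated miRNAs are singletons); the diagonal is all ones.
    """
    ids = [str(x) for x in mirna_ids]
    fams = np.array([fam.family_of(m) for m in ids], dtype=object)
    mat = (fams[:, None] == fams[None, :]).astype(float)
    np.fill_diagonal(mat, 1.0)
    return SimilarityMatrix(tuple(ids), mat)
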