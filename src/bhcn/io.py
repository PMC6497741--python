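"""Readers and writers for the plain-text formats the tool consumes.

Formats
-------
Edge list
    Two-column TSV, no header, one ``disease<TAB>miRNA`` association per
    line.
Matrix TSV
    Tab-separated; header row of column labels, first column of row
    labels, ``.`` as the decimal point.  Used for the association matrix,
    both similarity matrices, and score output in wide form.
Family TSV
    Two-column TSV, no header: ``miRNA<TAB>family``.
Score TSV
    Three columns (disease, miRNA, score), sorted by score descending.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    BipartiteAssociation,
    FamilyAnnotation,
    ScoreMatrix,
    SimilarityMatrix,
)

__all__ = [
    "read_association",
    "write_association",
    "read_similarity",
    "write_similarity",
    "read_family",
    "write_family",
    "write_scores",
    "atomic_write_text",
]

logger = logging.getLogger(__name__)


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _first_appearance(labels: Iterable[str]) -> list[str]:
    return list(dict.fromkeys(labels))


def read_association(
    path: str | os.PathLike, format: str = "edge-list"
) -> BipartiteAssociation:
    """Read the Boolean disease x miRNA association matrix.

    Parameters
    ----------
    path
        Input file.
    format
        ``"edge-list"`` (disease, miRNA pairs; labels ordered by first
        appearance) or ``"matrix"`` (wide TSV with miRNA header and
        disease row labels).

    Duplicate edges in an edge list collapse to a single association with
    a logged warning.
    """
    path = Path(path)
    if format == "edge-list":
        pairs: list[tuple[str, str]] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{ln}: expected 2 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                pairs.append((fields[0].strip(), fields[1].strip()))
        if not pairs:
            raise ValueError(f"{path}: no associations")
        n_dup = len(pairs) - len(set(pairs))
        if n_dup:
            logger.warning("%s: %d duplicate association(s) collapsed", path, n_dup)
        diseases = _first_appearance(d for d, _ in pairs)
        mirnas = _first_appearance(m for _, m in pairs)
        dpos = {d: i for i, d in enumerate(diseases)}
        mpos = {m: j for j, m in enumerate(mirnas)}
        mat = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
        for d, m in pairs:
            mat[dpos[d], mpos[m]] = 1
        return BipartiteAssociation(tuple(diseases), tuple(mirnas), mat)

    if format == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.empty or not df.to_numpy().sum():
            raise ValueError(f"{path}: no associations")
        arr = df.to_numpy()
        bad = np.argwhere(~np.isin(arr, (0, 1)))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: non-binary value {arr[i, j]!r} at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
        return BipartiteAssociation(
            tuple(str(x) for x in df.index),
            tuple(str(x) for x in df.columns),
            arr,
        )

    raise ValueError(f"unknown association format {format!r}")


def write_association(
    assoc: BipartiteAssociation,
    path: str | os.PathLike,
    format: str = "edge-list",
    header: str = "",
) -> None:
    """Write an association matrix in either supported format."""
    if format == "edge-list":
        lines = [
            f"{assoc.disease_ids[i]}\t{assoc.mirna_ids[j]}"
            for i, j in np.argwhere(assoc.matrix == 1)
        ]
        atomic_write_text(path, header + "\n".join(lines) + "\n")
    elif format == "matrix":
        atomic_write_text(
            path, header + assoc.to_frame().to_csv(sep="\t", index_label="")
        )
    else:
        raise ValueError(f"unknown association format {format!r}")


def read_similarity(path: str | os.PathLike) -> SimilarityMatrix:
    """Read a square labeled similarity matrix from TSV.

    The header labels and the first-column labels must match; the matrix
    must be symmetric to 1e-9 with all entries in [0, 1].
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if len(rows) != len(cols):
        raise ValueError(f"{path}: matrix is not square ({len(rows)}x{len(cols)})")
    if rows != cols:
        raise ValueError(
            f"{path}: row labels do not match column labels "
            f"(first mismatch: {next((r, c) for r, c in zip(rows, cols) if r != c)})"
        )
    try:
        return SimilarityMatrix(tuple(rows), df.to_numpy(dtype=float))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_similarity(
    sim: SimilarityMatrix, path: str | os.PathLike, header: str = ""
) -> None:
    atomic_write_text(path, header + sim.to_frame().to_csv(sep="\t", index_label=""))


def read_family(path: str | os.PathLike) -> FamilyAnnotation:
    """Read a two-column miRNA -> family annotation TSV."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{ln}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            mirna, family = fields[0].strip(), fields[1].strip()
            if mirna in assignments and assignments[mirna] != family:
                raise ValueError(
                    f"{path}:{ln}: miRNA {mirna!r} assigned to two families"
                )
            assignments[mirna] = family
    return FamilyAnnotation(assignments)


def write_family(
    fam: FamilyAnnotation, path: str | os.PathLike, header: str = ""
) -> None:
    lines = [f"{m}\t{f}" for m, f in fam.assignments.items()]
    atomic_write_text(path, header + "\n".join(lines) + ("\n" if lines else ""))


def write_scores(
    scores: ScoreMatrix, path: str | os.PathLike, header: str = ""
) -> None:
    """Write scores as a 3-column TSV sorted by score descending."""
    long = scores.to_long()
    body = long.to_csv(sep="\t", index=False, header=False,
                       float_format="%.10g")
    atomic_write_text(path, header + body)
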