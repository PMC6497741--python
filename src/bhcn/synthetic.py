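"""Synthetic bipartite networks with planted block structure.

The generator emulates the structural hypothesis behind the method:
functionally similar miRNAs associate with phenotypically similar
diseases.  Diseases and miRNAs are assigned round-robin to matched
blocks; associations are dense within a block (``p_in``) and sparse
across blocks (``p_out``); both similarity matrices mix the block
indicator (weight ``sim_signal``) with Gaussian noise; miRNA families
coincide with miRNA blocks.  Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    BipartiteAssociation,
    FamilyAnnotation,
    SimilarityMatrix,
)

__all__ = ["SyntheticConfig", "generate", "toy_network"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-block generator.

    Defaults produce a sparse 40 x 60 network (4 matched blocks,
    within-block association probability 0.3, cross-block 0.02) with
    strongly block-correlated similarities (signal 0.8, noise sd 0.1).
    """

    n_diseases: int = 40
    n_mirnas: int = 60
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    sim_signal: float = 0.8
    noise_sd: float = 0.1
    seed: int = 7

    def __post_init__(self):
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, "
                f"p_out={self.p_out}"
            )
        if not 0.0 <= self.sim_signal <= 1.0:
            raise ValueError(f"sim_signal must lie in [0, 1], got {self.sim_signal}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 1 <= self.n_blocks <= min(self.n_diseases, self.n_mirnas):
            raise ValueError(
                "need 1 <= n_blocks <= min(n_diseases, n_mirnas), got "
                f"n_blocks={self.n_blocks}"
            )


def _block_similarity(
    blocks: np.ndarray, signal: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    indicator = (blocks[:, None] == blocks[None, :]).astype(float)
    raw = signal * indicator + rng.normal(0.0, noise_sd, indicator.shape)
    sym = 0.5 * (raw + raw.T)  # symmetrize before clipping
    sym = np.clip(sym, 0.0, 1.0)
    np.fill_diagonal(sym, 1.0)
    return sym


def generate(
    config: SyntheticConfig | None = None,
) -> tuple[BipartiteAssociation, SimilarityMatrix, SimilarityMatrix, FamilyAnnotation]:
    """Draw one synthetic dataset ``(AS, SM, SD, families)``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    disease_ids = tuple(f"D{i + 1:03d}" for i in range(config.n_diseases))
    mirna_ids = tuple(f"M{j + 1:03d}" for j in range(config.n_mirnas))
    d_blocks = np.arange(config.n_diseases) % config.n_blocks
    m_blocks = np.arange(config.n_mirnas) % config.n_blocks

    same_block = d_blocks[:, None] == m_blocks[None, :]
    prob = np.where(same_block, config.p_in, config.p_out)
    mat = (rng.random(prob.shape) < prob).astype(np.int8)
    assoc = BipartiteAssociation(disease_ids, mirna_ids, mat)

    sm = SimilarityMatrix(
        mirna_ids,
        _block_similarity(m_blocks, config.sim_signal, config.noise_sd, rng),
    )
    sd = SimilarityMatrix(
        disease_ids,
        _block_similarity(d_blocks, config.sim_signal, config.noise_sd, rng),
    )
    fam = FamilyAnnotation(
        {m: f"FAM{b + 1}" for m, b in zip(mirna_ids, m_blocks)}
    )
    return assoc, sm, sd, fam


def toy_network() -> tuple[
    BipartiteAssociation, SimilarityMatrix, SimilarityMatrix, FamilyAnnotation
]:
    """The 3x3, 5-edge worked example used throughout the docs and tests.

    Edges: (d1,m1), (d2,m1), (d2,m2), (d3,m2), (d3,m3).  The similarity
    matrices are small hand-written examples and the family annotation
    groups m1 and m2.
    """
    assoc = BipartiteAssociation(
        ("d1", "d2", "d3"),
        ("m1", "m2", "m3"),
        np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1]]),
    )
    sm = SimilarityMatrix(
        ("m1", "m2", "m3"),
        np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.4], [0.2, 0.4, 1.0]]),
    )
    sd = SimilarityMatrix(
        ("d1", "d2", "d3"),
        np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.6], [0.1, 0.6, 1.0]]),
    )
    fam = FamilyAnnotation({"m1": "F1", "m2": "F1"})
    return assoc, sm, sd, fam
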