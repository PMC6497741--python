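"""The BHCN estimator: co-neighbor scoring with similarity propagation.

The full scoring chain is

1. fuse the miRNA similarity network ``SIM`` (functional similarity
   reweighted by family co-membership),
2. fuse the disease similarity network ``SDD`` (association-derived
   functional similarity blended with semantic similarity),
3. count bipartite co-neighbors ``NCN`` on the training association
   matrix and normalize them under a local structural index,
4. clamp known pairs to the matrix maximum,
5. propagate the initial scores through the disease similarity space
   (``R_FBD = SDD @ R_PB``) and the miRNA similarity space
   (``R_FBM = R_PB @ SIM``),
6. blend: ``R_FB = (1 - gamma) * R_FBM + gamma * R_FBD``.

Scenarios select how much of the chain is used: ``MDA`` stops after the
clamped initial scores, ``MS-noMSR``/``MS-MSR`` return the miRNA-space
score (without/with family-informed network reconstruction),
``DS-noDSR``/``DS-DSR`` return the disease-space score (without/with
association-informed reconstruction), and ``full`` returns the blend.

The miRNA-space channel cannot score an isolated disease (its initial
score row is zero, and propagation over miRNAs stays within the row);
only the disease-space channel can.  Symmetrically, only the miRNA-space
channel can score a new miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import (
    BipartiteAssociation,
    FamilyAnnotation,
    ScoreMatrix,
    SimilarityMatrix,
    family_matrix,
)
from .coneighbor import count_simple_paths3, initial_score, normalize_index_name
from .similarity import (
    disease_functional_similarity,
    fuse_disease_similarity,
    fuse_mirna_similarity,
)

__all__ = [
    "SCENARIOS",
    "BHCNParams",
    "BHCN",
    "secondary_score_mirna",
    "secondary_score_disease",
    "combine_scores",
    "bhcn_predict",
]

SCENARIOS = ("MDA", "MS-noMSR", "MS-MSR", "DS-noDSR", "DS-DSR", "full")

_SCENARIO_ALIASES = {s.lower(): s for s in SCENARIOS}


def normalize_scenario(scenario: str) -> str:
    key = str(scenario).lower()
    if key not in _SCENARIO_ALIASES:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid scenarios are "
            f"{', '.join(SCENARIOS)}"
        )
    return _SCENARIO_ALIASES[key]


@dataclass
class BHCNParams:
    """Bag of BHCN hyper-parameters with validation.

    alpha, beta and gamma are the miRNA-fusion, disease-fusion and
    channel-blend weights; all default to 0.5.
    """

    alpha: float = 0.5
    beta: float = 0.5
    gamma: float = 0.5
    index: str = "HPI"
    scenario: str = "full"
    clamp: bool = True

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
            setattr(self, name, v)
        self.index = normalize_index_name(self.index)
        self.scenario = normalize_scenario(self.scenario)

    def to_estimator(self) -> "BHCN":
        return BHCN(
            index=self.index,
            scenario=self.scenario,
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
            clamp=self.clamp,
        )


def secondary_score_mirna(
    rpb: ScoreMatrix, sim: SimilarityMatrix
) -> ScoreMatrix:
    """Propagate initial scores through the miRNA similarity space.

    ``R_FBM(i,j) = sum_k R_PB(i,k) * SIM(k,j)`` over all miRNAs k.
    """
    if sim.ids != rpb.mirna_ids:
        raise ValueError("miRNA similarity labels do not match score columns")
    return ScoreMatrix(rpb.disease_ids, rpb.mirna_ids, rpb.matrix @ sim.matrix)


def secondary_score_disease(
    rpb: ScoreMatrix, sdd: SimilarityMatrix
) -> ScoreMatrix:
    """Propagate initial scores through the disease similarity space.

    ``R_FBD(i,j) = sum_k R_PB(k,j) * SDD(k,i)`` over all diseases k.
    """
    if sdd.ids != rpb.disease_ids:
        raise ValueError("disease similarity labels do not match score rows")
    return ScoreMatrix(rpb.disease_ids, rpb.mirna_ids, sdd.matrix.T @ rpb.matrix)


def combine_scores(
    rfbm: ScoreMatrix, rfbd: ScoreMatrix, gamma: float = 0.5
) -> ScoreMatrix:
    """Blend the two spatial scores: ``(1 - gamma) R_FBM + gamma R_FBD``."""
    gamma = float(gamma)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if rfbm.disease_ids != rfbd.disease_ids or rfbm.mirna_ids != rfbd.mirna_ids:
        raise ValueError("spatial score matrices have mismatched labels")
    return ScoreMatrix(
        rfbm.disease_ids,
        rfbm.mirna_ids,
        (1.0 - gamma) * rfbm.matrix + gamma * rfbd.matrix,
    )


def _unit_diagonal(sim: SimilarityMatrix) -> SimilarityMatrix:
    mat = sim.matrix.copy()
    np.fill_diagonal(mat, 1.0)
    return SimilarityMatrix(sim.ids, mat)


class BHCN(BaseEstimator):
    """Bipartite heterogeneous-network co-neighbor link predictor.

    Parameters
    ----------
    index : str, default="HPI"
        Local structural index normalizing the co-neighbor count: one of
        CN, Salton, Jaccard, Sorensen, HPI, HDI, LHN1, PA
        (case-insensitive).
    scenario : str, default="full"
        Which scoring channel to return: "MDA" (initial scores only),
        "MS-noMSR"/"MS-MSR" (miRNA-space), "DS-noDSR"/"DS-DSR"
        (disease-space), or "full" (gamma-weighted blend).
    alpha, beta, gamma : float, default=0.5
        Fusion weights for the miRNA network, the disease network, and
        the final channel blend.
    clamp : bool, default=True
        Overwrite known-pair initial scores with the matrix maximum
        before propagation.

    Attributes
    ----------
    ncn_ : ScoreMatrix
        Co-neighbor (simple length-3 path) counts.
    initial_scores_ : ScoreMatrix
        Index-normalized (and clamped) initial scores ``R_PB``.
    mirna_space_scores_, disease_space_scores_ : ScoreMatrix or None
        Secondary scores ``R_FBM`` / ``R_FBD`` where the scenario
        computes them.
    scores_ : ScoreMatrix
        The scenario's final score matrix.
    sim_, sdd_ : SimilarityMatrix or None
        The fused similarity networks actually used.

    Examples
    --------
    >>> from bhcn.synthetic import toy_network
    >>> assoc, sm, sd, fam = toy_network()
    >>> model = BHCN(index="CN", scenario="MDA").fit(assoc)
    >>> model.scores_.matrix.shape
    (3, 3)
    """

    def __init__(
        self,
        index: str = "HPI",
        scenario: str = "full",
        alpha: float = 0.5,
        beta: float = 0.5,
        gamma: float = 0.5,
        clamp: bool = True,
    ):
        self.index = index
        self.scenario = scenario
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.clamp = clamp

    # -- internal -----------------------------------------------------

    def _validated_params(self) -> BHCNParams:
        return BHCNParams(
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
            index=self.index,
            scenario=self.scenario,
            clamp=self.clamp,
        )

    # -- sklearn API --------------------------------------------------

    def fit(
        self,
        X: BipartiteAssociation,
        y=None,
        *,
        mirna_similarity: SimilarityMatrix | None = None,
        disease_similarity: SimilarityMatrix | None = None,
        family: FamilyAnnotation | None = None,
    ) -> "BHCN":
        """Score every disease-miRNA pair of the training network.

        Parameters
        ----------
        X : BipartiteAssociation
            Training association matrix (diseases x miRNAs).
        mirna_similarity : SimilarityMatrix, optional
            Functional similarity ``SM``; required by MS-* and full
            scenarios.  Extra labels are dropped to the association
            universe; missing labels raise.
        disease_similarity : SimilarityMatrix, optional
            Semantic similarity ``SD``; required by DS-* and full.
        family : FamilyAnnotation, optional
            miRNA family annotation; used by MS-MSR and full
            (unannotated miRNAs are singleton families).
        """
        params = self._validated_params()
        if not isinstance(X, BipartiteAssociation):
            X = BipartiteAssociation(
                tuple(f"d{i}" for i in range(np.asarray(X).shape[0])),
                tuple(f"m{j}" for j in range(np.asarray(X).shape[1])),
                np.asarray(X),
            )
        scenario = params.scenario
        needs_sim = scenario in ("MS-noMSR", "MS-MSR", "full")
        needs_sdd = scenario in ("DS-noDSR", "DS-DSR", "full")
        if needs_sim and mirna_similarity is None:
            raise ValueError(f"scenario {scenario!r} requires mirna_similarity")
        if needs_sdd and disease_similarity is None:
            raise ValueError(f"scenario {scenario!r} requires disease_similarity")

        # similarity networks per scenario
        self.sim_ = None
        self.sdd_ = None
        if needs_sim:
            sm = mirna_similarity.reindex(X.mirna_ids)
            if scenario == "MS-noMSR":
                self.sim_ = _unit_diagonal(sm)
            else:
                fam_mat = family_matrix(family or FamilyAnnotation({}), X.mirna_ids)
                self.sim_ = fuse_mirna_similarity(sm, fam_mat, params.alpha)
        if needs_sdd:
            sd = disease_similarity.reindex(X.disease_ids)
            if scenario == "DS-noDSR":
                self.sdd_ = _unit_diagonal(sd)
            else:  # DS-DSR or full: association-informed reconstruction
                self.sdd_ = fuse_disease_similarity(
                    disease_functional_similarity(X), sd, params.beta
                )

        # co-neighbor counting and initial scores
        self.association_ = X
        self.ncn_ = count_simple_paths3(X)
        self.initial_scores_ = initial_score(
            X, self.ncn_, params.index, clamp=params.clamp
        )

        # secondary propagation and blending
        self.mirna_space_scores_ = (
            secondary_score_mirna(self.initial_scores_, self.sim_)
            if self.sim_ is not None
            else None
        )
        self.disease_space_scores_ = (
            secondary_score_disease(self.initial_scores_, self.sdd_)
            if self.sdd_ is not None
            else None
        )
        if scenario == "MDA":
            self.scores_ = self.initial_scores_
        elif scenario in ("MS-noMSR", "MS-MSR"):
            self.scores_ = self.mirna_space_scores_
        elif scenario in ("DS-noDSR", "DS-DSR"):
            self.scores_ = self.disease_space_scores_
        else:
            self.scores_ = combine_scores(
                self.mirna_space_scores_,
                self.disease_space_scores_,
                params.gamma,
            )
        return self

    def predict(self, X=None) -> ScoreMatrix:
        """Return the fitted score matrix (``X`` is ignored)."""
        if not hasattr(self, "scores_"):
            raise AttributeError("BHCN instance is not fitted yet; call fit first")
        return self.scores_


def bhcn_predict(
    assoc: BipartiteAssociation,
    sm: SimilarityMatrix | None,
    sd: SimilarityMatrix | None,
    fam: FamilyAnnotation | None,
    params: BHCNParams | None = None,
) -> ScoreMatrix:
    """Functional front-end: fit a :class:`BHCN` and return its scores."""
    params = params or BHCNParams()
    model = params.to_estimator()
    model.fit(
        assoc,
        mirna_similarity=sm,
        disease_similarity=sd,
        family=fam,
    )
    return model.scores_
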