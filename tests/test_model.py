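import numpy as np
import pytest
from sklearn.base import clone

from bhcn.containers import (
    BipartiteAssociation,
    FamilyAnnotation,
    ScoreMatrix,
    SimilarityMatrix,
)
from bhcn.coneighbor import count_simple_paths3, initial_score
from bhcn.model import (
    BHCN,
    SCENARIOS,
    BHCNParams,
    bhcn_predict,
    combine_scores,
    secondary_score_disease,
    secondary_score_mirna,
)


def _scores(mat, d=None, m=None):
    mat = np.asarray(mat, dtype=float)
    d = d or tuple(f"d{i}" for i in range(mat.shape[0]))
    m = m or tuple(f"m{j}" for j in range(mat.shape[1]))
    return ScoreMatrix(d, m, mat)


def _sim(ids, mat):
    return SimilarityMatrix(tuple(ids), np.asarray(mat, dtype=float))


class TestSecondaryScores:
    def test_identity_similarity_is_noop(self):
        rpb = _scores([[1.0, 2.0], [0.5, 0.0]])
        ident_m = _sim(("m0", "m1"), np.eye(2))
        ident_d = _sim(("d0", "d1"), np.eye(2))
        np.testing.assert_array_equal(
            secondary_score_mirna(rpb, ident_m).matrix, rpb.matrix
        )
        np.testing.assert_array_equal(
            secondary_score_disease(rpb, ident_d).matrix, rpb.matrix
        )

    def test_mirna_propagation_hand_product(self):
        rpb = _scores([[1.0, 0.0]])
        sim = _sim(("m0", "m1"), [[1.0, 0.5], [0.5, 1.0]])
        out = secondary_score_mirna(rpb, sim).matrix
        np.testing.assert_allclose(out, [[1.0, 0.5]])

    def test_disease_propagation_hand_product(self):
        rpb = _scores([[1.0], [0.0]], m=("m0",))
        sdd = _sim(("d0", "d1"), [[1.0, 0.5], [0.5, 1.0]])
        out = secondary_score_disease(rpb, sdd).matrix
        np.testing.assert_allclose(out, [[1.0], [0.5]])

    def test_zero_scores_stay_zero(self):
        rpb = _scores(np.zeros((3, 2)))
        sim = _sim(("m0", "m1"), [[1.0, 0.9], [0.9, 1.0]])
        assert secondary_score_mirna(rpb, sim).matrix.sum() == 0.0

    def test_linearity_in_initial_scores(self):
        rng = np.random.default_rng(11)
        rpb = _scores(rng.random((4, 3)))
        doubled = _scores(2 * rpb.matrix)
        raw = rng.random((3, 3))
        sim = _sim(("m0", "m1", "m2"), np.clip(0.5 * (raw + raw.T), 0, 1))
        np.testing.assert_allclose(
            secondary_score_mirna(doubled, sim).matrix,
            2 * secondary_score_mirna(rpb, sim).matrix,
        )

    def test_label_mismatch_errors(self):
        rpb = _scores([[1.0, 0.0]])
        with pytest.raises(ValueError, match="labels"):
            secondary_score_mirna(rpb, _sim(("x", "y"), np.eye(2)))
        with pytest.raises(ValueError, match="labels"):
            secondary_score_disease(rpb, _sim(("x",), np.eye(1)))


class TestCombineScores:
    @pytest.mark.parametrize("gamma, expected", [(0.0, 0.4), (1.0, 0.8), (0.5, 0.6)])
    def test_blend(self, gamma, expected):
        rfbm = _scores([[0.4]])
        rfbd = _scores([[0.8]])
        assert combine_scores(rfbm, rfbd, gamma).matrix[0, 0] == pytest.approx(
            expected
        )

    def test_gamma_out_of_range_errors(self):
        with pytest.raises(ValueError, match="gamma"):
            combine_scores(_scores([[0.0]]), _scores([[0.0]]), 1.2)

    def test_blend_bounded_by_channels(self):
        rng = np.random.default_rng(4)
        rfbm = _scores(rng.random((5, 6)))
        rfbd = _scores(rng.random((5, 6)))
        for gamma in (0.0, 0.25, 0.6, 1.0):
            blend = combine_scores(rfbm, rfbd, gamma).matrix
            lo = np.minimum(rfbm.matrix, rfbd.matrix)
            hi = np.maximum(rfbm.matrix, rfbd.matrix)
            assert ((blend >= lo - 1e-12) & (blend <= hi + 1e-12)).all()


class TestBHCNEstimator:
    def test_mda_scenario_returns_clamped_counts(self, toy_assoc):
        model = BHCN(index="CN", scenario="MDA").fit(toy_assoc)
        expected = initial_score(
            toy_assoc, count_simple_paths3(toy_assoc), "CN", clamp=True
        )
        np.testing.assert_array_equal(model.scores_.matrix, expected.matrix)

    def test_identity_similarities_collapse_to_initial_scores(self, toy_assoc):
        # SM = I makes SIM = I; SD = I with beta=0 makes SDD = I, so both
        # propagation stages are identity maps for any gamma
        ident_m = _sim(toy_assoc.mirna_ids, np.eye(3))
        ident_d = _sim(toy_assoc.disease_ids, np.eye(3))
        model = BHCN(index="PA", scenario="full", beta=0.0, gamma=0.3).fit(
            toy_assoc,
            mirna_similarity=ident_m,
            disease_similarity=ident_d,
        )
        np.testing.assert_allclose(
            model.scores_.matrix, model.initial_scores_.matrix
        )

    @pytest.mark.parametrize("gamma, channel", [(0.0, "mirna"), (1.0, "disease")])
    def test_gamma_limits_recover_single_channel(self, toy, gamma, channel):
        assoc, sm, sd, fam = toy
        model = BHCN(scenario="full", gamma=gamma).fit(
            assoc, mirna_similarity=sm, disease_similarity=sd, family=fam
        )
        expected = {
            "mirna": model.mirna_space_scores_,
            "disease": model.disease_space_scores_,
        }[channel]
        np.testing.assert_array_equal(model.scores_.matrix, expected.matrix)

    def test_isolated_disease_rescued_only_by_disease_channel(self, toy):
        assoc, sm, sd, fam = toy
        mat = assoc.matrix.copy()
        mat[0, :] = 0
        isolated = assoc.with_matrix(mat)
        model = BHCN(scenario="full", gamma=0.5).fit(
            isolated, mirna_similarity=sm, disease_similarity=sd, family=fam
        )
        assert model.initial_scores_.matrix[0].sum() == 0.0
        assert model.mirna_space_scores_.matrix[0].sum() == 0.0
        assert model.disease_space_scores_.matrix[0].sum() > 0.0
        assert model.scores_.matrix[0].sum() > 0.0

    def test_new_mirna_rescued_only_by_mirna_channel(self, toy):
        assoc, sm, sd, fam = toy
        mat = assoc.matrix.copy()
        mat[:, 0] = 0
        model = BHCN(scenario="full", gamma=0.5).fit(
            assoc.with_matrix(mat),
            mirna_similarity=sm,
            disease_similarity=sd,
            family=fam,
        )
        assert model.initial_scores_.matrix[:, 0].sum() == 0.0
        assert model.disease_space_scores_.matrix[:, 0].sum() == 0.0
        assert model.mirna_space_scores_.matrix[:, 0].sum() > 0.0

    @pytest.mark.parametrize("scenario", SCENARIOS)
    def test_deterministic_refits(self, toy, scenario):
        assoc, sm, sd, fam = toy
        kwargs = dict(
            mirna_similarity=sm, disease_similarity=sd, family=fam
        )
        a = BHCN(scenario=scenario).fit(assoc, **kwargs).scores_.matrix
        b = BHCN(scenario=scenario).fit(assoc, **kwargs).scores_.matrix
        np.testing.assert_array_equal(a, b)

    def test_missing_required_similarity_errors(self, toy_assoc):
        with pytest.raises(ValueError, match="requires mirna_similarity"):
            BHCN(scenario="MS-MSR").fit(toy_assoc)
        with pytest.raises(ValueError, match="requires disease_similarity"):
            BHCN(scenario="DS-DSR").fit(toy_assoc)

    def test_predict_before_fit_errors(self):
        with pytest.raises(AttributeError, match="not fitted"):
            BHCN().predict()

    def test_sklearn_clone_round_trip(self):
        model = BHCN(index="PA", gamma=0.2)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_accepts_bare_arrays(self):
        model = BHCN(scenario="MDA", index="CN").fit(
            np.array([[1, 0], [1, 1]])
        )
        assert model.scores_.matrix.shape == (2, 2)

    def test_invalid_scenario_errors(self, toy_assoc):
        with pytest.raises(ValueError, match="scenario"):
            BHCN(scenario="bogus").fit(toy_assoc)


class TestBHCNPredictWrapper:
    def test_matches_estimator(self, toy):
        assoc, sm, sd, fam = toy
        params = BHCNParams(index="HDI", scenario="full", gamma=0.4)
        via_fn = bhcn_predict(assoc, sm, sd, fam, params)
        via_est = (
            params.to_estimator()
            .fit(assoc, mirna_similarity=sm, disease_similarity=sd, family=fam)
            .scores_
        )
        np.testing.assert_array_equal(via_fn.matrix, via_est.matrix)

    def test_params_validate_weights(self):
        with pytest.raises(ValueError, match="beta"):
            BHCNParams(beta=-0.1)
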