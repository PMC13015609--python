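"""Entropy decomposition: closed forms, pairing structure, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import uqtriage as uq
from uqtriage.uncertainty import (
    EPSILON, InconsistentInputsError, scores_from_samples)


def H2(p):
    """Independent closed-form binary entropy in nats."""
    terms = [q * math.log(q) for q in (p, 1 - p) if q > 0]
    return -sum(terms)


class TestClosedForms:
    def test_uniform_is_log2(self):
        assert uq.total_entropy(np.array([0.5, 0.5])) == pytest.approx(
            math.log(2), abs=1e-9)

    def test_degenerate_is_zero(self):
        assert uq.total_entropy(np.array([1.0, 0.0])) == pytest.approx(0.0, abs=1e-9)

    def test_skewed_vector(self):
        expected = H2(0.9)   # -0.9 ln 0.9 - 0.1 ln 0.1
        got = uq.total_entropy(np.array([0.9, 0.1]))
        assert got == pytest.approx(expected, abs=1e-9)
        assert round(got, 4) == 0.3251

    def test_aleatoric_average_of_row_entropies(self):
        s = uq.PredictiveSampleSet(np.array([[0.9, 0.1], [0.5, 0.5]]))
        expected = (H2(0.9) + H2(0.5)) / 2
        got = uq.aleatoric_uncertainty(s)
        assert got == pytest.approx(expected, abs=1e-9)
        assert round(got, 4) == 0.5091

    def test_epistemic_chain(self):
        s = uq.PredictiveSampleSet(np.array([[0.9, 0.1], [0.5, 0.5]]))
        p_hat = uq.mean_probability(s)
        assert np.allclose(p_hat, [0.7, 0.3])
        tot = uq.total_entropy(p_hat)
        ale = uq.aleatoric_uncertainty(s)
        epi = uq.epistemic_uncertainty(tot, ale)
        assert tot == pytest.approx(H2(0.7), abs=1e-9)
        assert epi == pytest.approx(H2(0.7) - (H2(0.9) + H2(0.5)) / 2, abs=1e-9)
        assert round(epi, 4) == pytest.approx(0.1018, abs=5e-4)

    def test_full_disagreement_is_pure_epistemic(self):
        s = uq.PredictiveSampleSet(np.array([[1.0, 0.0], [0.0, 1.0]]))
        scores = scores_from_samples(s)
        assert scores.total == pytest.approx(math.log(2), abs=1e-6)
        assert scores.aleatoric == pytest.approx(0.0, abs=1e-6)
        assert scores.epistemic == pytest.approx(math.log(2), abs=1e-6)

    def test_identical_rows_zero_epistemic(self):
        s = uq.PredictiveSampleSet(np.tile([0.3, 0.7], (5, 1)))
        scores = scores_from_samples(s)
        assert scores.epistemic == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(scores.mean_prob, [0.3, 0.7])

    def test_mean_probability_examples(self):
        assert np.allclose(uq.mean_probability(uq.PredictiveSampleSet(
            np.array([[1.0, 0.0], [0.0, 1.0]]))), [0.5, 0.5])
        assert np.allclose(uq.mean_probability(uq.PredictiveSampleSet(
            np.array([[0.2, 0.8], [0.4, 0.6], [0.6, 0.4]]))), [0.4, 0.6])


class TestNormalization:
    def test_bounds_and_examples(self):
        assert uq.normalize_uncertainty(math.log(2), 2) == pytest.approx(1.0)
        assert uq.normalize_uncertainty(0.0, 2) == 0.0
        assert uq.normalize_uncertainty(0.3251, 2) == pytest.approx(0.4690, abs=1e-4)

    def test_needs_two_classes(self):
        with pytest.raises(ValueError):
            uq.normalize_uncertainty(0.5, 1)


@st.composite
def sample_sets(draw):
    t = draw(st.integers(1, 12))
    c = draw(st.integers(2, 4))
    raw = draw(hnp.arrays(np.float64, (t, c),
                          elements=st.floats(1e-6, 1.0)))
    return uq.PredictiveSampleSet(raw / raw.sum(axis=1, keepdims=True))


class TestInvariants:
    @settings(max_examples=300, derandomize=True)
    @given(s=sample_sets())
    def test_additive_identity_and_bounds(self, s):
        scores = scores_from_samples(s)
        assert scores.total == pytest.approx(
            scores.aleatoric + scores.epistemic, abs=1e-9)
        assert -1e-9 <= scores.aleatoric <= scores.total + 1e-9
        assert scores.total <= math.log(s.n_classes) + EPSILON * s.n_classes
        assert 0.0 <= scores.total_norm <= 1.0 + 1e-9
        assert 0.0 <= scores.aleatoric_norm <= 1.0 + 1e-9
        assert scores.epistemic >= 0.0
        # identity survives normalization (linearity)
        assert scores.total_norm == pytest.approx(
            scores.aleatoric_norm + scores.epistemic_norm, abs=1e-9)

    def test_epsilon_insensitivity(self):
        s = uq.PredictiveSampleSet(np.array([[0.9, 0.1], [0.4, 0.6], [0.7, 0.3]]))
        ref = scores_from_samples(s, epsilon=1e-12)
        for eps in (1e-15, 1e-9):
            alt = scores_from_samples(s, epsilon=eps)
            assert abs(alt.total - ref.total) < 1e-6
            assert abs(alt.aleatoric - ref.aleatoric) < 1e-6

    def test_strongly_negative_epistemic_rejected(self):
        with pytest.raises(InconsistentInputsError):
            uq.epistemic_uncertainty(0.1, 0.5)

    def test_malformed_sample_sets_rejected(self):
        with pytest.raises(ValueError):
            uq.PredictiveSampleSet(np.array([[0.5, 0.6]]))
        with pytest.raises(ValueError):
            uq.PredictiveSampleSet(np.zeros((0, 2)))


class TestPairing:
    def test_study_pairing_yields_1410_samples(self):
        trees, passes = uq.generate_branch_samples(1, n_trees=47, n_passes=30, seed=0)
        s = uq.pair_branch_samples(passes[0], trees[0], uq.FusionParams(t=0.8, k=0.5))
        assert s.n_samples == 30 * 47 == 1410

    def test_single_pair_equals_direct_fusion(self):
        params = uq.FusionParams(t=0.8, k=0.3)
        p_pass, p_tree = np.array([[0.4, 0.6]]), np.array([[0.7, 0.3]])
        s = uq.pair_branch_samples(p_pass, p_tree, params)
        assert s.n_samples == 1
        assert np.allclose(s.samples[0],
                           uq.fuse_probabilities(p_tree[0], p_pass[0], params))

    def test_k_zero_rows_depend_only_on_trees(self):
        params = uq.FusionParams(t=1.0, k=0.0)
        trees = np.array([[0.2, 0.8], [0.5, 0.5], [0.9, 0.1]])
        passes = np.array([[0.1, 0.9], [0.6, 0.4]])
        s = uq.pair_branch_samples(passes, trees, params)
        assert s.n_samples == 6
        uniq, counts = np.unique(s.samples, axis=0, return_counts=True)
        assert len(uniq) == 3
        assert np.all(counts == 2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            uq.pair_branch_samples(np.array([[0.5, 0.5]]),
                                   np.array([[0.2, 0.3, 0.5]]),
                                   uq.FusionParams(t=0.5, k=0.5))


class TestMCForwardPasses:
    def test_requires_stochastic_model(self, fitted):
        models, _, X, _ = fitted
        from uqtriage._nn import DropoutMLP
        det = DropoutMLP(n_features=len(models.feature_idx), dropout=0.0, seed=0)
        with pytest.raises(ValueError):
            uq.mc_forward_passes(det, X[:2, models.feature_idx], n_passes=5)

    def test_seeded_reproducibility_and_shape(self, fitted):
        models, _, X, _ = fitted
        Xs = X[:3, models.feature_idx]
        a = uq.mc_forward_passes(models.dl, Xs, n_passes=7, seed=5)
        b = uq.mc_forward_passes(models.dl, Xs, n_passes=7, seed=5)
        assert a.shape == (3, 7, 2)
        assert np.array_equal(a, b)
        # dropout masks differ across passes
        assert not np.allclose(a[:, 0], a[:, 1])


class TestScoreCase:
    def test_degenerate_branches_give_zero_uncertainty(self):
        params = uq.FusionParams(t=0.0, k=0.5)
        trees = np.tile([0.001, 0.999], (5, 1))
        passes = np.tile([0.001, 0.999], (4, 1))
        s = uq.pair_branch_samples(passes, trees, params)
        assert scores_from_samples(s).total_norm < 0.02

    def test_maximally_conflicted_branches_saturate(self):
        params = uq.FusionParams(t=1.0, k=0.5)
        trees = np.array([[1.0, 0.0], [0.0, 1.0]])
        passes = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = uq.pair_branch_samples(passes, trees, params)
        assert scores_from_samples(s).total_norm > 0.99

    def test_decomposition_identity_on_cohort(self, fitted):
        models, params, X, _ = fitted
        unc = uq.score_cohort(models, X[:100], params, n_passes=10, seed=0)
        assert np.allclose(unc.total, unc.aleatoric + unc.epistemic, atol=1e-9)
        assert ((unc.total_norm >= 0) & (unc.total_norm <= 1 + 1e-9)).all()

    def test_score_case_matches_structure(self, fitted):
        models, params, X, _ = fitted
        s = uq.score_case(models, X[0], params, n_passes=5, seed=0)
        assert s.total == pytest.approx(s.aleatoric + s.epistemic, abs=1e-9)
        assert s.predicted_class in (0, 1)
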