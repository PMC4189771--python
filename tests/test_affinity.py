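"""Affinity propagation: update rules, convergence, oracle and reference
agreement."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.cluster import AffinityPropagation as SkAffinityPropagation
from sklearn.metrics import adjusted_rand_score

from exemplarnet.affinity import (
    APConfig,
    APResult,
    APState,
    AffinityPropagation,
    brute_force_exemplars,
    median_preference,
    net_similarity,
    run_affinity_propagation,
    update_availabilities,
    update_responsibilities,
)
from exemplarnet.errors import ValidationError
from exemplarnet.synthetic import generate_separated_similarity


def block_matrix(sizes, within=0.9, between=0.05):
    """Planted-block similarity matrix, zero diagonal."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.size
    M = np.full((n, n), between)
    M[labels[:, None] == labels[None, :]] = within
    np.fill_diagonal(M, 0.0)
    return M, labels


class TestConfig:
    def test_damping_one_rejected(self):
        with pytest.raises(ValidationError):
            APConfig(damping=1.0)

    def test_damping_below_half_rejected(self):
        with pytest.raises(ValidationError):
            APConfig(damping=0.3)

    def test_convergence_window_must_be_shorter_than_max(self):
        with pytest.raises(ValidationError):
            APConfig(max_iterations=10, convergence_iterations=10)


class TestMedianPreference:
    def test_median_of_off_diagonals(self):
        S = np.zeros((3, 3))
        S[0, 1] = S[1, 0] = 0.1
        S[0, 2] = S[2, 0] = 0.2
        S[1, 2] = S[2, 1] = 0.9
        assert np.allclose(median_preference(S), 0.2)

    def test_constant_off_diagonals(self):
        S = np.full((4, 4), 0.7)
        np.fill_diagonal(S, 0.0)
        assert np.allclose(median_preference(S), 0.7)

    def test_two_genes_single_value(self):
        S = np.array([[0.0, 0.4], [0.4, 0.0]])
        assert np.allclose(median_preference(S), 0.4)


class TestUpdateRules:
    def test_responsibility_hand_values_two_genes(self):
        # preferences s(1,1)=s(2,2)=-1, cross similarity -2, availabilities 0
        S = np.array([[-1.0, -2.0], [-2.0, -1.0]])
        state = APState(np.zeros((2, 2)), np.zeros((2, 2)))
        new = update_responsibilities(S, state, damping=0.0)
        assert new.responsibilities[0, 1] == pytest.approx(-1.0)  # -2 - (-1)
        assert new.responsibilities[0, 0] == pytest.approx(1.0)   # -1 - (-2)

    def test_availability_hand_values_three_genes(self):
        # r(B,B) = -1 with a single positive off-point responsibility 0.5
        R = np.zeros((3, 3))
        R[2, 2] = -1.0
        R[1, 2] = 0.5
        state = APState(R, np.zeros((3, 3)))
        new = update_availabilities(state, damping=0.0)
        assert new.availabilities[0, 2] == pytest.approx(-0.5)  # min(0, -1+0.5)
        # for A=1 the only other point contributes nothing positive
        assert new.availabilities[1, 2] == pytest.approx(-1.0)
        # self-availability collects the positive responsibilities
        assert new.availabilities[2, 2] == pytest.approx(0.5)

    def test_availability_no_other_points(self):
        R = np.array([[0.3, -0.2], [0.1, -0.4]])
        new = update_availabilities(APState(R, np.zeros((2, 2))), damping=0.0)
        assert new.availabilities[0, 1] == pytest.approx(min(0.0, R[1, 1]))

    def test_damping_blends_old_and_new(self):
        S = np.array([[-1.0, -2.0], [-2.0, -1.0]])
        state = APState(np.full((2, 2), 5.0), np.zeros((2, 2)))
        new = update_responsibilities(S, state, damping=0.5)
        undamped = update_responsibilities(
            S, APState(np.zeros((2, 2)), np.zeros((2, 2))), 0.0
        )
        assert np.allclose(
            new.responsibilities, 0.5 * 5.0 + 0.5 * undamped.responsibilities
        )


class TestRunAffinityPropagation:
    def test_single_gene_is_its_own_exemplar(self):
        res = run_affinity_propagation(np.array([[0.5]]))
        assert res.exemplars == {"0"} and res.assignment == {"0": "0"}
        assert res.converged

    def test_two_planted_blocks_recovered(self):
        M, labels = block_matrix([4, 4])
        res = run_affinity_propagation(M, APConfig(noise_scale=1e-9, seed=0))
        assert len(res.exemplars) == 2
        pred = [res.assignment[str(i)] for i in range(8)]
        assert adjusted_rand_score(labels, [hash(p) for p in pred]) == 1.0

    def test_identical_rows_with_jitter_single_exemplar(self):
        # all pairwise similarities equal and preference below them: the
        # one-exemplar solution is optimal but the exemplar identity is a
        # pure tie — jitter resolves it to exactly one exemplar
        S = np.full((5, 5), 0.6)
        np.fill_diagonal(S, 0.0)
        res = run_affinity_propagation(
            S, APConfig(preference=0.0, noise_scale=1e-6, seed=1)
        )
        assert len(res.exemplars) == 1

    def test_exemplars_assigned_to_themselves(self, standard_result):
        for e in standard_result.exemplars:
            assert standard_result.assignment[e] == e
        assert set(standard_result.assignment.values()) <= standard_result.exemplars

    def test_monotone_preference_effect(self):
        M, _ = block_matrix([3, 3, 3], within=0.85, between=0.05)
        counts = []
        for pref in (-1.0, -0.2, 0.05, 0.3, 0.9):
            res = run_affinity_propagation(
                M, APConfig(preference=pref, noise_scale=1e-9, seed=0)
            )
            counts.append(len(res.exemplars))
        assert counts == sorted(counts)

    def test_agreement_with_reference_implementation(self):
        """Same exemplar count and partition as scikit-learn's affinity
        propagation on planted-block fixtures."""
        # block sizes chosen so between-block pairs dominate the median and
        # the preference lands strictly below the within-block similarity
        for sizes in ([4, 4], [3, 5, 4], [5, 3]):
            M, _ = block_matrix(sizes)
            pref = float(median_preference(M)[0])
            ours = run_affinity_propagation(M, APConfig(noise_scale=1e-9, seed=0))
            ref = SkAffinityPropagation(
                affinity="precomputed", preference=pref, damping=0.5,
                max_iter=1000, convergence_iter=50, random_state=0,
            ).fit(M)
            assert len(ours.exemplars) == len(ref.cluster_centers_indices_)
            ours_labels = [hash(ours.assignment[str(i)]) for i in range(M.shape[0])]
            assert adjusted_rand_score(ours_labels, ref.labels_) == 1.0


class TestEstimatorApi:
    def test_get_set_params_and_clone(self):
        est = AffinityPropagation(damping=0.7, random_state=3)
        assert est.get_params()["damping"] == 0.7
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(damping=0.5)
        assert est.damping == 0.5

    def test_fitted_attributes(self):
        M, _ = block_matrix([3, 3])
        est = AffinityPropagation(noise_scale=1e-9, random_state=0).fit(M)
        assert est.labels_.shape == (6,)
        assert est.converged_ and est.n_iter_ > 0
        assert len(est.exemplar_indices_) == len(est.result_.exemplars)
        assert est.fit_predict(M).shape == (6,)


class TestNetSimilarity:
    def test_single_gene_equals_preference(self):
        res = APResult({"0"}, {"0": "0"}, 0, True, 0.0)
        assert net_similarity(np.array([[0.7]]), res) == pytest.approx(0.7)

    def test_hand_sum_on_partitioned_matrix(self):
        M, _ = block_matrix([2, 2], within=0.9, between=0.1)
        np.fill_diagonal(M, -0.5)
        res = APResult(
            {"0", "2"}, {"0": "0", "1": "0", "2": "2", "3": "2"}, 0, True, 0.0
        )
        assert net_similarity(M, res) == pytest.approx(-0.5 + 0.9 - 0.5 + 0.9)

    def test_assignment_to_non_exemplar_is_contract_violation(self):
        res = APResult({"0"}, {"0": "0", "1": "2"}, 0, True, 0.0)
        with pytest.raises(ValidationError):
            net_similarity(np.zeros((3, 3)), res)


class TestBruteForceOracle:
    def test_single_gene(self):
        res = brute_force_exemplars(np.array([[0.3]]))
        assert res.exemplars == {"0"}

    def test_negative_preferences_merge_to_one_exemplar(self):
        S = np.array([[0.0, 0.9], [0.9, 0.0]])
        res = brute_force_exemplars(S, preference=-5.0)
        assert len(res.exemplars) == 1

    def test_dissimilar_points_with_high_preference_all_exemplars(self):
        S = np.zeros((3, 3))
        res = brute_force_exemplars(S, preference=1.0)
        assert len(res.exemplars) == 3

    def test_size_guard(self):
        with pytest.raises(ValidationError):
            brute_force_exemplars(np.zeros((13, 13)))

    def test_converged_runs_match_oracle(self):
        """Converged message passing attains the brute-force optimum on
        well-separated random matrices (spot check; the full 100-matrix
        suite runs in the acceptance tests)."""
        rng = np.random.default_rng(12345)
        checked = 0
        for _ in range(25):
            M, _ = generate_separated_similarity(rng)
            ap = run_affinity_propagation(M, APConfig(noise_scale=1e-9, seed=0))
            if not ap.converged:
                continue
            bf = brute_force_exemplars(M)
            assert ap.net_similarity == pytest.approx(bf.net_similarity, abs=1e-9)
            checked += 1
        assert checked >= 15
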