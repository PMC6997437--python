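import numpy as np
import pytest

from mdadti import (
    RWRConfig,
    SimilaritySet,
    SimilarityView,
    minmax_scale,
    ppmi,
    row_normalize,
    rwr_features,
    topologize,
)
from mdadti.toposim import ConfigError, DegenerateInputError

from conftest import random_similarity_view
from oracles import rwr_closed_form, rwr_step_distributions


def _view(vals, name="v"):
    return SimilarityView(
        name=name, labels=[f"e{i}" for i in range(len(vals))], values=np.asarray(vals, float)
    )


class TestRowNormalize:
    @pytest.mark.parametrize(
        "vals,expected",
        [
            ([[1, 1], [0, 1]], [[0.5, 0.5], [0, 1]]),
            ([[1, 0], [0, 1]], [[1, 0], [0, 1]]),
        ],
    )
    def test_forced_arithmetic(self, vals, expected):
        np.testing.assert_allclose(row_normalize(_view(vals)), expected)

    def test_zero_row_becomes_self_loop(self):
        T = row_normalize(_view([[0, 0], [1, 1]]))
        np.testing.assert_allclose(T, [[1, 0], [0.5, 0.5]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = random_similarity_view(rng, int(rng.integers(2, 8)))
            np.testing.assert_allclose(row_normalize(v).sum(axis=1), 1.0, atol=1e-12)


class TestRWR:
    def test_two_node_chain_hand_iteration(self):
        # transition [[0,1],[1,0]], alpha=0.5, T=2: p(1)=[.5,.5], p(2)=[.75,.25]
        v = _view([[0, 1], [1, 0]])
        P = rwr_features(v, RWRConfig(alpha=0.5, steps=2))
        np.testing.assert_allclose(P[0], [1.25, 0.75], atol=1e-12)

    def test_alpha_zero_rows_are_scaled_one_hot(self):
        rng = np.random.default_rng(5)
        v = random_similarity_view(rng, 6)
        P = rwr_features(v, RWRConfig(alpha=0.0, steps=3))
        np.testing.assert_allclose(P, 3 * np.eye(6), atol=1e-12)

    def test_matches_matrix_power_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            m = int(rng.integers(3, 11))
            v = random_similarity_view(rng, m)
            alpha = float(rng.random())
            T = int(rng.integers(1, 8))
            P = rwr_features(v, RWRConfig(alpha=alpha, steps=T))
            oracle = rwr_closed_form(row_normalize(v), alpha, T)
            np.testing.assert_allclose(P, oracle, atol=1e-9, rtol=0)

    def test_probability_conservation(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            v = random_similarity_view(rng, int(rng.integers(3, 10)))
            cfg = RWRConfig(alpha=0.8, steps=6)
            for p_t in rwr_step_distributions(row_normalize(v), cfg.alpha, cfg.steps):
                np.testing.assert_allclose(p_t.sum(axis=1), 1.0, atol=1e-9)
            P = rwr_features(v, cfg)
            np.testing.assert_allclose(P.sum(axis=1), cfg.steps, atol=1e-9)
            assert P.min() >= 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            RWRConfig(alpha=1.5)
        with pytest.raises(ConfigError):
            RWRConfig(steps=0)


class TestPPMI:
    def test_rank_one_independence_gives_zero_matrix(self):
        rng = np.random.default_rng(11)
        u, w = rng.random(6) + 0.1, rng.random(6) + 0.1
        X = ppmi(np.outer(u, w))
        np.testing.assert_allclose(X, 0.0, atol=1e-12)

    def test_identity_input_gives_identity(self):
        np.testing.assert_allclose(ppmi(np.eye(2)), np.eye(2), atol=1e-12)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(13)
        P = rng.random((7, 7))
        P = P + P.T
        X = ppmi(P)
        np.testing.assert_allclose(X, X.T, atol=1e-12)

    def test_nonnegative_and_finite_on_random_inputs(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            P = rng.random((int(rng.integers(2, 9)),) * 2)
            P[rng.random(P.shape) < 0.3] = 0.0  # include exact zeros
            if P.sum() == 0:
                continue
            X = ppmi(P)
            assert np.all(np.isfinite(X)) and X.min() >= 0
            assert np.all(X[P == 0] == 0)

    def test_all_zero_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ppmi(np.zeros((3, 3)))


class TestTopologize:
    def _sims(self, rng, m=8, n_views=3):
        return SimilaritySet(
            "drug", [random_similarity_view(rng, m, name=f"v{j}") for j in range(n_views)]
        )

    def test_structure_and_determinism(self):
        rng = np.random.default_rng(17)
        sims = self._sims(rng)
        out1 = topologize(sims, RWRConfig())
        out2 = topologize(sims, RWRConfig())
        assert out1.n_views == 3 and out1.labels == sims.labels
        for a, b in zip(out1.matrices, out2.matrices):
            np.testing.assert_array_equal(a, b)

    def test_duplicate_views_give_identical_outputs(self):
        rng = np.random.default_rng(19)
        v = random_similarity_view(rng, 6)
        dup = SimilarityView(name="dup", labels=v.labels, values=v.values.copy())
        out = topologize(SimilaritySet("drug", [v, dup]), RWRConfig())
        np.testing.assert_array_equal(out.matrices[0], out.matrices[1])

    def test_scaled_output_hits_zero_and_one(self):
        rng = np.random.default_rng(21)
        out = topologize(self._sims(rng), RWRConfig(), scale=True)
        for X in out.matrices:
            assert X.min() == 0.0 and X.max() == 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(23)
        v = random_similarity_view(rng, 7)
        perm = rng.permutation(7)
        v_perm = SimilarityView(
            name="p",
            labels=[v.labels[i] for i in perm],
            values=v.values[np.ix_(perm, perm)],
        )
        out = topologize(SimilaritySet("drug", [v]), RWRConfig())
        out_p = topologize(SimilaritySet("drug", [v_perm]), RWRConfig())
        np.testing.assert_allclose(
            out_p.matrices[0], out.matrices[0][np.ix_(perm, perm)], atol=1e-9
        )

    def test_minmax_scale_constant_matrix(self):
        np.testing.assert_array_equal(minmax_scale(np.full((3, 3), 2.0)), np.zeros((3, 3)))
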