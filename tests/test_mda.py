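import numpy as np
import pytest

from mdadti import (
    LayerConfig,
    MDATrainConfig,
    RWRConfig,
    SynthConfig,
    TopoFeatureSet,
    build_mda,
    decode,
    encode,
    extract_features,
    generate,
    train_mda,
)
from mdadti.dataset_model import Dataset, InteractionMatrix
from mdadti.mda import ConfigError


def _topo(rng, m=10, n=2, entity_kind="drug"):
    return TopoFeatureSet(
        entity_kind=entity_kind,
        labels=[f"e{i}" for i in range(m)],
        matrices=[rng.random((m, m)) for _ in range(n)],
        scaled=True,
    )


def _zero_params(model):
    for p in model.parameters():
        p[...] = 0.0


def shape_audit(config: LayerConfig) -> int:
    """Independent parameter count: walk the declared architecture."""
    n, m, d = config.n_modalities, config.input_dim, config.bottleneck
    widths = list(config.branch_widths)
    count = 0
    for _ in range(n):  # encoder branches
        prev = m
        for w in widths:
            count += prev * w + w
            prev = w
    concat = n * (widths[-1] if widths else m)
    count += concat * d + d  # fusion
    for _ in range(n):  # mirrored decoder branches
        prev = d
        for w in widths[::-1] + [m]:
            count += prev * w + w
            prev = w
    return count


class TestLayerConfig:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("n*100,50", ((100,), 50)),
            ("25", ((), 25)),
            ("[n*m, 50, n*m]", ((), 50)),
            ("[n*m, n*100, n*75, 50, n*75, n*100, n*m]", ((100, 75), 50)),
            ("[n*n_d, n*200, 100, n*200, n*n_d]", ((200,), 100)),
        ],
    )
    def test_parse_layer_strings(self, text, expected):
        assert LayerConfig.parse_widths(text) == expected

    def test_asymmetric_decoder_half_rejected(self):
        with pytest.raises(ConfigError):
            LayerConfig.parse_widths("[n*m, n*100, 50, n*75, n*m]")

    def test_zero_bottleneck_rejected(self):
        with pytest.raises(ConfigError):
            LayerConfig(2, 10, (), 0)


class TestBuildMDA:
    @pytest.mark.parametrize(
        "config",
        [
            LayerConfig(2, 40, (), 50),
            LayerConfig(3, 20, (100,), 25),
            LayerConfig(2, 15, (100, 75), 50),
        ],
    )
    def test_parameter_count_matches_shape_audit(self, config):
        model = build_mda(config, seed=0)
        assert model.n_parameters() == shape_audit(config)

    def test_same_seed_gives_bitwise_identical_parameters(self):
        cfg = LayerConfig(2, 12, (8,), 4)
        a, b = build_mda(cfg, seed=9), build_mda(cfg, seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)


class TestEncodeDecode:
    def test_encode_shape_and_open_interval(self):
        rng = np.random.default_rng(0)
        topo = _topo(rng, m=10, n=2)
        model = build_mda(LayerConfig(2, 10, (), 4), seed=1)
        H = encode(model, topo)
        assert H.shape == (10, 4)
        assert np.all((H > 0) & (H < 1))

    def test_zero_parameters_give_exact_half(self):
        rng = np.random.default_rng(0)
        topo = _topo(rng, m=6, n=2)
        model = build_mda(LayerConfig(2, 6, (5,), 3), seed=1)
        _zero_params(model)
        np.testing.assert_array_equal(encode(model, topo), np.full((6, 3), 0.5))
        recon = decode(model, np.full((6, 3), 0.5))
        assert len(recon) == 2
        for X in recon:
            np.testing.assert_array_equal(X, np.full((6, 6), 0.5))

    def test_entity_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        topo = _topo(rng, m=8, n=2)
        model = build_mda(LayerConfig(2, 8, (), 3), seed=3)
        H = encode(model, topo)
        perm = rng.permutation(8)
        topo_p = TopoFeatureSet(
            entity_kind="drug",
            labels=[topo.labels[i] for i in perm],
            matrices=[X[perm] for X in topo.matrices],
            scaled=True,
        )
        np.testing.assert_allclose(encode(model, topo_p), H[perm], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        model = build_mda(LayerConfig(2, 8, (), 3), seed=0)
        with pytest.raises(ValueError):
            encode(model, _topo(rng, m=9, n=2))
        with pytest.raises(ValueError):
            decode(model, np.zeros((5, 4)))


class TestTraining:
    def test_loss_descends_on_planted_fixture(self):
        rng = np.random.default_rng(6)
        topo = _topo(rng, m=30, n=2)
        model = build_mda(LayerConfig(2, 30, (), 8), seed=1)
        _, trace = train_mda(model, topo, MDATrainConfig(epochs=100, rng_seed=2))
        assert len(trace) == 100
        assert trace[-1] < trace[0]

    def test_zero_learning_rate_freezes_loss(self):
        rng = np.random.default_rng(8)
        topo = _topo(rng, m=12, n=2)
        model = build_mda(LayerConfig(2, 12, (), 4), seed=1)
        _, trace = train_mda(
            model, topo, MDATrainConfig(epochs=5, learning_rate=0.0, rng_seed=2)
        )
        assert len(set(trace)) == 1

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(10)
        mats = [rng.random((12, 12)) for _ in range(2)]
        traces = []
        for _ in range(2):
            topo = TopoFeatureSet("drug", [f"e{i}" for i in range(12)],
                                  [m.copy() for m in mats], True)
            model = build_mda(LayerConfig(2, 12, (), 4), seed=5)
            model, trace = train_mda(model, topo, MDATrainConfig(epochs=10, rng_seed=6))
            traces.append((trace, [p.copy() for p in model.parameters()]))
        assert traces[0][0] == traces[1][0]
        for pa, pb in zip(traces[0][1], traces[1][1]):
            np.testing.assert_array_equal(pa, pb)

    def test_gradients_match_directional_finite_differences(self):
        rng = np.random.default_rng(12)
        topo = _topo(rng, m=5, n=2)
        model = build_mda(LayerConfig(2, 5, (4,), 3), seed=7)
        xs = [np.asarray(X) for X in topo.matrices]
        _, cache = model._forward(xs)
        grads = model._backward(xs, cache)
        params = model.parameters()
        eps = 1e-6
        for trial in range(5):
            dirs = [rng.normal(size=p.shape) for p in params]
            analytic = sum(float(np.sum(g * d)) for g, d in zip(grads, dirs))
            for p, d in zip(params, dirs):
                p += eps * d
            lp = model.loss(xs)
            for p, d in zip(params, dirs):
                p -= 2 * eps * d
            lm = model.loss(xs)
            for p, d in zip(params, dirs):
                p += eps * d
            numeric = (lp - lm) / (2 * eps)
            assert abs(numeric - analytic) / max(abs(numeric), abs(analytic)) <= 1e-5


class TestExtractFeatures:
    def test_feature_dims_follow_bottlenecks(self, tiny_dataset):
        dataset, _, _ = tiny_dataset
        H_d, H_t = extract_features(
            dataset,
            LayerConfig(dataset.drug_sims.n_views, dataset.n_drugs, (), 50),
            LayerConfig(dataset.target_sims.n_views, dataset.n_targets, (), 25),
            RWRConfig(),
            MDATrainConfig(epochs=20, rng_seed=1),
        )
        assert H_d.shape == (dataset.n_drugs, 50)
        assert H_t.shape == (dataset.n_targets, 25)

    def test_branching_architecture_dims(self, tiny_dataset):
        dataset, _, _ = tiny_dataset
        H_d, H_t = extract_features(
            dataset,
            LayerConfig(dataset.drug_sims.n_views, dataset.n_drugs, (18,), 8),
            LayerConfig(dataset.target_sims.n_views, dataset.n_targets, (12,), 8),
            RWRConfig(),
            MDATrainConfig(epochs=20, rng_seed=1),
        )
        assert H_d.shape[1] == 8 and H_t.shape[1] == 8

    def test_unsupervised_features_ignore_interaction_labels(self, tiny_dataset):
        dataset, _, _ = tiny_dataset
        args = (
            LayerConfig(dataset.drug_sims.n_views, dataset.n_drugs, (), 6),
            LayerConfig(dataset.target_sims.n_views, dataset.n_targets, (), 6),
            RWRConfig(),
            MDATrainConfig(epochs=10, rng_seed=3),
        )
        H_d1, H_t1 = extract_features(dataset, *args)
        flipped = Dataset(
            drug_sims=dataset.drug_sims,
            target_sims=dataset.target_sims,
            interactions=InteractionMatrix(
                dataset.interactions.drug_labels,
                dataset.interactions.target_labels,
                1 - dataset.interactions.y,
            ),
        )
        H_d2, H_t2 = extract_features(flipped, *args)
        np.testing.assert_array_equal(H_d1, H_d2)
        np.testing.assert_array_equal(H_t1, H_t2)

    def test_planted_clusters_separate_in_feature_space(self):
        cfg = SynthConfig(
            n_drugs=30, n_targets=20, k_drug_clusters=2, k_target_clusters=2,
            n_drug_views=2, n_target_views=2, seed=17,
        )
        dataset, clusters = generate(cfg)
        H_d, _ = extract_features(
            dataset,
            LayerConfig(2, 30, (), 10),
            LayerConfig(2, 20, (), 10),
            RWRConfig(),
            MDATrainConfig(rng_seed=5),
        )
        cl = clusters["drug"]
        from scipy.spatial.distance import cdist

        D = cdist(H_d, H_d)
        same = cl[:, None] == cl[None, :]
        off = ~np.eye(len(cl), dtype=bool)
        assert D[~same].mean() > D[same & off].mean()
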