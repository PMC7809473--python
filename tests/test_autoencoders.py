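import numpy as np
import pytest

from overlapnet.autoencoders import (
    AutoencoderModel,
    AutoencoderSpec,
    CVPlan,
    build_autoencoder,
    canonical_specs,
    canonicalize_latents,
    closed_form_linear_ae,
    compare_architectures,
    explained_variance_score,
    reconstruction_mae,
    train_autoencoder,
    training_loss,
    xcov_penalty,
)
from overlapnet.errors import RankError, ShapeMismatchError, SpecError
from overlapnet.synthetic import SyntheticSpec, simulate_volumes

MEAN_PREDICTOR_SCORE = 1.0 - np.sqrt(2.0 / np.pi)  # 1 - E|Z|, Z ~ N(0,1)


class TestMetrics:
    def test_mae_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 4))
        assert reconstruction_mae(x, x) == 0.0
        assert explained_variance_score(x, x) == 1.0

    def test_mae_constant_offset(self):
        x = np.zeros((5, 3))
        assert reconstruction_mae(x, x + 0.5) == pytest.approx(0.5)
        assert explained_variance_score(x, x + 0.5) == pytest.approx(0.5)

    def test_zero_predictor_on_standard_normal(self):
        x = np.random.default_rng(1).normal(size=(200_000, 5))
        assert reconstruction_mae(x, np.zeros_like(x)) == pytest.approx(
            np.sqrt(2 / np.pi), abs=0.005)
        assert explained_variance_score(x, np.zeros_like(x)) == pytest.approx(
            MEAN_PREDICTOR_SCORE, abs=0.005)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            reconstruction_mae(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_score_is_one_minus_mae(self):
        rng = np.random.default_rng(2)
        x, xhat = rng.normal(size=(20, 6)), rng.normal(size=(20, 6))
        assert explained_variance_score(x, xhat) == pytest.approx(
            1.0 - reconstruction_mae(x, xhat))


class TestBuild:
    def test_baseline_shapes(self):
        model = build_autoencoder(AutoencoderSpec(), 36)
        assert [w.shape for w in model.weights] == [(36, 15), (15, 36)]

    def test_deep5_widths(self):
        spec = canonical_specs()["deep5"]
        model = build_autoencoder(spec, 36)
        assert model.widths == [36, 25, 20, 15, 20, 25, 36]
        assert spec.bottleneck_width == 15

    def test_same_seed_identical_init(self):
        a = build_autoencoder(AutoencoderSpec(seed=5), 12)
        b = build_autoencoder(AutoencoderSpec(seed=5), 12)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_tied_requires_symmetric_plan(self):
        with pytest.raises(SpecError):
            AutoencoderSpec(latent_layers=(25, 15), tied_weights=True)

    def test_canonical_set_bottleneck_15(self):
        for spec in canonical_specs().values():
            assert spec.bottleneck_width == 15

    def test_json_roundtrip(self, tmp_path):
        model = build_autoencoder(AutoencoderSpec(seed=3), 8)
        model.bottleneck_means = np.arange(15.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = AutoencoderModel.from_json(path)
        for wa, wb in zip(model.weights, back.weights):
            assert np.array_equal(wa, wb)
        assert np.array_equal(back.bottleneck_means, model.bottleneck_means)


class TestTrainingLoss:
    def test_no_penalty_is_pure_reconstruction(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 6))
        model = build_autoencoder(AutoencoderSpec(latent_layers=(3,)), 6)
        loss = training_loss(model, x)
        assert loss == pytest.approx(np.mean((model.reconstruct(x) - x) ** 2))

    def test_xcov_zero_for_uncorrelated_latents(self):
        h = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        assert xcov_penalty(h) == pytest.approx(0.0, abs=1e-12)

    def test_xcov_perfectly_correlated_unit_variance(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=1000)
        z = (z - z.mean()) / z.std()
        h = np.stack([z, z], axis=1)
        assert xcov_penalty(h) == pytest.approx(1.0, abs=1e-10)

    def test_l1_l2_penalties_added(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 4))
        for penalty, fn in [("l1", lambda w: np.abs(w).sum()),
                            ("l2", lambda w: (w**2).sum())]:
            spec = AutoencoderSpec(latent_layers=(2,), penalty=penalty,
                                   penalty_coefficient=0.7)
            model = build_autoencoder(spec, 4)
            expected = np.mean((model.reconstruct(x) - x) ** 2) \
                + 0.7 * sum(fn(w) for w in model.weights)
            assert training_loss(model, x) == pytest.approx(expected)


class TestGradients:
    """Finite-difference checks of the hand-written backprop."""

    @pytest.mark.parametrize("spec", [
        AutoencoderSpec(latent_layers=(3,), activation="identity"),
        AutoencoderSpec(latent_layers=(4, 3, 4), activation="relu"),
        AutoencoderSpec(latent_layers=(3,), penalty="l1", penalty_coefficient=0.1),
        AutoencoderSpec(latent_layers=(3,), penalty="l2", penalty_coefficient=0.1),
        AutoencoderSpec(latent_layers=(3,), penalty="xcov", penalty_coefficient=0.5),
        AutoencoderSpec(latent_layers=(3,), activation="relu", tied_weights=True),
    ], ids=["identity", "deep_relu", "l1", "l2", "xcov", "tied_relu"])
    def test_backward_matches_finite_differences(self, spec):
        from overlapnet.autoencoders import _backward

        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 5))
        model = build_autoencoder(spec, 5)
        grads_w, grads_b = _backward(model, x)
        eps = 1e-6
        free = range((model.n_layers + 1) // 2) if spec.tied_weights \
            else range(model.n_layers)
        for li in free:
            w = model.weights[li]
            idx = (w.shape[0] // 2, w.shape[1] // 2)
            orig = w[idx]
            w[idx] = orig + eps
            if spec.tied_weights:
                model._retie()
            up = training_loss(model, x)
            w = model.weights[li]
            w[idx] = orig - eps
            if spec.tied_weights:
                model._retie()
            down = training_loss(model, x)
            w[idx] = orig
            if spec.tied_weights:
                model._retie()
            assert grads_w[li][idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-8)


class TestTraining:
    def test_baseline_recovers_rank15_data(self, rank15_zscored):
        z = rank15_zscored.values
        spec = AutoencoderSpec(max_epochs=400, seed=1)
        model = train_autoencoder(spec, z[:500], z[500:])
        assert model.score(z[500:]) >= 0.99

    def test_huge_l1_collapses_to_mean_predictor(self, rank15_zscored):
        z = rank15_zscored.values
        spec = AutoencoderSpec(penalty="l1", penalty_coefficient=1e3,
                               max_epochs=150, seed=2)
        model = train_autoencoder(spec, z[:500], z[500:])
        assert np.max(np.abs(np.concatenate([w.ravel() for w in model.weights]))) < 0.05
        assert model.score(z[500:]) == pytest.approx(MEAN_PREDICTOR_SCORE, abs=0.05)

    def test_tied_weights_exact_after_training(self, rank15_zscored):
        z = rank15_zscored.values
        spec = AutoencoderSpec(name="tied_relu", activation="relu",
                               tied_weights=True, max_epochs=40, seed=3)
        model = train_autoencoder(spec, z[:500], z[500:])
        assert np.array_equal(model.weights[1], model.weights[0].T)

    def test_training_reproducible(self, rank15_zscored):
        z = rank15_zscored.values
        spec = AutoencoderSpec(max_epochs=30, seed=4)
        a = train_autoencoder(spec, z[:300], z[300:])
        b = train_autoencoder(spec, z[:300], z[300:])
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_xcov_training_decorrelates_latents(self):
        deltas = []
        for seed in range(5):
            spec = SyntheticSpec(n_participants=600, n_regions=12, n_factors=4,
                                 support_size=4, noise_sd=0.3, seed=seed)
            ds = simulate_volumes(spec)
            x = ds.volumes.values
            z = (x - x.mean(0)) / x.std(0)
            plain = train_autoencoder(
                AutoencoderSpec(latent_layers=(4,), max_epochs=150, seed=seed), z)
            pen = train_autoencoder(
                AutoencoderSpec(latent_layers=(4,), penalty="xcov",
                                penalty_coefficient=1.0, max_epochs=150, seed=seed), z)
            deltas.append(xcov_penalty(plain.encode(z)) - xcov_penalty(pen.encode(z)))
        assert all(d > 0 for d in deltas)


class TestClosedFormOracle:
    def test_rank_k_data_scores_one(self, rank15_zscored):
        model = closed_form_linear_ae(rank15_zscored.values, 15)
        assert model.score(rank15_zscored.values) == pytest.approx(1.0, abs=1e-9)

    def test_full_basis_is_identity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(50, 6))
        model = closed_form_linear_ae(x, 6)
        assert np.allclose(model.reconstruct(x), x, atol=1e-10)

    def test_rank_error(self):
        x = np.random.default_rng(9).normal(size=(30, 2)) @ np.ones((2, 6))
        with pytest.raises(RankError):
            closed_form_linear_ae(x, 3)

    def test_oracle_dominates_trained_model(self, rank15_zscored):
        z = rank15_zscored.values[:400]
        trained = train_autoencoder(AutoencoderSpec(max_epochs=200, seed=5), z)
        oracle = closed_form_linear_ae(z, 15)
        mse_trained = np.mean((trained.reconstruct(z) - z) ** 2)
        mse_oracle = np.mean((oracle.reconstruct(z) - z) ** 2)
        assert mse_trained >= mse_oracle - 1e-6

    def test_encode_decode_roundtrip_on_rank_k(self, rank15_zscored):
        z = rank15_zscored.values
        model = closed_form_linear_ae(z, 15)
        assert np.allclose(model.decode(model.encode(z)), z, atol=1e-8)


class TestEncode:
    def test_identity_model_encode_is_affine(self):
        model = build_autoencoder(AutoencoderSpec(latent_layers=(4,)), 8)
        rng = np.random.default_rng(10)
        x1, x2 = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        alpha = 0.3
        mix = model.encode(alpha * x1 + (1 - alpha) * x2)
        assert np.allclose(mix, alpha * model.encode(x1) + (1 - alpha) * model.encode(x2),
                           atol=1e-10)

    def test_zero_weight_model_returns_bias(self):
        model = build_autoencoder(AutoencoderSpec(latent_layers=(3,)), 5)
        model.weights[0][:] = 0.0
        model.biases[0][:] = [1.0, 2.0, 3.0]
        out = model.encode(np.random.default_rng(11).normal(size=(4, 5)))
        assert np.allclose(out, [1.0, 2.0, 3.0])

    def test_encode_shape_check(self):
        model = build_autoencoder(AutoencoderSpec(), 36)
        with pytest.raises(ShapeMismatchError):
            model.encode(np.zeros((3, 10)))


class TestCanonicalization:
    def test_preserves_input_output_map(self, rank15_zscored):
        z = rank15_zscored.values[:300]
        model = train_autoencoder(AutoencoderSpec(max_epochs=50, seed=6), z)
        canon = canonicalize_latents(model, z)
        assert np.allclose(canon.reconstruct(z), model.reconstruct(z), atol=1e-8)

    def test_diagonalizes_latent_covariance(self, rank15_zscored):
        z = rank15_zscored.values[:300]
        model = train_autoencoder(AutoencoderSpec(max_epochs=100, seed=6), z)
        canon = canonicalize_latents(model, z)
        cov = np.cov(canon.encode(z), rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(cov))
        assert np.all(np.diff(np.diag(cov)) <= 1e-8)

    def test_rejects_relu(self):
        model = build_autoencoder(AutoencoderSpec(activation="relu"), 8)
        with pytest.raises(SpecError):
            canonicalize_latents(model, np.zeros((4, 8)))


@pytest.fixture(scope="module")
def report(rank15_zscored):
    specs = [AutoencoderSpec(name="baseline", max_epochs=60, seed=0),
             AutoencoderSpec(name="deep3", activation="relu",
                             latent_layers=(25, 15, 25), max_epochs=60, seed=0)]
    return compare_architectures(specs, rank15_zscored.values,
                                 CVPlan(outer_folds=3, inner_folds=5, seed=0))


class TestCompareArchitectures:
    def test_no_deep_advantage_on_linear_data(self, report):
        base = report.row("baseline")
        deep = report.row("deep3")
        assert base["mean_score"] >= deep["mean_score"] - deep["sd_score"]

    def test_report_structure(self, report):
        assert set(report.table.index) == {"baseline", "deep3"}
        assert (report.table["sd_score"] >= 0).all()
        assert report.winner in report.table.index

    def test_duplicate_specs_identical_rows(self, rank15_zscored):
        spec = AutoencoderSpec(name="a", max_epochs=20, seed=0)
        dup = AutoencoderSpec(name="b", max_epochs=20, seed=0)
        rep = compare_architectures([spec, dup], rank15_zscored.values[:200],
                                    CVPlan(outer_folds=2, inner_folds=2, seed=1))
        assert rep.row("a")["mean_score"] == pytest.approx(rep.row("b")["mean_score"])
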