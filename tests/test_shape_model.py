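"""Point-distribution model: alignment, PCA construction, sampling, inversion."""

import numpy as np
import pytest

import octsynth as oc
from octsynth.shape_model import (
    DegenerateShapeError,
    DimensionError,
    InsufficientDataError,
)


def _random_shape(rng, n=20, dim=3):
    return oc.ShapeVector.from_points(rng.normal(0, 10, size=(n, dim)))


def _random_rotation(rng, dim=3):
    q, r = np.linalg.qr(rng.normal(size=(dim, dim)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestAlignment:
    def test_identical_shapes_align_to_identity(self, rng):
        a = _random_shape(rng)
        aligned, transforms = oc.align_shapes([a, a])
        for al, tr in zip(aligned, transforms):
            assert np.allclose(al.coords, a.coords, atol=1e-8)
            assert np.allclose(tr.rotation, np.eye(3), atol=1e-8)
            assert abs(tr.scale - 1) < 1e-8
            assert np.allclose(tr.translation, 0, atol=1e-8)

    def test_translation_removed(self, rng):
        a = _random_shape(rng)
        b = oc.ShapeVector.from_points(a.points + np.array([5.0, 3.0, -2.0]))
        aligned, _ = oc.align_shapes([a, b])
        assert np.linalg.norm(aligned[0].coords - aligned[1].coords) < 1e-6

    def test_rotation_and_scale_recovered(self, rng):
        a = _random_shape(rng)
        R = _random_rotation(rng)
        b = oc.ShapeVector.from_points(1.7 * a.points @ R.T + np.array([1.0, -4.0, 2.0]))
        aligned, _ = oc.align_shapes([a, b])
        assert np.linalg.norm(aligned[0].coords - aligned[1].coords) < 1e-6

    def test_alignment_idempotent(self, rng):
        shapes = [_random_shape(rng) for _ in range(4)]
        aligned, _ = oc.align_shapes(shapes)
        again, _ = oc.align_shapes(aligned)
        for a, b in zip(aligned, again):
            assert np.linalg.norm(a.coords - b.coords) < 1e-6

    def test_mismatched_landmark_counts_rejected(self, rng):
        a = _random_shape(rng, n=20)
        b = _random_shape(rng, n=21)
        with pytest.raises(DimensionError):
            oc.align_shapes([a, b])

    def test_degenerate_shape_rejected(self, rng):
        a = _random_shape(rng)
        b = oc.ShapeVector.from_points(np.ones((20, 3)))
        with pytest.raises(DegenerateShapeError):
            oc.align_shapes([a, b])


class TestBuildPdm:
    def test_identical_shapes_zero_variance(self, rng):
        a = _random_shape(rng)
        model = oc.build_pdm([a] * 5)
        assert model.t == 1
        assert np.allclose(model.variances, 0)
        assert np.allclose(model.mean.coords, a.coords)

    def test_rank_one_hand_eigendecomposition(self):
        # two shapes ±1 along one coordinate about the mean: the 1/N
        # covariance is the rank-1 matrix e·eᵀ with eigenvalue (1²+1²)/2 = 1
        base = np.zeros(12)
        x1, x2 = base.copy(), base.copy()
        x1[4] += 1.0
        x2[4] -= 1.0
        shapes = [oc.ShapeVector(coords=c, n_landmarks=4, dim=3) for c in (x1, x2)]
        model = oc.build_pdm(shapes)
        assert model.t == 1
        assert model.variances[0] == pytest.approx(1.0, abs=1e-12)
        expected_mode = np.zeros(12)
        expected_mode[4] = 1.0
        assert np.allclose(np.abs(model.modes[0]), expected_mode, atol=1e-12)

    def test_eigenpairs_match_explicit_covariance(self, rng):
        # brute-force oracle: assemble S = (1/N) Σ (x̄−xᵢ)(x̄−xᵢ)ᵀ explicitly
        shapes = [_random_shape(rng, n=8) for _ in range(6)]
        model = oc.build_pdm(shapes, variance_fraction=1.0)
        X = np.stack([s.coords for s in shapes])
        mean = X.mean(axis=0)
        S = sum(np.outer(mean - x, mean - x) for x in X) / len(X)
        w, v = np.linalg.eigh(S)
        w, v = w[::-1], v[:, ::-1]
        assert np.allclose(model.variances, w[: model.t], atol=1e-9)
        for i in range(model.t):
            dot = abs(float(model.modes[i] @ v[:, i]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_cumulative_variance_rule(self, landmarked):
        vecs, _ = landmarked
        aligned, _ = oc.align_shapes(vecs)
        model = oc.build_pdm(aligned, variance_fraction=0.94)
        share = model.variances.sum() / model.total_variance
        assert share >= 0.94
        # minimality: dropping the last mode falls below the threshold
        if model.t > 1:
            assert model.variances[:-1].sum() / model.total_variance < 0.94

    def test_variances_sorted_and_orthonormal(self, trained_model):
        model, _ = trained_model
        assert np.all(np.diff(model.variances) <= 1e-12)
        assert np.allclose(model.modes @ model.modes.T, np.eye(model.t), atol=1e-8)

    def test_too_few_shapes_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            oc.build_pdm([_random_shape(rng)])


class TestSampling:
    def test_zero_coefficients_return_mean(self, trained_model):
        model, _ = trained_model
        out = oc.sample_shape(model, np.zeros(model.t))
        assert np.array_equal(out.coords, model.mean.coords)

    def test_constrained_sampling_clips_to_limit(self, trained_model):
        model, _ = trained_model
        b = np.zeros(model.t)
        b[0] = 5 * np.sqrt(model.variances[0])
        with pytest.warns(UserWarning):
            out = oc.sample_shape(model, b, constrained=True)
        expected = model.mean.coords + 3 * np.sqrt(model.variances[0]) * model.modes[0]
        assert np.allclose(out.coords, expected, atol=1e-9)

    def test_unconstrained_sampling_passes_through(self, trained_model):
        model, _ = trained_model
        b = np.zeros(model.t)
        b[0] = 5 * np.sqrt(model.variances[0])
        out = oc.sample_shape(model, b, constrained=False)
        expected = model.mean.coords + b[0] * model.modes[0]
        assert np.allclose(out.coords, expected, atol=1e-9)

    def test_wrong_length_rejected(self, trained_model):
        model, _ = trained_model
        with pytest.raises(DimensionError):
            oc.sample_shape(model, np.zeros(model.t + 1))

    def test_seeded_draws_reproducible(self, trained_model):
        model, _ = trained_model
        b1 = oc.random_coefficients(model, 42)
        b2 = oc.random_coefficients(model, 42)
        assert np.array_equal(b1.b, b2.b)

    def test_constrained_draws_respect_limits(self, trained_model):
        model, _ = trained_model
        rng = np.random.default_rng(7)
        std = np.sqrt(model.variances)
        worst = 0.0
        for _ in range(2000):
            b = oc.random_coefficients(model, rng, constrained=True).b
            worst = max(worst, float(np.max(np.abs(b) / std)))
        assert worst <= 3.0

    def test_unconstrained_variance_matches_model(self, trained_model):
        # Monte-Carlo check that b_i ~ Normal(0, σ_i)
        model, _ = trained_model
        rng = np.random.default_rng(5)
        draws = np.stack(
            [oc.random_coefficients(model, rng, constrained=False).b for _ in range(10_000)]
        )
        sample_var = draws.var(axis=0)
        assert np.all(np.abs(sample_var - model.variances) <= 0.1 * model.variances)


class TestProjection:
    def test_mean_projects_to_zero(self, trained_model):
        model, _ = trained_model
        b = oc.project_shape(model, model.mean)
        assert np.allclose(b.b, 0, atol=1e-10)

    def test_roundtrip_recovers_coefficients(self, trained_model):
        model, _ = trained_model
        rng = np.random.default_rng(3)
        b_star = rng.normal(0, 1, size=model.t) * np.sqrt(model.variances)
        shape = oc.sample_shape(model, b_star, constrained=False)
        b_hat = oc.project_shape(model, shape)
        assert np.max(np.abs(b_hat.b - b_star)) < 1e-8

    def test_off_subspace_residual_orthogonal_to_modes(self, trained_model):
        model, _ = trained_model
        rng = np.random.default_rng(9)
        x = oc.ShapeVector(
            coords=model.mean.coords + rng.normal(0, 5, model.mean.coords.size),
            n_landmarks=model.mean.n_landmarks,
            dim=model.dim,
        )
        b = oc.project_shape(model, x)
        recon = model.mean.coords + model.modes.T @ b.b
        residual = x.coords - recon
        assert np.max(np.abs(model.modes @ residual)) < 1e-8


class TestPersistence:
    def test_save_load_roundtrip(self, trained_model, tmp_path):
        model, _ = trained_model
        path = tmp_path / "model.json"
        oc.save_pdm(model, path, provenance={"seed": 11})
        loaded = oc.load_pdm(path)
        assert np.array_equal(loaded.mean.coords, model.mean.coords)
        assert np.array_equal(loaded.modes, model.modes)
        assert np.array_equal(loaded.variances, model.variances)
        assert loaded.total_variance == model.total_variance
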