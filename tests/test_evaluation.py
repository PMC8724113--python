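"""Evaluation battery: thickness maps, projections, GLCM features, K-S."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import octsynth as oc
from octsynth.evaluation import EvaluationError, glcm_features

from conftest import flat_surfaces


def glcm_bruteforce(region, n_levels, offset):
    """Independent double-loop oracle for the four co-occurrence features."""
    region = np.asarray(region, dtype=float)
    lo, hi = region.min(), region.max()
    if hi > lo:
        q = np.clip(np.floor((region - lo) / (hi - lo) * n_levels), 0, n_levels - 1).astype(int)
    else:
        q = np.zeros_like(region, dtype=int)
    dr, dc = offset
    H, W = region.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[q[r, c], q[r2, c2]] += 1
    p = counts / counts.sum()
    energy = contrast = homogeneity = 0.0
    mu_x = mu_y = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            energy += p[i, j] ** 2
            contrast += (i - j) ** 2 * p[i, j]
            homogeneity += p[i, j] / (1 + (i - j) ** 2)
            mu_x += i * p[i, j]
            mu_y += j * p[i, j]
    sx = sy = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            sx += (i - mu_x) ** 2 * p[i, j]
            sy += (j - mu_y) ** 2 * p[i, j]
    sx, sy = np.sqrt(sx), np.sqrt(sy)
    corr = float("nan")
    if sx > 0 and sy > 0:
        corr = sum(
            ((i - mu_x) / sx) * ((j - mu_y) / sy) * p[i, j]
            for i in range(n_levels)
            for j in range(n_levels)
        )
    return energy, contrast, homogeneity, corr


def ks_bruteforce(a, b):
    """Exhaustive ECDF-gap enumeration over the pooled points."""
    a, b = np.sort(a), np.sort(b)
    pooled = np.concatenate([a, b])
    gaps = [
        abs(np.searchsorted(a, t, side="right") / a.size
            - np.searchsorted(b, t, side="right") / b.size)
        for t in pooled
    ]
    return max(gaps)


class TestThickness:
    def test_flat_pair_constant_map(self):
        s = flat_surfaces([100.0, 115.0])
        tm = oc.thickness_map(s, (1, 2))
        assert np.all(tm.values == 15.0)
        assert tm.units == "voxels"

    def test_spacing_converts_to_micrometres(self):
        s = flat_surfaces([100.0, 115.0], spacing=(10.0, 200.0, 4.0))
        tm = oc.thickness_map(s, (1, 2))
        assert np.all(tm.values == 60.0)
        assert tm.units == "um"

    def test_telescoping_identity(self, phantom_surfaces):
        s = phantom_surfaces[0]
        total = oc.thickness_map(s, (1, s.n_surfaces)).values
        parts = sum(
            oc.thickness_map(s, (k, k + 1)).values for k in range(1, s.n_surfaces)
        )
        assert np.allclose(total, parts, atol=1e-9)

    def test_bad_pair_rejected(self, phantom_surfaces):
        with pytest.raises(EvaluationError):
            oc.thickness_map(phantom_surfaces[0], (3, 2))


class TestProjection:
    def test_constant_volume_constant_projection(self):
        s = flat_surfaces([50.0, 80.0])
        vol = oc.OCTVolume(intensities=np.full((2, 200, 8), 0.5))
        proj = oc.projection_image(vol, s, (1, 2))
        assert np.allclose(proj, 0.5)

    def test_two_row_band_mean(self):
        s = flat_surfaces([100.0, 102.0], width=4)
        arr = np.zeros((2, 200, 4))
        arr[:, 100, :] = 0.2
        arr[:, 101, :] = 0.8
        proj = oc.projection_image(oc.OCTVolume(intensities=arr), s, (1, 2))
        assert np.allclose(proj, 0.5)

    def test_vessel_free_projection_matches_layer_mean_mixture(
        self, phantom_surfaces, small_config
    ):
        # analytic oracle: projection between surfaces 1..K is the
        # thickness-weighted mixture of the per-layer brightnesses
        s = phantom_surfaces[0]
        mu = np.asarray(small_config.layer_brightness)
        vol = oc.render_layers(s, oc.LayerAppearance(layer_brightness=mu))
        proj = oc.projection_image(vol, s, (1, s.n_surfaces))
        z = s.surfaces
        rows_between = np.ceil(z[-1]) - np.ceil(z[0])
        weighted = sum(
            (np.ceil(z[k + 1]) - np.ceil(z[k])) * mu[k] for k in range(len(mu))
        )
        expected = weighted / np.maximum(rows_between, 1)
        assert np.allclose(proj, expected, atol=1e-9)

    def test_degenerate_band_rejected(self):
        s = flat_surfaces([100.0, 100.0])
        vol = oc.OCTVolume(intensities=np.zeros((2, 200, 8)))
        with pytest.raises(EvaluationError):
            oc.projection_image(vol, s, (1, 2))


class TestGLCM:
    def test_constant_region(self):
        f = glcm_features(np.full((5, 5), 0.3), n_levels=4)
        assert f.energy == pytest.approx(1.0)
        assert f.contrast == pytest.approx(0.0)
        assert f.homogeneity == pytest.approx(1.0)
        assert np.isnan(f.correlation)

    def test_hand_counted_two_by_two(self):
        # [[0,0],[1,1]], 2 levels, offset (0,1): the two horizontal pairs
        # are (0,0) and (1,1), each with probability 1/2
        f = glcm_features(np.array([[0.0, 0.0], [1.0, 1.0]]), n_levels=2, offset=(0, 1))
        assert f.energy == pytest.approx(0.5)
        assert f.contrast == pytest.approx(0.0)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.correlation == pytest.approx(1.0)

    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (0, 2)])
    def test_matches_bruteforce_oracle(self, offset):
        rng = np.random.default_rng(17)
        for _ in range(100):
            region = rng.uniform(0, 1, size=(8, 8))
            f = glcm_features(region, n_levels=8, offset=offset)
            e, c, h, r = glcm_bruteforce(region, 8, offset)
            assert f.energy == pytest.approx(e, abs=1e-12)
            assert f.contrast == pytest.approx(c, abs=1e-12)
            assert f.homogeneity == pytest.approx(h, abs=1e-12)
            assert f.correlation == pytest.approx(r, abs=1e-12)

    def test_feature_ranges(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = glcm_features(rng.uniform(0, 1, (10, 10)), n_levels=8)
            assert 0 < f.energy <= 1
            assert 0 < f.homogeneity <= 1
            assert f.contrast >= 0
            assert -1 <= f.correlation <= 1

    def test_region_feature_table_shape(self, dme_library):
        model_scene = oc.DMEScene(
            image=dme_library[0].image,
            boundaries=dme_library[0].boundaries,
            fluid_mask=dme_library[0].fluid_mask,
        )
        tbl = oc.region_features(model_scene, layer_indices=(1, 3, 5))
        assert len(tbl) == 4 * 3
        assert set(tbl["region"]) == {"layer_1", "layer_3", "layer_5"}


class TestKS:
    def test_identical_samples_zero_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = oc.ks_two_sample(a, a)
        assert res.statistic == 0.0

    def test_disjoint_supports_full_statistic(self):
        res = oc.ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.statistic == 1.0

    def test_enumerated_ecdf_example(self):
        res = oc.ks_two_sample([1.0, 2.0], [1.5, 2.5])
        assert res.statistic == pytest.approx(0.5)

    def test_matches_ecdf_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 11))
            b = rng.normal(size=rng.integers(2, 11))
            res = oc.ks_two_sample(a, b)
            assert res.statistic == pytest.approx(ks_bruteforce(a, b), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=3, max_size=20),
        st.lists(st.integers(-1000, 1000), min_size=3, max_size=20),
    )
    def test_invariant_under_monotone_transform(self, a, b):
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        d0 = oc.ks_two_sample(a, b).statistic
        f = lambda x: np.exp(0.05 * x) + 3 * x
        d1 = oc.ks_two_sample(f(a), f(b)).statistic
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(EvaluationError):
            oc.ks_two_sample([1.0], [1.0, 2.0])

    def test_qq_points_are_quantiles(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(size=40)
        res = oc.ks_two_sample(a, b)
        assert res.qq_points.shape == (30, 2)
        assert np.all(np.diff(res.qq_points[:, 0]) >= 0)


class TestCompareGroups:
    def test_identical_groups_full_agreement(self, phantom_surfaces):
        group = phantom_surfaces[:4]
        img = np.random.default_rng(0).uniform(0, 1, (128, 64))
        imgs = [img] * 4
        rep = oc.compare_groups(group, list(group), real_images=imgs, synth_images=imgs)
        assert np.allclose(rep.thickness["p_value"].to_numpy(), 1.0)
        assert np.all(rep.ks["D"] == 0.0)

    def test_report_mirrors_layer_table_layout(self, phantom_surfaces):
        rep = oc.compare_groups(phantom_surfaces[:4], phantom_surfaces[4:])
        assert list(rep.thickness["layer"]) == ["total_macula", "RNFL", "GCIPL", "RPE"]
        for col in ("real_mean", "real_sd", "synth_mean", "synth_sd", "p_value"):
            assert col in rep.thickness.columns

    def test_single_member_group_descriptive_only(self, phantom_surfaces):
        rep = oc.compare_groups(phantom_surfaces[:1], phantom_surfaces[1:3])
        assert np.all(np.isnan(rep.thickness["p_value"]))

    def test_type_one_error_rate_near_alpha(self):
        # two groups drawn from the same phantom distribution: the Welch
        # test should reject at ~the nominal 5% level
        pvals = []
        for rep_i in range(50):
            cfg_a = oc.PhantomConfig.scaled(
                n_volumes=8, n_bscans=3, width=48, height=96, rng_seed=1000 + 2 * rep_i
            )
            cfg_b = oc.PhantomConfig.scaled(
                n_volumes=8, n_bscans=3, width=48, height=96, rng_seed=1001 + 2 * rep_i
            )
            ga = oc.generate_surfaces(cfg_a)
            gb = oc.generate_surfaces(cfg_b)
            report = oc.compare_groups(ga, gb)
            pvals.extend(report.thickness["p_value"].tolist())
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert abs(frac - 0.05) <= 0.03
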