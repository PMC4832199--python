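"""GLCM/Haralick, ranklet, decomposition, angle averaging, bootstrap selection."""

import numpy as np
import pandas as pd
import pytest

from cadx.texture import (
    GlcmSpec,
    RankletSpec,
    average_over_angles,
    bootstrap_select,
    curve_features,
    decompose,
    glcm,
    haralick,
    quantize,
    rank_features,
    ranklet_response,
    ranklet_transform,
    HARALICK_NAMES,
    RANK_SUBSET,
    FeatureVector,
    _orientation_split,
)

from _oracles import glcm_bruteforce, haralick_naive, ranklet_pairs


class TestGlcm:
    def test_constant_image_single_cell(self):
        spec = GlcmSpec(levels=4)
        P = glcm(np.full((6, 6), 2, dtype=np.uint8), spec, 1, 0)
        assert P[2, 2] == 1.0
        assert P.sum() == 1.0

    def test_two_by_two_hand_example(self):
        img = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        P = glcm(img, GlcmSpec(levels=2), 1, 0)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matches_bruteforce_enumeration(self, angle, rng):
        spec = GlcmSpec(levels=8)
        for _ in range(12):
            img = rng.integers(0, 8, size=(8, 8)).astype(np.uint8)
            P = glcm(img, spec, 1, angle)
            O = glcm_bruteforce(img, 8, 1, angle)
            assert np.array_equal(P, O)

    def test_normalization_sums_to_one(self, rng):
        img = rng.integers(0, 16, size=(12, 12)).astype(np.uint8)
        for angle in (0, 45, 90, 135):
            assert glcm(img, GlcmSpec(), 1, angle).sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_levels_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.full((4, 4), 16, dtype=np.uint8), GlcmSpec(levels=16), 1, 0)


class TestHaralick:
    def test_degenerate_distribution(self):
        P = glcm(np.full((6, 6), 1, dtype=np.uint8), GlcmSpec(levels=4), 1, 0)
        f = haralick(P).as_dict()
        assert f["energy"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["entropy"] == pytest.approx(0.0)

    def test_checkerboard_contrast_is_squared_level_gap(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 3  # levels 0 and 3
        P = glcm(board.astype(np.uint8), GlcmSpec(levels=4), 1, 0)
        f = haralick(P).as_dict()
        assert f["contrast"] == pytest.approx(9.0)  # every pair differs by 3

    def test_all_features_match_direct_summation(self, rng):
        for _ in range(20):
            raw = rng.uniform(size=(6, 6))
            P = (raw + raw.T) / (2 * raw.sum())
            mine = haralick(P).as_dict()
            oracle = haralick_naive(P)
            for name in HARALICK_NAMES:
                assert mine[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_symmetric_glcm_invariant_to_180_degree_rotation(self, rng):
        img = rng.integers(0, 8, size=(10, 10)).astype(np.uint8)
        spec = GlcmSpec(levels=8)
        for angle in (0, 45, 90, 135):
            a = haralick(glcm(img, spec, 1, angle)).values
            b = haralick(glcm(img[::-1, ::-1].copy(), spec, 1, angle)).values
            assert np.allclose(a, b, atol=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            haralick(np.ones((4, 4)))

    def test_rank_subset_has_twelve_names(self):
        assert len(RANK_SUBSET) == 12
        P = glcm(np.arange(16).reshape(4, 4).astype(np.uint8) % 4, GlcmSpec(levels=4), 1, 0)
        assert haralick(P, subset=RANK_SUBSET).names == RANK_SUBSET


class TestRanklet:
    def test_fully_separated_window_is_plus_one(self):
        win = np.zeros((4, 4))
        win[:, 2:] = 5.0  # treatment (right half) all larger
        assert ranklet_response(win, "vertical") == pytest.approx(1.0)

    def test_constant_window_is_zero(self):
        for orient in ("vertical", "horizontal", "diagonal"):
            assert ranklet_response(np.ones((6, 6)), orient) == pytest.approx(0.0)

    @pytest.mark.parametrize("orient", ["vertical", "horizontal", "diagonal"])
    def test_matches_all_pairs_counting(self, orient, rng):
        for _ in range(10):
            win = rng.integers(0, 5, size=(6, 6)).astype(float)  # ties likely
            t = _orientation_split(6, orient)
            assert ranklet_response(win, orient) == pytest.approx(ranklet_pairs(win, t), abs=1e-12)

    def test_transform_shapes_and_range(self, rng):
        img = rng.uniform(size=(20, 24))
        out = ranklet_transform(img, RankletSpec(window_sizes=(4,)))
        assert set(out) == {(4, "vertical"), (4, "horizontal"), (4, "diagonal")}
        for resp in out.values():
            assert resp.shape == (17, 21)
            assert resp.min() >= -1.0 and resp.max() <= 1.0

    def test_invariant_under_monotone_intensity_transforms(self, rng):
        transforms = [lambda x: 2 * x + 3, lambda x: x**3, np.expm1]
        for _ in range(10):
            img = rng.uniform(size=(12, 12))
            base = ranklet_transform(img, RankletSpec(window_sizes=(4, 6)))
            for f in transforms:
                warped = ranklet_transform(f(img), RankletSpec(window_sizes=(4, 6)))
                for key in base:
                    assert np.array_equal(base[key], warped[key])

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            RankletSpec(window_sizes=(5,))


class TestDecompose:
    def test_identity_returns_input(self, rng):
        img = rng.uniform(size=(16, 16))
        dec = decompose(img, method="identity")
        assert dec.names == ["identity"]
        assert np.array_equal(dec.bands[0], img)

    def test_two_level_wavelet_has_seven_bands(self, rng):
        dec = decompose(rng.uniform(size=(28, 28)), method="wavelet")
        assert len(dec.bands) == 7
        assert dec.names[0] == "approx_2"

    def test_perfect_reconstruction(self, rng):
        img = rng.uniform(size=(28, 28))
        dec = decompose(img, method="wavelet")
        assert np.abs(dec.reconstruct() - img).max() < 1e-8

    def test_plugin_callable(self, rng):
        img = rng.uniform(size=(10, 10))
        dec = decompose(img, method=lambda x: [("halved", x / 2)])
        assert dec.names == ["halved"]
        assert np.allclose(dec.bands[0], img / 2)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            decompose(rng.uniform(size=(10, 10)), method="curvelet")

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.ones((4, 4)))


class TestAverageOverAngles:
    def test_single_angle_identity(self):
        f = FeatureVector(names=["a", "b"], values=[1.0, 2.0])
        out = average_over_angles([f])
        assert np.array_equal(out.values, f.values)

    def test_elementwise_mean(self):
        fs = [FeatureVector(names=["a"], values=[1.0]), FeatureVector(names=["a"], values=[3.0])]
        assert average_over_angles(fs).values[0] == pytest.approx(2.0)

    def test_matches_bruteforce_loop(self, rng):
        names = [f"f{i}" for i in range(14)]
        fs = [FeatureVector(names=names, values=rng.normal(size=14)) for _ in range(4)]
        out = average_over_angles(fs)
        for i in range(14):
            assert out.values[i] == pytest.approx(np.mean([f.values[i] for f in fs]), abs=1e-12)

    def test_name_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_over_angles(
                [FeatureVector(names=["a"], values=[1.0]), FeatureVector(names=["b"], values=[1.0])]
            )


class TestBootstrapSelect:
    def _table(self, rng, n=80):
        y = ["malignant" if i % 2 else "benign" for i in range(n)]
        sig = np.array([1.0 if l == "malignant" else 0.0 for l in y]) + rng.normal(0, 0.05, n)
        X = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(6)})
        X.insert(3, "signal", sig)
        return X, y

    def test_perfect_feature_always_selected(self, rng):
        X, y = self._table(rng)
        names = bootstrap_select(X, y, B=50, k=2, tau=1.0, rng=rng)
        assert names[0] == "signal"

    def test_threshold_extremes(self, rng):
        X, y = self._table(rng)
        pooled = bootstrap_select(X, y, B=10, k=3, tau=0.0, rng=np.random.default_rng(1))
        assert "signal" in pooled and len(pooled) >= 3
        assert bootstrap_select(X, y, B=10, k=3, tau=1.5, rng=np.random.default_rng(1)) == []

    def test_same_seed_same_selection(self, rng):
        X, y = self._table(rng)
        a = bootstrap_select(X, y, B=20, k=3, tau=0.3, rng=np.random.default_rng(7))
        b = bootstrap_select(X, y, B=20, k=3, tau=0.3, rng=np.random.default_rng(7))
        assert a == b


class TestStacks:
    def test_rank_stack_names_and_finiteness(self, rng):
        roi = rng.uniform(size=(24, 24))
        f = rank_features(roi, RankletSpec(window_sizes=(4,)))
        assert len(f.names) == 3 * 12  # 1 window x 3 orientations x 12 features
        assert np.all(np.isfinite(f.values))

    def test_curve_stack_names_and_finiteness(self, rng):
        patch = rng.uniform(size=(28, 28))
        f = curve_features(patch)
        assert len(f.names) == 7 * 14  # 7 bands x 14 features
        assert np.all(np.isfinite(f.values))

    def test_quantize_range_handling(self):
        assert quantize(np.zeros((3, 3)), 16).max() == 0
        q = quantize(np.array([[-1.0, 1.0]]), 4, value_range=(-1.0, 1.0000001))
        assert q[0, 0] == 0 and q[0, 1] == 3
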