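"""Candidate construction, LCoV smoothness, and flat-field selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rankflat as rf
from oracles import naive_candidates, naive_lcov, naive_smoothness


def _stack(arr, **kw):
    return rf.TileStack(np.asarray(arr, dtype=float), **kw)


class TestBuildCandidates:
    def test_descending_sort_single_pixel(self):
        stack = _stack(np.array([5, 9, 7]).reshape(3, 1, 1, 1))
        cands = rf.build_candidates(stack)
        np.testing.assert_array_equal(cands.ranks.ravel(), [9, 7, 5])

    def test_per_pixel_independence(self):
        stack = _stack(np.array([[[1, 4]], [[3, 2]]])[..., None])
        cands = rf.build_candidates(stack)
        np.testing.assert_array_equal(cands.rank(1)[..., 0], [[3, 4]])
        np.testing.assert_array_equal(cands.rank(2)[..., 0], [[1, 2]])

    def test_per_channel_independence(self):
        stack = _stack(np.array([[[[10, 0, 5]]], [[[2, 8, 5]]]]))
        cands = rf.build_candidates(stack)
        np.testing.assert_array_equal(cands.rank(1).ravel(), [10, 8, 5])
        np.testing.assert_array_equal(cands.rank(2).ravel(), [2, 0, 5])

    def test_matches_naive_sort_oracle(self, rng):
        for shape in [(5, 8, 8, 1), (4, 3, 7, 3), (2, 2, 2, 3)]:
            data = rng.integers(0, 256, size=shape).astype(float)
            cands = rf.build_candidates(_stack(data))
            np.testing.assert_array_equal(cands.ranks, naive_candidates(data))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariants_on_random_stacks(self, seed):
        """Monotone ranks, multiset preservation, permutation invariance."""
        r = np.random.default_rng(seed)
        data = r.integers(0, 100, size=(r.integers(2, 7), 4, 4, 1)).astype(float)
        cands = rf.build_candidates(_stack(data))
        assert np.all(np.diff(cands.ranks, axis=0) <= 0)
        np.testing.assert_array_equal(cands.rank(1), data.max(axis=0))
        np.testing.assert_array_equal(cands.rank(cands.n), data.min(axis=0))
        np.testing.assert_array_equal(
            np.sort(cands.ranks, axis=0), np.sort(data, axis=0)
        )
        perm = r.permutation(data.shape[0])
        shuffled = rf.build_candidates(_stack(data[perm]))
        np.testing.assert_array_equal(shuffled.ranks, cands.ranks)


class TestLocalCoV:
    def test_constant_image_is_zero(self):
        out = rf.local_coefficient_of_variation(np.full((7, 7), 42.0), window=5)
        np.testing.assert_array_equal(out, 0.0)

    def test_scale_invariance(self, rng):
        img = rng.uniform(1, 200, size=(9, 9))
        a = rf.local_coefficient_of_variation(img, 3, epsilon=0.0)
        b = rf.local_coefficient_of_variation(3.7 * img, 3, epsilon=0.0)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_center_pixel_full_window_statistics(self, rng):
        img = rng.uniform(0, 1, size=(5, 5))
        out = rf.local_coefficient_of_variation(img, 5, epsilon=0.0)
        expected = img.std() / img.mean()  # population sigma over all 25
        np.testing.assert_allclose(out[2, 2], expected, rtol=1e-12)

    def test_matches_naive_window_oracle(self, rng):
        for shape, window in [((8, 8), 5), ((6, 7), 3), ((5, 5), 5)]:
            img = rng.uniform(0, 255, size=shape)
            fast = rf.local_coefficient_of_variation(img, window, epsilon=0.5)
            slow = naive_lcov(img, window, epsilon=0.5)
            np.testing.assert_allclose(fast, slow, rtol=1e-9)

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_bad_window_rejected(self, window):
        with pytest.raises(rf.ParameterError):
            rf.local_coefficient_of_variation(np.ones((4, 4)), window)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(rf.ParameterError):
            rf.local_coefficient_of_variation(np.ones((4, 4)), 3, epsilon=-1.0)


class TestSmoothnessScore:
    def test_constant_is_perfectly_smooth(self):
        assert rf.smoothness_score(np.full((10, 10), 7.0), 5) == 0.0

    def test_scale_invariance(self, rng):
        img = rng.uniform(10, 200, size=(12, 12))
        s1 = rf.smoothness_score(img, 5, epsilon=0.0)
        s2 = rf.smoothness_score(0.25 * img, 5, epsilon=0.0)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_artifact_strictly_increases_score(self):
        clean = np.full((16, 16), 100.0)
        dirty = clean.copy()
        dirty[8, 8] = 180.0  # one-pixel bright artifact
        assert rf.smoothness_score(dirty, 5) > rf.smoothness_score(clean, 5)

    def test_matches_naive_oracle(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        np.testing.assert_allclose(
            rf.smoothness_score(img, 5, 0.1), naive_smoothness(img, 5, 0.1), rtol=1e-9
        )


def _vignette_field(h, w, strength=0.3):
    y, x = np.mgrid[0:h, 0:w]
    r = np.hypot(y - (h - 1) / 2, x - (w - 1) / 2)
    r_max = r.max()
    return 200.0 * ((1 - strength) + strength * np.cos(0.5 * np.pi * r / r_max) ** 2)


class TestSelectFlatField:
    def test_identical_tiles_tie_break_to_rank_one(self):
        vignette = _vignette_field(16, 16)[..., None]
        stack = _stack(np.repeat(vignette[None], 4, axis=0))
        model = rf.select_flat_field(rf.build_candidates(stack))
        assert model.selected_rank == (1,)
        np.testing.assert_array_equal(model.field, vignette)
        s = model.smoothness.scores[0]
        np.testing.assert_allclose(s, s[0])

    def test_bright_artifact_pushes_selection_past_rank_one(self):
        """With one tile carrying a bright blob, the selected rank skips the
        contaminated brightest candidate and recovers the true field exactly."""
        field = _vignette_field(32, 32)[..., None]
        tiles = np.repeat(field[None], 5, axis=0)
        tiles[0, 10:16, 10:16] *= 1.5  # dust blob in tile 0 only
        model = rf.select_flat_field(rf.build_candidates(_stack(tiles)))
        assert model.selected_rank[0] > 1
        np.testing.assert_allclose(model.field, field, rtol=1e-12)

    def test_forced_search_rank(self, small_collection):
        _, observed, _, _ = small_collection
        cands = rf.build_candidates(observed)
        model = rf.select_flat_field(cands, search_ranks=[3])
        assert model.selected_rank == (3, 3, 3)
        np.testing.assert_array_equal(model.field, cands.rank(3))
        # unsearched ranks are not scored
        assert np.isnan(model.smoothness.scores[:, 0]).all()

    def test_zero_channel_is_degenerate(self):
        tiles = np.ones((3, 8, 8, 3))
        tiles[..., 1] = 0.0
        with pytest.raises(rf.DegenerateFieldError):
            rf.select_flat_field(rf.build_candidates(_stack(tiles)))

    def test_bad_search_ranks(self, small_collection):
        _, observed, _, _ = small_collection
        cands = rf.build_candidates(observed)
        with pytest.raises(rf.ParameterError):
            rf.select_flat_field(cands, search_ranks=[])
        with pytest.raises(rf.ParameterError):
            rf.select_flat_field(cands, search_ranks=[0, 5])


class TestEstimateFlatField:
    def test_identical_tiles_return_the_tile(self, rng):
        img = rng.uniform(50, 250, size=(8, 8, 3))
        stack = _stack(np.repeat(img[None], 3, axis=0))
        model = rf.estimate_flat_field(stack)
        np.testing.assert_array_equal(model.field, img)

    def test_minimal_two_tile_stack(self, rng):
        stack = _stack(rng.uniform(50, 250, size=(2, 8, 8, 1)))
        model = rf.estimate_flat_field(stack)
        assert model.selected_rank[0] in (1, 2)

    def test_background_only_recovers_field(self):
        cfg = rf.SynthConfig(
            height=32, width=32, n_tiles=10, object_density=0.0,
            artifact_rate=0.0, photon_noise_sd=0.0, seed=3,
        )
        observed, _, truth = rf.make_collection(cfg)
        model = rf.estimate_flat_field(observed)
        np.testing.assert_allclose(model.field, truth.field, rtol=1e-12)

    def test_permutation_invariance(self, small_collection, rng):
        _, observed, _, _ = small_collection
        model = rf.estimate_flat_field(observed)
        perm = rng.permutation(observed.n)
        shuffled = observed.copy_with(observed.data[perm])
        model2 = rf.estimate_flat_field(shuffled)
        assert model.selected_rank == model2.selected_rank
        np.testing.assert_array_equal(model.field, model2.field)
        np.testing.assert_allclose(
            model.smoothness.scores, model2.smoothness.scores, rtol=1e-12
        )

    def test_exposure_scale_equivariance(self, small_collection):
        _, observed, _, _ = small_collection
        m1 = rf.estimate_flat_field(observed, epsilon=0.0)
        scaled = observed.copy_with(2.5 * observed.data)
        m2 = rf.estimate_flat_field(scaled, epsilon=0.0)
        assert m1.selected_rank == m2.selected_rank
        np.testing.assert_allclose(m2.field, 2.5 * m1.field, rtol=1e-12)

    def test_dark_frame_subtraction(self, small_collection):
        _, observed, _, _ = small_collection
        dark = np.full(observed.tile_shape, 5.0)
        shifted = observed.copy_with(observed.data + 5.0)
        m_ref = rf.estimate_flat_field(observed)
        m_dark = rf.estimate_flat_field(shifted, dark_frame=dark)
        np.testing.assert_allclose(m_dark.field, m_ref.field, rtol=1e-12)

    def test_fixed_pattern_recovery(self):
        """The selected field reproduces vignette x per-pixel gain where
        background samples exist — the fixed-pattern-noise claim."""
        cfg = rf.SynthConfig(
            height=48, width=48, n_tiles=40, photon_noise_sd=0.0, seed=21
        )
        observed, _, truth = rf.make_collection(cfg)
        model = rf.estimate_flat_field(observed)
        r = np.corrcoef(model.field.ravel(), truth.field.ravel())[0, 1]
        assert r > 0.99

    def test_model_class_matches_function(self, small_collection):
        _, observed, _, _ = small_collection
        np.testing.assert_array_equal(
            rf.RankedFlatField(observed, window=3).fit().field,
            rf.estimate_flat_field(observed, window=3).field,
        )
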