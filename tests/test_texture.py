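"""GLCM construction, Haralick features, and the rotation-invariant form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import stedtex as st
from stedtex.config import DEFAULT_OFFSETS, GlcmConfig

from conftest import glcm_oracle, haralick_oracle, leading_singular_value_oracle

CFG8 = GlcmConfig(levels=8)


def _random_block(seed, shape=(16, 16), hi=100):
    return np.random.default_rng(seed).integers(0, hi, shape).astype(float)


class TestQuantize:
    def test_constant_block_all_zero(self):
        assert np.all(st.quantize_block(np.full((6, 6), 9.0), CFG8) == 0)

    def test_range_endpoints(self):
        block = np.array([[0.0, 255.0]])
        q = st.quantize_block(block, GlcmConfig(levels=64))
        assert q[0, 0] == 0 and q[0, 1] == 63

    @settings(deadline=None, max_examples=50)
    @given(hst.integers(0, 2**31 - 1))
    def test_matches_per_pixel_oracle(self, seed):
        block = _random_block(seed, (8, 8))
        cfg = GlcmConfig(levels=16)
        q = st.quantize_block(block, cfg)
        lo, hi = block.min(), block.max()
        for (r, c), v in np.ndenumerate(block):
            expect = min(int(cfg.levels * (v - lo) / (hi - lo + 1e-300)), cfg.levels - 1)
            assert q[r, c] == expect

    def test_global_range_mode(self):
        cfg = GlcmConfig(levels=4, quantization="global_range", global_range=(0, 100))
        q = st.quantize_block(np.array([[0.0, 30.0, 99.0, 150.0]]), cfg)
        assert q.tolist() == [[0, 1, 3, 3]]


class TestGlcm:
    def test_constant_block_single_entry(self):
        g = st.compute_glcm(np.zeros((6, 6), dtype=int), (0, 1), CFG8)
        assert g[0, 0] == 1.0
        assert g.sum() == pytest.approx(1.0)

    def test_vertical_stripes_distinguish_offsets(self):
        # columns alternate 0/1: horizontal neighbours always differ,
        # vertical neighbours never do
        q = np.tile([0, 1], (4, 2))
        cfg = GlcmConfig(levels=2, symmetric=True)
        g_h = st.compute_glcm(q, (1, 0), cfg)   # dx=1: horizontal step
        g_v = st.compute_glcm(q, (0, 1), cfg)   # dy=1: vertical step
        # hand enumeration: 12 horizontal pairs, all discordant (symmetrized)
        assert g_h.tolist() == [[0.0, 0.5], [0.5, 0.0]]
        # 12 vertical pairs, all concordant, half at level 0, half at 1
        assert g_v.tolist() == [[0.5, 0.0], [0.0, 0.5]]

    @settings(deadline=None, max_examples=50)
    @given(hst.integers(0, 2**31 - 1), hst.sampled_from(DEFAULT_OFFSETS),
           hst.booleans())
    def test_normalized_symmetric_and_matches_double_loop(self, seed, offset, sym):
        cfg = GlcmConfig(levels=8, symmetric=sym)
        q = np.random.default_rng(seed).integers(0, 8, (9, 9))
        g = st.compute_glcm(q, offset, cfg)
        assert g.sum() == pytest.approx(1.0)
        if sym:
            assert np.allclose(g, g.T)
        assert np.allclose(g, glcm_oracle(q, offset[0], offset[1], 8, sym))

    def test_offset_exceeding_block_is_undefined(self):
        assert st.compute_glcm(np.zeros((3, 3), int), (0, 4), CFG8) is None

    def test_matches_skimage_for_axis_offset(self):
        from skimage.feature import graycomatrix
        q = np.random.default_rng(0).integers(0, 8, (12, 12)).astype(np.uint8)
        ours = st.compute_glcm(q, (1, 0), GlcmConfig(levels=8, symmetric=True))
        ref = graycomatrix(q, [1], [0], levels=8, symmetric=True, normed=True)
        assert np.allclose(ours, ref[:, :, 0, 0])


class TestHaralick:
    def test_uniform_glcm_energy(self):
        L = 8
        p = np.full((L, L), 1 / L**2)
        assert st.haralick_feature(p, "energy") == pytest.approx(1 / L**2)

    def test_diagonal_glcm(self):
        p = np.diag(np.full(8, 1 / 8))
        assert st.haralick_feature(p, "contrast") == 0
        assert st.haralick_feature(p, "homogeneity") == 1

    def test_two_entry_symmetric_glcm(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        assert st.haralick_feature(p, "energy") == pytest.approx(0.5)
        assert st.haralick_feature(p, "contrast") == pytest.approx(1.0)
        assert st.haralick_feature(p, "homogeneity") == pytest.approx(0.5)

    def test_abs_homogeneity_form(self):
        p = np.zeros((3, 3))
        p[0, 2] = p[2, 0] = 0.5
        assert st.haralick_feature(p, "homogeneity", "abs") == pytest.approx(1 / 3)
        assert st.haralick_feature(p, "homogeneity") == pytest.approx(1 / 5)

    @settings(deadline=None, max_examples=30)
    @given(hst.integers(0, 2**31 - 1))
    def test_matches_double_loop_oracle(self, seed):
        g = np.random.default_rng(seed).random((6, 6))
        g /= g.sum()
        expect = haralick_oracle(g)
        for name, val in expect.items():
            assert st.haralick_feature(g, name) == pytest.approx(val)


class TestInvariantForm:
    def test_constant_matrix_is_fixed_point(self):
        assert st.invariant_form(np.full((4, 3), 0.25)) == pytest.approx(0.25)

    def test_column_permutation_invariance(self, rng):
        m = rng.random((4, 3))
        swapped = m[:, [2, 1, 0]]
        assert st.invariant_form(m) == pytest.approx(st.invariant_form(swapped))

    def test_matches_power_iteration_oracle(self):
        m = np.array([[0.9, 0.7, 0.8], [0.5, 0.4, 0.6],
                      [0.3, 0.35, 0.2], [0.15, 0.1, 0.12]])
        expect = leading_singular_value_oracle(m) / np.sqrt(12)
        assert st.invariant_form(m) == pytest.approx(expect, rel=1e-9)

    def test_undefined_cell_rejected(self):
        m = np.full((4, 3), 0.5)
        m[2, 1] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            st.invariant_form(m)


class TestBlockTexture:
    def test_constant_block_through_whole_chain(self):
        tf = st.block_texture(np.full((20, 20), 7.0))
        assert tf.energy == pytest.approx(1.0)
        assert tf.contrast == pytest.approx(0.0)
        assert tf.homogeneity == pytest.approx(1.0)
        assert tf.heterogeneity == pytest.approx(0.0)

    @settings(deadline=None, max_examples=25)
    @given(hst.integers(0, 2**31 - 1))
    def test_heterogeneity_complements_homogeneity(self, seed):
        tf = st.block_texture(_random_block(seed, (12, 12)))
        assert tf.heterogeneity + tf.homogeneity == 1.0
        assert 0 < tf.energy <= 1
        assert 0 < tf.homogeneity <= 1
        assert tf.contrast >= 0

    def test_checkerboard_rougher_than_constant(self):
        i, j = np.indices((16, 16))
        checker = ((i + j) % 2).astype(float)
        tf_c = st.block_texture(checker)
        tf_flat = st.block_texture(np.full((16, 16), 1.0))
        assert tf_c.contrast > tf_flat.contrast
        assert tf_c.energy < tf_flat.energy

    def test_energy_and_contrast_monotone_in_checker_frequency(self):
        # coarser -> finer checkerboards (periods well above the max offset 4)
        i, j = np.indices((64, 64))
        feats = [st.block_texture(((i // p + j // p) % 2).astype(float))
                 for p in (32, 16, 8)]
        energies = [f.energy for f in feats]
        contrasts = [f.contrast for f in feats]
        assert energies == sorted(energies, reverse=True)
        assert contrasts == sorted(contrasts)

    def test_block_smaller_than_offset_span_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            st.block_texture(np.ones((4, 4)))

    @settings(deadline=None, max_examples=20)
    @given(hst.integers(0, 2**31 - 1))
    def test_exact_180_degree_rotation_invariance(self, seed):
        block = _random_block(seed, (14, 14))
        tf = st.block_texture(block)
        tf_rot = st.block_texture(np.rot90(block, 2))
        for name in ("energy", "contrast", "homogeneity"):
            a, b = getattr(tf, name), getattr(tf_rot, name)
            assert abs(a - b) <= 1e-6 * max(abs(a), 1e-12)

    @settings(deadline=None, max_examples=20)
    @given(hst.integers(0, 2**31 - 1), hst.sampled_from([1, 3]))
    def test_90_degree_invariance_for_mirror_symmetric_blocks(self, seed, k):
        # under a mirror symmetry the 45-degree and 135-degree co-occurrence
        # statistics coincide, so a quarter turn only permutes the angle
        # columns of the feature matrix
        half = _random_block(seed, (14, 7))
        block = np.hstack([half, half[:, ::-1]])
        tf = st.block_texture(block)
        tf_rot = st.block_texture(np.rot90(block, k))
        for name in ("energy", "contrast", "homogeneity"):
            a, b = getattr(tf, name), getattr(tf_rot, name)
            assert abs(a - b) <= 1e-6 * max(abs(a), 1e-12)
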