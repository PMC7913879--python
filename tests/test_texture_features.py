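import dataclasses
import itertools

import numpy as np
import pytest

from pdff_texture import (
    DIRECTIONS_13,
    GLCM_FEATURE_NAMES,
    RoiMask,
    TEXTURE_FEATURE_NAMES,
    VolumeGrid,
    average_over_directions,
    build_glcm,
    glcm_directions,
    glcm_features,
    global_features,
    build_histogram,
    select_bin_count,
    texture_profile,
)
from pdff_texture.exceptions import ContractViolation, DegenerateDataError
from pdff_texture.preprocess import Histogram, QuantizedRoi
from pdff_texture.texture_features import Glcm

from glcm_oracle import brute_glcm, brute_glcm_features, random_masked_grid


def make_quantized(levels, ng, mask=None, spacing=(1.0, 1.0, 1.0)):
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    roi = RoiMask(values=mask, spacing=spacing)
    return QuantizedRoi(levels=levels, ng=ng, mask=roi, spacing=spacing)


class TestDirections:
    def test_thirteen_directions(self):
        assert len(glcm_directions()) == 13

    def test_with_negations_covers_all_26_neighbors(self):
        offsets = set(glcm_directions())
        neg = {tuple(-c for c in o) for o in offsets}
        all26 = {t for t in itertools.product((-1, 0, 1), repeat=3)
                 if t != (0, 0, 0)}
        assert offsets | neg == all26
        assert not offsets & neg

    def test_no_two_directions_parallel(self):
        for a, b in itertools.combinations(glcm_directions(), 2):
            assert np.any(np.cross(a, b))


class TestBuildGlcm:
    def test_three_voxel_line(self):
        q = make_quantized(np.array([1, 2, 1]).reshape(1, 1, 3), ng=2)
        g = build_glcm(q, (0, 0, 1))
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(g.p, expected)
        assert g.pair_count == 2

    def test_constant_roi_is_point_mass(self):
        q = make_quantized(np.ones((3, 3, 3)), ng=1)
        g = build_glcm(q, (1, 0, 0))
        assert g.p[0, 0] == 1.0

    def test_no_valid_pair_flags_skip(self):
        q = make_quantized(np.array([1]).reshape(1, 1, 1), ng=1)
        g = build_glcm(q, (0, 0, 1))
        assert g.pair_count == 0

    def test_matches_brute_force_on_random_grids(self, rng):
        for _ in range(10):
            levels, mask, ng = random_masked_grid(rng)
            q = make_quantized(levels, ng, mask)
            for off in DIRECTIONS_13:
                g = build_glcm(q, off)
                ref, pairs = brute_glcm(levels, mask, off, ng)
                assert g.pair_count == pairs
                if pairs:
                    np.testing.assert_allclose(g.p, ref, atol=1e-15)
                    np.testing.assert_allclose(g.p, g.p.T, atol=0)


class TestGlcmFeatures:
    def test_point_mass_matrix(self):
        p = np.zeros((3, 3))
        p[0, 0] = 1.0
        f = glcm_features(Glcm(p=p, offset=(1, 0, 0), pair_count=4))
        assert (f.energy, f.entropy, f.contrast, f.homogeneity,
                f.dissimilarity, f.sum_average, f.variance) == \
            (1.0, 0.0, 0.0, 1.0, 0.0, 2.0, 0.0)
        assert f.correlation == 0.0 and f.correlation_degenerate

    def test_two_level_antidiagonal_matrix(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(Glcm(p=p, offset=(0, 0, 1), pair_count=2))
        assert f.energy == pytest.approx(0.5)
        assert f.entropy == pytest.approx(1.0)       # bits
        assert f.contrast == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.correlation == pytest.approx(-1.0)
        assert f.variance == pytest.approx(0.25)
        assert f.sum_average == pytest.approx(3.0)
        assert f.dissimilarity == pytest.approx(1.0)

    def test_unnormalized_input_rejected(self):
        p = np.full((2, 2), 0.3)
        with pytest.raises(ContractViolation):
            glcm_features(Glcm(p=p, offset=(1, 0, 0), pair_count=1))

    def _random_glcm(self, rng, ng):
        c = rng.random((ng, ng))
        p = c + c.T
        return p / p.sum()

    def test_dissimilarity_squared_bounded_by_contrast(self, rng):
        for _ in range(20):
            p = self._random_glcm(rng, int(rng.integers(2, 8)))
            f = glcm_features(Glcm(p=p, offset=(1, 0, 0), pair_count=1))
            assert f.dissimilarity ** 2 <= f.contrast + 1e-12

    def test_level_axis_reversal_invariances(self, rng):
        for _ in range(10):
            ng = int(rng.integers(2, 8))
            p = self._random_glcm(rng, ng)
            f = glcm_features(Glcm(p=p, offset=(1, 0, 0), pair_count=1))
            fr = glcm_features(Glcm(p=p[::-1, ::-1].copy(), offset=(1, 0, 0),
                                    pair_count=1))
            for name in ("energy", "entropy", "contrast", "homogeneity",
                         "correlation", "variance", "dissimilarity"):
                assert getattr(fr, name) == pytest.approx(getattr(f, name))
            # i -> ng+1-i maps level sums k to 2(ng+1)-k
            assert fr.sum_average == pytest.approx(2 * (ng + 1) - f.sum_average)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            p = self._random_glcm(rng, int(rng.integers(2, 7)))
            f = glcm_features(Glcm(p=p, offset=(1, 0, 0), pair_count=1))
            ref = brute_glcm_features(p)
            for name in GLCM_FEATURE_NAMES:
                assert getattr(f, name) == pytest.approx(ref[name], abs=1e-12)


class TestDirectionAveraging:
    def test_mean_of_identical_vectors(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(Glcm(p=p, offset=(1, 0, 0), pair_count=1))
        avg = average_over_directions([f, f, f])
        assert avg.contrast == f.contrast and avg.entropy == f.entropy

    def test_mean_of_two_contrasts(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f1 = glcm_features(Glcm(p=p, offset=(1, 0, 0), pair_count=1))
        f3 = dataclasses.replace(f1, contrast=3.0)
        assert average_over_directions([f1, f3]).contrast == pytest.approx(2.0)

    def test_all_directions_skipped_rejected(self):
        with pytest.raises(DegenerateDataError):
            average_over_directions([])

    def _avg_features(self, levels, ng):
        q = make_quantized(levels, ng)
        feats = []
        for off in DIRECTIONS_13:
            g = build_glcm(q, off)
            if g.pair_count:
                feats.append(glcm_features(g))
        return average_over_directions(feats)

    def test_invariant_under_axis_permutation(self, rng):
        levels = rng.integers(1, 5, size=(5, 5, 5))
        base = self._avg_features(levels, 4)
        for perm in itertools.permutations((0, 1, 2)):
            rot = self._avg_features(np.transpose(levels, perm).copy(), 4)
            for name in GLCM_FEATURE_NAMES:
                assert getattr(rot, name) == pytest.approx(
                    getattr(base, name), abs=1e-12)

    def test_invariant_under_quarter_turn(self, rng):
        levels = rng.integers(1, 5, size=(6, 6, 6))
        base = self._avg_features(levels, 4)
        rot = self._avg_features(np.rot90(levels, axes=(0, 1)).copy(), 4)
        for name in GLCM_FEATURE_NAMES:
            assert getattr(rot, name) == pytest.approx(
                getattr(base, name), abs=1e-12)


class TestGlobalFeatures:
    def test_two_point_histogram_moments(self):
        h = Histogram(bin_edges=np.array([-5.0, 5.0, 15.0]),
                      bin_centers=np.array([0.0, 10.0]),
                      probabilities=np.array([0.5, 0.5]))
        g = global_features(h)
        assert g.variance_global == pytest.approx(25.0)
        assert g.skewness_global == pytest.approx(0.0)
        assert g.kurtosis_global == pytest.approx(1.0)

    def test_symmetric_histogram_has_zero_skewness(self, rng):
        v = rng.normal(size=2000)
        v = np.concatenate([v, -v])  # exactly symmetric sample
        g = global_features(build_histogram(v, 21))
        assert g.skewness_global == pytest.approx(0.0, abs=1e-10)

    def test_normal_sample_kurtosis_near_three(self):
        rng = np.random.default_rng(2024)
        v = rng.normal(size=100_000)
        g = global_features(build_histogram(v, select_bin_count(v)))
        assert g.kurtosis_global == pytest.approx(3.0, abs=0.1)

    def test_degenerate_histogram_flagged(self):
        h = Histogram(bin_edges=np.array([0.0, 1.0]),
                      bin_centers=np.array([0.5]),
                      probabilities=np.array([1.0]))
        g = global_features(h)
        assert g.degenerate and g.variance_global == 0.0

    def test_matches_raw_moments_when_each_value_owns_a_bin(self):
        # with one bin per distinct value the centers are an affine map of
        # the values: standardized moments match the raw sample moments
        # exactly, variance up to the (bin width / value step)^2 factor
        v = np.array([0.0, 1.0, 2.0, 3.0], dtype=float)
        g = global_features(build_histogram(np.repeat(v, 5), 4))
        d = v - v.mean()
        m2 = np.mean(d ** 2)
        assert g.variance_global == pytest.approx(m2 * 0.75 ** 2)
        assert g.skewness_global == pytest.approx(np.mean(d ** 3) / m2 ** 1.5)
        assert g.kurtosis_global == pytest.approx(np.mean(d ** 4) / m2 ** 2)


class TestTextureProfile:
    def _constant_phantom(self, study_spacing):
        vol = VolumeGrid(values=np.full((6, 6, 6), 12.0), spacing=study_spacing)
        mask = RoiMask(values=np.ones((6, 6, 6)), spacing=study_spacing,
                       muscle="ES", side="right")
        return vol, mask

    def test_exactly_eleven_features(self, study_spacing):
        vol, mask = self._constant_phantom(study_spacing)
        fs = texture_profile(vol, mask)
        assert len(fs.features) == 11
        assert set(fs.features) == set(TEXTURE_FEATURE_NAMES)

    def test_constant_phantom_degenerate_values(self, study_spacing):
        vol, mask = self._constant_phantom(study_spacing)
        fs = texture_profile(vol, mask)
        assert fs.features["variance_global"] == 0.0
        assert fs.features["contrast"] == 0.0
        assert fs.features["energy"] == 1.0
        assert fs.mean_pdff == pytest.approx(12.0)

    def test_streaky_beats_homogeneous_at_matched_mean(self):
        from pdff_texture import (
            default_phantom_config,
            generate_phantom,
            match_mean,
        )

        homog = default_phantom_config(seed=31, es_n_streaks=0, ps_n_streaks=0)
        streaky = default_phantom_config(seed=32, es_n_streaks=5, ps_n_streaks=0)
        homog, streaky = match_mean(homog, streaky)
        fh = texture_profile(*_es_right(generate_phantom(homog)))
        fs = texture_profile(*_es_right(generate_phantom(streaky)))
        assert fs.features["variance_global"] > fh.features["variance_global"]


def _es_right(phantom):
    grid, masks = phantom
    return grid, masks[("ES", "right")]
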