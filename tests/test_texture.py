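import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from livercad.errors import (
    EmptyMaskError,
    EmptyRunMatrixError,
    NoCooccurrencesError,
    NotNormalizedError,
)
from livercad.texture import (
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    GLCM_OFFSETS,
    GLRLM_NAMES,
    CoocMatrix,
    first_order_markers,
    glcm,
    glcm_markers,
    glrlm,
    glrlm_markers,
    normalize_gray_levels,
    textural_markers,
)
from tests.conftest import tiny_study


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately dumb and independent)
# ---------------------------------------------------------------------------


def brute_glcm(levels):
    """Exhaustive enumeration of all ordered voxel pairs at distance <= sqrt(2)."""
    counts = np.zeros((256, 256))
    shape = levels.shape
    offsets = [
        o
        for o in itertools.product((-1, 0, 1), repeat=3)
        if 0 < sum(abs(c) for c in o) <= 2
    ]
    for idx in np.ndindex(shape):
        if levels[idx] < 0:
            continue
        for off in offsets:
            j = tuple(a + b for a, b in zip(idx, off))
            if all(0 <= c < s for c, s in zip(j, shape)) and levels[j] >= 0:
                counts[levels[idx], levels[j]] += 1
    return counts / counts.sum()


def brute_glrlm(levels, r_max):
    """Exhaustive maximal-run enumeration along the three axes."""
    mat = np.zeros((256, r_max))
    for axis in range(3):
        moved = np.moveaxis(levels, axis, -1)
        for line in moved.reshape(-1, moved.shape[-1]):
            run_val, run_len = None, 0
            for v in list(line) + [-1]:
                if v == run_val:
                    run_len += 1
                    continue
                if run_val is not None and run_val >= 0:
                    mat[run_val, run_len - 1] += 1
                run_val, run_len = v, 1
    return mat


def brute_first_order(levels1d):
    """Histogram statistics recomputed from scratch."""
    v = levels1d.astype(float)
    hist = np.bincount(levels1d, minlength=256) / len(v)
    mean = v.mean()
    var = ((v - mean) ** 2).mean()
    std = np.sqrt(var)
    skew = ((v - mean) ** 3).mean() / std**3 if var > 0 else 0.0
    kurt = ((v - mean) ** 4).mean() / var**2 if var > 0 else 0.0
    ent = -sum(p * np.log2(p) for p in hist if p > 0)
    out = [mean, var, std, skew, kurt, ent]
    cdf = np.cumsum(hist)
    for k in range(1, 11):
        out.append(cdf[int(np.floor(k * 25.5))])
    for k in range(1, 11):
        out.append(float(np.argmax(cdf >= k / 10.0 - 1e-12)))
    return np.array(out)


def region_from_levels(levels3d):
    from livercad.texture import QuantizedRegion

    return QuantizedRegion(
        np.asarray(levels3d, dtype=np.int16), np.asarray(levels3d) >= 0
    )


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


class TestNormalizeGrayLevels:
    def test_three_value_example(self):
        vol = np.array([10.0, 20.0, 30.0]).reshape(3, 1, 1)
        q = normalize_gray_levels(vol, np.ones((3, 1, 1), bool))
        assert sorted(q.values.tolist()) == [0, 128, 255]

    def test_constant_region_all_zero(self):
        vol = np.full((3, 3, 3), 7.0)
        q = normalize_gray_levels(vol, np.ones((3, 3, 3), bool))
        assert np.all(q.values == 0)

    def test_endpoints_present(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(5, 5, 5))
        q = normalize_gray_levels(vol, np.ones((5, 5, 5), bool))
        assert q.values.min() == 0
        assert q.values.max() == 255

    def test_empty_mask(self):
        with pytest.raises(EmptyMaskError, match="empty mask"):
            normalize_gray_levels(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        q1 = normalize_gray_levels(vol, mask)
        q2 = normalize_gray_levels(3.5 * vol + 120.0, mask)
        np.testing.assert_array_equal(q1.levels, q2.levels)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------


class TestFirstOrder:
    def test_against_brute_force(self):
        rng = np.random.default_rng(2)
        levels = rng.integers(0, 256, size=(6, 6, 6)).astype(np.int16)
        q = region_from_levels(levels)
        got = np.array(list(first_order_markers(q).values()))
        np.testing.assert_allclose(got, brute_first_order(q.values), rtol=1e-12)

    def test_constant_region(self):
        q = region_from_levels(np.zeros((3, 3, 3), dtype=np.int16))
        m = first_order_markers(q)
        assert m["variance"] == 0
        assert m["entropy"] == 0
        assert m["skewness"] == 0
        assert m["kurtosis"] == 0
        assert all(m[f"cdf_{10 * k:03d}"] == 1.0 for k in range(1, 11))

    def test_two_level_half_half(self):
        levels = np.concatenate([np.zeros(50), np.full(50, 255)]).reshape(4, 25, 1)
        q = region_from_levels(levels.astype(np.int16))
        m = first_order_markers(q)
        assert m["mean"] == pytest.approx(127.5)
        assert m["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert m["entropy"] == pytest.approx(1.0)

    def test_length_26(self):
        assert len(FIRST_ORDER_NAMES) == 26
        q = region_from_levels(np.arange(27).reshape(3, 3, 3).astype(np.int16))
        assert len(first_order_markers(q)) == 26

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_voxel_shuffling(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 256, size=64).astype(np.int16)
        a = region_from_levels(levels.reshape(4, 4, 4))
        b = region_from_levels(rng.permutation(levels).reshape(4, 4, 4))
        ma, mb = first_order_markers(a), first_order_markers(b)
        assert list(ma) == list(mb)
        np.testing.assert_allclose(  # summation order may differ by ulps
            list(ma.values()), list(mb.values()), rtol=1e-12
        )


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


class TestGLCM:
    def test_offsets_are_the_18_neighborhood(self):
        lens = {np.sqrt(sum(c * c for c in o)) for o in GLCM_OFFSETS}
        assert lens <= {1.0, np.sqrt(2)}
        assert len(GLCM_OFFSETS) == 9  # both orders counted -> 18 directed

    def test_two_voxel_example(self):
        levels = np.full((1, 1, 2), -1, dtype=np.int16)
        levels[0, 0, 0], levels[0, 0, 1] = 0, 255
        cm = glcm(region_from_levels(levels))
        assert cm.matrix[0, 255] == pytest.approx(0.5)
        assert cm.matrix[255, 0] == pytest.approx(0.5)
        assert cm.matrix.sum() == pytest.approx(1.0)

    def test_against_brute_force(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(0, 4, size=(5, 5, 5)).astype(np.int16) * 80
        levels[rng.random((5, 5, 5)) < 0.3] = -1
        if not (levels >= 0).any():
            pytest.skip("empty")
        cm = glcm(region_from_levels(levels))
        np.testing.assert_allclose(cm.matrix, brute_glcm(levels), atol=1e-15)

    def test_constant_region_diagonal(self):
        cm = glcm(region_from_levels(np.zeros((3, 3, 3), dtype=np.int16)))
        assert cm.matrix[0, 0] == pytest.approx(1.0)

    def test_dimensions_256(self):
        cm = glcm(region_from_levels(np.zeros((2, 2, 2), dtype=np.int16)))
        assert cm.matrix.shape == (256, 256)

    def test_no_cooccurrences(self):
        levels = np.full((5, 5, 5), -1, dtype=np.int16)
        levels[0, 0, 0] = 5
        levels[4, 4, 4] = 9
        with pytest.raises(NoCooccurrencesError, match="no co-occurrences"):
            glcm(region_from_levels(levels))

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("axes", [(0, 1), (0, 2), (1, 2)])
    def test_rotation_invariance(self, k, axes):
        rng = np.random.default_rng(4)
        levels = rng.integers(0, 256, size=(6, 7, 8)).astype(np.int16)
        levels[rng.random((6, 7, 8)) < 0.4] = -1
        base = glcm(region_from_levels(levels)).matrix
        rot = glcm(region_from_levels(np.rot90(levels, k=k, axes=axes))).matrix
        np.testing.assert_allclose(rot, base, atol=1e-12)

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(5)
        levels = rng.integers(0, 256, size=(5, 6, 7)).astype(np.int16)
        base = glcm(region_from_levels(levels)).matrix
        for perm in itertools.permutations((0, 1, 2)):
            p = glcm(region_from_levels(np.transpose(levels, perm))).matrix
            np.testing.assert_allclose(p, base, atol=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        levels = rng.integers(0, 256, size=(5, 5, 5)).astype(np.int16)
        m = glcm(region_from_levels(levels)).matrix
        np.testing.assert_allclose(m, m.T, atol=1e-15)


class TestGLCMMarkers:
    def test_constant_region_limits(self):
        cm = glcm(region_from_levels(np.zeros((3, 3, 3), dtype=np.int16)))
        m = glcm_markers(cm)
        assert m["contrast"] == 0
        assert m["dissimilarity"] == 0
        assert m["homogeneity"] == 1
        assert m["asm"] == 1
        assert m["energy"] == 1
        assert m["correlation"] == 1

    def test_uniform_matrix_asm(self):
        cm = CoocMatrix(np.full((256, 256), 1 / 65536.0), n_pairs=65536)
        assert glcm_markers(cm)["asm"] == pytest.approx(1 / 65536.0)

    def test_two_level_contrast(self):
        levels = np.full((1, 1, 2), -1, dtype=np.int16)
        levels[0, 0, 0], levels[0, 0, 1] = 0, 255
        m = glcm_markers(glcm(region_from_levels(levels)))
        assert m["contrast"] == pytest.approx(255.0**2)

    def test_unnormalized_rejected(self):
        with pytest.raises(NotNormalizedError, match="matrix not normalized"):
            glcm_markers(CoocMatrix(np.ones((256, 256)), n_pairs=1))

    def test_names(self):
        assert GLCM_NAMES == [
            "contrast", "dissimilarity", "homogeneity", "asm", "energy", "correlation",
        ]


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


class TestGLRLM:
    def test_single_row_example(self):
        levels = np.full((5, 1, 1), -1, dtype=np.int16)
        levels[:, 0, 0] = [0, 0, 255, 255, 255]
        m = glrlm(region_from_levels(levels))
        assert m.matrix[0, 1] == 1  # one x-run of length 2, level 0
        assert m.matrix[255, 2] == 1  # one x-run of length 3, level 255
        assert m.matrix[0, 0] == 4  # y and z runs of length 1
        assert m.matrix[255, 0] == 6

    def test_against_brute_force(self):
        rng = np.random.default_rng(7)
        levels = rng.integers(0, 3, size=(6, 5, 4)).astype(np.int16) * 100
        levels[rng.random((6, 5, 4)) < 0.3] = -1
        if not (levels >= 0).any():
            pytest.skip("empty")
        m = glrlm(region_from_levels(levels))
        np.testing.assert_array_equal(
            m.matrix, brute_glrlm(levels, m.matrix.shape[1])
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 5, size=(5, 5, 5)).astype(np.int16) * 50
        levels[rng.random((5, 5, 5)) < 0.4] = -1
        if not (levels >= 0).any():
            return
        q = region_from_levels(levels)
        m = glrlm(q)
        lengths = np.arange(1, m.matrix.shape[1] + 1)
        assert (m.matrix * lengths).sum() == 3 * q.n_voxels

    def test_checkerboard_all_runs_length_one(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        levels = np.where(idx % 2 == 0, 0, 255).astype(np.int16)
        m = glrlm(region_from_levels(levels))
        assert m.matrix[:, 1:].sum() == 0
        mk = glrlm_markers(m)
        assert mk["sre"] == pytest.approx(1.0)
        assert mk["lre"] == pytest.approx(1.0)
        assert mk["rp"] == pytest.approx(1.0)

    def test_row_count_256_and_columns_bbox(self):
        levels = np.full((9, 4, 6), 3, dtype=np.int16)
        m = glrlm(region_from_levels(levels))
        assert m.matrix.shape == (256, 9)


class TestGLRLMMarkers:
    def test_single_run_closed_form(self):
        levels = np.full((1, 1, 7), 255, dtype=np.int16)
        q = region_from_levels(levels)
        m = glrlm(q)
        mk = glrlm_markers(m)
        # z-run of length 7 plus 7 unit runs along each of x and y
        total = m.n_runs
        lre = (14 * 1 + 1 * 49) / total
        sre = (14 * 1 + 1 / 49) / total
        assert mk["lre"] == pytest.approx(lre)
        assert mk["sre"] == pytest.approx(sre)

    def test_pure_single_direction_run(self):
        # restrict to the one-cell matrix: LRE = L^2, SRE = 1/L^2
        from livercad.texture import RunLengthMatrix

        mat = np.zeros((256, 9), dtype=np.int64)
        mat[255, 8] = 1  # one run, length 9
        mk = glrlm_markers(RunLengthMatrix(mat, n_voxels=9, n_directions=1))
        assert mk["lre"] == pytest.approx(81.0)
        assert mk["sre"] == pytest.approx(1 / 81.0)
        assert mk["rp"] == pytest.approx(1 / 9.0)

    def test_empty_matrix_rejected(self):
        from livercad.texture import RunLengthMatrix

        with pytest.raises(EmptyRunMatrixError, match="empty run matrix"):
            glrlm_markers(RunLengthMatrix(np.zeros((256, 4), np.int64), n_voxels=0))

    def test_names_length_12(self):
        assert len(GLRLM_NAMES) == 12


# ---------------------------------------------------------------------------
# per-study driver
# ---------------------------------------------------------------------------


class TestTexturalMarkers:
    def test_census_176(self):
        s = tiny_study(noise=5.0, seed=9)
        m = textural_markers(s)
        assert len(m) == 176
        assert sum("_fo_" in k for k in m) == 104
        assert sum("_glcm_" in k for k in m) == 24
        assert sum("_glrlm_" in k for k in m) == 48

    def test_identical_phases_identical_blocks(self):
        s = tiny_study(noise=5.0, seed=10)
        for k in ("arterial", "venous", "delayed"):
            s.phases[k] = s.phases["pre"].copy()
        m = textural_markers(s)
        for name in (n for n in m if n.startswith("pre_")):
            stem = name[len("pre_"):]
            assert m[name] == m[f"arterial_{stem}"] == m[f"delayed_{stem}"]

    def test_heterogeneous_has_higher_contrast(self):
        # equal mean and quantization range; only the spatial structure of
        # the texture differs (correlated vs white noise)
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(11)
        smooth = tiny_study(seed=11)
        rough = tiny_study(seed=11)
        for k in smooth.phases:
            corr = gaussian_filter(rng.normal(size=smooth.mask.shape), 2.0)
            white = rng.normal(size=smooth.mask.shape)
            smooth.phases[k] = smooth.phases[k] + 30 * corr / corr.std()
            rough.phases[k] = rough.phases[k] + 30 * white
        ms, mr = textural_markers(smooth), textural_markers(rough)
        for phase in ("pre", "arterial", "venous", "delayed"):
            assert mr[f"{phase}_glcm_contrast"] > ms[f"{phase}_glcm_contrast"]

    def test_affine_intensity_invariance(self):
        s = tiny_study(noise=5.0, seed=12)
        m1 = textural_markers(s)
        for k in s.phases:
            s.phases[k] = 2.0 * s.phases[k] + 300.0
        m2 = textural_markers(s)
        for name in m1:
            if name.endswith(("slope_washin", "slope_pv", "slope_del")):
                continue
            assert m1[name] == pytest.approx(m2[name], rel=1e-9), name

    def test_shuffled_phantom_contrast_increases(self):
        s = tiny_study(noise=3.0, seed=13)
        # spatially smooth texture: correlated via coarse modulation
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(13)
        base = gaussian_filter(rng.normal(size=s.mask.shape), 2.0)
        vol = np.where(s.mask, 100 + 50 * base, 0.0)
        q = normalize_gray_levels(vol, s.mask)
        c_orig = glcm_markers(glcm(q))["contrast"]
        shuffled = q.levels.copy()
        vals = shuffled[q.mask]
        shuffled[q.mask] = rng.permutation(vals)
        from livercad.texture import QuantizedRegion

        c_shuf = glcm_markers(glcm(QuantizedRegion(shuffled, q.mask)))["contrast"]
        assert c_shuf > c_orig
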