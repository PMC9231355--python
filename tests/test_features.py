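import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosestab import (
    CANONICAL_ORDER,
    DoseGrid,
    ExtractorConfig,
    N_FEATURES,
    RoiMask,
    extract_features,
)
from dosestab.dosiomics.features import CLASS_NAMES, FEATURE_CLASSES

from oracle_features import oracle_all_features


def _pair(dose, mask=None, spacing=(1.0, 1.0, 1.0)):
    dose = np.asarray(dose, dtype=np.float64)
    if mask is None:
        mask = np.ones(dose.shape, dtype=bool)
    return DoseGrid(dose, spacing=spacing), RoiMask(mask, "GTV", spacing=spacing)


def test_feature_census():
    assert N_FEATURES == 93
    counts = {cls: len(CLASS_NAMES[cls]) for cls in FEATURE_CLASSES}
    assert counts == {
        "firstorder": 18, "glcm": 24, "glrlm": 16,
        "glszm": 16, "ngtdm": 5, "gldm": 14,
    }
    assert len(set(CANONICAL_ORDER)) == 93
    grid, mask = _pair(np.random.default_rng(0).uniform(0, 70, (5, 5, 5)))
    fv = extract_features(grid, mask)
    assert len(fv) == 93 and fv.values.shape == (93,) and fv.valid.all()


def test_constant_roi_values():
    grid, mask = _pair(np.full((4, 4, 4), 40.5), spacing=(2.0, 2.0, 2.0))
    fv = extract_features(grid, mask)
    assert fv[("firstorder", "Mean")] == 40.5
    assert fv[("firstorder", "Variance")] == 0.0
    assert fv[("firstorder", "Uniformity")] == 1.0
    assert fv[("firstorder", "Entropy")] == 0.0
    assert fv[("firstorder", "Energy")] == pytest.approx(64 * 40.5**2)
    assert fv[("firstorder", "TotalEnergy")] == pytest.approx(8.0 * 64 * 40.5**2)
    assert fv[("glcm", "MaximumProbability")] == 1.0
    assert fv[("glcm", "Contrast")] == 0.0
    assert fv[("glcm", "JointEntropy")] == 0.0
    assert fv[("glcm", "Correlation")] == 1.0  # degenerate-variance convention
    assert fv[("glszm", "ZonePercentage")] == pytest.approx(1 / 64)
    assert fv[("ngtdm", "Contrast")] == 0.0
    assert fv[("ngtdm", "Coarseness")] == 1e6  # zero-denominator convention
    # dependence = 1 + in-mask neighbor count: 8 corner, 24 edge, 24 face
    # and 8 interior voxels in a 4^3 cube
    expected_lde = (8 * 8**2 + 24 * 12**2 + 24 * 18**2 + 8 * 27**2) / 64
    assert fv[("gldm", "LargeDependenceEmphasis")] == pytest.approx(expected_lde)


def test_single_voxel_roi_flags_pair_classes_invalid():
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    grid, roi = _pair(np.full((3, 3, 3), 30.0), mask)
    fv = extract_features(grid, roi)
    for name in CLASS_NAMES["glcm"]:
        assert not fv.is_valid(("glcm", name))
        assert np.isnan(fv[("glcm", name)])
    for name in CLASS_NAMES["ngtdm"]:
        assert not fv.is_valid(("ngtdm", name))
    # run/zone/dependence structures still exist for one voxel
    assert fv.is_valid(("glrlm", "ShortRunEmphasis"))
    assert fv[("glszm", "ZonePercentage")] == 1.0
    assert fv[("firstorder", "Mean")] == 30.0


def test_rotation_invariance():
    rng = np.random.default_rng(3)
    dose = rng.uniform(0, 70, (6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.8
    mask[2:4, 2:4, 2:4] = True
    grid, roi = _pair(dose, mask)
    fv = extract_features(grid, roi)
    for axes in ((0, 1), (1, 2), (0, 2)):
        grid_r, roi_r = _pair(np.rot90(dose, axes=axes), np.rot90(mask, axes=axes))
        fv_r = extract_features(grid_r, roi_r)
        np.testing.assert_allclose(fv_r.values, fv.values, rtol=1e-10, atol=1e-12)


def test_whole_voxel_translation_invariance():
    rng = np.random.default_rng(4)
    dose = np.zeros((8, 8, 8))
    mask = np.zeros((8, 8, 8), dtype=bool)
    dose[1:6, 1:6, 1:6] = rng.uniform(5, 65, (5, 5, 5))
    mask[1:6, 1:6, 1:6] = rng.random((5, 5, 5)) < 0.9
    mask[2, 2, 2] = True
    fv = extract_features(*_pair(dose, mask))
    fv_t = extract_features(*_pair(np.roll(dose, (2, 1, 2), axis=(0, 1, 2)),
                                   np.roll(mask, (2, 1, 2), axis=(0, 1, 2))))
    np.testing.assert_allclose(fv_t.values, fv.values, rtol=1e-10, atol=1e-12)


def test_sub_bin_shift_leaves_discretized_features_unchanged():
    """Texture features depend only on the gray level, so a dose perturbation
    that never crosses a 1 Gy bin edge cannot change them."""
    rng = np.random.default_rng(5)
    dose = np.floor(rng.uniform(0, 70, (5, 5, 5))) + 0.4
    grid, roi = _pair(dose)
    shifted, _ = _pair(dose + 0.2)
    fv, fv_s = extract_features(grid, roi), extract_features(shifted, roi)
    for k, (cls, name) in enumerate(CANONICAL_ORDER):
        if cls != "firstorder" or name in ("Entropy", "Uniformity"):
            assert fv_s.values[k] == pytest.approx(fv.values[k], rel=1e-12), (cls, name)
    assert fv_s[("firstorder", "Mean")] == pytest.approx(
        fv[("firstorder", "Mean")] + 0.2
    )


def test_matches_brute_force_oracle_on_random_images():
    rng = np.random.default_rng(11)
    for _ in range(8):
        shape = tuple(rng.integers(2, 6, size=3))
        ng = int(rng.integers(3, 8))
        dose = rng.uniform(0, 70, shape)
        mask = rng.random(shape) < 0.75
        if mask.sum() < 2:
            continue
        grid, roi = _pair(dose, mask, spacing=(2.0, 2.5, 3.0))
        cfg = ExtractorConfig(lo_gy=0.0, hi_gy=70.0, n_levels=ng)
        fv = extract_features(grid, roi, cfg)
        ora = oracle_all_features(dose, mask, lo=0.0, hi=70.0, ng=ng,
                                  voxel_volume=grid.voxel_volume)
        for k, key in enumerate(CANONICAL_ORDER):
            a, b = fv.values[k], ora[key]
            if np.isnan(b):
                assert np.isnan(a), key
            else:
                assert a == pytest.approx(b, rel=1e-9, abs=1e-9), key


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data())
def test_feature_values_well_behaved(data):
    shape = data.draw(st.tuples(*[st.integers(2, 5)] * 3))
    seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    dose = rng.uniform(0, 70, shape)
    mask = rng.random(shape) < 0.8
    if mask.sum() < 2:
        mask[0, 0, 0] = mask[1, 1, 1] = True
    grid, roi = _pair(dose, mask)
    fv = extract_features(grid, roi)
    assert np.all(np.isfinite(fv.values[fv.valid]))
    rp = fv[("glrlm", "RunPercentage")]
    if fv.is_valid(("glrlm", "RunPercentage")):
        assert 0.0 < rp <= 1.0
    assert 0.0 < fv[("glszm", "ZonePercentage")] <= 1.0
    assert 0.0 < fv[("firstorder", "Uniformity")] <= 1.0
    assert 0.0 <= fv[("glcm", "MaximumProbability")] <= 1.0 or not fv.is_valid(
        ("glcm", "MaximumProbability")
    )
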