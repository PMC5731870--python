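import numpy as np
import pytest

from conftest import make_qroi
from gliotex.texture import (
    COARSENESS_CAP,
    all_feature_names,
    extract_all,
    glcm_matrix,
    glszm_features,
    glszm_matrix,
    gtsdm_features,
    histogram_features,
    load_feature_registry,
    modality_feature_names,
    ngtdm_features,
    ngtdm_table,
    regional_features,
)
from oracles import (
    naive_glcm,
    naive_glcm_features,
    naive_glszm,
    naive_glszm_features,
    naive_ngtdm,
    naive_ngtdm_features,
)


class TestHistogram:
    def test_uniform_four_levels_moments(self):
        # levels 1..4 once each: m2 = 1.25, m4 = 2.5625, kurtosis = 1.64
        q = make_qroi([1, 2, 3, 4], n_levels=4)
        f = histogram_features(q).values
        assert f["mean"] == pytest.approx(2.5)
        assert f["variance"] == pytest.approx(1.25)
        assert f["kurtosis"] == pytest.approx(1.64)
        assert f["skewness"] == pytest.approx(0.0)

    def test_equiprobable_entropy_and_uniformity(self):
        q = make_qroi(list(range(1, 9)), n_levels=8)
        f = histogram_features(q).values
        assert f["entropy"] == pytest.approx(3.0)
        assert f["uniformity"] == pytest.approx(0.125)

    def test_constant_roi_degenerate(self):
        q = make_qroi(np.full((3, 3, 3), 5), n_levels=8)
        blk = histogram_features(q)
        assert blk.values["variance"] == 0.0
        assert blk.values["uniformity"] == 1.0
        assert blk.values["skewness"] == 0.0
        assert blk.values["kurtosis"] == 0.0
        assert "kurtosis" in blk.flags


class TestGLCM:
    def test_constant_roi_single_cell(self):
        q = make_qroi(np.full((3, 3, 3), 4), n_levels=8)
        f = gtsdm_features(q).values
        assert f["contrast"] == pytest.approx(0.0)
        assert f["energy"] == pytest.approx(1.0)
        assert f["maximum_probability"] == pytest.approx(1.0)

    def test_alternating_strip(self):
        # 1D strip [1,2,1,2]: 3 adjacent pairs, all off-diagonal
        q = make_qroi([1, 2, 1, 2], n_levels=2)
        P = glcm_matrix(q)
        assert P[0, 0] == 0 and P[1, 1] == 0
        f = gtsdm_features(q).values
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)

    def test_matrix_normalized_and_symmetric(self, rng):
        levels = rng.integers(0, 9, size=(5, 5, 5))
        if not (levels > 0).any():
            levels[0, 0, 0] = 1
        q = make_qroi(levels)
        P = glcm_matrix(q)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)

    def test_isolated_voxels_rejected(self):
        levels = np.zeros((5, 5, 5), dtype=int)
        levels[0, 0, 0] = 3  # single voxel: no pairs at distance 1
        with pytest.raises(ValueError, match="pairs"):
            glcm_matrix(make_qroi(levels))


class TestNGTDM:
    def test_constant_roi_sentinels(self):
        q = make_qroi(np.full((3, 3, 3), 2), n_levels=8)
        blk = ngtdm_features(q)
        assert blk.values["contrast"] == 0.0
        assert blk.values["busyness"] == 0.0
        assert blk.values["coarseness"] == COARSENESS_CAP

    def test_single_deviant_center(self):
        # 3x3 slab of level 1 with a level-5 center: hand formula check
        arr = np.ones((3, 3, 1), dtype=int)
        arr[1, 1, 0] = 5
        q = make_qroi(arr, n_levels=8)
        n, s = ngtdm_table(q)
        n_o, s_o = naive_ngtdm(q.levels, 8)
        assert np.allclose(n, n_o) and np.allclose(s, s_o)
        f = ngtdm_features(q).values
        expected = naive_ngtdm_features(n_o, s_o, COARSENESS_CAP)
        for k, v in expected.items():
            assert f[k] == pytest.approx(v), k
        # deviant center: s_5 = |5 - 1| = 4 (all 8 neighbors are 1)
        assert s[5] == pytest.approx(4.0)


class TestGLSZM:
    grid = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]])

    def test_three_zones_of_three(self):
        q = make_qroi(self.grid, n_levels=3)
        Z = glszm_matrix(q)
        assert Z.sum() == 3
        assert np.all(Z[:, 2] == 1)  # each gray level: one zone of size 3
        f = glszm_features(q).values
        assert f["small_zone_emphasis"] == pytest.approx(1.0 / 9.0)
        assert f["high_gray_level_zone_emphasis"] == pytest.approx(14.0 / 3.0)
        assert f["low_gray_level_zone_emphasis"] == pytest.approx(49.0 / 108.0)

    def test_constant_roi_single_zone(self):
        q = make_qroi(np.full((4, 4, 2), 3), n_levels=8)
        f = glszm_features(q).values
        assert f["zone_percentage"] == pytest.approx(1.0 / 32.0)
        assert f["large_zone_emphasis"] == pytest.approx(32.0**2)


@pytest.mark.parametrize("trial", range(30))
def test_matrix_families_match_oracles(trial):
    """Implementation vs naive enumeration on random small arrays."""
    r = np.random.default_rng(1000 + trial)
    shape = tuple(r.integers(2, 6, size=3))
    G = int(r.integers(2, 9))
    levels = r.integers(0, G + 1, size=shape)
    if not (levels > 0).any():
        levels[0, 0, 0] = 1
    q = make_qroi(levels, n_levels=G)

    zones = naive_glszm(q.levels, G)
    got = glszm_features(q).values
    want = naive_glszm_features(zones, int((q.levels > 0).sum()))
    for k, v in want.items():
        assert got[k] == pytest.approx(v), f"glszm {k}"
    # voxel conservation
    assert sum(j * c for (_, j), c in zones.items()) == (q.levels > 0).sum()

    P = naive_glcm(q.levels, G)
    if P.sum() > 0:
        assert np.allclose(glcm_matrix(q), P)
        got = gtsdm_features(q).values
        want = naive_glcm_features(P)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-10), f"glcm {k}"

    n_o, s_o = naive_ngtdm(q.levels, G)
    if n_o.sum() > 0:
        got = ngtdm_features(q).values
        want = naive_ngtdm_features(n_o, s_o, COARSENESS_CAP)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-10), f"ngtdm {k}"


def test_translation_invariance(rng):
    levels = np.zeros((10, 10, 10), dtype=int)
    levels[2:6, 2:6, 2:6] = rng.integers(1, 9, size=(4, 4, 4))
    q1 = make_qroi(levels)
    q2 = make_qroi(np.roll(levels, (3, 2, 1), axis=(0, 1, 2)))
    for fn in (gtsdm_features, ngtdm_features, glszm_features, histogram_features):
        f1, f2 = fn(q1).values, fn(q2).values
        for k in f1:
            assert f1[k] == pytest.approx(f2[k]), f"{fn.__name__}.{k}"


class TestRegional:
    def test_sums(self):
        from gliotex.image import ROIMask, VolumeImage

        vals = np.full((10, 10, 1), 2.0)
        vol = VolumeImage(vals, (1.0, 1.0, 1.0), "t1post")
        mask = ROIMask(np.ones((10, 10, 1), bool), (1.0, 1.0, 1.0), "tumor")
        f = regional_features(vol, mask).values
        assert f["tumor_volume_mm3"] == pytest.approx(100.0)
        assert f["total_intensity"] == pytest.approx(200.0)

    def test_locality_and_linearity(self, rng):
        from gliotex.image import ROIMask, VolumeImage

        vals = rng.normal(1.0, 0.1, size=(8, 8, 8))
        mask = ROIMask(rng.random((8, 8, 8)) < 0.4, (1, 1, 1), "tumor")
        vol = VolumeImage(vals, (1, 1, 1), "t1post")
        f = regional_features(vol, mask).values
        outside_changed = vals.copy()
        outside_changed[~mask.values] = 99.0
        f2 = regional_features(VolumeImage(outside_changed, (1, 1, 1), "t1post"), mask).values
        assert f == f2
        f3 = regional_features(VolumeImage(2 * vals, (1, 1, 1), "t1post"), mask).values
        assert f3["total_intensity"] == pytest.approx(2 * f["total_intensity"])
        assert f3["tumor_volume_mm3"] == f["tumor_volume_mm3"]


class TestExtractAll:
    def test_counts_and_finiteness(self, phantom_features):
        vals = phantom_features.values
        assert len(vals) == 86
        assert all(np.isfinite(v) for v in vals.values())
        for mod in ("t1post", "flair"):
            names = modality_feature_names(mod)
            assert len(names) == 43
            assert all(n in vals for n in names)

    def test_family_sizes(self):
        names = modality_feature_names("t1post")
        fams = {}
        for n in names:
            fams.setdefault(n.split("_")[1], []).append(n)
        assert {k: len(v) for k, v in fams.items()} == {
            "hist": 6, "gtsdm": 19, "ngtdm": 5, "glszm": 11, "regional": 2,
        }

    def test_registry_matches_code(self):
        assert load_feature_registry() == all_feature_names()

    def test_identical_modalities_give_identical_values(self, phantom_patient):
        from gliotex.image import VolumeImage

        volumes, tumors, nawm, _ = phantom_patient
        t1 = volumes["t1post"]
        fake_flair = VolumeImage(t1.values.copy(), t1.spacing_mm, "flair")
        fb = extract_all(
            {"t1post": t1, "flair": fake_flair},
            {"t1post": tumors["t1post"], "flair": tumors["t1post"]},
            {"t1post": nawm, "flair": nawm},
        )
        for name in modality_feature_names("t1post"):
            twin = name.replace("t1post", "flair", 1)
            assert fb.values[name] == pytest.approx(fb.values[twin])

    def test_missing_modality_rejected(self, phantom_patient):
        volumes, tumors, nawm, _ = phantom_patient
        with pytest.raises(ValueError, match="missing modality"):
            extract_all(
                {"t1post": volumes["t1post"]},
                {"t1post": tumors["t1post"]},
                {"t1post": nawm},
            )
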