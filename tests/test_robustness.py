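import numpy as np
import pandas as pd
import pytest

from gliotex.image import ROIMask
from gliotex.robustness import (
    PERTURBATION_KINDS,
    PerturbationSpec,
    canonical_perturbations,
    icc,
    perturb_mask,
    robust_features,
)


def _ball_mask(shape=(24, 24, 12), center=(12, 12, 6), radius=6.0):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return ROIMask(d2 <= radius**2, (1.0, 1.0, 1.0), "tumor")


@pytest.fixture(scope="module")
def ball():
    return _ball_mask()


class TestPerturbations:
    def test_exactly_eight_kinds(self):
        specs = canonical_perturbations(seed=0)
        assert len(specs) == 8
        assert [s.kind for s in specs] == list(PERTURBATION_KINDS)

    def test_jitter_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            PerturbationSpec(kind="jitter_sd0.5")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PerturbationSpec(kind="translate_v")

    def test_translation_inverts_exactly(self, ball):
        shifted = perturb_mask(ball, PerturbationSpec("translate_h"))
        back = np.roll(shifted.values, -2, axis=0)
        assert np.array_equal(back, ball.values)

    def test_dilation_grows_erosion_shrinks(self, ball):
        grown = perturb_mask(ball, PerturbationSpec("dilate_1"))
        shrunk = perturb_mask(ball, PerturbationSpec("erode_1"))
        assert grown.n_voxels > ball.n_voxels > shrunk.n_voxels

    def test_jitter_deterministic_under_seed(self, ball):
        a = perturb_mask(ball, PerturbationSpec("jitter_sd0.1", seed=7))
        b = perturb_mask(ball, PerturbationSpec("jitter_sd0.1", seed=7))
        assert np.array_equal(a.values, b.values)

    def test_erosion_emptying_rejected(self):
        tiny = ROIMask(np.zeros((8, 8, 8), bool), (1, 1, 1), "tumor")
        tiny.values[4, 4, 4] = True
        with pytest.raises(ValueError, match="emptied"):
            perturb_mask(tiny, PerturbationSpec("erode_1"))

    def test_all_eight_masks_distinct_on_generic_roi(self):
        # needs an asymmetric ROI large enough that a 1-degree rotation
        # moves boundary voxels (a perfect ball is rotation-invariant)
        shape = (96, 96, 10)
        g = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        m = (
            ((g[0] - 48) / 38.0) ** 2
            + ((g[1] - 48) / 20.0) ** 2
            + ((g[2] - 5) / 4.0) ** 2
            <= 1
        )
        roi = ROIMask(m, (1.0, 1.0, 1.0), "tumor")
        masks = [
            perturb_mask(roi, spec).values for spec in canonical_perturbations(3)
        ]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not np.array_equal(masks[i], masks[j]), (i, j)


class TestICC:
    def test_identical_versions_icc_one(self):
        mat = np.array([[1.0, 1.0], [3.0, 3.0]])
        assert icc(mat) == pytest.approx(1.0)
        many = np.tile(np.arange(10.0)[:, None], (1, 9))
        assert icc(many) == pytest.approx(1.0)

    def test_pure_noise_icc_near_zero(self):
        r = np.random.default_rng(42)
        mat = r.normal(size=(50, 9))
        assert abs(icc(mat)) < 0.15

    def test_zero_total_variance_defined_as_one(self):
        assert icc(np.full((4, 9), 2.5)) == 1.0

    def test_affine_invariance(self):
        r = np.random.default_rng(1)
        subj = r.normal(size=(20, 1))
        mat = subj + 0.3 * r.normal(size=(20, 9))
        assert icc(3.7 * mat - 11.0) == pytest.approx(icc(mat))

    def test_icc3_consistency_under_version_offsets(self):
        # a constant per-version offset hurts ICC(1,1) but not ICC(3,1)
        r = np.random.default_rng(2)
        subj = r.normal(size=(30, 1))
        mat = subj + 0.05 * r.normal(size=(30, 5))
        shifted = mat + np.linspace(0, 3, 5)[None, :]
        assert icc(shifted, form="icc3") > icc(shifted, form="icc1")

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 9)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestRobustFeatures:
    def _tables(self, n=30, seed=0):
        r = np.random.default_rng(seed)
        subj = r.normal(size=n)
        robust = [subj + 0.05 * r.normal(size=n) for _ in range(9)]
        fragile = [r.normal(size=n) for _ in range(9)]
        tables = []
        for v in range(9):
            tables.append(
                pd.DataFrame({"stable": robust[v], "noisy": fragile[v]})
            )
        return tables

    def test_screening_separates_stable_from_noise(self):
        retained, report = robust_features(self._tables())
        assert "stable" in retained
        assert "noisy" not in retained
        assert set(report.columns) >= {"feature_name", "icc", "passed", "threshold"}

    def test_fresh_noise_excluded_across_seeds(self):
        excluded = 0
        for seed in range(20):
            retained, _ = robust_features(self._tables(seed=seed))
            excluded += "noisy" not in retained
        assert excluded >= 19  # >= 95% of seeds

    def test_retained_set_monotone_in_threshold(self):
        tables = self._tables()
        sizes = [
            len(robust_features(tables, threshold=t)[0])
            for t in (0.0, 0.3, 0.6, 0.9, 0.999)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_identical_remeasurement_gives_icc_one(self):
        base = pd.DataFrame(
            {"f": np.arange(10.0), "g": np.arange(10.0) ** 2}
        )
        retained, report = robust_features([base.copy() for _ in range(9)])
        assert (report["icc"] == 1.0).all()
        assert retained == ["f", "g"]

    def test_misaligned_tables_rejected(self):
        a = pd.DataFrame({"f": [1.0, 2.0]})
        b = pd.DataFrame({"g": [1.0, 2.0]})
        with pytest.raises(ValueError, match="aligned"):
            robust_features([a, b])


def test_volume_invariant_under_translations(ball):
    """Tumor volume re-measured under the two translations is unchanged,
    so its ICC across those versions is exactly 1."""
    from gliotex.image import VolumeImage
    from gliotex.texture import regional_features

    vol = VolumeImage(
        np.ones(ball.shape), (1.0, 1.0, 1.0), "t1post"
    )
    v0 = regional_features(vol, ball).values["tumor_volume_mm3"]
    for kind in ("translate_h", "translate_hv"):
        m = perturb_mask(ball, PerturbationSpec(kind))
        assert regional_features(vol, m).values["tumor_volume_mm3"] == v0
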