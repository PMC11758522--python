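"""Areal texture measures, screening, PCA, and hull separation."""

import numpy as np
import pandas as pd
import pytest

from cementochron import synthgen, texture
from cementochron.imgstack import StraightenedCementum
from cementochron.increments import PeakSet
from cementochron.texture import (
    MEASURE_NAMES,
    TexturePatch,
    compute_features,
    hull_separation,
    screen_measures,
    subsample_patches,
    texture_pca,
)


class TestSubsamplePatches:
    def region(self, rows=120, cols=200):
        rng = np.random.default_rng(0)
        px = rng.integers(50, 200, (rows, cols)).astype(np.uint8)
        return StraightenedCementum(px, voxel_size_um=1.0)

    def peaks(self, positions):
        return PeakSet(np.asarray(positions, float), [])

    def test_symmetric_cutoff_equal_patches(self):
        reg = self.region()
        pk = self.peaks([10, 30, 50, 70, 90, 110])
        juv, adu = subsample_patches(reg, cutoff_year=3, peaks=pk)
        assert juv.pixels.shape == adu.pixels.shape

    def test_shorter_side_sets_radial_length(self):
        reg = self.region(rows=160)
        # juvenile extent = 50-3 = 47; adult extent = 150-50 = 100 -> radial 47
        pk = self.peaks([10, 30, 50, 100, 150])
        juv, adu = subsample_patches(reg, cutoff_year=3, peaks=pk)
        assert juv.pixels.shape[0] == adu.pixels.shape[0] == 47
        assert juv.pixels.shape[1] == 2 * 47

    def test_width_clamped_to_region(self):
        reg = self.region(cols=60)
        pk = self.peaks([10, 30, 50, 70, 90, 110])
        with pytest.warns(UserWarning, match="clamped"):
            juv, adu = subsample_patches(reg, cutoff_year=3, peaks=pk)
        assert juv.pixels.shape[1] == 60

    def test_cutoff_outside_years_errors(self):
        reg = self.region()
        with pytest.raises(ValueError, match="outside recorded years"):
            subsample_patches(reg, cutoff_year=9, peaks=self.peaks([10, 30, 50]))


class TestComputeFeatures:
    def test_all_measures_present(self):
        rng = np.random.default_rng(1)
        f = compute_features(rng.normal(128, 20, (32, 32)))
        assert list(f.index) == MEASURE_NAMES
        assert f.drop(["ssk", "sku"]).notna().all() or f.notna().all()

    def test_constant_patch(self):
        f = compute_features(np.full((20, 20), 77.0))
        assert f["sa"] == 0 and f["sq"] == 0 and f["sz"] == 0
        assert np.isnan(f["ssk"]) and np.isnan(f["str"])

    def test_horizontal_bands_strongly_anisotropic(self):
        yy = np.arange(64)[:, None]
        img = 100 + 60 * np.sin(2 * np.pi * yy / 8.0) * np.ones((1, 64))
        f = compute_features(img)
        assert f["str"] < 0.2  # near 0: one dominant direction
        assert f["std"] == pytest.approx(0.0, abs=5.0)  # horizontal banding
        assert abs(f["ssk"]) < 0.1  # sinusoid is symmetric

    def test_iid_noise_isotropic_and_symmetric(self):
        rng = np.random.default_rng(2)
        n = 64
        f = compute_features(rng.normal(0, 10, (n, n)))
        se_skew = np.sqrt(6.0 / (n * n))
        assert abs(f["ssk"]) < 3 * se_skew + 0.05
        assert f["str"] > 0.6

    def test_offset_invariance_of_amplitude_measures(self):
        rng = np.random.default_rng(3)
        base = rng.normal(100, 15, (32, 32))
        f1, f2 = compute_features(base), compute_features(base + 40.0)
        for m in ("sa", "sq", "ssk", "sku", "sp", "sv", "sz"):
            assert f1[m] == pytest.approx(f2[m], rel=1e-9)

    def test_rms_scales_linearly(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 10, (32, 32))
        f1, f2 = compute_features(base), compute_features(2.0 * base)
        assert f2["sq"] == pytest.approx(2.0 * f1["sq"], rel=1e-9)
        assert f2["sa"] == pytest.approx(2.0 * f1["sa"], rel=1e-9)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError, match="16x16"):
            compute_features(np.zeros((8, 8)))

    def test_contrast_monotonically_recovered(self):
        # generator contrast knob must map monotonically onto amplitude
        # measures for noise-free images
        sqs = []
        for contrast in (0.2, 0.4, 0.6, 0.8):
            spec = synthgen.SyntheticSpec(
                schedule=synthgen.GrowthSchedule("linear", (10.0, 0.0), 6, 10.0),
                texture=synthgen.TextureParams(contrast, 1e9, 0.0),
                image_shape=(100, 80),
                seed=1,
            )
            img, _ = synthgen.render_cementum(spec)
            sqs.append(compute_features(img[10:60, :].astype(float))["sq"])
        assert all(a < b for a, b in zip(sqs, sqs[1:]))


class TestScreenMeasures:
    def dataset(self, shift, seed, n=8):
        rng = np.random.default_rng(seed)
        rows = []
        for stage, delta in (("juvenile", 0.0), ("adult", shift)):
            for _ in range(n):
                f = compute_features(rng.normal(100 + delta, 10 + delta, (24, 24)))
                f["stage"] = stage
                rows.append(f)
        return pd.DataFrame(rows)

    def test_identical_stages_measure_dropped(self):
        df = self.dataset(shift=0.0, seed=5)
        # force one measure identical across stages
        df["sa"] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            retained, table = screen_measures({"d1": df})
        assert "sa" not in retained

    def test_strong_shift_retains_amplitude_measures(self):
        datasets = {f"d{k}": self.dataset(shift=25.0, seed=k) for k in range(2)}
        retained, table = screen_measures(datasets)
        assert "sq" in retained
        assert set(table["dataset"]) == set(datasets)

    def test_retained_requires_every_dataset(self):
        d_yes = self.dataset(shift=25.0, seed=1)
        d_no = self.dataset(shift=0.0, seed=2)
        retained_both, _ = screen_measures({"a": d_yes, "b": d_no})
        retained_one, _ = screen_measures({"a": d_yes})
        assert set(retained_both) <= set(retained_one)

    def test_anova_hand_value(self):
        # one-way ANOVA of {1,2,3} vs {4,5,6} has F = 13.5
        df = pd.DataFrame(
            {"sa": [1, 2, 3, 4, 5, 6], "stage": ["j"] * 3 + ["a"] * 3}
        )
        for m in MEASURE_NAMES:
            if m != "sa":
                df[m] = np.arange(6) * 0.1 + (np.arange(6) % 2)
        _, table = screen_measures({"d": df})
        F = table.set_index("measure").loc["sa", "F"]
        assert F == pytest.approx(13.5)


class TestTexturePca:
    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(0, 1, (20, 6)), columns=list("abcdef"))
        space = texture_pca(X)
        LtL = space.loadings.T @ space.loadings
        assert np.allclose(LtL, np.eye(LtL.shape[0]), atol=1e-10)

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(0, 1, (15, 4)), columns=list("abcd"))
        space = texture_pca(X)
        assert space.variance_explained.sum() == pytest.approx(1.0)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(0, 1, (12, 5)), columns=list("abcde"))
        space = texture_pca(X)
        Z = (X - X.mean()) / X.std(ddof=0)
        recon = space.scores @ space.loadings.T
        assert np.allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_correlated_pair_loads_on_pc1(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 30)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(0, 1e-3, 30)})
        space = texture_pca(X)
        assert space.variance_explained[0] >= 2.0 / 3.0 - 1e-6

    def test_scores_invariant_to_column_order(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(0, 1, (18, 5)), columns=list("abcde"))
        s1 = texture_pca(X)
        s2 = texture_pca(X[list("edcba")])
        assert np.allclose(np.abs(s1.scores), np.abs(s2.scores), atol=1e-8)

    def test_too_few_patches(self):
        with pytest.raises(ValueError):
            texture_pca(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestHullSeparation:
    def test_disjoint_clusters_distinct(self):
        a = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        b = a + 10.0
        pts = np.vstack([a, b])
        labels = ["j"] * 4 + ["a"] * 4
        overlap, distinct = hull_separation(pts, labels)
        assert overlap == 0.0 and distinct

    def test_identical_sets_not_distinct(self):
        a = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], float)
        pts = np.vstack([a, a])
        overlap, distinct = hull_separation(pts, ["j"] * 4 + ["a"] * 4)
        assert overlap == pytest.approx(1.0)
        assert not distinct

    def test_partial_overlap_fraction(self):
        # unit squares offset by 0.5 in x: inter 0.5, union 1.5 -> 1/3
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        pts = np.vstack([sq, sq + [0.5, 0.0]])
        overlap, _ = hull_separation(pts, ["j"] * 4 + ["a"] * 4)
        assert overlap == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_collinear_fallback(self):
        a = np.array([[0, 0], [1, 0], [2, 0]], float)
        b = np.array([[5, 0], [6, 0], [7, 0]], float)
        overlap, distinct = hull_separation(np.vstack([a, b]), ["j"] * 3 + ["a"] * 3)
        assert overlap == 0.0 and distinct

    def test_fewer_than_three_points_errors(self):
        pts = np.array([[0, 0], [1, 1], [0, 1], [5, 5]], float)
        with pytest.raises(ValueError, match="fewer than 3"):
            hull_separation(pts, ["j", "j", "j", "a"])


def _stage_features(shift_on: bool, seed: int, n_specimens: int = 8):
    """End-to-end: render specimens, cut juvenile/adult patches, features.

    Specimens vary individually in growth scale and life span, as real
    conspecifics do, so any stage separation must come from the texture
    shift and not from shared band geometry.
    """
    shift = (
        synthgen.JuvenileAdultShift(contrast=0.3, anisotropy=6.0, noise_sd=-6.0)
        if shift_on
        else synthgen.JuvenileAdultShift()
    )
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_specimens):
        base = 10.0 * float(np.exp(rng.normal(0.0, 0.1)))
        n_years = int(rng.integers(9, 13))
        spec = synthgen.SyntheticSpec(
            schedule=synthgen.GrowthSchedule("linear", (10.0, 0.0), n_years, base),
            texture=synthgen.TextureParams(0.4, 1.0, 8.0, juvenile_adult_shift=shift),
            maturity_year=5,
            image_shape=(180, 120),
            seed=int(rng.integers(2**31)),
        )
        img, truth = synthgen.render_cementum(spec)
        region = StraightenedCementum(img, voxel_size_um=1.0)
        juv, adu = subsample_patches(
            region, 5, PeakSet(truth.peak_positions_um, [])
        )
        for patch in (juv, adu):
            f = compute_features(patch)
            f["stage"] = patch.stage
            rows.append(f)
    return pd.DataFrame(rows)


class TestEndToEndDiscrimination:
    def run_cohort(self, shift_on, seed):
        df = _stage_features(shift_on, seed)
        cols = [m for m in MEASURE_NAMES if df[m].notna().all()]
        space = texture_pca(df[cols])
        return hull_separation(space, df["stage"].to_numpy())

    def test_shifted_cohort_distinct(self):
        overlap, distinct = self.run_cohort(True, seed=100)
        assert distinct

    def test_unshifted_cohort_not_distinct(self):
        overlap, distinct = self.run_cohort(False, seed=100)
        assert not distinct
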