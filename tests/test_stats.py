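"""PCA, LOO-SVM classification, augmentation, CV and the paired t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotovol import phantom, stats
from rotovol.exceptions import UndefinedStatisticError
from rotovol.phantom import Image2D


def paired_t_oracle(a, b):
    """Closed-form paired t computed from first principles."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    mean = d.sum() / n
    sd = math.sqrt(((d - mean) ** 2).sum() / (n - 1))
    t = mean / (sd / math.sqrt(n))
    return t, n - 1


class TestPCA:
    def test_collinear_data_one_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": 2 * x})
        _, _, ratio = stats.pca_project(table, k=1)
        assert ratio[0] >= 0.999

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(40, 6)))
        _, loadings, _ = stats.pca_project(table, k=3)
        assert np.allclose(loadings.T @ loadings, np.eye(3), atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 4))
        scores, loadings, _ = stats.pca_project(
            pd.DataFrame(x), k=4, standardize=False)
        xc = x - x.mean(axis=0)
        assert np.abs(scores @ loadings.T - xc).max() < 1e-8

    def test_k_above_rank_raises(self):
        x = np.ones((10, 3)) * np.arange(3)  # rank 0 after centering
        with pytest.raises(ValueError):
            stats.pca_project(pd.DataFrame(x), k=2)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(3)
        _, _, ratio = stats.pca_project(pd.DataFrame(rng.normal(size=(50, 6))), k=3)
        assert np.all(np.diff(ratio) <= 1e-12)


@pytest.fixture(scope="module")
def separated_table():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(10 * i, 1.0, size=(30, 6)) for i in range(4)])
    y = np.repeat(["hela", "b16", "h9c2", "mp"], 30)
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
    table["label"] = y
    return table


class TestSvmLoo:
    def test_well_separated_classes_high_accuracy(self, separated_table):
        rep = stats.svm_loo_classify(separated_table)
        assert rep.accuracy >= 0.95
        assert rep.matrix.sum() == len(separated_table)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.matrix) / rep.matrix.sum())

    def test_shuffled_labels_near_chance(self, separated_table):
        rng = np.random.default_rng(7)
        shuffled = separated_table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        rep = stats.svm_loo_classify(shuffled)
        assert 0.25 - 0.1 <= rep.accuracy <= 0.25 + 0.1

    def test_row_sums_equal_class_counts(self, separated_table):
        rep = stats.svm_loo_classify(separated_table)
        for i, c in enumerate(rep.classes):
            assert rep.matrix[i].sum() == (separated_table["label"] == c).sum()

    def test_singleton_class_infeasible(self):
        table = pd.DataFrame({"f0": [1, 2, 3], "label": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="leave-one-out"):
            stats.svm_loo_classify(table)

    def test_histogram_feature_table_separates_intensity_shifted_volumes(self):
        rng = np.random.default_rng(0)
        vols, labels = [], []
        for label, lo, hi in (("dim", 0.0, 0.4), ("bright", 0.6, 1.0)):
            for _ in range(5):
                vols.append(rng.uniform(lo, hi, size=(8, 8, 4)))
                labels.append(label)
        table = stats.histogram_feature_table(vols, labels, bins=16)
        assert table.shape == (10, 17)
        assert np.allclose(table.drop(columns="label").sum(axis=1), 1.0)
        rep = stats.svm_loo_classify(table)
        assert rep.accuracy == 1.0


class TestAugmentation:
    def make_images(self, n=4):
        rng = np.random.default_rng(0)
        return [Image2D(rng.random((20, 20))) for _ in range(n)]

    def test_identity_when_no_extra_requested(self):
        imgs = self.make_images()
        out, prov = stats.augment_images(imgs, n_out=len(imgs), seed=0)
        assert prov == list(range(len(imgs)))
        for a, b in zip(out, imgs):
            assert np.array_equal(a.pixels, b.pixels)

    def test_seed_determinism_and_provenance(self):
        imgs = self.make_images()
        a, prov_a = stats.augment_images(imgs, n_out=12, seed=5)
        b, prov_b = stats.augment_images(imgs, n_out=12, seed=5)
        assert prov_a == prov_b
        for ia, ib in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)
        assert len(a) == 12
        c, _ = stats.augment_images(imgs, n_out=12, seed=6)
        assert any(not np.array_equal(x.pixels, y.pixels)
                   for x, y in zip(a[4:], c[4:]))

    def test_n_out_below_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.augment_images(self.make_images(), n_out=2, seed=0)


class TestCoefficientOfVariation:
    def test_no_variability(self):
        assert stats.coefficient_of_variation([2, 2, 2]) == 0.0

    def test_closed_form_two_points(self):
        # sd = sqrt(2), mean = 2 -> 70.71%
        assert stats.coefficient_of_variation([1, 3]) == pytest.approx(70.71, abs=0.01)

    def test_scale_invariance(self):
        x = [1.2, 3.4, 2.2, 5.0]
        assert stats.coefficient_of_variation(
            [5 * v for v in x]) == pytest.approx(stats.coefficient_of_variation(x))

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            stats.coefficient_of_variation([-1.0, 1.0])

    def test_population_flag(self):
        sample = stats.coefficient_of_variation([1, 3])
        population = stats.coefficient_of_variation([1, 3], population=True)
        assert population == pytest.approx(sample / math.sqrt(2))


class TestPairedT:
    def test_equal_samples_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            stats.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(3, 10))
    def test_matches_closed_form_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = a + rng.normal(0.5, 1.0, size=n)
        if np.allclose(a - b, (a - b)[0]):
            return
        t, p, df = stats.paired_t_test(a, b)
        t_oracle, df_oracle = paired_t_oracle(a, b)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == df_oracle
        assert 0 <= p <= 1


class TestTimeCourse:
    def test_identical_volumes_zero_cv(self):
        rng = np.random.default_rng(0)
        v = rng.random((12, 12, 6))
        rep = stats.time_course_report({10: v, 20: v.copy(), 30: v.copy()})
        assert all(cv == pytest.approx(0.0, abs=1e-9)
                   for cv in rep.cv_per_feature.values())

    def test_roughness_ramp_increases_contrast(self):
        vols = {}
        for i, amp in enumerate((0.02, 0.1, 0.2)):
            ph = phantom.make_phantom(4, "rough", 40, (9, 9, 9),
                                      roughness_amp=amp)
            vols[10 * (i + 1)] = ph.membrane_field
        rep = stats.time_course_report(vols)
        traj = rep.trajectories["contrast"]
        assert traj[0] < traj[1] < traj[2]

    def test_two_group_paired_test(self):
        rng = np.random.default_rng(1)
        a = {t: rng.random((10, 10, 5)) for t in (10, 20, 30)}
        b = {t: rng.random((10, 10, 5)) * 0.5 + 0.25 for t in (10, 20, 30)}
        rep = stats.time_course_report(a, group_b=b)
        t, p, df = rep.test
        assert df == 5
        assert 0 <= p <= 1
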