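import numpy as np
import pytest

import trussmorph as tm
from trussmorph.procrustes import (
    centroid_size,
    confidence_ellipse,
    group_tests_frame,
    optimal_rotation,
)


def rot(angle):
    return np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )


def random_shape(seed, k=9):
    return np.random.default_rng(seed).normal(size=(k, 2)) * 10


class TestProcrustesDistance:
    def test_identical_shapes(self):
        s = random_shape(0)
        assert tm.procrustes_distance(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_similarity_invariance(self):
        s = random_shape(1)
        moved = (s @ rot(np.radians(37)).T) * 2.3 + np.array([5.0, -11.0])
        assert tm.procrustes_distance(s, moved) == pytest.approx(0.0, abs=1e-9)

    def test_partial_distance_matches_rotation_grid_search(self):
        """Brute-force oracle: minimize ||A - B R(theta)|| over a 1e-5
        grid of rotation angles for two distinct 9-point shapes."""
        a, b = random_shape(2), random_shape(3)
        ours = tm.procrustes_distance(a, b, kind="partial")
        A = (a - a.mean(0)) / centroid_size(a)
        B = (b - b.mean(0)) / centroid_size(b)
        thetas = np.arange(0, 2 * np.pi, 1e-5)
        cos, sin = np.cos(thetas), np.sin(thetas)
        # ||A - B R||^2 = 2 - 2 tr(R' B' A); expand with 2x2 cross-covariance
        H = B.T @ A
        trace = (H[0, 0] + H[1, 1]) * cos + (H[1, 0] - H[0, 1]) * sin
        brute = np.sqrt(np.clip(2.0 - 2.0 * trace.max(), 0, None))
        assert ours == pytest.approx(brute, abs=1e-8)

    def test_metric_properties(self):
        a, b, c = (random_shape(s) for s in (4, 5, 6))
        dab = tm.procrustes_distance(a, b)
        dba = tm.procrustes_distance(b, a)
        assert dab == pytest.approx(dba, abs=1e-10)
        assert dab >= 0
        dac = tm.procrustes_distance(a, c)
        dbc = tm.procrustes_distance(b, c)
        assert dab <= dac + dbc + 1e-12


class TestGpa:
    def test_aligned_configurations_are_normalized(self, gpa_result):
        centroids = gpa_result.aligned.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        sizes = np.sqrt((gpa_result.aligned**2).sum(axis=(1, 2)))
        assert np.allclose(sizes, 1.0, atol=1e-9)

    def test_consensus_is_mean_of_aligned(self, gpa_result):
        assert np.allclose(
            gpa_result.consensus, gpa_result.aligned.mean(axis=0), atol=1e-8
        )

    def test_invariance_to_input_similarity_transforms(self, study_dataset):
        """Arbitrarily pre-rotating/translating/scaling the raw specimens
        leaves the aligned pairwise distances unchanged."""
        sub = study_dataset.subset(np.arange(study_dataset.n_specimens) < 20)
        rng = np.random.default_rng(8)
        coords = sub.coords.copy()
        for i in range(len(coords)):
            coords[i] = (
                coords[i] @ rot(rng.uniform(0, 2 * np.pi)).T
            ) * rng.uniform(0.5, 2.0) + rng.normal(size=2) * 50
        moved = tm.LandmarkDataset(sub.specimen_ids, sub.group_labels, coords)
        d1 = tm.gpa(sub).distance_matrix().to_numpy()
        d2 = tm.gpa(moved).distance_matrix().to_numpy()
        assert np.allclose(d1, d2, atol=1e-9)

    def test_consensus_minimizes_residual_sum(self, gpa_result):
        """Perturbing the consensus in random directions increases the
        summed squared deviation of the aligned shapes."""
        base = ((gpa_result.aligned - gpa_result.consensus) ** 2).sum()
        rng = np.random.default_rng(0)
        for _ in range(5):
            bump = rng.normal(size=gpa_result.consensus.shape) * 1e-3
            perturbed = (
                (gpa_result.aligned - (gpa_result.consensus + bump)) ** 2
            ).sum()
            assert perturbed > base

    def test_zero_size_configuration_named(self):
        coords = np.zeros((2, 9, 2))
        coords[1] = random_shape(1)
        data = tm.LandmarkDataset(["flat", "ok"], ["G", "G"], coords)
        with pytest.raises(ValueError, match="flat"):
            tm.gpa(data)

    def test_centroid_sizes_in_mm(self, study_dataset, gpa_result):
        expected = [centroid_size(s) for s in study_dataset.coords]
        assert np.allclose(gpa_result.centroid_sizes, expected)

    def test_rotation_never_reflects(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x, y = rng.normal(size=(2, 9, 2))
            R = optimal_rotation(x - x.mean(0), y - y.mean(0))
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)


class TestProcrustesAnova:
    def test_identical_specimens_degenerate(self):
        coords = np.repeat(random_shape(3)[None], 6, axis=0)
        data = tm.LandmarkDataset(
            [f"s{i}" for i in range(6)], ["A"] * 3 + ["B"] * 3, coords
        )
        tables = tm.procrustes_anova(tm.gpa(data), n_perm=19, seed=0)
        assert tables["shape"].attrs["degenerate"]

    def test_power_against_single_landmark_offset(self):
        """Two groups differing by a 5-SD displacement of one landmark
        are detected at p <= 0.005 with 999 permutations."""
        off = {"A": np.zeros((9, 2)), "B": np.zeros((9, 2))}
        off["B"][4] = (0.0, 2.5)  # 5 x noise_sd
        model = tm.ShapeModel(
            group_offsets=off,
            group_sizes={"A": 30, "B": 30},
            noise_sd=0.5,
            seed=21,
        )
        result = tm.gpa(tm.generate_dataset(model))
        tables = tm.procrustes_anova(result, n_perm=999, seed=4)
        assert tables["shape"].loc["between_groups", "p_perm"] <= 0.005

    def test_centroid_size_anova_detects_size_shift(self):
        model_a = tm.ShapeModel(
            group_offsets={"A": np.zeros((9, 2)), "B": np.zeros((9, 2))},
            group_sizes={"A": 30, "B": 30},
            noise_sd=0.5,
            seed=5,
        )
        data = tm.generate_dataset(model_a)
        # push group B to systematically larger specimens
        labels = np.asarray(data.group_labels)
        coords = data.coords.copy()
        coords[labels == "B"] *= 1.5
        bigger = tm.LandmarkDataset(data.specimen_ids, data.group_labels, coords)
        tables = tm.procrustes_anova(tm.gpa(bigger), n_perm=49, seed=0)
        assert tables["size"].loc["log_centroid_size", "p"] < 0.01

    def test_permutation_p_reproducible(self, gpa_result):
        a = tm.procrustes_anova(gpa_result, n_perm=99, seed=123)
        b = tm.procrustes_anova(gpa_result, n_perm=99, seed=123)
        assert (
            a["shape"].loc["between_groups", "p_perm"]
            == b["shape"].loc["between_groups", "p_perm"]
        )


class TestShapePca:
    def test_zero_variance_means_zero_eigenvalues(self):
        coords = np.repeat(random_shape(7)[None], 5, axis=0)
        data = tm.LandmarkDataset([f"s{i}" for i in range(5)], ["G"] * 5, coords)
        result = tm.shape_pca(tm.gpa(data))
        assert np.allclose(result.eigenvalues, 0.0, atol=1e-20)

    def test_rank_bound_2k_minus_4(self, gpa_result):
        result = tm.shape_pca(gpa_result)
        assert result.eigenvalues[: 2 * 9 - 4].sum() == pytest.approx(
            result.eigenvalues.sum()
        )
        assert (result.eigenvalues[2 * 9 - 4 :] < 1e-12).all()

    def test_percent_variance_sums_to_100(self, gpa_result):
        result = tm.shape_pca(gpa_result)
        assert result.percent_variance.sum() == pytest.approx(100.0)

    def test_confidence_ellipses_cover_group_spread(self, gpa_result):
        result = tm.shape_pca(gpa_result)
        frame = confidence_ellipse(result.scores, gpa_result.group_labels)
        assert set(frame["group"]) == set(gpa_result.group_labels)
        assert (frame["semi_major"] >= frame["semi_minor"]).all()


class TestGroupMeanTests:
    def test_null_split_of_one_group(self):
        """A single homogeneous population split randomly in two: tiny
        distance and a non-significant permutation p."""
        model = tm.ShapeModel(
            group_offsets={"A": np.zeros((9, 2))},
            group_sizes={"A": 60},
            noise_sd=0.5,
            seed=2,
        )
        data = tm.generate_dataset(model)
        rng = np.random.default_rng(0)
        labels = np.array(["L", "R"])[rng.integers(0, 2, 60)]
        split = tm.LandmarkDataset(data.specimen_ids, labels.tolist(), data.coords)
        (test,) = tm.group_mean_tests(tm.gpa(split), n_perm=199, seed=3)
        assert test.procrustes_distance < 0.01
        assert test.p_perm > 0.05

    def test_identical_means_shrink_with_n(self):
        model = tm.ShapeModel(
            group_offsets={"A": np.zeros((9, 2)), "B": np.zeros((9, 2))},
            group_sizes={"A": 200, "B": 200},
            noise_sd=0.01,
            seed=13,
        )
        result = tm.gpa(tm.generate_dataset(model))
        (test,) = tm.group_mean_tests(result, n_perm=49, seed=1)
        assert test.procrustes_distance <= 0.005

    def test_offset_recovery_in_difference_vectors(self):
        """A known single-landmark offset reappears in the per-landmark
        mean-difference vector at that landmark and nowhere else."""
        d = 4.0
        off = {"A": np.zeros((9, 2)), "B": np.zeros((9, 2))}
        off["B"][5] = (0.0, d)
        model = tm.ShapeModel(
            group_offsets=off,
            group_sizes={"A": 150, "B": 150},
            noise_sd=0.2,
            size_range=(320.0, 320.0),
            seed=17,
        )
        data = tm.generate_dataset(model)
        result = tm.gpa(data)
        (test,) = tm.group_mean_tests(result, n_perm=19, seed=1)
        vec = test.shape_difference_vectors
        # work in mm: undo the unit-size scaling with the mean centroid size
        mm = vec * result.centroid_sizes.mean()
        # superimposition re-centers each shape, so roughly 1/9 of the
        # offset leaks onto the other landmarks; the displaced landmark
        # still carries ~8/9 of it along the offset direction
        assert mm[5, 1] == pytest.approx(d * 8 / 9, abs=0.15 * d)
        others = np.delete(mm, 5, axis=0)
        assert np.abs(others).max() < d / 3

    def test_pair_count_and_frame(self, gpa_result):
        tests = tm.group_mean_tests(gpa_result, n_perm=19, seed=0)
        assert len(tests) == 21  # C(7,2)
        frame = group_tests_frame(tests)
        assert set(frame.columns) >= {
            "group1",
            "group2",
            "proc_dist",
            "mahalanobis",
            "p_perm",
            "loo_cv",
        }
        assert (frame["proc_dist"] >= 0).all()
        assert ((frame["p_perm"] > 0) & (frame["p_perm"] <= 1)).all()
        assert ((frame["loo_cv"] >= 0) & (frame["loo_cv"] <= 1)).all()

    def test_small_group_skipped_with_warning(self, caplog):
        coords = np.stack([random_shape(s) for s in range(5)])
        data = tm.LandmarkDataset(
            [f"s{i}" for i in range(5)], ["A", "A", "A", "B", "B"], coords
        )
        with caplog.at_level("WARNING"):
            tests = tm.group_mean_tests(tm.gpa(data), n_perm=9, seed=0)
        assert tests == []
        assert "too small" in caplog.text
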