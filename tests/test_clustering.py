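import numpy as np
import pytest

from phodnet.clustering import (
    count_responsive_otus,
    fuzzy_cmeans,
    partition_coefficient,
    standardize_profiles,
)
from phodnet.core_io import OtuTable, SampleMetadata
from phodnet.errors import ConvergenceError, ValidationError


def trajectory_table(trends, n_years=5, noise=0.0, seed=0, treatment="NS"):
    """Table with one sample per year whose taxa follow given linear trends."""
    rng = np.random.default_rng(seed)
    years = np.arange(n_years)
    rows = [
        100 + slope * years + rng.normal(0, noise, n_years) for slope in trends
    ]
    counts = np.clip(np.array(rows, dtype=float), 0.1, None)
    sample_ids = [f"{treatment}_y{y}" for y in years]
    meta = [SampleMetadata(s, treatment, int(y), 1) for s, y in zip(sample_ids, years)]
    return (
        OtuTable([f"t{i}" for i in range(len(trends))], sample_ids, counts),
        meta,
    )


class TestStandardizeProfiles:
    def test_linear_trend_z_scores(self):
        # constant column sums, so taxon a's relative abundance has yearly
        # means (1/6, 2/6, 3/6): an even ramp whose z-profile is ∝ (-1, 0, 1)
        counts = np.array([[1.0, 2.0, 3.0], [5.0, 4.0, 3.0]])
        meta = [SampleMetadata(f"s{y}", "CK", y, 1) for y in range(3)]
        t = OtuTable(["a", "b"], [f"s{y}" for y in range(3)], counts)
        z, ids, years = standardize_profiles(t, meta, "CK")
        assert years == [0, 1, 2]
        row_a = z[ids.index("a")]
        np.testing.assert_allclose(row_a / np.abs(row_a[0]), [-1, 0, 1], atol=1e-9)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_constant_taxon_dropped(self):
        counts = np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        meta = [SampleMetadata(f"s{y}", "CK", y, 1) for y in range(3)]
        t = OtuTable(["const", "trend"], [f"s{y}" for y in range(3)], counts)
        z, ids, _ = standardize_profiles(t, meta, "CK")
        assert "trend" in ids
        # relative abundances of a 2-taxon table both vary; the dropped-taxon
        # path is exercised with a 1-taxon table below
        t1 = OtuTable(["only"], [f"s{y}" for y in range(3)], np.array([[2.0, 2.0, 2.0]]))
        meta1 = [SampleMetadata(f"s{y}", "CK", y, 1) for y in range(3)]
        z1, ids1, _ = standardize_profiles(t1, meta1, "CK")
        assert ids1 == [] and z1.shape[0] == 0

    def test_missing_treatment_rejected(self):
        t, meta = trajectory_table([1.0, -1.0])
        with pytest.raises(ValidationError):
            standardize_profiles(t, meta, "NB")

    def test_fewer_than_three_years_rejected(self):
        t, meta = trajectory_table([1.0, -1.0], n_years=2)
        with pytest.raises(ValidationError):
            standardize_profiles(t, meta, "NS")


class TestFuzzyCMeans:
    def separated_profiles(self, seed=0, per_group=10):
        rng = np.random.default_rng(seed)
        up = np.linspace(-1, 1, 6)
        a = up + rng.normal(0, 0.05, (per_group, 6))
        b = -up + rng.normal(0, 0.05, (per_group, 6))
        return np.vstack([a, b])

    def test_single_cluster_memberships_are_one(self):
        x = self.separated_profiles()
        fc = fuzzy_cmeans(x, n_clusters=1, seed=0)
        np.testing.assert_array_equal(fc.membership, 1.0)

    def test_two_separated_groups_recovered(self):
        x = self.separated_profiles()
        fc = fuzzy_cmeans(x, n_clusters=2, seed=0)
        top = fc.membership.max(axis=1)
        assert (top > 0.9).all()
        labels = fc.hard_assignment()
        assert len(set(labels[:10])) == 1
        assert labels[0] != labels[10]

    def test_membership_rows_sum_to_one(self):
        x = self.separated_profiles(seed=3)
        fc = fuzzy_cmeans(x, n_clusters=3, seed=1)
        np.testing.assert_allclose(fc.membership.sum(axis=1), 1.0, atol=1e-9)
        assert ((fc.membership >= 0) & (fc.membership <= 1)).all()

    def test_same_seed_identical(self):
        x = self.separated_profiles(seed=5)
        a = fuzzy_cmeans(x, n_clusters=2, seed=11)
        b = fuzzy_cmeans(x, n_clusters=2, seed=11)
        assert a.membership.tobytes() == b.membership.tobytes()
        assert a.centroids.tobytes() == b.centroids.tobytes()

    def test_coincident_point_gets_crisp_membership(self):
        x = self.separated_profiles()
        fc = fuzzy_cmeans(x, n_clusters=2, seed=0)
        x2 = np.vstack([x, fc.centroids[0]])
        fc2 = fuzzy_cmeans(x2, n_clusters=2, seed=0)
        np.testing.assert_allclose(fc2.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_data_rejected(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1))  # one distinct profile
        with pytest.raises(ConvergenceError):
            fuzzy_cmeans(x, n_clusters=2, seed=0)

    def test_invalid_cluster_count(self):
        x = self.separated_profiles()
        with pytest.raises(ValidationError):
            fuzzy_cmeans(x, n_clusters=0, seed=0)
        with pytest.raises(ValidationError):
            fuzzy_cmeans(x, n_clusters=len(x) + 1, seed=0)

    def test_partition_coefficient_range(self):
        x = self.separated_profiles()
        fc = fuzzy_cmeans(x, n_clusters=2, seed=0)
        assert 0.5 <= partition_coefficient(fc) <= 1.0


class TestCountResponsiveOtus:
    def make_fc(self, centroids, membership):
        centroids = np.asarray(centroids, dtype=float)
        membership = np.asarray(membership, dtype=float)
        from phodnet.clustering import FuzzyClustering

        return FuzzyClustering(
            [f"t{i}" for i in range(membership.shape[0])],
            centroids,
            membership,
            2.0,
            centroids.shape[0],
            0,
            0.0,
        )

    def test_flat_centroids_count_zero(self):
        fc = self.make_fc([[0.2, 0.2, 0.2]], np.ones((5, 1)))
        assert count_responsive_otus(fc)["total"] == 0

    def test_all_confident_in_moving_cluster(self):
        fc = self.make_fc([[-1.0, 0.0, 1.0]], np.ones((7, 1)))
        assert count_responsive_otus(fc)["total"] == 7

    def test_known_mixed_fixture(self):
        # cluster 0 moves (range 2), cluster 1 is flat; 6 taxa confidently in
        # cluster 0, 3 in flat cluster 1, 1 unconfident -> 6 responsive
        centroids = [[-1.0, 0.0, 1.0], [0.1, 0.0, 0.1]]
        membership = np.array(
            [[0.95, 0.05]] * 6 + [[0.1, 0.9]] * 3 + [[0.45, 0.55]]
        )
        fc = self.make_fc(centroids, membership)
        out = count_responsive_otus(fc, membership_min=0.6, amplitude_min=1.0)
        assert out["total"] == 6
        assert out["per_cluster"][0] == 6 and out["per_cluster"][1] == 0
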