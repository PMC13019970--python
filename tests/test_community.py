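import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix

import soiltrace as st


def counts_table(array):
    array = np.asarray(array)
    return st.AbundanceTable(
        pd.DataFrame(
            array,
            index=[f"F{i}" for i in range(array.shape[0])],
            columns=[f"S{j}" for j in range(array.shape[1])],
        ),
        kingdom="bacteria",
    )


class TestBrayCurtis:
    def test_identical_vectors_give_zero(self):
        assert st.bray_curtis([3, 1, 2], [3, 1, 2]) == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self):
        assert st.bray_curtis([3, 0, 0], [0, 2, 5]) == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        assert st.bray_curtis([2, 2, 0], [1, 1, 2]) == pytest.approx(0.5)

    def test_both_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            st.bray_curtis([0, 0], [0, 0])


class TestAitchison:
    def test_identical_compositions_give_zero(self):
        clr = st.clr_transform(counts_table([[4], [2]]), 1.0)["S0"]
        assert st.aitchison_distance(clr, clr) == 0.0

    def test_euclidean_formula(self):
        assert st.aitchison_distance([1, -1], [-1, 1]) == pytest.approx(np.sqrt(8))
        assert st.aitchison_distance([1, -1], [-1, 1]) == pytest.approx(2.8284, abs=1e-4)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            x, y, z = rng.normal(size=(3, 8))
            assert st.aitchison_distance(x, z) <= (
                st.aitchison_distance(x, y) + st.aitchison_distance(y, z) + 1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            st.aitchison_distance([1, 2], [1, 2, 3])


class TestDistanceMatrix:
    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(7)
        table = counts_table(rng.integers(0, 50, size=(12, 5)))
        bc = st.distance_matrix(table, "bray_curtis")
        for i, si in enumerate(table.sample_ids):
            for j, sj in enumerate(table.sample_ids):
                assert bc.data[i, j] == pytest.approx(
                    0.0 if i == j else st.bray_curtis(table.data[si], table.data[sj])
                )
        ait = st.distance_matrix(table, "aitchison", pseudocount=1.0)
        clr = st.clr_transform(table, 1.0)
        assert ait.data[0, 3] == pytest.approx(
            st.aitchison_distance(clr["S0"], clr["S3"])
        )

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        table = counts_table(rng.integers(0, 30, size=(10, 6)))
        for metric in ("bray_curtis", "aitchison"):
            dm = st.distance_matrix(table, metric)
            np.testing.assert_allclose(dm.data, dm.data.T)
            np.testing.assert_allclose(np.diag(dm.data), 0.0)

    def test_two_samples_single_entry(self):
        table = counts_table([[2, 1], [2, 1], [0, 2]])
        dm = st.distance_matrix(table, "bray_curtis")
        assert dm.data[0, 1] == pytest.approx(st.bray_curtis([2, 2, 0], [1, 1, 2]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            st.distance_matrix(counts_table([[1], [2]]), "bray_curtis")


class TestSourceBaseline:
    def _metadata(self, homes):
        rows = [
            {
                "sample_id": sid, "home": home, "sample_type": "source_aliquot",
                "location": "source", "height": "none", "week": 0,
                "is_control_home": False, "kingdom": "bacteria",
            }
            for sid, home in homes.items()
        ]
        return st.SampleMetadata(pd.DataFrame(rows))

    def test_identical_aliquots_reproduce_themselves(self):
        table = st.AbundanceTable(
            pd.DataFrame({"a1": [0.4, 0.6], "a2": [0.4, 0.6]}, index=["A", "B"]),
            kingdom="bacteria", mode="relative",
        )
        md = self._metadata({"a1": "H1", "a2": "H1"})
        baseline = st.source_baseline(table, md)
        np.testing.assert_allclose(baseline["H1"], [0.4, 0.6])

    def test_mean_of_orthogonal_aliquots(self):
        table = st.AbundanceTable(
            pd.DataFrame({"a1": [1.0, 0.0], "a2": [0.0, 1.0]}, index=["A", "B"]),
            kingdom="bacteria", mode="relative",
        )
        md = self._metadata({"a1": "H2", "a2": "H2"})
        np.testing.assert_allclose(st.source_baseline(table, md)["H2"], [0.5, 0.5])

    def test_profiles_sum_to_one(self, default_bundle, default_result):
        genus = default_result.genus_table
        aliquots = [s for s in default_bundle.aliquot_ids if s in genus.sample_ids]
        baseline = st.source_baseline(
            genus.subset_samples(aliquots), default_bundle.metadata
        )
        for profile in baseline.values():
            assert profile.sum() == pytest.approx(1.0)

    def test_missing_home_listed(self):
        table = st.AbundanceTable(
            pd.DataFrame({"a1": [1.0]}, index=["A"]), kingdom="bacteria", mode="relative"
        )
        md = self._metadata({"a1": "H1"})
        with pytest.raises(ValueError, match="H9"):
            st.source_baseline(table, md, homes=["H1", "H9"])


class TestBetaToBaseline:
    def test_dust_equal_to_baseline_and_disjoint_dust(self):
        dust = st.AbundanceTable(
            pd.DataFrame({"d1": [0.5, 0.5, 0.0], "d2": [0.0, 0.0, 1.0]},
                         index=["A", "B", "C"]),
            kingdom="bacteria", mode="relative",
        )
        rows = [
            {"sample_id": s, "home": "H1", "sample_type": "floor_dust",
             "location": "floor", "height": "none", "week": 0,
             "is_control_home": False, "kingdom": "bacteria"}
            for s in ("d1", "d2")
        ]
        md = st.SampleMetadata(pd.DataFrame(rows))
        baseline = {"H1": pd.Series({"A": 0.5, "B": 0.5})}
        out = st.beta_to_baseline(dust, md, baseline)
        assert out["d1"] == pytest.approx(0.0)
        assert out["d2"] == pytest.approx(1.0)

    def test_post_seeding_dust_is_closer_to_soil_than_baseline_dust(
        self, default_bundle, default_result
    ):
        genus = default_result.genus_table
        aliquots = [s for s in default_bundle.aliquot_ids if s in genus.sample_ids]
        baseline = st.source_baseline(
            genus.subset_samples(aliquots), default_bundle.metadata
        )
        meta = default_bundle.metadata.frame.set_index("sample_id")
        dust = [
            s for s in default_result.dust_ids
            if not meta.loc[s, "is_control_home"] and meta.loc[s, "home"] in baseline
        ]
        series = st.beta_to_baseline(
            genus.subset_samples(dust), default_bundle.metadata, baseline
        )
        weeks = meta.loc[series.index, "week"]
        assert series[weeks > 0].mean() < series[weeks <= 0].mean()


class TestAlphaDiversity:
    def test_chao1_no_singletons_is_observed_richness(self):
        assert st.chao1([5, 3, 0, 4]) == 3

    def test_chao1_formula_by_hand(self):
        assert st.chao1([5, 3, 1, 1, 2]) == pytest.approx(7.0)

    def test_chao1_no_doubleton_fallback(self):
        assert st.chao1([1, 1]) == pytest.approx(3.0)

    def test_chao1_rejects_fractions(self):
        with pytest.raises(ValueError, match="integer"):
            st.chao1([1.5, 2.0])

    def test_chao1_never_below_observed_richness(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            counts = rng.integers(0, 10, size=20)
            if counts.sum() == 0:
                continue
            assert st.chao1(counts) >= (counts > 0).sum()

    def test_shannon_single_taxon_zero(self):
        assert st.shannon([7, 0, 0]) == pytest.approx(0.0)

    def test_shannon_uniform_is_log_richness(self):
        assert st.shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))
        assert st.shannon([5, 5, 5, 5]) == pytest.approx(1.3863, abs=1e-4)

    def test_shannon_bounded_by_log_observed_richness(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            counts = rng.integers(0, 50, size=12)
            if counts.sum() == 0:
                continue
            assert st.shannon(counts) <= np.log((counts > 0).sum()) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            st.shannon([0, 0])


class TestPcoa:
    def _euclidean_dm(self, points):
        points = np.asarray(points, dtype=float)
        diff = points[:, None, :] - points[None, :, :]
        mat = np.sqrt((diff ** 2).sum(axis=2))
        return DistanceMatrix(mat, ids=[f"p{i}" for i in range(len(points))])

    def test_exact_euclidean_configuration_recovered(self):
        points = [[0, 0], [3, 0], [0, 4], [3, 4], [1, 2]]
        dm = self._euclidean_dm(points)
        res = st.pcoa(dm, k=2)
        coords = res.coordinates.to_numpy()
        diff = coords[:, None, :] - coords[None, :, :]
        recovered = np.sqrt((diff ** 2).sum(axis=2))
        np.testing.assert_allclose(recovered, dm.data, atol=1e-9)

    def test_eigenvalues_descending(self):
        rng = np.random.default_rng(2)
        dm = self._euclidean_dm(rng.normal(size=(8, 3)))
        res = st.pcoa(dm, k=3)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_collinear_points_have_one_meaningful_axis(self):
        dm = self._euclidean_dm([[0, 0], [1, 1], [2, 2]])
        with pytest.warns(UserWarning, match="truncating"):
            res = st.pcoa(dm, k=2)
        positive = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(positive) == 1

    def test_matches_reference_implementation(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(21)
        dm = self._euclidean_dm(rng.normal(size=(10, 4)))
        ours = st.pcoa(dm, k=2).coordinates.to_numpy()
        theirs = skbio_pcoa(dm, number_of_dimensions=2).samples.to_numpy()
        # axes agree up to sign
        for j in range(2):
            assert min(
                np.abs(ours[:, j] - theirs[:, j]).max(),
                np.abs(ours[:, j] + theirs[:, j]).max(),
            ) < 1e-8


class TestPermanova:
    def _dm_from_1d(self, xs):
        xs = np.asarray(xs, dtype=float)
        mat = np.abs(xs[:, None] - xs[None, :])
        return DistanceMatrix(mat, ids=[f"s{i}" for i in range(len(xs))])

    def test_exhaustive_enumeration_on_four_point_configuration(self):
        dm = self._dm_from_1d([0, 0, 10, 10])
        res = st.permanova(dm, ["A", "A", "B", "B"], n_perm=999, seed=0)
        assert res.exhaustive
        assert res.p == pytest.approx(1 / 3)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        dm = self._dm_from_1d(rng.normal(size=14))
        groups = ["A"] * 7 + ["B"] * 7
        r1 = st.permanova(dm, groups, n_perm=199, seed=5)
        r2 = st.permanova(dm, groups, n_perm=199, seed=5)
        assert r1.p == r2.p
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)

    def test_statistic_matches_reference_implementation(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.5
        diff = pts[:, None, :] - pts[None, :, :]
        dm = DistanceMatrix(np.sqrt((diff ** 2).sum(axis=2)),
                            ids=[f"s{i}" for i in range(12)])
        groups = ["A"] * 6 + ["B"] * 6
        ours = st.permanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_single_group_rejected(self):
        dm = self._dm_from_1d([0, 1, 2])
        with pytest.raises(ValueError, match="2 groups"):
            st.permanova(dm, ["A", "A", "A"], n_perm=99, seed=0)

    def test_p_never_below_reciprocal_permutations(self):
        dm = self._dm_from_1d([0, 1, 10, 11, 20, 21, 30, 31, 5, 6, 15, 16])
        groups = list("ABABABABABAB")
        res = st.permanova(dm, groups, n_perm=49, seed=1)
        assert res.p >= 1 / (res.n_permutations + 1)


class TestPermanovaMarginal:
    def _dm(self, pts):
        pts = np.asarray(pts, dtype=float)
        diff = pts[:, None, :] - pts[None, :, :]
        return DistanceMatrix(np.sqrt((diff ** 2).sum(axis=2)),
                              ids=[f"s{i}" for i in range(len(pts))])

    def test_single_term_reduces_to_one_way_permanova(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.0
        dm = self._dm(pts)
        groups = ["A"] * 6 + ["B"] * 6
        one_way = st.permanova(dm, groups, n_perm=99, seed=9)
        covs = pd.DataFrame({"group": groups}, index=list(dm.ids))
        marginal = st.permanova_marginal(dm, covs, n_perm=99, seed=9)
        assert len(marginal) == 1
        assert marginal[0].pseudo_f == pytest.approx(one_way.pseudo_f, rel=1e-9)
        assert marginal[0].r2 == pytest.approx(one_way.r2, rel=1e-9)

    def test_duplicated_covariate_raises_rank_error(self):
        rng = np.random.default_rng(3)
        dm = self._dm(rng.normal(size=(10, 2)))
        groups = ["A", "B"] * 5
        covs = pd.DataFrame({"g1": groups, "g2": groups}, index=list(dm.ids))
        with pytest.raises(ValueError, match="rank deficient"):
            st.permanova_marginal(dm, covs, n_perm=9, seed=0)

    def test_irrelevant_term_has_unremarkable_p(self):
        # a covariate independent of the distances should not show signal
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(30):
            pts = rng.normal(size=(16, 3))
            dm = self._dm(pts)
            covs = pd.DataFrame(
                {"noise": rng.permutation(["A", "B"] * 8)}, index=list(dm.ids)
            )
            res = st.permanova_marginal(dm, covs, n_perm=99, seed=rep)
            ps.append(res[0].p)
        assert 0.3 < np.mean(ps) < 0.7
        assert np.mean(np.array(ps) <= 0.05) <= 0.2
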