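"""Distance-based community statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from necromass.ecology import (
    CountTable,
    aggregate_taxa,
    beta_dispersion,
    bray_curtis,
    dbrda_single,
    pairwise_permanova,
    pcoa,
    permanova,
    rarefy,
    variance_partition,
)
from conftest import euclidean_distance_frame


def toy_counts(arr, otus=None, samples=None):
    arr = np.asarray(arr)
    otus = otus or [f"o{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=otus, columns=samples)


class TestRarefy:
    def test_sample_at_depth_kept_verbatim(self):
        t = toy_counts([[5, 100], [5, 100]])
        out = rarefy(t, 10, seed=0)
        assert (out.counts["s0"] == [5, 5]).all()
        assert out.counts["s1"].sum() == 10

    def test_shallow_sample_dropped_with_warning(self, caplog):
        t = toy_counts([[5, 100], [4, 100]])
        with caplog.at_level("WARNING"):
            out = rarefy(t, 10, seed=0)
        assert "s0" not in out.counts.columns
        assert "s0" in caplog.text

    def test_all_samples_shallow_is_error(self):
        with pytest.raises(ValueError, match="fewer than"):
            rarefy(toy_counts([[1], [1]]), 10, seed=0)

    def test_counts_never_exceed_original_and_sum_to_depth(self):
        rng = np.random.default_rng(0)
        t = toy_counts(rng.integers(0, 50, size=(30, 5)))
        out = rarefy(t, 100, seed=1)
        assert (out.counts.sum(axis=0) == 100).all()
        assert (out.counts.to_numpy() <= t.loc[:, out.counts.columns].to_numpy()).all()

    def test_hypergeometric_expectation(self):
        """Two-OTU sample (90, 10) rarefied to 10: mean OTU-1 count ~ 9."""
        t = toy_counts([[90], [10]])
        draws = [rarefy(t, 10, seed=s).counts.iloc[0, 0] for s in range(2000)]
        # per-draw variance 10*0.9*0.1*(90/99) => se of the mean ~ 0.02
        assert np.mean(draws) == pytest.approx(9.0, abs=0.08)


class TestAggregateTaxa:
    def taxonomy(self):
        return pd.DataFrame(
            {"phylum": ["P1", "P1", "P2"]}, index=["o0", "o1", "o2"]
        )

    def test_single_phylum_is_total(self):
        t = toy_counts([[10, 20], [30, 20]], otus=["o0", "o1"])
        out = aggregate_taxa(t, self.taxonomy(), "phylum")
        assert out.loc["P1"].tolist() == [100.0, 100.0]

    def test_equal_split(self):
        t = toy_counts([[10, 30], [0, 0], [10, 30]])
        out = aggregate_taxa(t, self.taxonomy(), "phylum")
        assert out.loc["P1"].tolist() == [50.0, 50.0]
        assert out.loc["P2"].tolist() == [50.0, 50.0]

    def test_taxon_exactly_at_threshold_kept(self):
        t = toy_counts([[99, 99], [0, 0], [1, 1]])
        out = aggregate_taxa(t, self.taxonomy(), "phylum", other_threshold=1.0)
        assert "P2" in out.index and "others" not in out.index
        below = toy_counts([[995, 995], [0, 0], [5, 5]])
        out2 = aggregate_taxa(below, self.taxonomy(), "phylum", other_threshold=1.0)
        assert "others" in out2.index and "P2" not in out2.index

    def test_columns_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        t = toy_counts(rng.integers(0, 100, (3, 4)))
        out = aggregate_taxa(t, self.taxonomy(), "phylum")
        np.testing.assert_allclose(out.sum(axis=0), 100.0)


class TestBrayCurtis:
    def test_hand_computed_example(self):
        """d((1,2,3),(3,2,1)) = 1 - 2*min_sum/total = 1 - 8/12 = 1/3."""
        t = toy_counts(np.array([[1, 3], [2, 2], [3, 1]]))
        d = bray_curtis(t)
        assert d.loc["s0", "s1"] == pytest.approx(1.0 / 3.0)

    def test_identical_and_disjoint(self):
        t = toy_counts(np.array([[4, 4, 0], [1, 1, 0], [0, 0, 9]]))
        d = bray_curtis(t)
        assert d.loc["s0", "s1"] == 0.0
        assert d.loc["s0", "s2"] == 1.0

    def test_invariant_to_zero_otu_rows(self):
        rng = np.random.default_rng(2)
        t = toy_counts(rng.integers(0, 20, (5, 4)) + 1)
        padded = pd.concat([t, toy_counts(np.zeros((2, 4), int), otus=["z1", "z2"])])
        pd.testing.assert_frame_equal(bray_curtis(t), bray_curtis(padded))

    def test_symmetric_bounded(self):
        rng = np.random.default_rng(3)
        t = toy_counts(rng.integers(0, 30, (8, 6)) + 1)
        d = bray_curtis(t).to_numpy()
        assert np.allclose(d, d.T)
        assert ((d >= 0) & (d <= 1)).all()

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(toy_counts([[1, 0], [2, 0]]))


class TestPcoa:
    def test_three_equidistant_points(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])
        side = np.linalg.norm(res.coordinates.iloc[0] - res.coordinates.iloc[1])
        assert side == pytest.approx(1.0)

    def test_collinear_points_recovered_on_first_axis(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = euclidean_distance_frame(x[:, None])
        res = pcoa(d)
        axis1 = res.coordinates["PC1"].to_numpy()
        centered = x - x.mean()
        assert np.allclose(axis1, centered) or np.allclose(axis1, -centered)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_distances_reconstructed_for_euclidean_input(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((7, 3))
        d = euclidean_distance_frame(pts)
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        rebuilt = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(rebuilt, d.to_numpy(), atol=1e-8)

    def test_matches_skbio(self):
        import skbio

        rng = np.random.default_rng(5)
        pts = rng.standard_normal((10, 4))
        d = euclidean_distance_frame(pts)
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        np.testing.assert_allclose(
            ours.eigenvalues[:6], ref.eigvals.to_numpy()[:6], atol=1e-8
        )

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((6, 2))
        d = euclidean_distance_frame(pts)
        c1 = pcoa(d).coordinates
        c2 = pcoa(d).coordinates
        pd.testing.assert_frame_equal(c1, c2)
        for col in c1:
            assert c1[col].abs().max() == c1[col].max()  # dominant loading positive


def brute_force_permanova_p(d: np.ndarray, labels: list) -> tuple[float, float]:
    """Exhaustive one-way PERMANOVA oracle from the within-group sums of
    squared distances definition; returns (F_obs, exact p)."""
    labels = np.asarray(labels)
    n = len(labels)
    levels = np.unique(labels)

    def f_stat(lab):
        sst = (d**2).sum() / (2 * n)
        ssw = 0.0
        for lvl in levels:
            idx = np.where(lab == lvl)[0]
            ssw += (d[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
        ssa = sst - ssw
        return (ssa / (len(levels) - 1)) / (ssw / (n - len(levels)))

    f_obs = f_stat(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        count += f_stat(labels[list(perm)]) >= f_obs - 1e-12
        total += 1
    return f_obs, count / total


class TestPermanova:
    def _random_case(self, seed, n=8):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, 3))
        pts[: n // 2] += 1.0
        d = euclidean_distance_frame(pts)
        meta = pd.DataFrame({"g": ["a"] * (n // 2) + ["b"] * (n - n // 2)}, index=d.index)
        return d, meta

    def test_r2_components_sum_to_one(self, default_dataset):
        from necromass.ecology import bray_curtis, rarefy

        rare = rarefy(default_dataset.fungi, 25000, seed=0)
        d = bray_curtis(rare)
        res = permanova(d, default_dataset.metadata, ["depth", "season", "regime"],
                        n_perm=49, seed=0)
        terms = res.table.drop(index="Total")
        assert terms["R2"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_perfect_separation(self):
        d = np.ones((6, 6)) - np.eye(6)
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        dd = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        meta = pd.DataFrame({"g": ["x"] * 3 + ["y"] * 3}, index=dd.index)
        res = permanova(dd, meta, ["g"], n_perm=99, seed=0)
        assert res.table.loc["g", "R2"] == pytest.approx(1.0)
        assert res.table.loc["Residual", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_matches_brute_force_oracle(self):
        d, meta = self._random_case(seed=7, n=6)
        res = permanova(d, meta, ["g"], exhaustive=True)
        f_oracle, p_oracle = brute_force_permanova_p(d.to_numpy(), meta["g"].tolist())
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(f_oracle, rel=1e-10)
        assert res.table.loc["g", "p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_skbio_pseudo_f(self):
        import skbio

        d, meta = self._random_case(seed=8, n=12)
        res = permanova(d, meta, ["g"], n_perm=9, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            meta, column="g", permutations=9,
        )
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_single_level_factor_rejected(self):
        d, meta = self._random_case(seed=9)
        meta["g"] = "same"
        with pytest.raises(ValueError, match="single level"):
            permanova(d, meta, ["g"], n_perm=9, seed=0)


class TestPairwisePermanova:
    def _groups(self, centers, n_per=4, seed=0):
        rng = np.random.default_rng(seed)
        pts, labels = [], []
        for i, c in enumerate(centers):
            pts.append(rng.standard_normal((n_per, 2)) * 0.05 + c)
            labels += [f"g{i}"] * n_per
        d = euclidean_distance_frame(np.vstack(pts))
        meta = pd.DataFrame({"grp": labels}, index=d.index)
        return d, meta

    def test_identical_groups_share_letter(self):
        d, meta = self._groups([(0, 0)] * 4)
        out = pairwise_permanova(d, meta, "grp", n_perm=99, seed=0)
        assert len(set(out.attrs["letters"].values())) == 1

    def test_displaced_group_distinct(self):
        d, meta = self._groups([(0, 0), (0, 0), (0, 0), (50, 50)])
        out = pairwise_permanova(d, meta, "grp", n_perm=199, seed=0)
        letters = out.attrs["letters"]
        assert letters["g3"] not in {letters["g0"], letters["g1"], letters["g2"]}

    def test_bh_adjustment_not_below_raw(self):
        d, meta = self._groups([(0, 0), (1, 1), (0, 1), (1, 0)], seed=3)
        out = pairwise_permanova(d, meta, "grp", n_perm=99, seed=1)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestBetaDispersion:
    def test_translated_copies_have_equal_dispersion(self):
        rng = np.random.default_rng(10)
        cloud = rng.standard_normal((8, 2))
        pts = np.vstack([cloud, cloud + 10.0])
        d = euclidean_distance_frame(pts)
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=d.index)
        res = beta_dispersion(d, groups, n_perm=199, seed=0)
        assert res.f == pytest.approx(0.0, abs=1e-10)
        assert res.p > 0.9

    def test_identical_samples_have_zero_distances(self):
        pts = np.zeros((6, 2))
        d = euclidean_distance_frame(pts)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=d.index)
        res = beta_dispersion(d, groups, n_perm=49, seed=0)
        assert np.allclose(res.distances, 0.0)

    def test_power_against_tenfold_spread(self):
        """Groups with 10x spread ratio are flagged in >= 95% of simulations."""
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            pts = np.vstack([
                rng.standard_normal((10, 2)) * 0.1,
                rng.standard_normal((10, 2)) * 1.0,
            ])
            d = euclidean_distance_frame(pts)
            groups = pd.Series(["tight"] * 10 + ["wide"] * 10, index=d.index)
            res = beta_dispersion(d, groups, n_perm=199, seed=s)
            hits += res.p <= 0.05
        assert hits / n_sim >= 0.95

    def test_singleton_group_rejected(self):
        d = euclidean_distance_frame(np.random.default_rng(0).standard_normal((4, 2)))
        groups = pd.Series(["a", "a", "a", "b"], index=d.index)
        with pytest.raises(ValueError, match="single sample"):
            beta_dispersion(d, groups, n_perm=9, seed=0)


class TestVariancePartition:
    def test_fractions_sum_to_one(self, default_dataset):
        from necromass.ecology import bray_curtis, rarefy

        rare = rarefy(default_dataset.fungi, 25000, seed=1)
        d = bray_curtis(rare)
        vp = variance_partition(
            d, default_dataset.metadata,
            {"inorganic": ["inorganic"], "organic": ["organic"],
             "rotation": ["season"], "depth": ["depth"]},
        )
        total = sum(vp.unique.values()) + vp.shared + vp.residual
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_constructed_orthogonal_partition(self):
        """A Euclidean response built from two orthogonal groups explaining
        30% and 20% of variance partitions accordingly (tol 0.03)."""
        rng = np.random.default_rng(11)
        n = 200
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x2 -= x2 @ x1 / (x1 @ x1) * x1  # exact orthogonality
        e = rng.standard_normal(n)
        for v in (x1, x2):
            pass
        x1 = (x1 - x1.mean()) / x1.std()
        x2 = (x2 - x2.mean()) / x2.std()
        e = e - e.mean()
        e -= e @ x1 / (x1 @ x1) * x1
        e -= e @ x2 / (x2 @ x2) * x2
        e /= e.std()
        y = np.sqrt(0.30) * x1 + np.sqrt(0.20) * x2 + np.sqrt(0.50) * e
        d = euclidean_distance_frame(y[:, None])
        meta = pd.DataFrame({"v1": x1, "v2": x2}, index=d.index)
        vp = variance_partition(d, meta, {"g1": ["v1"], "g2": ["v2"]})
        assert vp.unique["g1"] == pytest.approx(0.30, abs=0.03)
        assert vp.unique["g2"] == pytest.approx(0.20, abs=0.03)

    def test_uninformative_group_has_near_zero_unique_fraction(self):
        rng = np.random.default_rng(12)
        n = 100
        x1 = rng.standard_normal(n)
        junk = rng.standard_normal(n)
        d = euclidean_distance_frame(x1[:, None])
        meta = pd.DataFrame({"v1": x1, "junk": junk}, index=d.index)
        vp = variance_partition(d, meta, {"signal": ["v1"], "noise": ["junk"]})
        assert abs(vp.unique["noise"]) < 0.02

    def test_zero_variance_group_rejected(self):
        d = euclidean_distance_frame(np.arange(5, dtype=float)[:, None])
        meta = pd.DataFrame({"v": np.arange(5.0), "c": 1.0}, index=d.index)
        with pytest.raises(ValueError, match="zero variance"):
            variance_partition(d, meta, {"a": ["v"], "b": ["c"]})


class TestDbRda:
    def test_first_axis_recovers_its_proportion_explained(self):
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((20, 4))
        d = euclidean_distance_frame(pts)
        res = pcoa(d)
        v = res.coordinates["PC1"]
        out = dbrda_single(d, v, n_perm=9, seed=0)
        assert out.r2 == pytest.approx(res.proportion_explained[0], abs=1e-8)

    def test_null_mean_r2_is_one_over_n_minus_one(self):
        """An unrelated regressor explains 1/(N-1) of a centered distance
        matrix on average."""
        rng = np.random.default_rng(14)
        n = 20
        d = euclidean_distance_frame(rng.standard_normal((n, 3)))
        r2s = []
        for s in range(500):
            v = pd.Series(np.random.default_rng(s).standard_normal(n), index=d.index)
            r2s.append(dbrda_single(d, v, n_perm=1, seed=0).r2)
        assert np.mean(r2s) == pytest.approx(1.0 / (n - 1), abs=0.01)

    def test_constant_variable_rejected(self):
        d = euclidean_distance_frame(np.arange(5, dtype=float)[:, None])
        with pytest.raises(ValueError, match="constant"):
            dbrda_single(d, pd.Series(np.ones(5), index=d.index), n_perm=9, seed=0)


class TestCountTable:
    def test_duplicate_ids_rejected(self):
        bad = pd.DataFrame([[1, 2], [3, 4]], index=["o1", "o1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="duplicate"):
            CountTable(bad)

    def test_negative_counts_located(self):
        bad = pd.DataFrame([[1, 2], [3, -4]], index=["o1", "o2"], columns=["a", "b"])
        with pytest.raises(ValueError, match="o2"):
            CountTable(bad)
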