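"""Community-analysis operations against brute-force and library oracles.

The package implements Hellinger distance, UPGMA, cophenetic
correlation, silhouette widths, NMDS, PERMANOVA and IndVal from their
definitions; scipy/scikit-learn/scikit-bio serve here only as
independent cross-checks.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist, squareform

from forestplots.community import (
    DistanceMatrix,
    bray_curtis_distance,
    choose_k,
    cophenetic_correlation,
    cophenetic_distances,
    hellinger_distance,
    hellinger_transform,
    indval,
    mantel_cluster_statistic,
    nmds,
    permanova,
    select_clustering,
    silhouette_widths,
    upgma,
)


def _random_dist(rng, n):
    pts = rng.random((n, 3))
    return DistanceMatrix(tuple(f"u{i}" for i in range(n)), squareform(pdist(pts)))


def _df(rows, prefix="u"):
    rows = np.asarray(rows, float)
    return pd.DataFrame(
        rows,
        index=[f"{prefix}{i}" for i in range(rows.shape[0])],
        columns=[f"t{j}" for j in range(rows.shape[1])],
    )


class TestHellinger:
    def test_transform_examples(self):
        t = hellinger_transform(_df([[1, 0, 0], [1, 1, 0]]))
        assert t.iloc[0].tolist() == pytest.approx([1, 0, 0])
        assert t.iloc[1].tolist() == pytest.approx([np.sqrt(0.5), np.sqrt(0.5), 0])

    def test_transform_row_norm(self):
        rng = np.random.default_rng(1)
        t = hellinger_transform(_df(rng.uniform(0, 10, (6, 8)) + 0.01))
        assert np.allclose((t.to_numpy() ** 2).sum(axis=1), 1.0)

    def test_all_zero_row_raises(self):
        with pytest.raises(ValueError, match="u1"):
            hellinger_transform(_df([[1, 2], [0, 0]]))

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0], [1, 0], 0.0),
            ([1, 0], [0, 1], np.sqrt(2)),
            ([1, 1], [1, 0], 0.765367),
        ],
    )
    def test_distance_examples(self, a, b, expected):
        d = hellinger_distance(_df([a, b]))
        assert d.matrix[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_matches_definitional_formula(self):
        """d(x,y) = sqrt(sum_j (sqrt(x_j/x.) - sqrt(y_j/y.))^2)."""
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 20, (5, 7)) + 0.01
        d = hellinger_distance(_df(x)).matrix
        for i, j in itertools.combinations(range(5), 2):
            direct = np.sqrt(
                ((np.sqrt(x[i] / x[i].sum()) - np.sqrt(x[j] / x[j].sum())) ** 2).sum()
            )
            assert d[i, j] == pytest.approx(direct, rel=1e-12)

    def test_metric_axioms_on_sampled_triples(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, (12, 9)) + 0.01
        d = hellinger_distance(_df(x)).matrix
        assert d.max() <= np.sqrt(2) + 1e-12
        for i, j, k in itertools.combinations(range(12), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


def _brute_force_upgma(d0):
    """Exhaustive average-linkage: recompute every cluster pair's mean
    leaf-to-leaf distance at each step from the original matrix."""
    n = d0.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dab = np.mean([d0[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or (dab, a, b) < best:
                best = (dab, a, b)
        dab, a, b = best
        merges.append((a, b, dab, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)


class TestUpgma:
    def test_three_equidistant_points(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(("a", "b", "c"), d))
        assert np.allclose(tree.merges[:, 2], 2.0)

    def test_tight_pairs_merge_first(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        d = squareform(pdist(pts))
        tree = upgma(DistanceMatrix(("a", "b", "c", "d"), d))
        first_two = {frozenset(tree.merges[0, :2].astype(int)),
                     frozenset(tree.merges[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        dist = _random_dist(rng, n)
        mine = upgma(dist).merges
        brute = _brute_force_upgma(dist.matrix)
        assert np.allclose(mine[:, 2], brute[:, 2], atol=1e-12)
        for row_m, row_b in zip(mine, brute):
            assert set(row_m[:2]) == set(row_b[:2])

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(9)
        dist = _random_dist(rng, 8)
        mine = upgma(dist).to_linkage()
        ref = scipy_average(dist.condensed())
        assert np.allclose(mine[:, 2], ref[:, 2], atol=1e-10)

    def test_heights_monotone(self):
        rng = np.random.default_rng(10)
        tree = upgma(_random_dist(rng, 10))
        assert (np.diff(tree.merges[:, 2]) >= -1e-12).all()

    def test_single_unit_raises(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(("a",), np.zeros((1, 1))))

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(11)
        dist = _random_dist(rng, 5)
        nwk = upgma(dist).to_newick()
        assert nwk.endswith(";") and all(u in nwk for u in dist.units)


class TestCophenetic:
    def test_ultrametric_input_gives_r_one(self):
        # distances generated from a tree are reproduced exactly
        d = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        dist = DistanceMatrix(("a", "b", "c", "d"), d)
        tree = upgma(dist)
        assert cophenetic_correlation(tree, dist) == pytest.approx(1.0)

    def test_equidistant_points_flagged_undefined(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        dist = DistanceMatrix(("a", "b", "c"), d)
        assert np.isnan(cophenetic_correlation(upgma(dist), dist))

    def test_matches_lca_brute_force_and_scipy(self):
        rng = np.random.default_rng(6)
        dist = _random_dist(rng, 6)
        tree = upgma(dist)
        coph = cophenetic_distances(tree)
        # scipy oracle on identical linkage
        ref = squareform(cophenet(scipy_average(dist.condensed())))
        assert np.allclose(coph, ref, atol=1e-10)
        r = cophenetic_correlation(tree, dist)
        ref_r = np.corrcoef(dist.condensed(), squareform(ref, checks=False))[0, 1]
        assert r == pytest.approx(ref_r, abs=1e-12)

    def test_cophenetic_is_ultrametric(self):
        rng = np.random.default_rng(7)
        coph = cophenetic_distances(upgma(_random_dist(rng, 7)))
        n = coph.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-12


class TestSelectClustering:
    def test_single_candidate(self):
        rng = np.random.default_rng(8)
        cover = _df(rng.uniform(0, 10, (6, 5)) + 0.1)
        best, table = select_clustering(cover, ["hellinger"], ["upgma"])
        assert best == ("hellinger", "upgma") and len(table) == 1

    def test_full_score_table(self):
        rng = np.random.default_rng(8)
        cover = _df(rng.uniform(0, 10, (8, 5)) + 0.1)
        best, table = select_clustering(cover)
        assert len(table) == 3
        assert table.loc[
            (table["distance"] == best[0]) & (table["linkage"] == best[1]),
            "cophenetic_r",
        ].iloc[0] == table["cophenetic_r"].max()


class TestSilhouette:
    def test_two_tight_far_clusters(self):
        pts = np.vstack([np.random.default_rng(1).normal(0, 0.01, (5, 2)),
                         np.random.default_rng(2).normal(10, 0.01, (5, 2))])
        dist = DistanceMatrix(tuple(f"u{i}" for i in range(10)),
                              squareform(pdist(pts)))
        widths, mean = silhouette_widths(dist, [0] * 5 + [1] * 5)
        assert mean > 0.9

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(4)
        dist = _random_dist(rng, 12)
        labels = rng.integers(0, 3, size=12)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, size=12)
        widths, _ = silhouette_widths(dist, labels)
        ref = silhouette_samples(dist.matrix, labels, metric="precomputed")
        assert np.allclose(widths, ref, atol=1e-10)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(5)
        means = []
        for _ in range(20):
            dist = _random_dist(rng, 14)
            labels = rng.integers(0, 2, size=14)
            if len(np.unique(labels)) < 2:
                continue
            means.append(silhouette_widths(dist, labels)[1])
        assert abs(np.mean(means)) < 0.15

    def test_single_cluster_raises(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            silhouette_widths(_random_dist(rng, 4), [0, 0, 0, 0])


class TestMantel:
    def test_perfect_block_structure(self):
        d = np.full((4, 4), 1.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0)
        dist = DistanceMatrix(("a", "b", "c", "d"), d)
        assert mantel_cluster_statistic(dist, [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_anti_structure_negative(self):
        d = np.full((4, 4), 0.1)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 1.0
        np.fill_diagonal(d, 0)
        dist = DistanceMatrix(("a", "b", "c", "d"), d)
        assert mantel_cluster_statistic(dist, [0, 0, 1, 1]) < 0

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(12)
        rs = []
        for _ in range(30):
            dist = _random_dist(rng, 12)
            labels = rng.integers(0, 2, size=12)
            if len(np.unique(labels)) < 2:
                continue
            rs.append(mantel_cluster_statistic(dist, labels))
        assert abs(np.mean(rs)) < 0.1


class TestChooseK:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_planted_clusters(self, k_true):
        rng = np.random.default_rng(k_true)
        pts = np.vstack([rng.normal(10 * c, 0.3, (6, 2)) for c in range(k_true)])
        dist = DistanceMatrix(tuple(f"u{i}" for i in range(len(pts))),
                              squareform(pdist(pts)))
        k, table = choose_k(upgma(dist), dist, k_max=6)
        assert k == k_true
        assert {"k", "mean_silhouette", "mantel_r"} <= set(table.columns)


class TestNmds:
    def test_line_embeds_in_one_dimension(self):
        pts = np.arange(6, dtype=float)[:, None]
        dist = DistanceMatrix(tuple("abcdef"), squareform(pdist(pts)))
        res = nmds(dist, n_dim=1, n_starts=8, seed=0)
        assert res.stress < 1e-3

    def test_planar_configuration_embeds(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 2))
        dist = DistanceMatrix(tuple(f"u{i}" for i in range(10)),
                              squareform(pdist(pts)))
        res = nmds(dist, n_dim=2, n_starts=8, seed=1)
        assert res.stress < 0.01

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(14)
        dist = _random_dist(rng, 8)
        a = nmds(dist, n_starts=4, seed=3)
        b = nmds(dist, n_starts=4, seed=3)
        assert a.coordinates.equals(b.coordinates) and a.stress == b.stress


def _perm_f_oracle(d, labels):
    """F for a one-factor design computed from the definition: Gower
    centring and explicit group-mean projection."""
    n = d.shape[0]
    a = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ a @ J
    X = pd.get_dummies(pd.Series(labels)).to_numpy(float)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    # H spans the intercept, so subtract the grand-mean projection
    ss_a = np.trace(H @ G) - float(np.ones(n) @ G @ np.ones(n)) / n
    ss_t = np.trace(G)
    df_a = len(set(labels)) - 1
    df_r = n - len(set(labels))
    return (ss_a / df_a) / ((ss_t - ss_a) / df_r)


class TestPermanova:
    def test_constructed_separation(self):
        rows = np.array([[10, 0, 0]] * 5 + [[0, 10, 0]] * 5, float)
        rng = np.random.default_rng(15)
        rows = rows + rng.uniform(0, 0.01, rows.shape)
        dist = hellinger_distance(_df(rows))
        factors = pd.DataFrame({"grp": ["a"] * 5 + ["b"] * 5},
                               index=list(dist.units))
        res = permanova(dist, factors, n_perm=99, seed=0)
        assert res.r2("grp") > 0.95
        assert res.p("grp") == pytest.approx(1.0 / 100.0)

    def test_r2_sums_to_one_and_table_shape(self, tiny_survey):
        ds = tiny_survey
        dist = hellinger_distance(ds.cover.to_plot_level(ds.design))
        fac = ds.plot_design.set_index("plot_id")[["forest_type", "island"]]
        res = permanova(dist, fac, n_perm=49, seed=1)
        r2 = res.table["R2"]
        assert r2[["forest_type", "island", "Residual"]].sum() == pytest.approx(1.0)
        assert (res.table["SS"] >= -1e-12).all()
        assert res.p("forest_type") >= 1.0 / 50.0

    def test_exhaustive_enumeration_n4(self):
        """For n = 4 the permutation p equals its exhaustive version."""
        rows = np.array([[5, 1], [4, 2], [1, 5], [2, 4]], float)
        dist = hellinger_distance(_df(rows))
        labels = ["a", "a", "b", "b"]
        d = dist.matrix
        f_obs = _perm_f_oracle(d, labels)
        fs = []
        for perm in itertools.permutations(range(4)):
            fs.append(_perm_f_oracle(d[np.ix_(perm, perm)], labels))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        factors = pd.DataFrame({"grp": labels}, index=list(dist.units))
        res = permanova(dist, factors, n_perm=4999, seed=2)
        assert res.p("grp") == pytest.approx(p_exact, abs=0.02)

    def test_matches_skbio_single_factor(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(16)
        rows = rng.uniform(0, 5, (12, 6)) + 0.1
        dist = hellinger_distance(_df(rows))
        labels = ["a", "b", "c"] * 4
        res = permanova(dist, pd.DataFrame({"g": labels}, index=list(dist.units)),
                        n_perm=9, seed=0)
        ref = skbio_permanova(SkbioDM(dist.matrix, ids=dist.units),
                              grouping=labels, permutations=9)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-9
        )

    def test_single_level_factor_raises(self):
        rng = np.random.default_rng(17)
        dist = _random_dist(rng, 6)
        fac = pd.DataFrame({"g": ["x"] * 6}, index=list(dist.units))
        with pytest.raises(ValueError, match="single level"):
            permanova(dist, fac, n_perm=9)


class TestIndval:
    def test_perfect_indicator(self):
        rows = np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], float)
        res = indval(_df(rows), ["A"] * 3 + ["B"] * 3, n_perm=99, seed=0)
        assert res.table.loc["t0", "indval_percent"] == pytest.approx(100.0)
        assert res.table.loc["t0", "best_group"] == "A"

    def test_symmetric_taxon_gets_100_over_k(self):
        rows = np.ones((6, 1))
        res = indval(_df(rows), ["A", "A", "B", "B", "C", "C"], n_perm=19, seed=0)
        assert res.table.loc["t0", "indval_percent"] == pytest.approx(100.0 / 3.0)

    def test_hand_computed_table_and_exhaustive_p(self):
        rows = np.array(
            [[4, 0, 1], [2, 0, 1], [6, 0, 0], [0, 3, 1], [1, 5, 0], [0, 4, 1]],
            float,
        )
        groups = np.array(["A"] * 3 + ["B"] * 3)
        res = indval(_df(rows, prefix="p"), groups, n_perm=999, seed=0)
        x = rows
        for t in range(3):
            means = np.array([x[:3, t].mean(), x[3:, t].mean()])
            A = means / means.sum()
            B = np.array([(x[:3, t] > 0).mean(), (x[3:, t] > 0).mean()])
            iv = 100 * A * B
            assert res.table.loc[f"t{t}", "indval_percent"] == pytest.approx(iv.max())
        # exhaustive p for t0 over all C(6,3)=20 label assignments
        stat_obs = res.table.loc["t0", "indval_percent"]
        stats = []
        for combo in itertools.combinations(range(6), 3):
            g = np.array(["B"] * 6)
            g[list(combo)] = "A"
            means = np.array([x[g == "A", 0].mean(), x[g == "B", 0].mean()])
            A = means / means.sum()
            B = np.array([(x[g == "A", 0] > 0).mean(), (x[g == "B", 0] > 0).mean()])
            stats.append((100 * A * B).max())
        p_exact = np.mean([s >= stat_obs - 1e-9 for s in stats])
        assert res.table.loc["t0", "p"] == pytest.approx(p_exact, abs=0.05)

    def test_invariant_to_taxon_rescaling(self):
        rng = np.random.default_rng(18)
        rows = (rng.random((8, 4)) < 0.6) * rng.uniform(1, 9, (8, 4))
        rows[:, 0] += 0.1  # keep every taxon present somewhere
        groups = ["A"] * 4 + ["B"] * 4
        a = indval(_df(rows), groups, n_perm=49, seed=5)
        rows2 = rows.copy()
        rows2[:, 1] *= 37.0
        b = indval(_df(rows2), groups, n_perm=49, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_absent_taxon_excluded_with_warning(self):
        rows = np.array([[1, 0], [2, 0], [3, 0], [4, 0]], float)
        with pytest.warns(UserWarning, match="absent"):
            res = indval(_df(rows), ["A", "A", "B", "B"], n_perm=9, seed=0)
        assert "t1" not in res.table.index
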