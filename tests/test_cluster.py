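"""Fold-change tiers, Ward agglomeration, bootstrap support, tree cuts."""

import itertools

import numpy as np
import pandas as pd
import pytest

import strainexpr as sx


def _means(df: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(df)
    df.index.name = "strain"
    return df


class TestFoldChange:
    def test_reference_row_zero_middle_tier(self):
        rng = np.random.default_rng(0)
        df = _means(pd.DataFrame(rng.normal(size=(5, 4)),
                                 index=list("ABCDE")))
        fc = sx.fold_change(sx.StrainMeans(df), "C")
        assert np.allclose(fc.values.loc["C"], 0.0)
        assert (fc.tiers.loc["C"] == 4).all()

    def test_edge_value_goes_to_lower_tier(self):
        # construct differences whose z-score hits an edge exactly
        df = _means(pd.DataFrame({"g": [0.0, 1.0, 2.0, 3.0]},
                                 index=list("RABC")))
        fc = sx.fold_change(sx.StrainMeans(df), "R")
        z = fc.values["g"] / fc.values["g"].std(ddof=1)
        for strain in "ABC":
            zval = z[strain]
            expected = int(np.digitize(zval, fc.edges, right=True)) + 1
            assert fc.tiers.loc[strain, "g"] == expected
        # explicit boundary check with a hand-made matrix
        tiers = np.digitize([0.5, 0.5 + 1e-9], fc.edges, right=True) + 1
        assert tiers[0] == 4 and tiers[1] == 5

    def test_tiers_match_digitize_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            df = _means(pd.DataFrame(rng.normal(size=(6, 8)),
                                     index=[f"S{i}" for i in range(6)]))
            fc = sx.fold_change(sx.StrainMeans(df), "S0")
            diff = df - df.loc["S0"]
            z = diff / diff.std(ddof=1)
            oracle = np.digitize(z.to_numpy(), np.asarray(fc.edges), right=True) + 1
            assert (fc.tiers.to_numpy() == oracle).all()

    def test_unknown_reference_rejected(self):
        df = _means(pd.DataFrame({"g": [1.0, 2.0]}, index=["A", "B"]))
        with pytest.raises(ValueError, match="reference"):
            sx.fold_change(sx.StrainMeans(df), "Z")


def brute_force_ward(points: dict[str, np.ndarray]):
    """Exhaustive minimal-variance agglomeration, SSE computed from scratch.

    Independent of the production implementation: cluster SSE is recomputed
    from the raw coordinates at every step.
    """
    def sse(members):
        arr = np.vstack([points[m] for m in members])
        return float(((arr - arr.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([name]) for name in points]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=min), 2):
            delta = sse(a | b) - sse(a) - sse(b)
            key = (delta, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (delta, _), a, b = best
        merges.append((a | b, delta))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


class TestWardCluster:
    def test_hand_worked_three_points(self):
        """{0, 1, 10} on one axis: merge (0,1) at 0.5, then all at 60.167."""
        df = _means(pd.DataFrame({"g": [0.0, 1.0, 10.0]}, index=list("ABC")))
        tree = sx.ward_cluster(df)
        heights = tree.merge_heights()
        assert heights[0] == pytest.approx(0.5)
        assert heights[1] == pytest.approx(60.1666667, abs=1e-6)
        # first merge is {A, B}
        first = min(tree.internal_nodes(), key=lambda n: n.height)
        assert first.leaves == frozenset("AB")

    def test_two_well_separated_pairs_merge_first(self):
        df = _means(pd.DataFrame(
            {"g1": [0.0, 0.1, 50.0, 50.1], "g2": [0.0, 0.1, 50.0, 50.1]},
            index=list("ABCD")))
        tree = sx.ward_cluster(df)
        low = sorted(tree.internal_nodes(), key=lambda n: n.height)[:2]
        assert {n.leaves for n in low} == {frozenset("AB"), frozenset("CD")}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        names = [f"S{i}" for i in range(n)]
        pts = {name: rng.normal(size=3) for name in names}
        df = _means(pd.DataFrame({name: pts[name] for name in names}).T)
        tree = sx.ward_cluster(df)
        oracle = brute_force_ward(pts)
        got = sorted(tree.internal_nodes(), key=lambda n: n.height)
        for node, (members, delta) in zip(got, oracle):
            assert node.leaves == members
            assert node.height == pytest.approx(delta)

    def test_matches_scipy_linkage_heights(self):
        """scipy's ward distances, squared and halved, are the SSE increments."""
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(11)
        df = _means(pd.DataFrame(rng.normal(size=(7, 5)),
                                 index=[f"S{i}" for i in range(7)]))
        tree = sx.ward_cluster(df)
        Z = linkage(df.to_numpy(), method="ward")
        assert np.allclose(sorted(tree.merge_heights()),
                           sorted(Z[:, 2] ** 2 / 2.0))

    def test_heights_non_decreasing_and_order_invariant(self):
        rng = np.random.default_rng(12)
        df = _means(pd.DataFrame(rng.normal(size=(8, 6)),
                                 index=[f"S{i}" for i in range(8)]))
        t1 = sx.ward_cluster(df)
        heights = [n.height for n in
                   sorted(t1.internal_nodes(), key=lambda n: n.height)]
        assert all(b >= a for a, b in zip(heights, heights[1:]))
        shuffled = df.sample(frac=1.0, random_state=3)
        t2 = sx.ward_cluster(shuffled)
        assert t1.splits() == t2.splits()
        assert np.allclose(t1.merge_heights(), t2.merge_heights())

    def test_duplicate_strains_rejected(self):
        df = pd.DataFrame({"g": [1.0, 2.0]}, index=["A", "A"])
        with pytest.raises(ValueError, match="duplicate"):
            sx.ward_cluster(df)


class TestBootstrapSupport:
    def test_b1_supports_binary(self):
        rng = np.random.default_rng(13)
        df = _means(pd.DataFrame(rng.normal(size=(5, 6)),
                                 index=[f"S{i}" for i in range(5)]))
        tree = sx.bootstrap_support(df, B=1, seed=0)
        for node in tree.internal_nodes():
            assert node.support in (0.0, 1.0)

    def test_separated_clouds_full_root_support(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(8, 10)) * 0.1
        base[4:] += 30.0
        df = _means(pd.DataFrame(base, index=[f"S{i}" for i in range(8)]))
        tree = sx.bootstrap_support(df, B=100, seed=5)
        split_node = [n for n in tree.internal_nodes()
                      if n.leaves == frozenset(f"S{i}" for i in range(4))
                      or n.leaves == frozenset(f"S{i}" for i in range(4, 8))]
        assert split_node and all(n.support == 1.0 for n in split_node)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(15)
        df = _means(pd.DataFrame(rng.normal(size=(6, 8)),
                                 index=[f"S{i}" for i in range(6)],
                                 columns=[f"g{i}" for i in range(8)]))
        t1 = sx.bootstrap_support(df, B=30, seed=7)
        t2 = sx.bootstrap_support(df[list(reversed(df.columns))], B=30, seed=7)
        s1 = {frozenset(n.leaves): n.support for n in t1.internal_nodes()}
        s2 = {frozenset(n.leaves): n.support for n in t2.internal_nodes()}
        assert s1 == s2

    def test_invalid_b(self):
        df = pd.DataFrame(np.eye(3), index=list("ABC"))
        with pytest.raises(ValueError, match="B"):
            sx.bootstrap_support(df, B=0, seed=0)


class TestClassifyClusters:
    def test_extremes(self):
        rng = np.random.default_rng(16)
        df = _means(pd.DataFrame(rng.normal(size=(5, 4)),
                                 index=[f"S{i}" for i in range(5)]))
        tree = sx.ward_cluster(df)
        assert sx.classify_clusters(tree, 1).nunique() == 1
        assert sx.classify_clusters(tree, 5).nunique() == 5

    def test_two_groups_recovered(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=(8, 10)) * 0.3
        base[4:] += 10.0
        df = _means(pd.DataFrame(base, index=[f"S{i}" for i in range(8)]))
        labels = sx.classify_clusters(sx.ward_cluster(df), 2)
        assert labels[[f"S{i}" for i in range(4)]].nunique() == 1
        assert labels[[f"S{i}" for i in range(4, 8)]].nunique() == 1
        assert labels["S0"] != labels["S7"]


class TestNewick:
    def test_roundtrip_through_dendropy(self):
        """The exported Newick parses and preserves leaves and support."""
        import dendropy

        rng = np.random.default_rng(18)
        df = _means(pd.DataFrame(rng.normal(size=(5, 6)),
                                 index=[f"S{i}" for i in range(5)]))
        tree = sx.bootstrap_support(df, B=20, seed=2)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == set(tree.leaf_names)
        edge_lengths = [e.length for e in parsed.preorder_edge_iter()
                        if e.length is not None]
        assert all(l >= -1e-12 for l in edge_lengths)
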