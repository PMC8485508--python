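import io

import dendropy
import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from gutshift.diversity import (distance_from_baseline, kruskal_wallis_groups,
                                pcoa, shannon, unweighted_unifrac)
from gutshift.simulate import simulate_tree_and_taxonomy, tree_to_newick
from gutshift.tables import CountTable


# ---------------------------------------------------------------------------
# independent brute-force UniFrac oracle (dendropy edge enumeration)
# ---------------------------------------------------------------------------

def unifrac_oracle(newick: str, profiles: dict[str, set[str]],
                   a: str, b: str) -> float:
    """Loop over every edge, test descendant-leaf presence per sample."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    unique = union = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        leaves = {leaf.taxon.label for leaf in edge.head_node.leaf_iter()}
        in_a = bool(leaves & profiles[a])
        in_b = bool(leaves & profiles[b])
        if in_a or in_b:
            union += edge.length
        if in_a != in_b:
            unique += edge.length
    return unique / union if union > 0 else 0.0


def integer_length_tree(n_taxa: int, seed: int) -> str:
    """Random rooted binary tree re-assigned integer branch lengths so the
    implementation and the oracle agree bit-for-bit."""
    tree, _ = simulate_tree_and_taxonomy(n_taxa, seed=seed)
    rng = np.random.default_rng(seed + 1)
    dtree = dendropy.Tree.get(data=tree_to_newick(tree), schema="newick")
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is not dtree.seed_node:
            edge.length = int(rng.integers(1, 11))
    return dtree.as_string(schema="newick", suppress_rooting=True)


def random_presence_table(taxa: list[str], n_samples: int, rng) -> CountTable:
    values = (rng.random((len(taxa), n_samples)) < 0.5).astype(int)
    return CountTable(values, taxa, [f"s{i}" for i in range(n_samples)])


class TestUnweightedUnifrac:
    def test_identical_profiles_are_distance_zero(self):
        tree = TreeNode.read(io.StringIO("((t0:1,t1:1):1,t2:2);"))
        table = CountTable(np.array([[3, 5], [0, 0], [1, 2]]),
                           ["t0", "t1", "t2"], ["a", "b"])
        dm = unweighted_unifrac(table, tree)
        assert dm["a", "b"] == 0.0

    def test_star_tree_closed_form(self):
        """Star tree, unit branches; A={1,2}, B={2,3} -> 2/3."""
        tree = TreeNode.read(io.StringIO("(t1:1,t2:1,t3:1);"))
        table = CountTable(np.array([[1, 0], [1, 1], [0, 1]]),
                           ["t1", "t2", "t3"], ["A", "B"])
        dm = unweighted_unifrac(table, tree)
        assert dm["A", "B"] == pytest.approx(2 / 3, abs=1e-15)

    def test_missing_taxon_is_hard_error(self):
        tree = TreeNode.read(io.StringIO("(t0:1,t1:1);"))
        table = CountTable(np.array([[1], [1]]), ["t0", "tX"], ["a"])
        with pytest.raises(ValueError, match="tX"):
            unweighted_unifrac(table, tree)

    def test_matches_edge_enumeration_oracle_exactly(self):
        """Random trees + random presence profiles: equality with the
        brute-force per-edge oracle, bit for bit (integer branch lengths)."""
        rng = np.random.default_rng(0)
        for rep in range(10):
            n = int(rng.integers(3, 13))
            newick = integer_length_tree(n, seed=100 + rep)
            taxa = [f"t{i}" for i in range(n)]
            table = random_presence_table(taxa, 3, rng)
            dm = unweighted_unifrac(table, TreeNode.read(io.StringIO(newick)))
            profiles = {s: {t for t, v in zip(taxa, table.values[:, j]) if v > 0}
                        for j, s in enumerate(table.sample_ids)}
            for i, a in enumerate(table.sample_ids):
                for b in table.sample_ids[i + 1:]:
                    assert dm[a, b] == unifrac_oracle(newick, profiles, a, b)

    def test_matches_scikit_bio(self):
        """Cross-check against the scikit-bio reference implementation."""
        from skbio.diversity import beta_diversity
        tree, _ = simulate_tree_and_taxonomy(12, seed=3)
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(12)]
        table = random_presence_table(taxa, 4, rng)
        dm = unweighted_unifrac(table, tree)
        ref = beta_diversity("unweighted_unifrac", table.values.T,
                             ids=table.sample_ids, tree=tree, taxa=taxa)
        assert np.allclose(dm.data, ref.data, atol=1e-12)

    def test_is_a_metric_on_random_triples(self):
        rng = np.random.default_rng(11)
        for rep in range(10):
            tree, _ = simulate_tree_and_taxonomy(8, seed=200 + rep)
            table = random_presence_table([f"t{i}" for i in range(8)], 3, rng)
            dm = unweighted_unifrac(table, tree)
            a, b, c = table.sample_ids
            assert dm[a, b] == dm[b, a]
            assert dm[a, a] == 0.0
            assert dm[a, c] <= dm[a, b] + dm[b, c] + 1e-12


class TestShannon:
    def test_closed_forms(self):
        table = CountTable(np.array([[25], [25], [25], [25]]),
                           [f"t{i}" for i in range(4)], ["s"])
        assert shannon(table).iloc[0] == pytest.approx(2.0)
        single = CountTable(np.array([[100]]), ["t0"], ["s"])
        assert shannon(single).iloc[0] == 0.0
        skewed = CountTable(np.array([[50], [25], [25]]), ["a", "b", "c"], ["s"])
        assert shannon(skewed).iloc[0] == pytest.approx(1.5)

    def test_uniform_maximizes_and_point_mass_minimizes(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = int(rng.integers(2, 30))
            counts = rng.integers(1, 1000, size=(d, 1))
            table = CountTable(counts, [f"t{i}" for i in range(d)], ["s"])
            h = shannon(table).iloc[0]
            assert -1e-12 <= h <= np.log2(d) + 1e-12

    def test_empty_sample_rejected(self):
        table = CountTable(np.array([[0], [0]]), ["a", "b"], ["s"])
        with pytest.raises(ValueError, match="empty"):
            shannon(table)


class TestDistanceFromBaseline:
    def _dm(self):
        ids = ["a1_d-4", "a1_d0", "a1_d4"]
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.2], [0.5, 0.2, 0.0]])
        return DistanceMatrix(d, ids)

    def test_baseline_sample_distance_zero(self):
        md = pd.DataFrame({"sample_id": ["a1_d-4", "a1_d0", "a1_d4"],
                           "animal_id": "a1", "group": "ABX",
                           "day": [-4, 0, 4],
                           "phase": ["pretreatment", "treatment", "treatment"]})
        series = distance_from_baseline(self._dm(), md)
        assert series.loc[series["day"] == -4, "distance"].iloc[0] == 0.0
        assert series.loc[series["day"] == 0, "distance"].iloc[0] == 0.3

    def test_fallback_to_nearest_pretreatment_day(self):
        md = pd.DataFrame({"sample_id": ["a1_d-4", "a1_d0", "a1_d4"],
                           "animal_id": "a1", "group": "ABX",
                           "day": [-6, 0, 4],  # no day -4 sample
                           "phase": ["pretreatment", "treatment", "treatment"]})
        md["sample_id"] = ["a1_d-4", "a1_d0", "a1_d4"]
        series = distance_from_baseline(self._dm(), md)
        assert (series["baseline_sample"] == "a1_d-4").all()

    def test_animal_without_pretreatment_excluded_with_warning(self):
        md = pd.DataFrame({"sample_id": ["a1_d-4", "a1_d0", "a1_d4"],
                           "animal_id": ["a2", "a1", "a1"], "group": "ABX",
                           "day": [2, -4, 4],
                           "phase": ["treatment", "pretreatment", "treatment"]})
        with pytest.warns(UserWarning, match="no pretreatment"):
            series = distance_from_baseline(self._dm(), md)
        assert "a2" not in series["animal_id"].tolist()


class TestPcoa:
    def test_equilateral_triangle_reconstructed(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ["a", "b", "c"])
        res = pcoa(dm, k=2)
        coords = res.samples.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0,
                                                                              abs=1e-8)

    def test_euclidean_input_reconstructed(self):
        rng = np.random.default_rng(8)
        pts = rng.random((10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(d, [f"s{i}" for i in range(10)]), k=2)
        coords = res.samples.to_numpy()
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(recon, d, atol=1e-8)

    def test_duplicate_samples_get_identical_coordinates(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float)
        res = pcoa(DistanceMatrix(d, ["a", "a2", "b"]), k=1)
        coords = res.samples.to_numpy()
        assert np.allclose(coords[0], coords[1], atol=1e-10)

    def test_k_beyond_rank_warns(self):
        d = np.array([[0, 1], [1, 0]], float)
        with pytest.warns(UserWarning, match="available"):
            res = pcoa(DistanceMatrix(d, ["a", "b"]), k=5)
        assert res.samples.shape[1] < 5


class TestKruskalWallis:
    def test_full_ties_give_zero(self):
        h, p = kruskal_wallis_groups(pd.Series([2.0] * 6),
                                     pd.Series(["a"] * 3 + ["b"] * 3))
        assert h == 0.0

    def test_hand_computed_rank_statistic(self):
        """Groups (1,2,3) vs (4,5,6): H = 12/(N(N+1)) * sum n_i Rbar_i^2
        - 3(N+1) = 3.857 with no ties."""
        h, p = kruskal_wallis_groups(pd.Series([1, 2, 3, 4, 5, 6.0]),
                                     pd.Series(["a"] * 3 + ["b"] * 3))
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_groups(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))

    def test_permutation_calibration(self):
        """Under label permutation the p-value is approximately uniform."""
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.random(12))
        ps = []
        for _ in range(500):
            groups = pd.Series(rng.permutation(["a"] * 6 + ["b"] * 6))
            ps.append(kruskal_wallis_groups(vals, groups)[1])
        assert abs(np.mean(np.array(ps) <= 0.5) - 0.5) < 0.1
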