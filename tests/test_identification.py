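import numpy as np
import pytest
import skbio

from barcodegap.distances import DistanceMatrix, distance_matrix
from barcodegap.identification import (
    _bipartitions,
    best_match_identify,
    bootstrap_supports,
    identification_rates,
    is_monophyletic,
    nj_tree,
    tree_path_matrix,
    write_newick,
)
from barcodegap.records import RegionAlignment
from conftest import rec


def dm_from(labels, species, dense):
    return DistanceMatrix(labels, dict(zip(labels, species)), np.asarray(dense, float))


def random_additive_matrix(n_taxa, rng):
    """Independent construction of an additive matrix: build a random
    binary tree as a weighted graph and read off shortest paths."""
    import networkx as nx

    g = nx.Graph()
    leaves = [f"t{i}" for i in range(n_taxa)]
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = f"i{nxt}"
        nxt += 1
        g.add_edge(a, parent, weight=float(rng.uniform(0.05, 1.0)))
        g.add_edge(b, parent, weight=float(rng.uniform(0.05, 1.0)))
        nodes.remove(a)
        nodes.remove(b)
        nodes.append(parent)
    g.add_edge(nodes[0], nodes[1], weight=float(rng.uniform(0.05, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    mat = np.array([[dist[a][b] for b in leaves] for a in leaves])
    mat = (mat + mat.T) / 2.0  # remove float summation-order asymmetry
    return leaves, mat


class TestNJTree:
    def test_four_taxon_additive_example(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = dm_from(labels, ["a", "b", "c", "d"], mat)
        tree = nj_tree(dm)
        assert np.allclose(tree_path_matrix(tree, labels), mat, atol=1e-9)
        # AB|CD split present
        assert frozenset(["C", "D"]) in _bipartitions(tree) or frozenset(
            ["A", "B"]
        ) in _bipartitions(tree)

    def test_three_taxa_linear_solve(self):
        labels = ["A", "B", "C"]
        mat = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        dm = dm_from(labels, list("abc"), mat)
        tree = nj_tree(dm)
        assert np.allclose(tree_path_matrix(tree, labels), mat, atol=1e-12)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.2)
        assert lengths["B"] == pytest.approx(0.1)
        assert lengths["C"] == pytest.approx(0.3)

    def test_additive_recovery_50_random_trees(self):
        rng = np.random.default_rng(99)
        for trial in range(50):
            n = int(rng.integers(4, 13))
            labels, mat = random_additive_matrix(n, rng)
            dm = dm_from(labels, labels, mat)
            tree = nj_tree(dm)
            assert np.allclose(tree_path_matrix(tree, labels), mat, atol=1e-9), (
                f"trial {trial}, n={n}"
            )

    def test_agrees_with_skbio_nj_topology(self):
        rng = np.random.default_rng(5)
        labels, mat = random_additive_matrix(8, rng)
        dm = dm_from(labels, labels, mat)
        ours = _bipartitions(nj_tree(dm))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=labels))
        theirs = _bipartitions(sk_tree)
        assert ours == theirs

    def test_equidistant_tie_deterministic(self):
        labels = ["d", "c", "b", "a"]
        mat = np.full((4, 4), 0.5)
        np.fill_diagonal(mat, 0.0)
        dm = dm_from(labels, labels, mat)
        t1 = write_newick(nj_tree(dm))
        t2 = write_newick(nj_tree(dm))
        assert t1 == t2
        # lexicographically lowest pair joined first
        tree = nj_tree(dm)
        first_cherry = min(
            (
                sorted(t.name for t in node.tips())
                for node in tree.non_tips()
                if len(list(t for t in node.tips())) == 2
            ),
            default=None,
        )
        assert first_cherry == ["a", "b"]

    def test_undefined_entries_rejected(self):
        mat = np.array([[0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]])
        dm = dm_from(list("abc"), list("abc"), mat)
        with pytest.raises(ValueError):
            nj_tree(dm)


class TestBootstrap:
    def make_split_alignment(self, n_support=30, n_conflict=0, n_const=150):
        """Columns supporting split {a1,a2}|{b1,b2} plus conflicting ones,
        over a constant background that keeps divergence mild."""
        rows = {"a1": [], "a2": [], "b1": [], "b2": []}
        for _ in range(n_const):
            for k in rows:
                rows[k].append("A")
        for _ in range(n_support):
            rows["a1"].append("C")
            rows["a2"].append("C")
            rows["b1"].append("T")
            rows["b2"].append("T")
        for _ in range(n_conflict):
            rows["a1"].append("G")
            rows["b1"].append("G")
            rows["a2"].append("T")
            rows["b2"].append("T")
        return RegionAlignment(
            region="R1",
            records=[
                rec(k, "Sp " + k[0], "".join(v)) for k, v in sorted(rows.items())
            ],
        )

    def test_unanimous_columns_give_full_support(self):
        aln = self.make_split_alignment(n_support=40)
        tree = bootstrap_supports(aln, replicates=50, seed=1)
        sups = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
        assert sups and all(s == 100.0 for s in sups)

    def test_same_seed_reproducible(self, sim_recovery):
        _, records, _ = sim_recovery
        aln = RegionAlignment(region="SIM", records=records[:20])
        t1 = bootstrap_supports(aln, replicates=30, seed=7)
        t2 = bootstrap_supports(aln, replicates=30, seed=7)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False) if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False) if hasattr(n, "support"))
        assert s1 == s2

    def test_conflicting_columns_give_intermediate_support(self):
        # 50:50 conflicting signal -> support near 50 for the winning split
        aln = self.make_split_alignment(n_support=25, n_conflict=25)
        tree = bootstrap_supports(aln, replicates=400, seed=3)
        sups = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
        assert sups
        # binomial tolerance: p=0.5ish, 400 reps -> a few SE wide band
        assert 30.0 < sups[0] < 70.0

    def test_bipartitions_invariant_to_leaf_order(self, sim_recovery):
        _, records, _ = sim_recovery
        sub = records[:12]
        aln1 = RegionAlignment(region="SIM", records=sub)
        aln2 = RegionAlignment(region="SIM", records=list(reversed(sub)))
        b1 = _bipartitions(nj_tree(distance_matrix(aln1)))
        b2 = _bipartitions(nj_tree(distance_matrix(aln2)))
        assert b1 == b2


class TestMonophyly:
    @pytest.mark.parametrize(
        "newick,species_of,species,expected",
        [
            ("((a1:1,a2:1):1,(b1:1,b2:1):1);", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, "A", True),
            ("((a1:1,b1:1):1,(a2:1,b2:1):1);", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, "A", False),
            ("((a1:1,a2:1):1,(b1:1,c1:1):1);", {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}, "C", True),
        ],
    )
    def test_known_topologies(self, newick, species_of, species, expected):
        tree = skbio.TreeNode.read([newick])
        assert is_monophyletic(tree, species, species_of) is expected

    def test_missing_species_raises(self):
        tree = skbio.TreeNode.read(["((a1:1,a2:1):1,b1:1);"])
        with pytest.raises(ValueError):
            is_monophyletic(tree, "Z", {"a1": "A", "a2": "A", "b1": "B"})

    def test_rooting_by_outgroup_blocks_paraphyly(self):
        # a1 groups with the outgroup: species A is NOT monophyletic
        tree = skbio.TreeNode.read(["((a1:1,out:1):1,a2:1,b1:1);"])
        species_of = {"a1": "A", "a2": "A", "b1": "B", "out": "OG"}
        assert is_monophyletic(tree, "A", species_of, outgroup=["out"]) is False

    def test_random_clades_vs_construction_truth(self, sim_recovery):
        """Clades of a simulated tree are monophyletic by construction;
        labels scrambled across clades are not."""
        from barcodegap.simulate import simulate_species_tree

        tree = simulate_species_tree(10, 0.05, seed=4)
        tips = [t.name for t in tree.tips()]
        for node in tree.non_tips(include_self=False):
            clade = [t.name for t in node.tips()]
            if len(clade) < 2 or len(clade) > len(tips) - 2:
                continue
            species_of = {t: ("IN" if t in clade else "OUT") for t in tips}
            assert is_monophyletic(tree, "IN", species_of)
            # swap one member across the boundary -> broken
            inside, outside = clade[0], next(t for t in tips if t not in clade)
            broken = dict(species_of)
            broken[inside], broken[outside] = "OUT", "IN"
            assert not is_monophyletic(tree, "IN", broken)


class TestBestMatch:
    def test_rule_application(self):
        labels = ["a1", "a2", "b1"]
        species = ["A", "A", "B"]
        # a1's best hit is a2 -> correct; b1 singleton -> excluded
        mat = np.array([[0, 0.001, 0.08], [0.001, 0, 0.09], [0.08, 0.09, 0]])
        verdicts = best_match_identify(dm_from(labels, species, mat))
        assert {v.sample_id: v.classification for v in verdicts} == {
            "a1": "correct",
            "a2": "correct",
        }

    def test_tied_hits_are_ambiguous(self):
        labels = ["a1", "a2", "b1", "b2"]
        species = ["A", "A", "B", "B"]
        mat = np.array(
            [
                [0, 0.01, 0.01, 0.08],
                [0.01, 0, 0.09, 0.08],
                [0.01, 0.09, 0, 0.05],
                [0.08, 0.08, 0.05, 0],
            ]
        )
        verdicts = {v.sample_id: v for v in best_match_identify(dm_from(labels, species, mat))}
        assert verdicts["a1"].classification == "ambiguous"
        assert verdicts["a1"].best_hit_species == frozenset({"A", "B"})

    def test_wrong_nearest_neighbour_is_incorrect(self):
        labels = ["a1", "a2", "b1", "b2"]
        species = ["A", "A", "B", "B"]
        mat = np.array(
            [
                [0, 0.05, 0.01, 0.08],
                [0.05, 0, 0.09, 0.08],
                [0.01, 0.09, 0, 0.05],
                [0.08, 0.08, 0.05, 0],
            ]
        )
        verdicts = {v.sample_id: v for v in best_match_identify(dm_from(labels, species, mat))}
        assert verdicts["a1"].classification == "incorrect"

    def test_outgroup_excluded_from_queries_and_references(self):
        labels = ["a1", "a2", "og"]
        species = ["A", "A", "OG"]
        mat = np.array([[0, 0.02, 0.001], [0.02, 0, 0.09], [0.001, 0.09, 0]])
        verdicts = best_match_identify(dm_from(labels, species, mat), exclude=["og"])
        assert {v.sample_id for v in verdicts} == {"a1", "a2"}
        assert all(v.classification == "correct" for v in verdicts)


class TestIdentificationRates:
    @pytest.mark.parametrize(
        "n_ok,n_total,expected",
        [(10, 11, 90.91), (9, 12, 75.0), (12, 12, 100.0), (11, 12, 91.67)],
    )
    def test_species_rate_granularity(self, n_ok, n_total, expected):
        """Small-integer species fractions print at the familiar
        granularity (10/11 -> 90.91%, 9/12 -> 75.0%)."""
        from barcodegap.identification import QueryVerdict

        verdicts = []
        for s in range(n_total):
            cls = "correct" if s < n_ok else "incorrect"
            verdicts.append(
                QueryVerdict(f"s{s}.1", f"Sp{s}", frozenset({f"Sp{s}"}), 0.01, cls)
            )
            verdicts.append(
                QueryVerdict(f"s{s}.2", f"Sp{s}", frozenset({f"Sp{s}"}), 0.01, "correct")
            )
        rep = identification_rates(region="R", verdicts=verdicts)
        assert rep.n_species == n_total
        assert round(rep.species_rate, 2) == expected

    def test_tree_method_counts_monophyletic_species(self):
        tree = skbio.TreeNode.read(["((a1:1,a2:1):1,(b1:1,(b2:1,c1:1):1):1);"])
        species_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        rep = identification_rates(region="R", tree=tree, species_of=species_of)
        assert rep.per_species == {"A": True, "B": False, "C": True}
        assert rep.species_rate == pytest.approx(100.0 * 2 / 3)
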