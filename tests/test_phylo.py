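import math

import dendropy
import numpy as np
import pytest

from pcfam import (
    DistanceMatrix,
    GeneModel,
    ancestral_counts,
    bootstrap,
    infer_retro_donors,
    map_introns_to_domain,
    neighbor_joining,
    protein_distance,
    read_newick,
    reconcile,
)
from pcfam.phylo import tree_splits

from .oracles import brute_dl_minimum, random_additive_tree


def _matrix_from_tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(t.label for t in tree.taxon_namespace)
    m = np.array(
        [
            [
                pdm.distance(
                    tree.taxon_namespace.get_taxon(a),
                    tree.taxon_namespace.get_taxon(b),
                )
                for b in ids
            ]
            for a in ids
        ]
    )
    return tree, DistanceMatrix(ids, m)


class TestProteinDistance:
    def test_identical_sequences(self):
        d = protein_distance({"a": "MKLV", "b": "MKLV"})
        assert d.matrix[0, 1] == 0

    def test_one_mismatch_in_ten(self):
        aln = {"a": "MKLVMKLVMK", "b": "MKLVMKLVMA"}
        p = protein_distance(aln, "p").matrix[0, 1]
        assert p == pytest.approx(0.1)
        k = protein_distance(aln, "kimura").matrix[0, 1]
        assert k == pytest.approx(-math.log(1 - 0.1 - 0.01 / 5))

    def test_gap_columns_excluded(self):
        aln = {"a": "MK-V", "b": "MKLV"}
        assert protein_distance(aln, "p").matrix[0, 1] == 0

    def test_saturated_pair_is_infinite(self):
        aln = {"a": "MMMM", "b": "KKKK"}
        assert protein_distance(aln, "kimura").matrix[0, 1] == math.inf

    def test_zero_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            protein_distance({"a": "M-", "b": "-M"})


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        source, D = _matrix_from_tree("((A:1,B:2):1,(C:3,D:4):1);")
        tree = neighbor_joining(D)
        got = tree_splits(tree)
        want = tree_splits(source)
        assert set(got) == set(want)
        # leaf branch lengths recovered exactly
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        )

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = neighbor_joining(D)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]]))
            )

    def test_random_additive_trees_recovered(self):
        # NJ is consistent on additive matrices: exact topology, and the
        # tree metric reproduces the input distances
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            newick, _ = random_additive_tree(n, rng)
            source, D = _matrix_from_tree(newick)
            tree = neighbor_joining(D)
            assert set(tree_splits(tree)) == set(tree_splits(source))
            pdm = tree.phylogenetic_distance_matrix()
            tn = tree.taxon_namespace
            for i, a in enumerate(D.ids):
                for j in range(i + 1, len(D.ids)):
                    got = pdm.distance(
                        tn.get_taxon(a), tn.get_taxon(D.ids[j])
                    )
                    assert got == pytest.approx(D.matrix[i, j], abs=1e-9)

    def test_tie_broken_toward_lowest_index_pair(self):
        # perfectly symmetric matrix: every Q entry equal
        D = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 2, 2, 2], [2, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]],
                dtype=float,
            ),
        )
        tree = neighbor_joining(D)
        cherries = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in tree.preorder_internal_node_iter()
            if len(nd.leaf_nodes()) == 2
        }
        assert frozenset({"A", "B"}) in cherries


class TestBootstrap:
    @staticmethod
    def _clean_alignment():
        # two clades separated in 40% of columns: clear signal while
        # staying well below distance-correction saturation
        return {
            "a1": "MMMMMMKKKK" * 4,
            "a2": "MMMMMMKKKK" * 4,
            "b1": "MMMMMMEEEE" * 4,
            "b2": "MMMMMMEEEE" * 4,
        }

    def test_clean_split_gets_full_support(self):
        aln = {
            "a1": "MMMMMKKKKLLLVVAA",
            "a2": "MMMMMKKKKLLLVVAC",
            "b1": "MMMMMEEEELLLVVGG",
            "b2": "MMMMMEEEELLLVVGC",
        }
        _, support = bootstrap(aln, n_reps=100, seed=1)
        split = frozenset({"b1", "b2"})
        assert support[split] == 100.0

    def test_single_replicate_support_binary(self):
        aln = self._clean_alignment()
        _, support = bootstrap(aln, n_reps=1, seed=3)
        assert set(support.values()) <= {0.0, 100.0}

    def test_seed_reproducibility(self):
        aln = self._clean_alignment()
        _, s1 = bootstrap(aln, n_reps=25, seed=11)
        _, s2 = bootstrap(aln, n_reps=25, seed=11)
        assert s1 == s2

    def test_taxon_order_invariance(self):
        aln = self._clean_alignment()
        reordered = dict(reversed(list(aln.items())))
        _, s1 = bootstrap(aln, n_reps=25, seed=11)
        _, s2 = bootstrap(reordered, n_reps=25, seed=11)
        assert s1 == s2


class TestReconcile:
    def test_congruent_tree_has_no_events(self):
        st = read_newick("((A,B)AB,(C,D)CD)ROOT;")
        gt = read_newick("((a,b),(c,d));")
        r = reconcile(
            gt, st, {"a": "A", "b": "B", "c": "C", "d": "D"}
        )
        assert r.n_duplications == 0
        assert r.n_losses == 0
        assert all(v == 1 for v in r.copies_at.values())

    def test_worked_duplication_loss_example(self):
        st = read_newick("((A,B)AB,C)ROOT;")
        gt = read_newick("((a1,b1),(a2,c1));")
        r = reconcile(
            gt, st, {"a1": "A", "b1": "B", "a2": "A", "c1": "C"}
        )
        assert r.n_duplications == 1
        assert r.n_losses == 2
        assert r.duplication_nodes == ["ROOT"]
        assert r.copies_at["AB"] == 2
        assert r.copies_at["A"] == 2

    def test_unmapped_leaf_rejected(self):
        st = read_newick("((A,B),C);")
        gt = read_newick("((a,b),c);")
        with pytest.raises(ValueError, match="missing"):
            reconcile(gt, st, {"a": "A", "b": "B"})

    def test_congruent_any_size(self):
        from pcfam import DEFAULT_SPECIES_TREE

        st = read_newick(DEFAULT_SPECIES_TREE)
        gt = read_newick(DEFAULT_SPECIES_TREE)
        leaf_map = {lf.taxon.label: lf.taxon.label
                    for lf in gt.leaf_node_iter()}
        r = reconcile(gt, st, leaf_map)
        assert r.n_duplications == 0 and r.n_losses == 0

    @staticmethod
    def _random_gene_tree(species, n_leaves, rng):
        leaves = [
            f"{rng.choice(species)}_x{i}" for i in range(n_leaves)
        ]
        nodes = list(leaves)
        while len(nodes) > 1:
            i = int(rng.integers(0, len(nodes)))
            a = nodes.pop(i)
            j = int(rng.integers(0, len(nodes)))
            b = nodes.pop(j)
            nodes.append(f"({a},{b})")
        return nodes[0] + ";", leaves

    def test_event_total_matches_exhaustive_minimum(self):
        st = read_newick("((A,B)AB,(C,D)CD)ROOT;")
        species = np.array(["A", "B", "C", "D"])
        rng = np.random.default_rng(47)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            newick, leaves = self._random_gene_tree(species, n, rng)
            gt = read_newick(newick)
            leaf_map = {lf: lf.split("_")[0] for lf in leaves}
            r = reconcile(gt, st, leaf_map)
            gt2 = read_newick(newick)
            assert r.n_duplications + r.n_losses == brute_dl_minimum(
                gt2, read_newick("((A,B)AB,(C,D)CD)ROOT;"), leaf_map
            )

    def test_leaf_copies_equal_observed_counts(self):
        st = read_newick("((A,B)AB,C)ROOT;")
        gt = read_newick("(((a1,a2),a3),(b1,c1));")
        leaf_map = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "c1": "C"}
        r = reconcile(gt, st, leaf_map)
        assert r.copies_at["A"] == 3
        assert r.copies_at["B"] == 1
        assert r.copies_at["C"] == 1


class TestAncestralCounts:
    def test_single_congruent_family_counts_one_everywhere(self):
        st = read_newick("((A,B)AB,C)ROOT;")
        gt = read_newick("((a,b),c);")
        r = reconcile(gt, st, {"a": "A", "b": "B", "c": "C"})
        totals = ancestral_counts([r], ["ROOT", "AB"])
        assert totals["copies"] == {"ROOT": 1, "AB": 1}

    def test_empty_family_set_is_all_zeros(self):
        totals = ancestral_counts([], ["V", "E"])
        assert totals["copies"] == {"V": 0, "E": 0}

    def test_unknown_label_rejected(self):
        st = read_newick("((A,B)AB,C)ROOT;")
        gt = read_newick("((a,b),c);")
        r = reconcile(gt, st, {"a": "A", "b": "B", "c": "C"})
        with pytest.raises(KeyError):
            ancestral_counts([r], ["NOPE"])


class TestIntronMapping:
    def _gene(self, exons, strand="+"):
        return GeneModel("g", "sp", "c", strand, exons[0][0],
                         exons[-1][1], exons=exons)

    def test_intron_inside_domain(self):
        # 100 coding bases upstream -> residue 33.33, phase 1
        g = self._gene([(1, 100), (201, 500)])
        placement = map_introns_to_domain(g, (20, 60))
        assert placement.has_conserved_intron
        (pos, phase), = placement.introns_in_domain
        assert pos == pytest.approx(100 / 3)
        assert phase == 1

    def test_intronless_gene(self):
        g = self._gene([(1, 300)])
        assert not map_introns_to_domain(g, (20, 60)).has_conserved_intron

    def test_intron_outside_domain_excluded(self):
        g = self._gene([(1, 100), (201, 500)])
        placement = map_introns_to_domain(g, (50, 90))
        assert not placement.has_conserved_intron

    def test_inconsistent_protein_length_rejected(self):
        g = self._gene([(1, 100), (201, 500)])  # 400 coding bases? no: 100+300
        with pytest.raises(ValueError, match="inconsist"):
            map_introns_to_domain(g, (20, 60), protein_length=50)


class TestRetroDonors:
    def test_basal_intron_bearing_gene_is_sole_donor(self):
        leaves = [f"r{i}" for i in range(1, 11)]
        sub = leaves[0]
        for leaf in leaves[1:]:
            sub = f"({sub},{leaf})"
        tree = read_newick(f"(donor,{sub});")
        evidence = {leaf: False for leaf in leaves}
        evidence["donor"] = True
        events = infer_retro_donors(tree, evidence)
        assert len(events) == 1
        assert events[0].donor == "donor"
        assert sorted(events[0].retro_genes) == sorted(leaves)

    def test_all_intron_bearing_means_no_events(self):
        tree = read_newick("((a,b),c);")
        assert infer_retro_donors(tree, {"a": True, "b": True, "c": True}) == []

    def test_no_intron_bearing_gene_reports_nothing(self):
        tree = read_newick("((a,b),c);")
        assert infer_retro_donors(
            tree, {"a": False, "b": False, "c": False}
        ) == []

    def test_two_independent_retro_clades(self):
        tree = read_newick("(((x1,x2),donor1),((y1,y2),donor2));")
        evidence = {"x1": False, "x2": False, "y1": False, "y2": False,
                    "donor1": True, "donor2": True}
        events = infer_retro_donors(tree, evidence)
        assert len(events) == 2
        donors = {tuple(e.retro_genes): e.donor for e in events}
        assert donors[("x1", "x2")] == "donor1"
        assert donors[("y1", "y2")] == "donor2"

    def test_donor_never_intronless(self):
        tree = read_newick("((a,b),(c,d));")
        evidence = {"a": True, "b": False, "c": False, "d": False}
        for event in infer_retro_donors(tree, evidence):
            assert evidence[event.donor]

    def test_tandem_expansion_annotated(self):
        tree = read_newick("(donor,((x1,x2),x3));")
        evidence = {"donor": True, "x1": False, "x2": False, "x3": False}
        events = infer_retro_donors(
            tree, evidence, tandem_clusters=[["x1", "x2"]]
        )
        assert len(events) == 1
        assert events[0].tandem_expansion
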