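"""Distances, neighbor joining, and family-bootstrap supports."""

import dendropy
import numpy as np
import pytest

from bacpan.cluster import OrthologFamily, PresenceAbsenceMatrix
from bacpan.errors import ConsistencyError, InputError
from bacpan.phylogeny import (
    DistanceMatrix,
    bootstrap_support,
    concat_distances,
    nj_tree,
    robinson_foulds,
    root_at,
    single_copy_core,
    tree_splits,
)

from oracles import best_quartet_by_least_squares

import pandas as pd


def dm(taxa, values):
    return DistanceMatrix(list(taxa), np.asarray(values, dtype=float))


class TestSingleCopyCore:
    def test_only_all_ones_rows_qualify(self):
        df = pd.DataFrame([[1, 1], [2, 1], [1, 0]], index=["a", "b", "c"],
                          columns=["S1", "S2"])
        assert single_copy_core(PresenceAbsenceMatrix(df)) == ["a"]

    def test_generator_core_families_recovered(self, clustered_panel):
        cfg, *_rest, matrix = clustered_panel
        scc = single_copy_core(matrix)
        assert len(scc) == cfg.n_core


class TestConcatDistances:
    def make_families(self, proteomes):
        strains = sorted(proteomes)
        fam_ids = sorted({g.split("|")[1] for p in proteomes.values() for g in p})
        return [
            OrthologFamily(fid, [(s, f"{s}|{fid}") for s in strains], True)
            for fid in fam_ids
        ]

    def test_identical_proteomes_zero_matrix(self):
        genes = {"f1": "MKLVPT" * 10, "f2": "AWYHRD" * 8}
        proteomes = {s: {f"{s}|{fid}": seq for fid, seq in genes.items()}
                     for s in ("S1", "S2", "S3")}
        result = concat_distances(self.make_families(proteomes), proteomes)
        assert np.allclose(result.d, 0.0)

    def test_direct_count_of_differing_columns(self):
        base = "ACDEFGHIKLMNPQRSTVWY" * 25  # 500 columns
        mutated = list(base)
        for pos in (3, 77, 150, 320, 481):
            mutated[pos] = "W" if base[pos] != "W" else "Y"
        proteomes = {
            "S1": {"S1|f1": base}, "S2": {"S2|f1": "".join(mutated)},
            "S3": {"S3|f1": base},
        }
        result = concat_distances(self.make_families(proteomes), proteomes)
        idx = result.taxa.index
        assert result.d[idx("S1"), idx("S2")] == pytest.approx(5 / 500)

    def test_missing_gene_is_consistency_error(self):
        proteomes = {"S1": {"S1|f1": "MKL"}, "S2": {}, "S3": {"S3|f1": "MKL"}}
        fams = [OrthologFamily("f1", [("S1", "S1|f1"), ("S2", "S2|f1"),
                                      ("S3", "S3|f1")], True)]
        with pytest.raises(ConsistencyError):
            concat_distances(fams, proteomes)

    def test_distances_correlate_with_tree_path_lengths(self, clustered_panel):
        cfg, proteomes, genomes, truth, hits, families, matrix = clustered_panel
        scc_ids = set(single_copy_core(matrix))
        scc = [f for f in families if f.family_id in scc_ids]
        result = concat_distances(scc, proteomes)
        pdm = truth.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in truth.tree.taxon_namespace}
        est, true = [], []
        for i, a in enumerate(result.taxa):
            for b in result.taxa[i + 1:]:
                est.append(result.d[result.taxa.index(a), result.taxa.index(b)])
                true.append(pdm.patristic_distance(taxa[a], taxa[b]))
        r = np.corrcoef(est, true)[0, 1]
        assert r > 0.95


class TestNeighborJoining:
    def test_four_taxon_additive_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives these path distances
        d4 = dm("ABCD", [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]])
        tree = nj_tree(d4)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_matches_least_squares_topology_oracle(self, rng):
        # random additive quartets: NJ topology equals exhaustive LS search
        for _ in range(25):
            lengths = rng.uniform(0.5, 5.0, size=5)
            ta, tb, tc, td, internal = lengths
            d4 = np.array([
                [0, ta + tb, ta + internal + tc, ta + internal + td],
                [ta + tb, 0, tb + internal + tc, tb + internal + td],
                [ta + internal + tc, tb + internal + tc, 0, tc + td],
                [ta + internal + td, tb + internal + td, tc + td, 0]])
            tree = nj_tree(dm("ABCD", d4))
            topo, ls_lengths, rss = best_quartet_by_least_squares(d4)
            assert rss < 1e-18
            assert topo == ((0, 1), (2, 3))
            assert tree_splits(tree) == {frozenset({"C", "D"})}
            leaf_lengths = sorted(leaf.edge.length for leaf in tree.leaf_node_iter())
            assert np.allclose(leaf_lengths, sorted(lengths[:4]))

    def test_three_taxa_closed_form(self):
        tree = nj_tree(dm("XYZ", [[0, 2, 3], [2, 0, 4], [3, 4, 0]]))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"X": 0.5, "Y": 1.5, "Z": 2.5}

    def test_negative_branch_lengths_clamped(self):
        # strongly non-additive matrix can push NJ lengths negative
        d4 = dm("ABCD", [[0, 1, 1, 1], [1, 0, 1, 10], [1, 1, 0, 1], [1, 10, 1, 0]])
        tree = nj_tree(d4)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(InputError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_true_topology_recovered_on_synthetic_panel(self, clustered_panel):
        cfg, proteomes, genomes, truth, hits, families, matrix = clustered_panel
        scc_ids = set(single_copy_core(matrix))
        scc = [f for f in families if f.family_id in scc_ids]
        tree = nj_tree(concat_distances(scc, proteomes))
        tns = dendropy.TaxonNamespace()
        est = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                                schema="newick", taxon_namespace=tns)
        true = dendropy.Tree.get(data=truth.tree_newick(), schema="newick",
                                 taxon_namespace=tns)
        assert robinson_foulds(est, true) == 0


class TestBootstrap:
    def _tiny_input(self, signal="same"):
        base = "MKLVPTAWYHRD" * 10
        variant = "W" + base[1:]
        proteomes = {}
        for k, s in enumerate(("S1", "S2", "S3", "S4")):
            genes = {}
            for f in ("f1", "f2", "f3", "f4", "f5"):
                seq = base
                if s in ("S3", "S4"):
                    seq = variant  # S3,S4 deviate identically in every family
                genes[f"{s}|{f}"] = seq
            proteomes[s] = genes
        fams = [OrthologFamily(f, [(s, f"{s}|{f}") for s in sorted(proteomes)], True)
                for f in ("f1", "f2", "f3", "f4", "f5")]
        return fams, proteomes

    def test_identical_signal_gives_full_support(self):
        fams, proteomes = self._tiny_input()
        tree = bootstrap_support(fams, proteomes, n_reps=25, seed=0)
        supports = [int(n.label) for n in tree.preorder_node_iter()
                    if n.label is not None and not n.is_leaf()]
        assert supports and all(s == 100 for s in supports)

    def test_seeded_run_reproducible(self, clustered_panel):
        cfg, proteomes, genomes, truth, hits, families, matrix = clustered_panel
        scc_ids = set(single_copy_core(matrix))
        scc = [f for f in families if f.family_id in scc_ids]
        t1 = bootstrap_support(scc, proteomes, n_reps=50, seed=99)
        t2 = bootstrap_support(scc, proteomes, n_reps=50, seed=99)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_true_splits_outsupport_false_ones(self):
        # over seeds: supports of true-tree bipartitions exceed supports of
        # bipartitions absent from the true tree
        from bacpan.simulate import SimulationConfig, simulate_strains
        from bacpan.align import all_vs_all
        from bacpan.cluster import cluster_families, build_matrix

        true_hits, false_hits = [], []
        for seed in (11, 12, 13):
            cfg = SimulationConfig(n_strains=6, n_core=10, dispensable_rate=0,
                                   unique_per_strain=0, seed=seed)
            proteomes, genomes, truth = simulate_strains(cfg)
            hits = all_vs_all(proteomes)
            universe = [g for p in proteomes for g in p.genes]
            families = cluster_families(hits, universe)
            matrix = build_matrix(families, [p.strain_id for p in proteomes])
            scc_ids = set(single_copy_core(matrix))
            scc = [f for f in families if f.family_id in scc_ids]
            tree = bootstrap_support(scc, proteomes, n_reps=50, seed=seed)
            tns = dendropy.TaxonNamespace()
            true_tree = dendropy.Tree.get(data=truth.tree_newick(),
                                          schema="newick", taxon_namespace=tns)
            true_splits = tree_splits(true_tree)
            labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
            first, all_set = labels[0], set(labels)
            for node in tree.preorder_node_iter():
                if node is tree.seed_node or node.is_leaf() or node.label is None:
                    continue
                below = {l.taxon.label for l in node.leaf_iter()}
                side = below if first not in below else all_set - below
                (true_hits if frozenset(side) in true_splits else false_hits).append(
                    int(node.label))
        assert true_hits
        if false_hits:  # may be empty when every estimated split is true
            assert np.mean(true_hits) > np.mean(false_hits)

    def test_rooting_on_outgroup_leaf(self):
        fams, proteomes = self._tiny_input()
        tree = bootstrap_support(fams, proteomes, n_reps=10, seed=0)
        rooted = root_at(tree, "S1")
        children = rooted.seed_node.child_nodes()
        sides = [{l.taxon.label for l in c.leaf_iter()} for c in children]
        assert {"S1"} in sides
        with pytest.raises(InputError):
            root_at(tree, "nope")
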