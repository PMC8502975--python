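"""Single-copy-core phylogenomics: concatenated p-distances, neighbor
joining, and family-resampling bootstrap.

The distance between two strains is the proportion of differing non-gap
columns pooled over global pairwise alignments of every single-copy core
family (concatenation p-distance). Trees are built with the canonical
Saitou-Nei neighbor-joining agglomeration: at each step the pair
minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined; ties are broken
deterministically toward the lexicographically smallest pair of cluster
representatives, and negative branch lengths are clamped to zero. On an
additive distance matrix NJ recovers the generating topology and branch
lengths exactly.

Bootstrap support resamples families (genes) with replacement - the
standard unit for concatenated matrices - rebuilds the NJ tree per
replicate, and reports the percentage of replicates containing each
internal bipartition of the original tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .align import ScoringParams, global_pdistance
from .cluster import OrthologFamily, PresenceAbsenceMatrix
from .errors import ConsistencyError, InputError


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise InputError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise InputError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, taxon in enumerate(self.taxa):
                row = " ".join(f"{v:.6f}" for v in self.d[i])
                fh.write(f"{taxon:<12s}{row}\n")


def single_copy_core(matrix: PresenceAbsenceMatrix) -> list[str]:
    """Families with copy count exactly 1 in every strain."""
    df = matrix.df
    mask = (df == 1).all(axis=1)
    return sorted(df.index[mask])


def _proteome_map(proteomes) -> dict[str, dict[str, str]]:
    if isinstance(proteomes, Mapping):
        return {s: dict(genes) for s, genes in proteomes.items()}
    return {p.strain_id: dict(p.genes) for p in proteomes}


def family_pair_counts(families: Sequence[OrthologFamily], proteomes,
                       scoring: ScoringParams | None = None,
                       ) -> tuple[list[str], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-family (differing, total) non-gap column counts for every strain pair.

    The expensive alignments are done once here; concatenated distances and
    bootstrap replicates are cheap sums over these counts.
    """
    seqs = _proteome_map(proteomes)
    taxa = sorted(seqs)
    index = {t: i for i, t in enumerate(taxa)}
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for fam in families:
        by_strain = {}
        for strain_id, gene_id in fam.members:
            if strain_id not in seqs or gene_id not in seqs[strain_id]:
                raise ConsistencyError(
                    f"family {fam.family_id!r}: gene {gene_id!r} missing from "
                    f"proteome of strain {strain_id!r}")
            by_strain[strain_id] = seqs[strain_id][gene_id]
        missing = set(taxa) - set(by_strain)
        if missing:
            raise ConsistencyError(
                f"family {fam.family_id!r} is not single-copy core: missing "
                f"strain(s) {sorted(missing)}")
        diff = np.zeros((len(taxa), len(taxa)))
        total = np.zeros_like(diff)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                j = index[b]
                nd, nt = global_pdistance(by_strain[a], by_strain[b], scoring)
                diff[i, j] = diff[j, i] = nd
                total[i, j] = total[j, i] = nt
        counts[fam.family_id] = (diff, total)
    return taxa, counts


def _distances_from_counts(taxa, counts, fam_ids) -> DistanceMatrix:
    diff = np.zeros((len(taxa), len(taxa)))
    total = np.zeros_like(diff)
    for fid in fam_ids:
        d, t = counts[fid]
        diff += d
        total += t
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(total > 0, diff / np.maximum(total, 1), 0.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(taxa), dist)


def concat_distances(families: Sequence[OrthologFamily], proteomes,
                     scoring: ScoringParams | None = None) -> DistanceMatrix:
    """Concatenated p-distance over all single-copy core families."""
    if not families:
        raise InputError("no families supplied")
    taxa, counts = family_pair_counts(families, proteomes, scoring)
    if len(taxa) < 3:
        raise InputError("need at least 3 taxa")
    return _distances_from_counts(taxa, counts, [f.family_id for f in families])


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted tree with clamped branch lengths."""
    n = len(dm.taxa)
    if n < 3:
        raise InputError("need at least 3 taxa for a tree")
    taxa_ns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # lexicographically smallest leaf under each cluster
    for taxon in dm.taxa:
        node = dendropy.Node(taxon=taxa_ns.get_taxon(taxon))
        nodes.append(node)
        reps.append(taxon)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(li, 0.0)
        nj.edge.length = max(lj, 0.0)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, ai, aj)
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        new_index = join(i, j, li, lj)
        # distances from the new node to every other active cluster
        new_row = np.zeros(len(nodes))
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_index, :new_index] = new_row[:new_index]
        d[:new_index, new_index] = new_row[:new_index]
        active = [k for k in active if k not in (i, j)] + [new_index]

    # Final three clusters joined at the central (unrooted) node via the
    # three-point formulas.
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa_ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels (normalized to
    the side not containing the alphabetically first taxon)."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    first = labels[0]
    all_set = set(labels)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if first not in below else all_set - below
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(frozenset(side))
    return splits


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted RF distance: size of the symmetric difference of split sets."""
    return len(tree_splits(tree_a) ^ tree_splits(tree_b))


def bootstrap_support(families: Sequence[OrthologFamily], proteomes,
                      n_reps: int = 500, seed: int = 0,
                      scoring: ScoringParams | None = None) -> dendropy.Tree:
    """NJ tree with per-edge bootstrap supports from family resampling.

    Support for each internal edge of the tree built on the full family set
    is the percentage of replicates whose NJ tree contains the same
    bipartition; it is written into the subtending node's label.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    taxa, counts = family_pair_counts(families, proteomes, scoring)
    if len(taxa) < 3:
        raise InputError("need at least 3 taxa")
    fam_ids = sorted(counts)
    tree = nj_tree(_distances_from_counts(taxa, counts, fam_ids))
    rng = np.random.default_rng(seed)
    split_hits: dict[frozenset, int] = {s: 0 for s in tree_splits(tree)}
    for _ in range(n_reps):
        sample = [fam_ids[k] for k in rng.integers(0, len(fam_ids), size=len(fam_ids))]
        rep_tree = nj_tree(_distances_from_counts(taxa, counts, sample))
        rep_splits = tree_splits(rep_tree)
        for split in split_hits:
            if split in rep_splits:
                split_hits[split] += 1
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    first, all_set = labels[0], set(labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if first not in below else all_set - below
        key = frozenset(side)
        if key in split_hits:
            node.label = str(int(round(100.0 * split_hits[key] / n_reps)))
    return tree


def root_at(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root the (unrooted) tree on the edge leading to the named leaf."""
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon.label == outgroup:
            leaf = node
            break
    if leaf is None:
        raise InputError(f"outgroup {outgroup!r} is not a leaf of the tree")
    tree.to_outgroup_position(leaf, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)
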