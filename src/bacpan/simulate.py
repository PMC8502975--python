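"""Ground-truthed simulation of a multi-strain bacterial panel.

The generator produces, for ``n_strains`` strains related by a known rooted
binary tree:

* a shared single-copy core gene set present in every strain,
* dispensable families gained on tree branches (gain-only, no loss) and
  inherited by all descendant strains,
* strain-specific (unique) families drawn per tip,
* nucleotide genes that evolve along the tree by independent per-site
  substitution (no indels in genes), translated to proteins with the
  bacterial genetic code (table 11),
* genomes assembled as genes separated by intergenic spacers whose base
  composition is controlled so that expected GC equals ``background_gc``,
* optionally a planted contiguous gene cluster whose GC is shifted by
  ``gc_shift`` and whose sequences derive from a labeled foreign donor
  lineage — a known-true horizontal transfer.

Because the tree, the family table, the per-branch substitution
probabilities and the transfer coordinates are all recorded in
:class:`GroundTruth`, every downstream stage (clustering, pan/core curves,
ANI, phylogeny, HGT screening) can be scored against known truth.

Spacers evolve along the tree exactly like genes (substitutions only by
default) so that genome-wide nucleotide identity between two strains equals
the product of ``(1 - d)`` over the branches separating them, up to the
small back-mutation correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import dendropy

from .errors import ConfigError, InputError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}
# Bacterial/plastid code (translation table 11): standard codon assignments.
_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]
    _CODON_TABLE.update(table.forward_table)
    for stop in table.stop_codons:
        _CODON_TABLE[stop] = "X"  # internal stops are tolerated, scored neutral


_build_codon_table()
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class HgtClusterSpec:
    """A planted foreign gene cluster: size, GC offset, donor lineage label."""

    n_genes: int = 3
    gc_shift: float = 0.08
    donor_label: str = "Donorella"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated strain panel.

    Defaults describe a desk-scale panel patterned on a 17-strain
    *Bacillus* comparison: Bacillus-like background GC (0.415), moderate
    per-branch divergence, and both tree-structured dispensable gain and
    per-strain unique gain so the pan-genome is open.
    """

    n_strains: int = 6
    n_core: int = 15
    dispensable_rate: float = 1.0  # Poisson mean gains per branch
    unique_per_strain: float = 2.0  # Poisson mean unique families per tip
    gene_len_range: tuple[int, int] = (300, 600)  # bp, rounded to codons
    per_branch_divergence: float = 0.02  # substitution prob/site/branch
    background_gc: float = 0.415
    hgt_cluster: Optional[HgtClusterSpec] = None
    seed: int = 0
    spacer_len_range: tuple[int, int] = (60, 160)
    spacer_indel_rate: float = 0.0  # per-site indel prob in spacers only
    tree_newick: Optional[str] = None  # branch lengths = per-branch divergence

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ConfigError("n_strains", "need at least 2 strains")
        if self.n_core < 1:
            raise ConfigError("n_core", "need at least 1 core family")
        for name in ("dispensable_rate", "unique_per_strain", "per_branch_divergence",
                     "spacer_indel_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if not (0.0 < self.background_gc < 1.0):
            raise ConfigError("background_gc", "must be strictly between 0 and 1")
        lo, hi = self.gene_len_range
        if lo < 30 or hi < lo:
            raise ConfigError("gene_len_range", "need 30 <= lo <= hi")
        lo, hi = self.spacer_len_range
        if lo < 1 or hi < lo:
            raise ConfigError("spacer_len_range", "need 1 <= lo <= hi")
        if self.hgt_cluster is not None:
            h = self.hgt_cluster
            if h.n_genes < 1:
                raise ConfigError("hgt_cluster.n_genes", "must be >= 1")
            gc = self.background_gc + h.gc_shift
            if not (0.0 < gc < 1.0):
                raise ConfigError("hgt_cluster.gc_shift",
                                  "background_gc + gc_shift must stay in (0, 1)")


@dataclass
class GeneFeature:
    """GFF-lite row: 0-based half-open coordinates on the strain genome."""

    strain_id: str
    gene_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class StrainProteome:
    strain_id: str
    genes: dict[str, str] = field(default_factory=dict)  # gene_id -> protein

    def items(self):
        return self.genes.items()

    def __len__(self):
        return len(self.genes)


@dataclass
class StrainGenome:
    strain_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __len__(self):
        return len(self.sequence)

    def features_by_gene(self) -> dict[str, tuple[int, int]]:
        return {f.gene_id: (f.start, f.end) for f in self.features}


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    tree: dendropy.Tree
    family_table: pd.DataFrame  # families x strains copy counts
    true_ani: pd.DataFrame  # strains x strains expected nucleotide identity
    hgt_gene_ids: list[str] = field(default_factory=list)
    hgt_cluster_coords: Optional[tuple[str, int, int]] = None  # strain, start, end
    donor_panel: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # donor_panel: planted gene id -> [(lineage label, seq id, protein)] homologs
    gene_family: dict[str, str] = field(default_factory=dict)  # gene -> family

    def tree_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


class _Node:
    __slots__ = ("name", "children", "edge_div", "is_leaf")

    def __init__(self, name: str, edge_div: float = 0.0):
        self.name = name
        self.children: list[_Node] = []
        self.edge_div = edge_div  # substitution probability on the edge above
        self.is_leaf = False


def _coalescent_topology(strain_ids: Sequence[str], d: float, rng: np.random.Generator) -> _Node:
    """Random rooted binary tree by uniform pair-merging; all edges get d."""
    lineages = []
    for sid in strain_ids:
        node = _Node(sid, d)
        node.is_leaf = True
        lineages.append(node)
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        counter += 1
        parent = _Node(f"N{counter}", d)
        parent.children = [lineages[i], lineages[j]]
        lineages = [n for k, n in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    root = lineages[0]
    root.edge_div = 0.0  # no edge above the root
    return root


def _tree_from_newick(newick: str, default_div: float) -> _Node:
    dt = dendropy.Tree.get(data=newick, schema="newick")
    counter = 0

    def convert(dnode) -> _Node:
        nonlocal counter
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = _Node(str(name).replace(" ", "_"))
            node.is_leaf = True
        else:
            counter += 1
            node = _Node(dnode.label or f"N{counter}")
            for child in dnode.child_nodes():
                node.children.append(convert(child))
        length = dnode.edge.length
        node.edge_div = default_div if length is None else float(length)
        return node

    root = convert(dt.seed_node)
    root.edge_div = 0.0
    return root


def _leaves(node: _Node) -> list[_Node]:
    if node.is_leaf:
        return [node]
    out = []
    for child in node.children:
        out.extend(_leaves(child))
    return out


def _to_dendropy(root: _Node) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: _Node, dnode):
        dnode.edge.length = node.edge_div
        if node.is_leaf:
            dnode.taxon = taxa.require_taxon(label=node.name)
        else:
            for child in node.children:
                build(child, dnode.new_child())

    build(root, tree.seed_node)
    tree.seed_node.edge.length = None
    return tree


def _gc_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=length, p=_gc_probs(gc)).astype(np.uint8)


def _random_gene(length_range: tuple[int, int], gc: float, rng: np.random.Generator) -> np.ndarray:
    """Random coding sequence without internal stop codons."""
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    length -= length % 3
    seq = _random_seq(length, gc, rng)
    # Resample any stop codon until the gene is stop-free.
    codons = _decode(seq)
    while True:
        stops = [i for i in range(0, len(codons), 3)
                 if codons[i:i + 3] in _STOP_CODONS]
        if not stops:
            break
        for i in stops:
            seq[i:i + 3] = _random_seq(3, gc, rng)
        codons = _decode(seq)
    return seq


def _decode(seq: np.ndarray) -> str:
    return "".join("ACGT"[b] for b in seq)


def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability d, uniformly to another base."""
    if d <= 0 or seq.size == 0:
        # Still consume one rng draw pattern-free: nothing drawn when d == 0.
        return seq.copy()
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < d)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def translate(nt_seq: str) -> str:
    """Translate a CDS with the bacterial code; stops become X."""
    if len(nt_seq) % 3 != 0:
        raise InputError("coding sequence length must be a multiple of 3")
    return "".join(_CODON_TABLE[nt_seq[i:i + 3]] for i in range(0, len(nt_seq), 3))


def _edge_list(root: _Node) -> list[_Node]:
    """Preorder list of non-root nodes (each stands for the edge above it)."""
    out: list[_Node] = []

    def walk(node: _Node):
        for child in node.children:
            out.append(child)
            walk(child)

    walk(root)
    return out


def expected_identity(path_a: list[float], path_b: list[float], shared: int) -> float:
    """Expected per-site identity between two leaves.

    ``shared`` edges from the root are common to both paths and do not
    separate the leaves. Per separating branch with substitution
    probability d, a site survives unchanged with probability (1 - d);
    double hits coincide with probability 1/3. For small d the product of
    (1 - d) over separating branches is the practical value; the 1/3
    coincidence correction is included for exactness at a single pair of
    branches and ignored for longer paths (it is O(d^2) per branch pair).
    """
    sep = path_a[shared:] + path_b[shared:]
    ident = 1.0
    for d in sep:
        ident *= (1.0 - d)
    if len(sep) == 2:
        ident += sep[0] * sep[1] / 3.0
    return ident


def _true_ani_table(root: _Node) -> pd.DataFrame:
    leaves = sorted(l.name for l in _leaves(root))

    # root-to-leaf edge paths as node id sequences for shared-prefix counts
    paths_nodes: dict[str, list[_Node]] = {}

    def walk(node: _Node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths_nodes[node.name] = acc
        for child in node.children:
            walk(child, acc)

    for child in root.children:
        walk(child, [])

    table = pd.DataFrame(np.eye(len(leaves)), index=leaves, columns=leaves)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            pa, pb = paths_nodes[a], paths_nodes[b]
            shared = 0
            while shared < min(len(pa), len(pb)) and pa[shared] is pb[shared]:
                shared += 1
            ident = expected_identity([n.edge_div for n in pa],
                                      [n.edge_div for n in pb], shared)
            table.loc[a, b] = table.loc[b, a] = ident
    return table


@dataclass
class _Family:
    family_id: str
    origin: _Node  # node at which the family's root sequence is born
    kind: str  # "core" | "dispensable" | "unique"


def _plan_families(root: _Node, config: SimulationConfig,
                   rng: np.random.Generator) -> list[_Family]:
    families: list[_Family] = [
        _Family(f"fam_core_{i:04d}", root, "core") for i in range(config.n_core)
    ]
    n_disp = 0
    for node in _edge_list(root):
        for _ in range(rng.poisson(config.dispensable_rate)):
            families.append(_Family(f"fam_disp_{n_disp:04d}", node, "dispensable"))
            n_disp += 1
    n_uniq = 0
    for leaf in sorted(_leaves(root), key=lambda l: l.name):
        for _ in range(rng.poisson(config.unique_per_strain)):
            families.append(_Family(f"fam_uniq_{n_uniq:04d}", leaf, "unique"))
            n_uniq += 1
    return families


def simulate_family_table(config: SimulationConfig) -> tuple[pd.DataFrame, dendropy.Tree]:
    """Family occupancy only (no sequences) — fast path for curve studies.

    Uses the same tree and gain bookkeeping as :func:`simulate_strains`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    root = _build_tree(config, rng)
    families = _plan_families(root, config, rng)
    strains = sorted(l.name for l in _leaves(root))
    table = pd.DataFrame(0, index=sorted(f.family_id for f in families),
                         columns=strains, dtype=int)
    for fam in families:
        for leaf in _leaves(fam.origin):
            table.loc[fam.family_id, leaf.name] = 1
    return table, _to_dendropy(root)


def _build_tree(config: SimulationConfig, rng: np.random.Generator) -> _Node:
    if config.tree_newick is not None:
        root = _tree_from_newick(config.tree_newick, config.per_branch_divergence)
        if len(_leaves(root)) != config.n_strains:
            raise ConfigError("tree_newick",
                              f"tree has {len(_leaves(root))} leaves, expected {config.n_strains}")
        return root
    strain_ids = [f"S{i:02d}" for i in range(config.n_strains)]
    return _coalescent_topology(strain_ids, config.per_branch_divergence, rng)


def simulate_strains(config: SimulationConfig) -> tuple[list[StrainProteome], list[StrainGenome], GroundTruth]:
    """Simulate the full panel: proteomes, genomes, and ground truth.

    Deterministic: identical config + seed gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    root = _build_tree(config, rng)
    families = _plan_families(root, config, rng)
    fam_by_id = {f.family_id: f for f in families}
    strains = sorted(l.name for l in _leaves(root))

    # Root sequences: one gene per family plus one linked spacer per family
    # (core spacers form the backbone, accessory spacers travel with their
    # gene). All at background GC.
    gc = config.background_gc
    gene_root: dict[str, np.ndarray] = {}
    spacer_root: dict[str, np.ndarray] = {}
    for fam in sorted(families, key=lambda f: f.family_id):
        gene_root[fam.family_id] = _random_gene(config.gene_len_range, gc, rng)
        lo, hi = config.spacer_len_range
        spacer_root[fam.family_id] = _random_seq(int(rng.integers(lo, hi + 1)), gc, rng)
    lo, hi = config.spacer_len_range
    terminal_spacer_root = _random_seq(int(rng.integers(lo, hi + 1)), gc, rng)

    # Evolve sequences down the tree. State at a node: family -> (gene, spacer).
    tip_state: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    tip_terminal_spacer: dict[str, np.ndarray] = {}

    def _mutate_spacer(seq, d, cfg, rng):
        out = _mutate(seq, d, rng)
        if cfg.spacer_indel_rate > 0 and out.size:
            keep = rng.random(out.size) >= cfg.spacer_indel_rate
            out = out[keep]
        return out

    def descend(node: _Node, state, term_spacer):
        for fam in sorted(families, key=lambda f: f.family_id):
            if fam.origin is node:
                state = dict(state)
                state[fam.family_id] = (gene_root[fam.family_id], spacer_root[fam.family_id])
        if node.is_leaf:
            tip_state[node.name] = state
            tip_terminal_spacer[node.name] = term_spacer
            return
        for child in node.children:
            d = child.edge_div
            child_state = {
                fid: (_mutate(g, d, rng), _mutate_spacer(s, d, config, rng))
                for fid, (g, s) in sorted(state.items())
            }
            descend(child, child_state, _mutate_spacer(term_spacer, d, config, rng))

    root_state = {}
    for fam in sorted(families, key=lambda f: f.family_id):
        if fam.origin is root:
            root_state[fam.family_id] = (gene_root[fam.family_id], spacer_root[fam.family_id])
    if root.is_leaf:  # degenerate; n_strains >= 2 forbids this
        raise ConfigError("n_strains", "tree root cannot be a leaf")
    # Families originating at root are in root_state; handle children.
    for child in root.children:
        d = child.edge_div
        child_state = {
            fid: (_mutate(g, d, rng), _mutate_spacer(s, d, config, rng))
            for fid, (g, s) in sorted(root_state.items())
        }
        descend(child, child_state, _mutate_spacer(terminal_spacer_root, d, config, rng))

    # Planted HGT material (donor lineage, independent of the panel tree).
    hgt_gene_ids: list[str] = []
    hgt_coords: Optional[tuple[str, int, int]] = None
    donor_panel: dict[str, list[tuple[str, str, str]]] = {}
    recipient = strains[0]
    hgt_block: list[tuple[str, np.ndarray]] = []  # (gene_id, seq), spacers interleaved
    hgt_spacers: list[np.ndarray] = []
    donor_root_genes: list[np.ndarray] = []
    if config.hgt_cluster is not None:
        h = config.hgt_cluster
        donor_gc = gc + h.gc_shift
        donor_div = 0.02  # small divergence between donor copies and the insert
        for k in range(h.n_genes):
            donor_gene = _random_gene(config.gene_len_range, donor_gc, rng)
            donor_root_genes.append(donor_gene)
            planted = _mutate(donor_gene, donor_div, rng)
            gene_id = f"{recipient}|hgt_{k:02d}"
            hgt_gene_ids.append(gene_id)
            hgt_block.append((gene_id, planted))
            relatives = []
            for r in range(2):
                rel = _mutate(donor_gene, donor_div, rng)
                relatives.append((h.donor_label, f"{h.donor_label}_{k:02d}_{r}",
                                  translate(_decode(rel))))
            donor_panel[gene_id] = relatives
        lo, hi = config.spacer_len_range
        for _ in range(h.n_genes + 1):
            hgt_spacers.append(_random_seq(int(rng.integers(lo, hi + 1)), donor_gc, rng))

    # Assemble genomes: backbone of core genes and their spacers in family
    # order, then accessory genes each preceded by its own spacer, then the
    # terminal spacer; the HGT block (if any) is inserted at a random core
    # boundary of the recipient strain.
    insert_slot = int(rng.integers(0, config.n_core + 1)) if config.hgt_cluster else -1

    proteomes: list[StrainProteome] = []
    genomes: list[StrainGenome] = []
    gene_family: dict[str, str] = {}
    table = pd.DataFrame(0, index=sorted(f.family_id for f in families),
                         columns=strains, dtype=int)

    for sid in strains:
        state = tip_state[sid]
        parts: list[str] = []
        features: list[GeneFeature] = []
        proteome = StrainProteome(sid)
        pos = 0

        def emit_spacer(seq: np.ndarray):
            nonlocal pos
            text = _decode(seq)
            parts.append(text)
            pos += len(text)

        def emit_gene(gene_id: str, seq: np.ndarray):
            nonlocal pos
            text = _decode(seq)
            parts.append(text)
            features.append(GeneFeature(sid, gene_id, pos, pos + len(text)))
            proteome.genes[gene_id] = translate(text)
            pos += len(text)

        def emit_hgt_block() -> tuple[int, int]:
            start = pos
            for k, (gene_id, seq) in enumerate(hgt_block):
                emit_spacer(hgt_spacers[k])
                emit_gene(gene_id, seq)
            emit_spacer(hgt_spacers[-1])
            return start, pos

        core_ids = sorted(f.family_id for f in families if f.kind == "core")
        accessory_ids = sorted(fid for fid in state
                               if fam_by_id[fid].kind != "core")
        slot = 0
        for fid in core_ids:
            if sid == recipient and slot == insert_slot and hgt_block:
                s, e = emit_hgt_block()
                hgt_coords = (sid, s, e)
            gene, spacer = state[fid]
            emit_spacer(spacer)
            gid = f"{sid}|{fid}"
            emit_gene(gid, gene)
            gene_family[gid] = fid
            table.loc[fid, sid] += 1
            slot += 1
        if sid == recipient and slot == insert_slot and hgt_block:
            s, e = emit_hgt_block()
            hgt_coords = (sid, s, e)
        for fid in accessory_ids:
            gene, spacer = state[fid]
            emit_spacer(spacer)
            gid = f"{sid}|{fid}"
            emit_gene(gid, gene)
            gene_family[gid] = fid
            table.loc[fid, sid] += 1
        emit_spacer(tip_terminal_spacer[sid])

        proteomes.append(proteome)
        genomes.append(StrainGenome(sid, "".join(parts), features))

    # Drop families that ended up on no strain (cannot happen under the
    # gain-only model, but keep the invariant explicit).
    table = table.loc[table.sum(axis=1) > 0]

    truth = GroundTruth(
        tree=_to_dendropy(root),
        family_table=table,
        true_ani=_true_ani_table(root),
        hgt_gene_ids=hgt_gene_ids,
        hgt_cluster_coords=hgt_coords,
        donor_panel=donor_panel,
        gene_family=gene_family,
    )
    return proteomes, genomes, truth


# ---------------------------------------------------------------------------
# Convenience panel builders used throughout tests and calibration studies.


def clade_panel_newick(n_clades: int, strains_per_clade: int,
                       within_div: float, between_div: float) -> tuple[str, int]:
    """Newick for a panel of ``n_clades`` equally sized clades.

    Within-clade terminal branches get ``within_div``; the stem of each
    clade gets ``between_div`` so between-clade identity is governed by two
    stems plus two terminal branches.
    """
    clades = []
    idx = 0
    for c in range(n_clades):
        tips = []
        for _ in range(strains_per_clade):
            tips.append(f"S{idx:02d}:{within_div}")
            idx += 1
        # ladderize tips into a binary subtree with zero-length internals
        sub = tips[0]
        for tip in tips[1:]:
            sub = f"({sub},{tip}):0.0"
        # outermost gets the clade stem
        sub = sub.rsplit(":", 1)[0] + f":{between_div}"
        clades.append(sub)
    tree = clades[0]
    for clade in clades[1:]:
        tree = f"({tree},{clade}):0.0"
    return tree.rsplit(":", 1)[0] + ";", idx


def two_strain_config(rate: float, seed: int = 0, n_core: int = 12,
                      **overrides) -> SimulationConfig:
    """A two-strain panel whose pairwise substitution distance is ``rate``.

    Each terminal branch carries rate/2 so expected identity is
    approximately 1 - rate.
    """
    cfg = SimulationConfig(
        n_strains=2, n_core=n_core, dispensable_rate=0.0, unique_per_strain=0.0,
        per_branch_divergence=rate / 2.0,
        tree_newick=f"(S00:{rate / 2.0},S01:{rate / 2.0});",
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# Writers


def write_panel(proteomes, genomes, truth, outdir) -> None:
    """Write FASTAs, the GFF-lite table and the ground-truth JSON."""
    from pathlib import Path
    from . import io as bio_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for proteome in proteomes:
        bio_io.write_fasta(
            ((gid, seq) for gid, seq in sorted(proteome.genes.items())),
            outdir / f"{proteome.strain_id}.faa",
        )
    for genome in genomes:
        bio_io.write_fasta([(genome.strain_id, genome.sequence)],
                           outdir / f"{genome.strain_id}.fna")
    rows = []
    for genome in genomes:
        for feat in genome.features:
            rows.append((feat.strain_id, feat.gene_id, feat.start, feat.end, feat.strand))
    pd.DataFrame(rows, columns=["strain", "gene_id", "start", "end", "strand"]).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    truth_json = {
        "tree_newick": truth.tree_newick(),
        "family_table": {fid: truth.family_table.loc[fid].to_dict()
                         for fid in truth.family_table.index},
        "true_ani": {a: truth.true_ani.loc[a].to_dict() for a in truth.true_ani.index},
        "hgt_gene_ids": truth.hgt_gene_ids,
        "hgt_cluster_coords": list(truth.hgt_cluster_coords) if truth.hgt_cluster_coords else None,
        "gene_family": truth.gene_family,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
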