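"""Ortholog gene-family construction from threshold-passing similarity hits.

Families are the connected components of the undirected pass-graph over all
genes: if a--b and b--c both pass the identity/coverage/e-value filters,
{a, b, c} is one family even if a--c itself fails (single-linkage
transitivity, as in gene-family pan-genome pipelines). Genes with no
passing edge are singleton families. An MCL-style option (Markov
clustering, inflation 1.5) is available for sensitivity analysis; the
default is connected components, which is deterministic and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .align import SimilarityHit
from .errors import InputError


@dataclass
class OrthologFamily:
    family_id: str
    members: list[tuple[str, str]]  # (strain_id, gene_id)
    is_single_copy_core: bool = False

    def strains(self) -> set[str]:
        return {s for s, _ in self.members}


@dataclass
class PresenceAbsenceMatrix:
    """Families x strains copy-count table, the pivot of the pipeline."""

    df: pd.DataFrame  # int copy counts, index=family ids, columns=strain ids

    def __post_init__(self):
        if (self.df.sum(axis=1) == 0).any():
            bad = self.df.index[self.df.sum(axis=1) == 0].tolist()
            raise InputError(f"all-zero row(s) in presence-absence matrix: {bad[:5]}")
        if (self.df.values < 0).any():
            raise InputError("negative copy counts in presence-absence matrix")

    @property
    def strains(self) -> list[str]:
        return list(self.df.columns)

    @property
    def families(self) -> list[str]:
        return list(self.df.index)

    def presence(self) -> pd.DataFrame:
        return self.df > 0

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="family_id")

    @classmethod
    def read_tsv(cls, path) -> "PresenceAbsenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="family_id"))


def _strain_of(gene_id: str, gene_strain: Mapping[str, str] | None) -> str:
    if gene_strain is not None:
        return gene_strain[gene_id]
    # simulator convention: gene ids are "<strain>|<family>"
    if "|" in gene_id:
        return gene_id.split("|", 1)[0]
    raise InputError(f"cannot infer strain for gene {gene_id!r}; pass gene_strain")


def cluster_families(hits: Iterable[SimilarityHit], all_gene_ids: Sequence[str],
                     gene_strain: Mapping[str, str] | None = None,
                     strain_ids: Sequence[str] | None = None,
                     method: str = "components",
                     inflation: float = 1.5) -> list[OrthologFamily]:
    """Partition the gene universe into ortholog families.

    ``hits`` must already be threshold-filtered (all_vs_all does this).
    ``all_gene_ids`` is the full gene universe including hit-less genes.
    Family ids are the lexicographically smallest member gene id, so the
    output is deterministic regardless of hit order.
    """
    universe = list(dict.fromkeys(all_gene_ids))
    if len(universe) != len(all_gene_ids):
        raise InputError("duplicate gene ids in universe")
    uset = set(universe)
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for hit in hits:
        for gid in (hit.query_id, hit.subject_id):
            if gid not in uset:
                raise InputError(f"hit references gene {gid!r} outside the universe")
        if hit.query_id != hit.subject_id:
            graph.add_edge(hit.query_id, hit.subject_id, weight=hit.bit_score)

    if method == "components":
        components = [sorted(c) for c in nx.connected_components(graph)]
    elif method == "mcl":
        components = _mcl_components(graph, universe, inflation)
    else:
        raise InputError(f"unknown clustering method {method!r}")

    if strain_ids is None:
        strain_ids = sorted({_strain_of(g, gene_strain) for g in universe})
    all_strains = set(strain_ids)

    families = []
    for comp in sorted(components, key=lambda c: c[0]):
        members = sorted((_strain_of(g, gene_strain), g) for g in comp)
        strains = [s for s, _ in members]
        single_copy_core = (
            set(strains) == all_strains and len(strains) == len(all_strains)
        )
        families.append(OrthologFamily(
            family_id=comp[0], members=members,
            is_single_copy_core=single_copy_core,
        ))
    return families


def _mcl_components(graph: nx.Graph, universe: Sequence[str],
                    inflation: float, max_iter: int = 100,
                    tol: float = 1e-8) -> list[list[str]]:
    """Markov clustering on the pass-graph (expansion 2, given inflation)."""
    idx = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = max(data.get("weight", 1.0), 1.0)
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    # Self-loops weighted like the heaviest incident edge prevent the
    # period-2 oscillation MCL exhibits on near-bipartite graphs.
    loops = np.maximum(m.max(axis=0), 1.0)
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated
    # attractors: rows with any mass; cluster = genes attracted to same rows
    clusters: dict[frozenset, set] = {}
    attract = m > 1e-6
    assign = nx.Graph()
    assign.add_nodes_from(range(n))
    for col in range(n):
        rows = np.nonzero(attract[:, col])[0]
        for r in rows:
            assign.add_edge(int(r), col)
    return [sorted(universe[i] for i in comp)
            for comp in nx.connected_components(assign)]


def build_matrix(families: Sequence[OrthologFamily],
                 strains: Sequence[str]) -> PresenceAbsenceMatrix:
    """Copy-count matrix with deterministic (sorted) row and column order."""
    strains = sorted(strains)
    fam_ids = sorted(f.family_id for f in families)
    if len(set(fam_ids)) != len(fam_ids):
        raise InputError("duplicate family ids")
    df = pd.DataFrame(0, index=fam_ids, columns=strains, dtype=int)
    for fam in families:
        for strain_id, _gene in fam.members:
            if strain_id not in df.columns:
                raise InputError(f"family {fam.family_id!r} references unknown "
                                 f"strain {strain_id!r}")
            df.loc[fam.family_id, strain_id] += 1
    return PresenceAbsenceMatrix(df)


def write_families_tsv(families: Sequence[OrthologFamily], path) -> None:
    rows = [(f.family_id, s, g) for f in families for s, g in f.members]
    pd.DataFrame(rows, columns=["family_id", "strain_id", "gene_id"]).to_csv(
        path, sep="\t", index=False)


def read_families_tsv(path, strain_ids: Sequence[str] | None = None) -> list[OrthologFamily]:
    df = pd.read_csv(path, sep="\t")
    families = []
    strains_seen = set(df["strain_id"]) if strain_ids is None else set(strain_ids)
    for fid, sub in df.groupby("family_id", sort=True):
        members = sorted(zip(sub["strain_id"], sub["gene_id"]))
        strains = [s for s, _ in members]
        families.append(OrthologFamily(
            family_id=str(fid), members=members,
            is_single_copy_core=(set(strains) == strains_seen
                                 and len(strains) == len(strains_seen)),
        ))
    return families
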