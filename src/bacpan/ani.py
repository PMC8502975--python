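"""Fragment-based average nucleotide identity (ANIb-style) and species grouping.

The query genome is cut into consecutive non-overlapping 1,020-bp
fragments, each locally aligned against the whole subject genome. A
fragment contributes to ANI only if its best local alignment has at least
30% identity and covers at least 70% of the fragment; ANI is the mean
identity of contributing fragments, in percent. These retention parameters
are the published defaults of the JSpecies/ANIb lineage of tools. The
reported per-pair value is the mean of the two directions, and strains are
grouped into species as connected components of the >95% ANI graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align import NucleotideScoring, make_nucleotide_aligner
from .errors import InputError

#: Sentinel for pairs where every fragment was filtered out: "no measurable
#: nucleotide identity", distinct from an identity of zero.
UNDEFINED_ANI = float("nan")


@dataclass(frozen=True)
class AniParams:
    fragment_len: int = 1020
    min_identity: float = 0.30  # of alignment columns
    min_alignable: float = 0.70  # aligned fragment span / fragment length
    scoring: NucleotideScoring = NucleotideScoring()


@dataclass
class AniMatrix:
    """Symmetrized percent-identity matrix with per-pair fragment counts."""

    values: pd.DataFrame  # percent, strains x strains, diagonal 100
    n_fragments_used: pd.DataFrame  # ordered-pair fragment counts

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="strain")


@dataclass
class SpeciesGrouping:
    threshold: float
    groups: list[list[str]]  # partition of strains, each group sorted

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def compute_ani(genome_a: str, genome_b: str,
                params: AniParams | None = None) -> tuple[float, int]:
    """Directional ANI of genome_a against genome_b.

    Returns (percent identity, number of retained fragments). If every
    fragment fails the 30%-identity/70%-alignable retention rule the ANI is
    undefined and NaN is returned (never 0).
    """
    params = params or AniParams()
    flen = params.fragment_len
    for name, g in (("genome_a", genome_a), ("genome_b", genome_b)):
        if len(g) < 2 * flen:
            raise InputError(f"{name} shorter than two fragment lengths "
                             f"({len(g)} < {2 * flen})")
    aligner = make_nucleotide_aligner(params.scoring)
    identities = []
    n_fragments = len(genome_a) // flen
    for i in range(n_fragments):
        frag = genome_a[i * flen:(i + 1) * flen]
        alignments = aligner.align(frag, genome_b)
        try:
            best = alignments[0]
        except IndexError:
            continue
        counts = best.counts()
        aln_len = counts.identities + counts.mismatches + counts.gaps
        if aln_len == 0:
            continue
        frag_blocks = best.aligned[0]
        frag_span = int(frag_blocks[-1][-1] - frag_blocks[0][0])
        identity = counts.identities / aln_len
        if identity >= params.min_identity and frag_span >= params.min_alignable * flen:
            identities.append(identity)
    if not identities:
        return UNDEFINED_ANI, 0
    return 100.0 * float(np.mean(identities)), len(identities)


def ani_matrix(genomes: Sequence[tuple[str, str]],
               params: AniParams | None = None) -> AniMatrix:
    """All ordered pairs; the reported value is the mean of both directions.

    Per-pair errors (genome too short, undefined ANI) are recorded as NaN
    cells rather than aborting the whole matrix.
    """
    if len(genomes) < 2:
        raise InputError("need at least 2 genomes")
    params = params or AniParams()
    names = [name for name, _ in genomes]
    if len(set(names)) != len(names):
        raise InputError("duplicate genome names")
    seqs = dict(genomes)
    directional = pd.DataFrame(np.nan, index=names, columns=names)
    nfrag = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        directional.loc[a, a] = 100.0
        for b in names:
            if a == b:
                continue
            try:
                value, n = compute_ani(seqs[a], seqs[b], params)
            except InputError:
                value, n = UNDEFINED_ANI, 0
            directional.loc[a, b] = value
            nfrag.loc[a, b] = n
    sym = (directional + directional.T) / 2.0
    np.fill_diagonal(sym.values, 100.0)
    return AniMatrix(values=sym, n_fragments_used=nfrag)


def species_groups(matrix: AniMatrix, threshold: float = 95.0) -> SpeciesGrouping:
    """Species = connected components of the ANI > threshold graph.

    Undefined (NaN) pairs never link strains, i.e. they count as below
    threshold.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(matrix.strains)
    vals = matrix.values
    for i, a in enumerate(matrix.strains):
        for b in matrix.strains[i + 1:]:
            v = vals.loc[a, b]
            if not math.isnan(v) and v > threshold:
                graph.add_edge(a, b)
    groups = sorted(sorted(c) for c in nx.connected_components(graph))
    return SpeciesGrouping(threshold=threshold, groups=groups)
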