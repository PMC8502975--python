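"""Horizontal-transfer screening by GC anomaly and gene-tree placement.

Two independent signals, mirroring the parametric/phylogenetic split of
HGT detection methods:

* **Composition**: the candidate cluster's GC content is compared with the
  distribution of same-length sliding windows over the host genome
  (windows overlapping the cluster are excluded from the background). The
  cluster is flagged when |z| >= 2 by default. This is a formalization of
  the visual cluster-vs-genome GC contrast; the threshold is configurable.
* **Placement**: a neighbor-joining gene tree over the candidate protein
  plus a labeled reference panel (self genus + foreign genera). The
  candidate's placement taxon is the lineage label of its nearest leaf by
  tree path length; the gene is flagged when that lineage is not the self
  genus. Ties break to the lexicographically first label and are marked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import global_pdistance
from .errors import InputError
from .phylogeny import DistanceMatrix, nj_tree


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases; N is excluded from both sides."""
    if not seq:
        raise InputError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise InputError("sequence contains no unambiguous bases")
    return gc / (gc + at)


@dataclass
class GcProfile:
    window_gc: np.ndarray
    background_mean: float
    background_sd: float
    window_len: int
    step: int


@dataclass
class HgtFlag:
    cluster_id: str
    cluster_gc: Optional[float] = None
    genome_gc: Optional[float] = None
    z_score: Optional[float] = None
    gc_flagged: Optional[bool] = None
    placement_taxon: Optional[str] = None
    placement_flagged: Optional[bool] = None
    placement_tie: bool = False


def gc_profile(genome: str, window_len: int, step: int,
               exclude: Optional[tuple[int, int]] = None) -> GcProfile:
    """Sliding-window GC fractions; windows overlapping ``exclude`` are
    dropped from the background statistics."""
    if window_len < 1 or window_len > len(genome):
        raise InputError("window longer than genome")
    if step < 1:
        raise InputError("step must be >= 1")
    starts = range(0, len(genome) - window_len + 1, step)
    values = []
    for s in starts:
        if exclude is not None and s < exclude[1] and s + window_len > exclude[0]:
            continue
        values.append(gc_content(genome[s:s + window_len]))
    if not values:
        raise InputError("no background windows left after exclusion")
    arr = np.asarray(values)
    return GcProfile(
        window_gc=arr,
        background_mean=float(arr.mean()),
        background_sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        window_len=window_len,
        step=step,
    )


def gc_zscore(cluster_coords: tuple[int, int], genome: str,
              window_len: Optional[int] = None, step: Optional[int] = None,
              z_threshold: float = 2.0, cluster_id: str = "cluster",
              exclude_cluster: bool = True) -> HgtFlag:
    """Composition screen: cluster GC versus same-length window background.

    Coordinates are 0-based half-open. The window length defaults to the
    cluster length and the step to window_len // 10 (at least 1).
    """
    start, end = cluster_coords
    if start < 0 or end > len(genome) or start >= end:
        raise InputError(f"cluster [{start},{end}) outside genome of length {len(genome)}")
    cluster = genome[start:end]
    window_len = window_len or (end - start)
    if window_len > len(genome):
        raise InputError("window/cluster longer than genome")
    step = step or max(window_len // 10, 1)
    profile = gc_profile(genome, window_len, step,
                         exclude=(start, end) if exclude_cluster else None)
    cluster_gc = gc_content(cluster)
    if profile.background_sd > 0:
        z = (cluster_gc - profile.background_mean) / profile.background_sd
    else:
        z = 0.0 if cluster_gc == profile.background_mean else float("inf")
    return HgtFlag(
        cluster_id=cluster_id,
        cluster_gc=cluster_gc,
        genome_gc=gc_content(genome),
        z_score=float(z),
        gc_flagged=bool(abs(z) >= z_threshold),
    )


def placement_test(gene_seq: str, reference_panel: Sequence[tuple[str, str, str]],
                   self_label: str, gene_id: str = "query") -> HgtFlag:
    """Phylogenetic screen: where does the gene fall among labeled lineages?

    ``reference_panel`` rows are (lineage label, sequence id, protein
    sequence). Requires at least two distinct labels and three sequences.
    """
    labels = {label for label, _, _ in reference_panel}
    if len(labels) < 2:
        raise InputError("reference panel must contain at least 2 lineage labels")
    if len(reference_panel) < 3:
        raise InputError("reference panel must contain at least 3 sequences")
    names = [gene_id] + [sid for _, sid, _ in reference_panel]
    if len(set(names)) != len(names):
        raise InputError("duplicate sequence ids in panel")
    seqs = [gene_seq] + [seq for _, _, seq in reference_panel]
    label_of = {sid: label for label, sid, _ in reference_panel}
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nd, nt = global_pdistance(seqs[i], seqs[j])
            d[i, j] = d[j, i] = nd / nt if nt else 1.0
    tree = nj_tree(DistanceMatrix(names, d))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    query = taxa[gene_id]
    dists = []
    for leaf_label, taxon in taxa.items():
        if leaf_label == gene_id:
            continue
        dists.append((float(pdm.patristic_distance(query, taxon)), leaf_label))
    dists.sort()
    best_dist = dists[0][0]
    nearest = [label_of[sid] for dist, sid in dists if abs(dist - best_dist) <= 1e-12]
    tie = len(set(nearest)) > 1
    placement = sorted(set(nearest))[0]
    return HgtFlag(
        cluster_id=gene_id,
        placement_taxon=placement,
        placement_flagged=bool(placement != self_label),
        placement_tie=tie,
    )
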