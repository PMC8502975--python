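"""Pairwise local alignment of proteins and nucleotide fragments.

Every similarity used downstream (ortholog clustering, ANI fragments,
concatenated core distances) funnels through the dynamic-programming
aligner configured here, so thresholds and score conventions live in one
place. Protein scoring is BLOSUM62 with affine gaps (open 11, extend 1),
the conventional defaults of the prokaryotic pan-genome pipelines this
package emulates; ambiguous residues (``X``) are tolerated and scored 0
against everything. Nucleotide scoring is +1/-1 with gap open 4, extend 1.

Raw Smith-Waterman scores are converted to bit scores with the standard
gapped BLOSUM62(11,1) Karlin-Altschul constants (lambda = 0.267,
K = 0.041) and the e-value is the plain bit-score identity
``E = m * n * 2**(-bits)`` over the per-pair search space, without
edge-length corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_ALPHABET = frozenset(AA20 + "X")

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
# (the values BLAST reports for this scoring system).
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring for protein comparisons.

    ``gap_open`` is the cost of opening a gap and ``gap_extend`` the cost of
    each gapped position, i.e. a gap of length L costs gap_open + L*gap_extend.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = KA_LAMBDA
    ka_k: float = KA_K


@dataclass(frozen=True)
class NucleotideScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class ClusterThresholds:
    """Hit filters for ortholog family construction.

    Defaults follow the GF-method convention: at least 50% identity, at
    least 50% overlap with the longer sequence, e-value at most 1e-5.
    """

    min_identity: float = 0.5
    min_coverage_longest: float = 0.5
    max_evalue: float = 1e-5


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise comparison that may enter the ortholog pass-graph."""

    query_id: str
    subject_id: str
    percent_identity: float  # fraction in [0, 1] over all alignment columns
    coverage_longest: float  # aligned span / length of the longer sequence
    bit_score: float
    e_value: float
    aln_length: int
    n_identical: int = 0
    n_mismatch: int = 0
    n_gaps: int = 0
    raw_score: float = 0.0

    def passes(self, thresholds: ClusterThresholds) -> bool:
        return (
            self.percent_identity >= thresholds.min_identity
            and self.coverage_longest >= thresholds.min_coverage_longest
            and self.e_value <= thresholds.max_evalue
        )


def _protein_matrix(params: ScoringParams):
    m = substitution_matrices.load(params.matrix_name)
    # X is tolerated but neutral: zero against every residue, including X.
    alphabet = m.alphabet
    if "X" in alphabet:
        xi = alphabet.index("X")
        m[xi, :] = 0.0
        m[:, xi] = 0.0
    return m


def make_protein_aligner(params: ScoringParams | None = None, mode: str = "local") -> Align.PairwiseAligner:
    params = params or ScoringParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _protein_matrix(params)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global":
        # End gaps in global protein alignments are free deletions/insertions
        # of terminal overhangs, matching semi-global ortholog alignment.
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def make_nucleotide_aligner(params: NucleotideScoring | None = None) -> Align.PairwiseAligner:
    params = params or NucleotideScoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise InputError(f"{name}: empty protein sequence")
    seq = seq.upper()
    bad = set(seq) - _PROTEIN_ALPHABET
    if bad:
        raise InputError(
            f"{name}: unknown residue(s) {sorted(bad)}; only the 20 amino acids plus X are accepted"
        )
    return seq


def bits_from_raw(raw_score: float, params: ScoringParams | None = None) -> float:
    """Convert a raw alignment score to bits: S' = (lambda*S - ln K) / ln 2."""
    params = params or ScoringParams()
    bits = (params.ka_lambda * raw_score - math.log(params.ka_k)) / math.log(2.0)
    return max(bits, 0.0)


def evalue(bit_score: float, m: int, n: int) -> float:
    """Expected chance hits: E = m * n * 2**(-bits) over an m x n search space."""
    if bit_score < 0:
        raise InputError("bit_score must be non-negative")
    if m < 1 or n < 1:
        raise InputError("sequence lengths must be >= 1")
    return float(m) * float(n) * 2.0 ** (-bit_score)


def _hit_from_alignment(aln, query_id: str, subject_id: str, len_a: int, len_b: int,
                        params: ScoringParams) -> SimilarityHit:
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    gaps = counts.gaps  # local mode: no terminal gaps, all gaps internal
    aln_length = identities + mismatches + gaps
    if aln_length == 0:
        # No positively scoring local alignment exists at all.
        bits = bits_from_raw(0.0, params)
        return SimilarityHit(query_id, subject_id, 0.0, 0.0, bits,
                             evalue(bits, len_a, len_b), 0)
    # Span measured on the longer of the two sequences, per the
    # "overlap with the longest sequence" convention.
    tgt_blocks, qry_blocks = aln.aligned
    tgt_span = int(tgt_blocks[-1][-1] - tgt_blocks[0][0])
    qry_span = int(qry_blocks[-1][-1] - qry_blocks[0][0])
    longest = max(len_a, len_b)
    if len_a > len_b:
        span_on_longest = tgt_span
    elif len_b > len_a:
        span_on_longest = qry_span
    else:
        # Equal lengths: take the larger span so the value is symmetric
        # under query/subject exchange.
        span_on_longest = max(tgt_span, qry_span)
    identity = identities / aln_length
    coverage = span_on_longest / longest
    bits = bits_from_raw(aln.score, params)
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=identity,
        coverage_longest=min(coverage, 1.0),
        bit_score=bits,
        e_value=evalue(bits, len_a, len_b),
        aln_length=int(aln_length),
        n_identical=int(identities),
        n_mismatch=int(mismatches),
        n_gaps=int(gaps),
        raw_score=float(aln.score),
    )


def align_proteins(a: str, b: str, scoring: ScoringParams | None = None,
                   query_id: str = "query", subject_id: str = "subject") -> SimilarityHit:
    """Smith-Waterman local alignment of two protein sequences.

    Identity is identical columns over all alignment columns (gap columns
    count in the denominator); coverage is the aligned span on the longer
    sequence divided by that sequence's length.
    """
    scoring = scoring or ScoringParams()
    a = _check_protein(a, "sequence a")
    b = _check_protein(b, "sequence b")
    # The optimal score is symmetric under swapping, but the traceback may
    # pick different co-optimal alignments for (a,b) and (b,a). Aligning the
    # canonically ordered pair makes identity/coverage exactly symmetric.
    if (len(b), b) < (len(a), a):
        a, b = b, a
    aligner = make_protein_aligner(scoring, mode="local")
    alignments = aligner.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        best = None
    if best is None:
        bits = bits_from_raw(0.0, scoring)
        return SimilarityHit(query_id, subject_id, 0.0, 0.0, bits,
                             evalue(bits, len(a), len(b)), 0)
    return _hit_from_alignment(best, query_id, subject_id, len(a), len(b), scoring)


def all_vs_all(proteomes: Sequence, scoring: ScoringParams | None = None,
               thresholds: ClusterThresholds | None = None) -> list[SimilarityHit]:
    """Exhaustive all-against-all protein comparison across strains.

    Emits one undirected hit per unordered gene pair that passes every
    threshold (identity >= 50%, coverage of the longer sequence >= 50%,
    e-value <= 1e-5 by default). Self-comparisons are skipped. Genes within
    the same strain ARE compared (paralog families are allowed).
    """
    scoring = scoring or ScoringParams()
    thresholds = thresholds or ClusterThresholds()
    genes: list[tuple[str, str]] = []  # (gene_id, sequence)
    seen: set[str] = set()
    for proteome in proteomes:
        for gene_id, seq in proteome.items():
            if gene_id in seen:
                raise InputError(f"duplicate gene id {gene_id!r} across proteomes")
            seen.add(gene_id)
            genes.append((gene_id, _check_protein(seq, gene_id)))
    aligner = make_protein_aligner(scoring, mode="local")
    hits: list[SimilarityHit] = []
    for i in range(len(genes)):
        id_a, seq_a = genes[i]
        for j in range(i + 1, len(genes)):
            id_b, seq_b = genes[j]
            sa, sb = seq_a, seq_b
            if (len(sb), sb) < (len(sa), sa):  # canonical order, see align_proteins
                sa, sb = sb, sa
            alignments = aligner.align(sa, sb)
            try:
                best = alignments[0]
            except IndexError:
                continue
            hit = _hit_from_alignment(best, id_a, id_b, len(seq_a), len(seq_b), scoring)
            if hit.passes(thresholds):
                hits.append(hit)
    return hits


def global_pdistance(a: str, b: str, scoring: ScoringParams | None = None) -> tuple[int, int]:
    """Needleman-Wunsch alignment returning (differing, total) non-gap columns.

    Used for concatenated single-copy-core distances: columns where either
    sequence is gapped are excluded; the p-distance is differing/total.
    """
    a = _check_protein(a, "sequence a")
    b = _check_protein(b, "sequence b")
    aligner = make_protein_aligner(scoring, mode="global")
    best = aligner.align(a, b)[0]
    counts = best.counts()
    total = counts.identities + counts.mismatches
    return int(counts.mismatches), int(total)


def write_hits_tsv(hits: Iterable[SimilarityHit], path) -> None:
    """Write hits as 12-column BLAST outfmt-6 style TSV.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Start/end positions are not tracked by the
    clustering pipeline and are written as 0; identity is printed as a
    percentage with two decimals, as BLAST does.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100.0 * h.percent_identity:.2f}\t"
                f"{h.aln_length}\t{h.n_mismatch}\t{h.n_gaps}\t0\t0\t0\t0\t"
                f"{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


def read_hits_tsv(path) -> list[SimilarityHit]:
    hits = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise InputError(f"{path}:{line_no}: expected 12 tab-separated columns")
            hits.append(
                SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]) / 100.0,
                    coverage_longest=1.0,  # not representable in outfmt 6
                    bit_score=float(parts[11]),
                    e_value=float(parts[10]),
                    aln_length=int(parts[3]),
                    n_mismatch=int(parts[4]),
                    n_gaps=int(parts[5]),
                )
            )
    return hits
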