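"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA parsing is delegated to Bio.SeqIO; this module adds the validation
the pipeline relies on (unique ids, non-empty records, uppercasing) and
byte-stable 60-column output so write-then-read round-trips exactly.
The gene-coordinate table ("GFF-lite") is a 5-column TSV:
strain, gene_id, start, end, strand with 0-based half-open coordinates.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import InputError

GFF_LITE_COLUMNS = ["strain", "gene_id", "start", "end", "strand"]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs.

    Duplicate ids and empty records are format errors reported with the
    header's line number. CRLF and LF input parse identically.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    records = []
    with open(path) as fh:
        text = fh.read()
    header_lines = [i + 1 for i, line in enumerate(text.splitlines())
                    if line.startswith(">")]
    seen: dict[str, int] = {}
    for k, rec in enumerate(SeqIO.parse(_io.StringIO(text), "fasta")):
        line_no = header_lines[k] if k < len(header_lines) else 0
        if rec.id in seen:
            raise InputError(f"{path}:{line_no}: duplicate record id {rec.id!r} "
                             f"(first seen at line {seen[rec.id]})")
        seen[rec.id] = line_no
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"{path}:{line_no}: empty record {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write records with fixed 60-column wrapping (byte-stable round trip)."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff_lite(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GFF_LITE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    return df[GFF_LITE_COLUMNS]


def write_gff_lite(df: pd.DataFrame, path) -> None:
    df[GFF_LITE_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GenomeSummary:
    """One replicon row of the genome summary table."""

    replicon_name: str
    length_bp: int
    gc_percent: float  # to 2 decimal places
    n_cds: int
    coding_percent: float
    mean_cds_len_bp: int  # rounded half-up


def _round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _merged_span(intervals: list[tuple[int, int]]) -> int:
    """Total covered length after merging overlapping intervals."""
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start >= last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def genome_summary(replicons: Sequence[tuple[str, str]],
                   cds_table: pd.DataFrame) -> list[GenomeSummary]:
    """Per-replicon summary rows plus a "Total" row.

    ``replicons`` are (name, nucleotide sequence) pairs; ``cds_table`` is a
    GFF-lite frame whose ``strain`` column names the replicon each CDS lies
    on. Coding percentage merges overlapping CDS before summing; the mean
    CDS length is rounded half-up to the nearest bp.
    """
    from .hgt import gc_content

    rows: list[GenomeSummary] = []
    seqs = dict(replicons)
    grand_len = 0
    grand_cds: list[int] = []
    grand_coding = 0
    gc_num = 0
    gc_den = 0
    for name, seq in replicons:
        sub = cds_table[cds_table["strain"] == name]
        intervals = []
        for _, row in sub.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if start < 0 or end > len(seq) or start >= end:
                raise InputError(
                    f"CDS {row['gene_id']!r} [{start},{end}) out of bounds "
                    f"for replicon {name!r} of length {len(seq)}")
            intervals.append((start, end))
        coding = _merged_span(intervals)
        lengths = [e - s for s, e in intervals]
        n_gc = sum(seq.count(b) for b in "GCgc")
        n_acgt = sum(seq.count(b) for b in "ACGTacgt")
        rows.append(GenomeSummary(
            replicon_name=name,
            length_bp=len(seq),
            gc_percent=_round_half_up(100.0 * gc_content(seq), 2),
            n_cds=len(intervals),
            coding_percent=_round_half_up(100.0 * coding / len(seq), 2),
            mean_cds_len_bp=int(_round_half_up(sum(lengths) / len(lengths))) if lengths else 0,
        ))
        grand_len += len(seq)
        grand_cds.extend(lengths)
        grand_coding += coding
        gc_num += n_gc
        gc_den += n_acgt
    unknown = set(cds_table["strain"]) - set(seqs)
    if unknown:
        raise InputError(f"CDS table names unknown replicon(s) {sorted(unknown)}")
    rows.append(GenomeSummary(
        replicon_name="Total",
        length_bp=grand_len,
        gc_percent=_round_half_up(100.0 * gc_num / gc_den, 2) if gc_den else 0.0,
        n_cds=len(grand_cds),
        coding_percent=_round_half_up(100.0 * grand_coding / grand_len, 2) if grand_len else 0.0,
        mean_cds_len_bp=int(_round_half_up(sum(grand_cds) / len(grand_cds))) if grand_cds else 0,
    ))
    return rows


def summary_totals(per_replicon: Sequence[GenomeSummary]) -> tuple[int, int]:
    """Arithmetic totals (length, CDS count) from already-summarized rows."""
    rows = [r for r in per_replicon if r.replicon_name != "Total"]
    return sum(r.length_bp for r in rows), sum(r.n_cds for r in rows)


def summary_table(rows: Sequence[GenomeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.replicon_name, r.length_bp, r.gc_percent, r.n_cds,
          r.coding_percent, r.mean_cds_len_bp) for r in rows],
        columns=["replicon", "length_bp", "gc_percent", "n_cds",
                 "coding_percent", "mean_cds_len_bp"],
    )
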