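"""Readers and writers for the plain-text dialects the pipeline consumes.

BED3/BED6 (tab-separated, no header, half-open coordinates), bedGraph
coverage, FASTA (via Biopython), and the TSV tables for junction counts,
library sizes, circRNA metadata and qPCR Ct values.  All writers emit
deterministically sorted output.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .intervals import Coverage, GenomicInterval, sort_intervals


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6; columns beyond the sixth are ignored, strand dropped."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 0.0
            out.append(GenomicInterval(chrom, start, end, score=score, name=name))
    return sort_intervals(out)


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write BED6 when any name/score is set, else BED3; sorted output."""
    ivs = sort_intervals(intervals)
    six = any(iv.name or iv.score for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{iv.score:g}\t.\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path: str | os.PathLike) -> Coverage:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            records.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return Coverage.from_records(records)


def write_bedgraph(coverage: Coverage, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in coverage.records():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """id -> sequence (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_desc(path: str | os.PathLike) -> dict[str, tuple[str, str]]:
    """id -> (sequence, description)."""
    return {
        rec.id: (str(rec.seq).upper(), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | os.PathLike,
                descriptions: Mapping[str, str] | None = None) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else list(seqs)
    records = [
        SeqRecord(Seq(s), id=name,
                  description=(descriptions or {}).get(name, ""))
        for name, s in items
    ]
    SeqIO.write(records, str(path), "fasta")


COUNT_COLUMNS = ["circ_id", "condition", "compartment", "replicate", "count"]


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing count columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_library_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "library_size"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns sample, library_size")
    return dict(zip(df["sample"], df["library_size"].astype(int)))


def read_qpcr_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "target" not in df.columns:
        raise ValidationError(f"{path}: qPCR table needs a 'target' column")
    return df
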