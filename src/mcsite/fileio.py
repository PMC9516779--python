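"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open. FASTA/FASTQ go through
Biopython; tabular formats (BED, bedGraph, cytosine call tables) are plain
pandas frames with fixed column names.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CALL_COLUMNS = ["chrom", "pos0", "strand", "context", "mc_count", "total_count"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterable[Tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[Tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file; malformed lines fail with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: BED interval start >= end")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3] if len(fields) > 3 else ".",
                    "score": fields[4] if len(fields) > 4 else ".",
                    "strand": fields[5] if len(fields) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BEDGRAPH_COLUMNS, comment="#",
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[BEDGRAPH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine methylation call table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table {path} missing columns: {sorted(missing)}")
    return df


def write_calls(df: pd.DataFrame, path: str | Path) -> None:
    df[CALL_COLUMNS].to_csv(path, sep="\t", index=False)
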