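"""Sequence and table I/O (FASTA/FASTQ via Biopython, TSV via pandas)."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Multi-contig FASTA (wrapped or unwrapped, case-insensitive) as an
    ordered name -> uppercase sequence mapping."""
    path = Path(path)
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = str(rec.seq).upper()
    except (ValueError, FileNotFoundError) as exc:
        raise ValueError(f"cannot read FASTA {path}: {exc}") from exc
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str] | list[tuple[str, str]], path, header: str | None = None) -> None:
    """Write records; ``header`` (e.g. run provenance) goes into the first
    record's description, since FASTA has no comment syntax."""
    items = list(seqs.items() if isinstance(seqs, dict) else seqs)
    records = [
        SeqRecord(Seq(s), id=name, description=header if (i == 0 and header) else "")
        for i, (name, s) in enumerate(items)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def iter_fastq_seqs(path):
    """Yield read sequences from a FASTQ file (.gz allowed)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        n = 0
        for rec in SeqIO.parse(fh, "fastq"):
            n += 1
            yield str(rec.seq).upper()
    if n == 0:
        raise ValueError(f"no parseable reads in {path}")


def write_fastq(reads, path) -> None:
    """Write (name, seq) pairs as FASTQ with a flat quality score."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_tsv(rows: list[dict], path, header: str | None = None, columns=None) -> None:
    df = pd.DataFrame(rows, columns=columns)
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)
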