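"""Readers and writers for the plain-text formats the pipeline speaks.

All genomic coordinates are 0-based half-open (BED convention).  Gzipped
outputs are written with a zeroed mtime so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTQ


def open_gzip_text_deterministic(path, mode: str = "wt", compresslevel: int = 1):
    """Gzip text handle with mtime=0 and no filename header."""
    raw = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"),
                        mtime=0, compresslevel=compresslevel)
    return _io.TextIOWrapper(raw, encoding="ascii", newline="\n")


class FastqQuadWriter:
    """Writes synchronized R1/R2/I1/I2 FASTQ.gz files for one modality."""

    def __init__(self, directory, prefix: str):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.paths = {
            src: directory / f"{prefix}_{src}.fastq.gz"
            for src in ("R1", "R2", "I1", "I2")
        }
        self._handles = {
            src: open_gzip_text_deterministic(p) for src, p in self.paths.items()
        }

    def write(self, name: str, reads: dict[str, str]) -> None:
        for src, fh in self._handles.items():
            seq = reads[src]
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    def close(self) -> None:
        for fh in self._handles.values():
            fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def iter_fastq_quads(paths: dict) -> Iterator[tuple[str, dict[str, str]]]:
    """Iterate synchronized (name, {R1,R2,I1,I2: seq}) tuples."""
    import pysam

    files = {src: pysam.FastxFile(str(p)) for src, p in paths.items()}
    try:
        for recs in zip(*(files[s] for s in ("R1", "R2", "I1", "I2"))):
            names = {r.name for r in recs}
            if len(names) != 1:
                raise ValueError(f"FASTQ files out of sync: {sorted(names)}")
            yield recs[0].name, dict(zip(("R1", "R2", "I1", "I2"), (r.sequence for r in recs)))
    finally:
        for f in files.values():
            f.close()


# ---------------------------------------------------------------------------
# FASTA / BED


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path, columns: Sequence[str]) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(columns))


def read_bed(path, columns: Sequence[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=list(columns))


# ---------------------------------------------------------------------------
# fragments file


FRAGMENT_COLUMNS = ["contig", "start", "end", "cell", "dup_count"]


def write_fragments(fragments: pd.DataFrame, path) -> None:
    """5-column sorted gzipped TSV: contig, start, end, 'sample:dropletBC', dup_count."""
    with open_gzip_text_deterministic(path) as fh:
        fragments.to_csv(fh, sep="\t", header=False, index=False,
                         columns=FRAGMENT_COLUMNS)


def read_fragments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# summary JSON


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
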