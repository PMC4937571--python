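"""Readers and writers for the plain-text interchange formats.

BED intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Parse BED3/BED6; raises with the offending line number on bad input."""
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {i}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: non-integer coordinate") from exc
            if end < start:
                raise ValueError(f"{path}: line {i}: end < start")
            name = fields[3] if len(fields) > 3 else f"interval_{i}"
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bedgraph(path) -> pd.DataFrame:
    """Parse bedGraph (chrom, start, end, value); line-numbered errors."""
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}: line {i}: expected 4 bedGraph fields")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]),
                             float(fields[3])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: malformed bedGraph") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def read_pentamer_table(path) -> dict[str, float]:
    """Pentamer<TAB>value lookup for DNA-shape features."""
    table = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or len(fields[0]) != 5:
                raise ValueError(f"{path}: line {i}: expected pentamer<TAB>value")
            table[fields[0].upper()] = float(fields[1])
    return table
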