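"""Readers for the pipeline's plain-text input formats.

Collapsed FASTA (headers ``>{id}_x{count}``, one file per sample), a sample
manifest TSV (sample, file, population), count/design TSVs, score tables
and GMT-style gene-set files.
"""
from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .isomir import ReadRecord
from .quant import validate_counts
from .targetstats import validate_score_table

__all__ = [
    "read_collapsed_fasta",
    "read_manifest",
    "load_reads",
    "read_counts",
    "read_design",
    "read_score_table",
    "read_gmt",
]

_COLLAPSED = re.compile(r"^(?P<id>.+)_x(?P<count>\d+)$")


def read_collapsed_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Parse one collapsed FASTA into (read_id, sequence, count) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED.match(rec.id)
        if not m:
            raise ValueError(f"{path}: header {rec.id!r} is not '<id>_x<count>'")
        out.append((m["id"], str(rec.seq), int(m["count"])))
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "file", "population"):
        if col not in df.columns:
            raise ValueError(f"manifest lacks column {col!r}")
    return df


def load_reads(manifest: pd.DataFrame, base_dir: str | Path = ".") -> list[ReadRecord]:
    """Merge per-sample collapsed FASTAs into ReadRecords keyed by sequence."""
    by_seq: dict[str, ReadRecord] = {}
    for _, row in manifest.iterrows():
        for rid, seq, count in read_collapsed_fasta(Path(base_dir) / row["file"]):
            seq = seq.upper().replace("T", "U")
            if seq in by_seq:
                rec = by_seq[seq]
                rec.count_per_sample[row["sample"]] = (
                    rec.count_per_sample.get(row["sample"], 0) + count
                )
            else:
                by_seq[seq] = ReadRecord(
                    read_id=rid, sequence=seq,
                    count_per_sample={row["sample"]: count},
                )
    return list(by_seq.values())


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(df)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "population" not in df.columns:
        raise ValueError("design lacks column 'population'")
    return df


def read_score_table(path: str | Path) -> pd.DataFrame:
    return validate_score_table(pd.read_csv(path, sep="\t"))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: one set per line, tab-separated name, description, genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
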