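"""Shared file I/O: FASTA/FASTQ (gzip-aware), tables, configs, manifests.

Sequences are normalized on read (uppercase, U->T).  Tables are CSV or
TSV by extension, UTF-8, header row mandatory.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import normalize

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_table",
    "write_table",
    "read_config",
    "write_manifest",
]

log = logging.getLogger("guidearray")


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) pairs, normalized to uppercase DNA."""
    path = Path(path)
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = normalize(str(rec.seq))
            if seq != str(rec.seq):
                log.debug("normalized sequence of %s on read", rec.id)
            records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with _open_text(Path(path), "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            fh,
            "fasta",
        )


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(read_id, sequence, quality) triples; strict 4-line records."""
    path = Path(path)
    records = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4:
        raise ValueError(
            f"{path}: truncated FASTQ — record {len(lines) // 4 + 1} is "
            f"incomplete ({len(lines) % 4} of 4 lines)"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i: i + 4]
        idx = i // 4 + 1
        if not header.startswith("@"):
            raise ValueError(f"{path}: record {idx}: header does not start with @")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: record {idx}: separator line missing")
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: record {idx}: sequence and quality lengths differ"
            )
        records.append((header[1:].split()[0], normalize(seq), qual))
    if not records:
        raise ValueError(f"{path}: no FASTQ records")
    return records


def write_fastq(path: str | Path, records: list[tuple[str, str, str]]) -> None:
    with _open_text(Path(path), "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix in (".tsv", ".tab", ".bed") else ","


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty and not len(df.columns):
        raise ValueError(f"{path}: empty table")
    return df


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=index)


def read_config(path: str | Path) -> dict:
    """Plain key = value config (comments with #); values parsed as JSON
    scalars when possible."""
    out = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {i}: expected key = value")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            out[key.strip()] = json.loads(value)
        except json.JSONDecodeError:
            out[key.strip()] = value
    return out


def write_manifest(out_dir: str | Path, params: dict) -> Path:
    """Echo effective parameters of a run (reproducibility record)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    payload = {"guidearray_version": __version__, **params}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
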