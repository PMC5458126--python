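"""Small deterministic readers/writers for FASTA, FASTQ and TSV tables.

FASTA parsing goes through Biopython; FASTQ is written by a plain 4-line
emitter because the simulator guarantees byte-identical output under a fixed
seed, which must not depend on a library's wrapping policy.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

FASTQ_QUAL_CHAR = "I"  # constant Q40; base qualities are never used downstream


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a 4-line FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record near {header!r}")
            yield header[1:].rstrip("\n").split()[0], seq, qual


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{FASTQ_QUAL_CHAR * len(seq)}\n")


def write_tsv(rows: list[dict], path: str | Path, columns: list[str],
              comments: list[str] | None = None) -> None:
    """Write a TSV table with optional '#'-prefixed metadata header lines."""
    with open(path, "w", newline="") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                extrasaction="ignore", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def read_tsv(path: str | Path) -> list[dict]:
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        return list(reader)
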