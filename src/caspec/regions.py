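"""Target regions: amplicon references annotated with protospacer, PAM and cut site.

A :class:`TargetRegion` is one amplicon (or small genomic window) that carries a
single SpCas9 target.  The blunt double-strand cut is predicted between
protospacer positions 17 and 18 (counting 5'->3' along the protospacer), i.e.
3 bp upstream of the PAM.  Throughout the package ``cleavage_coord`` denotes the
0-based region coordinate of the reference base immediately LEFT of the cut, so
the two bases flanking the cut are ``cleavage_coord`` and ``cleavage_coord + 1``
regardless of the strand the protospacer sits on.

Coordinates are 0-based, half-open everywhere in the API; human-readable report
tables convert to 1-based inclusive and say so in their headers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

# IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# 1-based protospacer position 5' of the blunt cut (cut between 17 and 18,
# 3 bp upstream of the PAM for SpCas9).
CUT_OFFSET = 17


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches ``pattern`` with IUPAC degeneracy in the pattern."""
    if len(pattern) != len(seq):
        return False
    return all(s in IUPAC.get(p, "") for p, s in zip(pattern.upper(), seq.upper()))


class RegionError(ValueError):
    """Raised when a region annotation is inconsistent with its sequence."""


@dataclass(frozen=True)
class TargetRegion:
    """One reference region with a validated protospacer annotation.

    Parameters
    ----------
    name
        Region identifier (FASTA header token).
    sequence
        Reference sequence of the region, uppercase ACGTN.
    protospacer
        20-nt protospacer in its own 5'->3' orientation.
    pam
        PAM pattern, possibly degenerate (default SpCas9 ``NGG``).
    strand
        ``'+'`` if the protospacer reads forward on the region, ``'-'`` if it
        appears reverse-complemented.
    start
        0-based start of the protospacer occurrence on the region (half-open
        interval ``[start, start + len(protospacer))`` in region coordinates,
        irrespective of strand).
    """

    name: str
    sequence: str
    protospacer: str
    pam: str
    strand: str
    start: int
    cleavage_coord: int = field(init=False)

    def __post_init__(self) -> None:
        self._validate()
        object.__setattr__(self, "cleavage_coord", self._compute_cut())

    @property
    def end(self) -> int:
        """0-based half-open end of the protospacer on the region."""
        return self.start + len(self.protospacer)

    def _validate(self) -> None:
        if self.strand not in "+-":
            raise RegionError(f"region {self.name!r}: strand must be '+' or '-'")
        if len(self.protospacer) != 20:
            raise RegionError(
                f"region {self.name!r}: protospacer must be 20 nt, got "
                f"{len(self.protospacer)}"
            )
        seq = self.sequence.upper()
        occ = seq[self.start:self.end]
        expected = (self.protospacer.upper() if self.strand == "+"
                    else revcomp(self.protospacer.upper()))
        if occ != expected:
            raise RegionError(
                f"region {self.name!r}: protospacer not found at {self.start} "
                f"on strand {self.strand} (saw {occ!r})"
            )
        plen = len(self.pam)
        if self.strand == "+":
            pam_seq = seq[self.end:self.end + plen]
        else:
            pam_seq = revcomp(seq[self.start - plen:self.start])
        if len(pam_seq) != plen or not iupac_match(self.pam, pam_seq):
            raise RegionError(
                f"region {self.name!r}: PAM {self.pam!r} does not match "
                f"{pam_seq!r} adjacent to the protospacer"
            )

    def _compute_cut(self) -> int:
        # '+': base 17 of the protospacer sits at start + 16; the cut lies
        # between it and base 18.  '-': base 17 maps to end - 17, base 18 to
        # end - 18; the left flank of the cut is end - 18.
        if self.strand == "+":
            return self.start + CUT_OFFSET - 1
        return self.end - CUT_OFFSET - 1

    @property
    def cut_point(self) -> int:
        """Insertion-point index of the cut: the cut lies between reference
        bases ``cleavage_coord`` and ``cleavage_coord + 1``, so an insertion at
        point ``cut_point`` sits exactly in the cut."""
        return self.cleavage_coord + 1


ANNOTATION_COLUMNS = ["region", "start", "end", "strand", "protospacer", "pam"]


def read_annotations(path: str | Path) -> list[dict]:
    """Read a BED-like protospacer annotation table.

    Tab-separated with header ``region start end strand protospacer pam``;
    ``start``/``end`` are the 0-based half-open protospacer interval.
    Lines starting with ``#`` are ignored.
    """
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise RegionError(f"annotation file missing columns: {sorted(missing)}")
        for row in reader:
            rows.append({
                "region": row["region"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "strand": row["strand"],
                "protospacer": row["protospacer"].upper(),
                "pam": row["pam"].upper(),
            })
    return rows


def build_region_index(fasta: str | Path, annotations: str | Path | list[dict],
                       ) -> dict[str, TargetRegion]:
    """Build the multi-region reference index from a FASTA and annotations.

    Every annotation must name a FASTA sequence, and the protospacer + PAM must
    be present at the stated locus and strand; violations are hard errors
    naming the offending region.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    if isinstance(annotations, (str, Path)):
        annotations = read_annotations(annotations)
    index: dict[str, TargetRegion] = {}
    for ann in annotations:
        name = ann["region"]
        if name not in seqs:
            raise RegionError(f"annotation names absent sequence {name!r}")
        span = ann["end"] - ann["start"]
        if span != len(ann["protospacer"]):
            raise RegionError(
                f"region {name!r}: interval length {span} != protospacer length"
            )
        index[name] = TargetRegion(
            name=name,
            sequence=seqs[name],
            protospacer=ann["protospacer"],
            pam=ann["pam"],
            strand=ann["strand"],
            start=ann["start"],
        )
    return index
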