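"""Indel qualification and per-region editing summaries.

A read counts as edited when it carries at least one *qualifying* indel.  The
qualification rule is positional, defined relative to the predicted blunt cut
(between reference bases ``cleavage_coord`` and ``cleavage_coord + 1``):

* a 1 bp indel qualifies only if it is directly adjacent to the cut — a 1 bp
  deletion must remove one of the two bases flanking the cut, a 1 bp insertion
  must sit exactly in the cut;
* an indel of size >= 2 qualifies if it overlaps the closed window of
  ``flank`` (default 5) reference bases on either side of the cut, i.e. bases
  ``[cleavage_coord - flank, cleavage_coord + 1 + flank]`` (12 bases at the
  default flank); an insertion overlaps iff its insertion point lies in
  ``[cleavage_coord - flank, cleavage_coord + 1 + flank]``.

Adjacency for the 1 bp case is the narrowest reading of "directly adjacent";
``adjacency_radius`` widens it symmetrically for sensitivity analyses and is
recorded in every report.

Substitutions never qualify: the readout is NHEJ-style indel formation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

from .align import ReadAlignment
from .regions import TargetRegion

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 5


@dataclass(frozen=True)
class IndelObservation:
    """One insertion or deletion on a region.

    ``ref_interval`` is 0-based half-open: the deleted span for deletions, an
    empty interval at the insertion point for insertions (the insertion sits
    between reference bases ``point - 1`` and ``point``).
    """

    read_id: str
    region: str
    kind: str          # 'insertion' | 'deletion'
    size: int
    ref_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("indel size must be >= 1")
        a, b = self.ref_interval
        expected = 0 if self.kind == "insertion" else self.size
        if b - a != expected:
            raise ValueError(
                f"ref_interval span {b - a} inconsistent with {self.kind} of "
                f"size {self.size}")

    @property
    def point(self) -> int:
        """Insertion point (only meaningful for insertions)."""
        return self.ref_interval[0]


@dataclass(frozen=True)
class SiteEditingSummary:
    region: str
    n_retained_reads: int
    n_qualifying_reads: int

    @property
    def pct_indels(self) -> float:
        if self.n_retained_reads == 0:
            return 0.0
        return 100.0 * self.n_qualifying_reads / self.n_retained_reads


def extract_indels(alignment: ReadAlignment) -> list[IndelObservation]:
    """Walk an alignment's ops and emit one observation per indel op."""
    out = []
    gpos = alignment.start
    for kind, length in alignment.ops:
        if kind == "D":
            out.append(IndelObservation(
                read_id=alignment.read_id, region=alignment.region,
                kind="deletion", size=length,
                ref_interval=(gpos, gpos + length)))
            gpos += length
        elif kind == "I":
            out.append(IndelObservation(
                read_id=alignment.read_id, region=alignment.region,
                kind="insertion", size=length, ref_interval=(gpos, gpos)))
        else:
            gpos += length
    return out


def qualifies(indel: IndelObservation, region: TargetRegion,
              flank: int = DEFAULT_FLANK, adjacency_radius: int = 0) -> bool:
    """Apply the positional qualification rule to one indel.

    See the module docstring for the rule; ``cleavage_coord`` (cc) is the base
    left of the cut, so the cut-flanking bases are cc and cc + 1 and the cut
    point as an insertion coordinate is cc + 1.
    """
    cc = region.cleavage_coord
    a, b = indel.ref_interval
    if indel.size == 1:
        r = adjacency_radius
        if indel.kind == "deletion":
            return cc - r <= a <= cc + 1 + r
        return cc + 1 - r <= a <= cc + 1 + r
    lo, hi = cc - flank, cc + 1 + flank  # closed window of reference bases
    if indel.kind == "deletion":
        return a <= hi and b - 1 >= lo
    return lo <= a <= hi


def qualifies_params(size: int, kind: str, a: int, b: int, cc: int,
                     flank: int = DEFAULT_FLANK, adjacency_radius: int = 0,
                     ) -> bool:
    """Rule on raw parameters (used by the simulator's truth tables)."""
    return qualifies(
        IndelObservation(read_id="", region="", kind=kind, size=size,
                         ref_interval=(a, b)),
        _CutOnly(cc), flank=flank, adjacency_radius=adjacency_radius)


class _CutOnly:
    """Duck-typed stand-in carrying only a cleavage coordinate."""

    def __init__(self, cc: int):
        self.cleavage_coord = cc


def summarize_region(alignments: Iterable[ReadAlignment], region: TargetRegion,
                     flank: int = DEFAULT_FLANK, adjacency_radius: int = 0,
                     ) -> SiteEditingSummary:
    """Count reads with >= 1 qualifying indel; reads counted once each.

    Alignments must already be MAPQ-filtered and on ``region``.
    """
    n_total = 0
    n_qual = 0
    for aln in alignments:
        if aln.region != region.name:
            raise ValueError(
                f"alignment of {aln.read_id!r} is on {aln.region!r}, "
                f"not {region.name!r}")
        n_total += 1
        if any(qualifies(obs, region, flank, adjacency_radius)
               for obs in extract_indels(aln)):
            n_qual += 1
    if n_total == 0:
        logger.warning("summarize_region(%s): no retained reads", region.name)
    return SiteEditingSummary(region=region.name, n_retained_reads=n_total,
                              n_qualifying_reads=n_qual)


def t7e1_percent_modification(fraction_cleaved: float) -> float:
    """Percent gene modification from a T7E1 cleaved fraction.

    The enzymatic assay cuts re-hybridized heteroduplexes; with modified
    fraction p the heteroduplex fraction is 1 - (1-p)^2, so inverting gives
    ``100 * (1 - sqrt(1 - fraction_cleaved))``.
    """
    if not 0.0 <= fraction_cleaved <= 1.0:
        raise ValueError("fraction_cleaved must lie in [0, 1]")
    return 100.0 * (1.0 - math.sqrt(1.0 - fraction_cleaved))
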