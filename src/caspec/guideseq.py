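"""GUIDE-seq-style off-target site discovery, plus an in-silico mismatch scanner.

The caller works on single-end reads spanning the junction between the genome
and an integrated dsODN tag (the blunt oligo captured in Cas9 cut sites):

1. exact-sequence PCR-duplicate consolidation;
2. dsODN localisation inside each read (edlib infix search, small edit
   allowance) and placement of the genomic flank on the genome via a unique
   k-mer seed — unique placement maps to mapping quality 60, ambiguous to 0;
3. MAPQ filter (>= 50 by default), clustering of junction coordinates within a
   +-10 bp collapse window, and a minimum consolidated-read support per site;
4. best placement of protospacer + PAM within +-25 bp of each site (PAM matched
   degenerately, mismatches counted on the 20 protospacer positions only);
   sites are retained when at most ``max_mm`` (default 8) mismatches are found;
5. subtraction of any site present in the background control.

The scanner (:func:`scan_offtargets`) is a brute-force every-position,
both-strand mismatch enumeration over a genome — the desk-scale equivalent of
the usual in-silico off-target search tools.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .align import encode_seq
from .regions import IUPAC, iupac_match, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 50
DEFAULT_MIN_READS = 2
DEFAULT_COLLAPSE_WINDOW = 10
DEFAULT_MAX_MISMATCHES = 8
TARGET_SEARCH_WINDOW = 25


@dataclass(frozen=True)
class ConsolidatedRead:
    """A distinct read sequence with its PCR-duplicate multiplicity."""

    read_id: str   # representative (first seen)
    seq: str
    multiplicity: int


@dataclass(frozen=True)
class Junction:
    """One consolidated read's dsODN-genome junction placed on the genome."""

    read_id: str
    contig: str
    position: int   # 0-based genomic coordinate of the integration point
    mapq_proxy: int
    multiplicity: int


@dataclass(frozen=True)
class TargetAlignment:
    site_sequence: str   # protospacer-oriented genomic sequence (proto + PAM)
    mismatch_count: int  # over the 20 protospacer positions
    strand: str
    start: int           # forward-strand start of the site's 23-mer


@dataclass(frozen=True)
class GuideSeqSite:
    contig: str
    position: int
    strand: str
    consolidated_read_count: int
    target_alignment: TargetAlignment | None
    in_background: bool = False


@dataclass(frozen=True)
class OfftargetCandidate:
    contig: str
    position: int        # forward-strand start of the 23-mer
    strand: str
    site_sequence: str   # protospacer-oriented
    mismatch_count: int
    pam_ok: bool = True


# ---------------------------------------------------------------------------
# read-level steps
# ---------------------------------------------------------------------------

def consolidate_duplicates(reads: Iterable[tuple[str, str]],
                           ) -> list[ConsolidatedRead]:
    """Collapse reads with identical sequence; deterministic lexicographic
    output order by sequence."""
    first_id: dict[str, str] = {}
    counts: Counter[str] = Counter()
    for rid, seq in reads:
        if seq not in first_id:
            first_id[seq] = rid
        counts[seq] += 1
    return [ConsolidatedRead(read_id=first_id[s], seq=s, multiplicity=counts[s])
            for s in sorted(counts)]


def locate_dsodn(seq: str, dsodn: str, max_edits: int = 3,
                 ) -> tuple[int, int] | None:
    """Locate the dsODN inside a read (infix alignment, <= max_edits edits).

    Returns the (start, end) interval of the tag on the read, or None.
    """
    res = edlib.align(dsodn.upper(), seq.upper(), mode="HW", task="locations",
                      k=max_edits)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1


class _GenomeIndex:
    """Exact k-mer index of a mini-genome for flank placement."""

    def __init__(self, genome: dict[str, str], k: int = 20):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("genome is empty")
        self.genome = {n: s.upper() for n, s in genome.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((name, i))

    def place(self, flank: str) -> tuple[str, int, int] | None:
        """Place a genomic flank; returns (contig, start, mapq_proxy) or None.

        The first and last k-mers of the flank vote; a unique consistent
        placement earns MAPQ 60, several placements 0.
        """
        k = self.k
        if len(flank) < k:
            return None
        hits: list[tuple[str, int]] = []
        for off in (0, len(flank) - k):
            for contig, pos in self.index.get(flank[off:off + k], []):
                hits.append((contig, pos - off))
            if hits:
                break
        if not hits:
            return None
        uniq = sorted(set(hits))
        contig, start = uniq[0]
        return contig, start, (60 if len(uniq) == 1 else 0)


def map_junctions(consolidated: Sequence[ConsolidatedRead], dsodn: str,
                  genome: dict[str, str], *, seed_k: int = 20,
                  max_tag_edits: int = 3) -> list[Junction]:
    """Find the dsODN in each read and place the longer genomic flank.

    Warns when no read of the sample contains the tag (suggests a sample
    swap).  Reads without the tag or with an unplaceable flank are skipped.
    """
    idx = _GenomeIndex(genome, k=seed_k)
    out: list[Junction] = []
    n_tagged = 0
    for cr in consolidated:
        loc = locate_dsodn(cr.seq, dsodn, max_tag_edits)
        if loc is None:
            continue
        n_tagged += 1
        tag_start, tag_end = loc
        left, right = cr.seq[:tag_start], cr.seq[tag_end:]
        flank, is_left = (left, True) if len(left) >= len(right) else (right, False)
        placed = idx.place(flank.upper())
        if placed is None:
            continue
        contig, start, mapq = placed
        junction = start + len(flank) if is_left else start
        out.append(Junction(read_id=cr.read_id, contig=contig,
                            position=junction, mapq_proxy=mapq,
                            multiplicity=cr.multiplicity))
    if n_tagged == 0 and consolidated:
        logger.warning(
            "map_junctions: dsODN found in no read of a treatment sample — "
            "possible sample swap")
    return out


# ---------------------------------------------------------------------------
# site-level steps
# ---------------------------------------------------------------------------

def _cluster_positions(positions: Sequence[int], window: int,
                       ) -> list[list[int]]:
    """Greedy 1-D clustering: successive positions within ``window`` of the
    running cluster's current maximum join it."""
    clusters: list[list[int]] = []
    for p in sorted(positions):
        if clusters and p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def detect_integration_sites(junctions: Iterable[Junction], *,
                             min_mapq: int = DEFAULT_MIN_MAPQ,
                             min_reads: int = DEFAULT_MIN_READS,
                             collapse_window: int = DEFAULT_COLLAPSE_WINDOW,
                             ) -> list[GuideSeqSite]:
    """Cluster junction placements into integration sites.

    MAPQ filtering happens before counting; a cluster's coordinate is its
    most-supported junction position (lowest coordinate on ties) and its
    support is the number of consolidated reads, which must reach
    ``min_reads``.
    """
    kept = [j for j in junctions if j.mapq_proxy >= min_mapq]
    by_contig: dict[str, list[Junction]] = {}
    for j in kept:
        by_contig.setdefault(j.contig, []).append(j)
    sites: list[GuideSeqSite] = []
    for contig in sorted(by_contig):
        js = by_contig[contig]
        pos_map: dict[int, list[Junction]] = {}
        for j in js:
            pos_map.setdefault(j.position, []).append(j)
        for cluster in _cluster_positions([j.position for j in js],
                                          collapse_window):
            members = [j for p in set(cluster) for j in pos_map[p]]
            support = len(members)
            if support < min_reads:
                continue
            votes = Counter(j.position for j in members)
            top = max(votes.values())
            position = min(p for p, c in votes.items() if c == top)
            sites.append(GuideSeqSite(
                contig=contig, position=position, strand=".",
                consolidated_read_count=support, target_alignment=None))
    return sites


def match_target(site: GuideSeqSite, protospacer: str, pam: str,
                 genome: dict[str, str],
                 max_mm: int = DEFAULT_MAX_MISMATCHES,
                 search_window: int = TARGET_SEARCH_WINDOW,
                 ) -> TargetAlignment | None:
    """Best PAM-valid protospacer placement near an integration site.

    Both strands within ``+-search_window`` bp of the integration coordinate
    are searched; among PAM-compatible placements the one minimising
    protospacer mismatches wins, ties broken by lower coordinate then '+'
    strand.  Returns None when the best exceeds ``max_mm`` or no PAM-valid
    placement exists.
    """
    proto = protospacer.upper()
    seq = genome[site.contig].upper()
    span = len(proto) + len(pam)
    lo = max(0, site.position - search_window - span)
    hi = min(len(seq) - span, site.position + search_window)
    best: tuple[int, int, int, TargetAlignment] | None = None
    for p in range(lo, hi + 1):
        window = seq[p:p + span]
        for strand in "+-":
            oriented = window if strand == "+" else revcomp(window)
            if not iupac_match(pam, oriented[len(proto):]):
                continue
            mm = sum(a != b for a, b in zip(oriented[:len(proto)], proto))
            key = (mm, p, 0 if strand == "+" else 1)
            if best is None or key < best[:3]:
                best = (*key, TargetAlignment(site_sequence=oriented,
                                              mismatch_count=mm,
                                              strand=strand, start=p))
    if best is None or best[0] > max_mm:
        return None
    return best[3]


def subtract_background(sites: Sequence[GuideSeqSite],
                        background_sites: Sequence[GuideSeqSite],
                        collapse_window: int = DEFAULT_COLLAPSE_WINDOW,
                        ) -> list[GuideSeqSite]:
    """Drop sites whose coordinate falls within the collapse window of a
    background-control site (idempotent)."""
    out = []
    for s in sites:
        hit = any(b.contig == s.contig
                  and abs(b.position - s.position) <= collapse_window
                  for b in background_sites)
        if not hit:
            out.append(s)
    return out


def call_guideseq_sites(treatment_reads: Iterable[tuple[str, str]],
                        background_reads: Iterable[tuple[str, str]],
                        genome: dict[str, str], protospacer: str,
                        pam: str = "NGG", dsodn: str | None = None, *,
                        min_mapq: int = DEFAULT_MIN_MAPQ,
                        min_reads: int = DEFAULT_MIN_READS,
                        collapse_window: int = DEFAULT_COLLAPSE_WINDOW,
                        max_mm: int = DEFAULT_MAX_MISMATCHES,
                        ) -> list[GuideSeqSite]:
    """Full site-calling pipeline on raw treatment/background read pairs."""
    from .simulate import DEFAULT_DSODN
    dsodn = dsodn or DEFAULT_DSODN

    def sites_of(reads):
        cons = consolidate_duplicates(reads)
        junctions = map_junctions(cons, dsodn, genome)
        return detect_integration_sites(
            junctions, min_mapq=min_mapq, min_reads=min_reads,
            collapse_window=collapse_window)

    trt_sites = sites_of(treatment_reads)
    bkg_sites = detect_integration_sites(
        map_junctions(consolidate_duplicates(background_reads), dsodn, genome),
        min_mapq=min_mapq, min_reads=1, collapse_window=collapse_window)
    retained = []
    for s in subtract_background(trt_sites, bkg_sites, collapse_window):
        ta = match_target(s, protospacer, pam, genome, max_mm=max_mm)
        if ta is None:
            continue
        retained.append(GuideSeqSite(
            contig=s.contig, position=s.position, strand=ta.strand,
            consolidated_read_count=s.consolidated_read_count,
            target_alignment=ta, in_background=False))
    return retained


# ---------------------------------------------------------------------------
# in-silico mismatch scanner
# ---------------------------------------------------------------------------

def _pam_mask(pam: str) -> np.ndarray:
    """allowed[t, code] — True when base code matches PAM position t."""
    mask = np.zeros((len(pam), 5), dtype=bool)
    for t, c in enumerate(pam.upper()):
        for b in IUPAC[c]:
            mask[t, "ACGT".index(b)] = True
    return mask


def scan_offtargets(genome: dict[str, str], protospacer: str, pam: str = "NGG",
                    max_mm: int = 4) -> list[OfftargetCandidate]:
    """Exhaustive both-strand scan for protospacer+PAM placements.

    Every genomic position is tested; mismatches are counted over the 20
    protospacer positions and the PAM must match degenerately.  Results are
    sorted by (mismatch_count, contig, position).
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    proto = protospacer.upper()
    span = len(proto) + len(pam)
    pam_mask = _pam_mask(pam)
    proto_enc = encode_seq(proto)
    out: list[OfftargetCandidate] = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        if len(seq) < span:
            continue
        enc = encode_seq(seq)
        win = np.lib.stride_tricks.sliding_window_view(enc, span)
        for strand in "+-":
            if strand == "+":
                mm = (win[:, :20] != proto_enc).sum(axis=1)
                pam_enc = win[:, 20:]
                pam_ok = np.ones(len(win), dtype=bool)
                for t in range(len(pam)):
                    pam_ok &= pam_mask[t][np.minimum(pam_enc[:, t], 4)]
            else:
                # reverse-complement placement: the forward-strand window is
                # revcomp(proto + pam) = revcomp(pam) + revcomp(proto)
                rc = encode_seq(revcomp(proto))
                mm = (win[:, len(pam):] != rc).sum(axis=1)
                pam_ok = np.ones(len(win), dtype=bool)
                for t in range(len(pam)):
                    # PAM position t sits at forward offset len(pam)-1-t,
                    # complemented
                    col = win[:, len(pam) - 1 - t]
                    comp = np.where(col < 4, 3 - col, 4)
                    pam_ok &= pam_mask[t][np.minimum(comp, 4)]
            for p in np.flatnonzero(pam_ok & (mm <= max_mm)):
                site = seq[p:p + span]
                out.append(OfftargetCandidate(
                    contig=contig, position=int(p), strand=strand,
                    site_sequence=site if strand == "+" else revcomp(site),
                    mismatch_count=int(mm[p])))
    out.sort(key=lambda c: (c.mismatch_count, c.contig, c.position))
    return out


def render_site_alignment(protospacer: str, pam: str, site_sequence: str) -> str:
    """Plain-text mismatch rendering: matching positions as '.', mismatches as
    the site's base (protospacer part), PAM shown verbatim."""
    proto = protospacer.upper()
    body = "".join("." if s == p else s
                   for s, p in zip(site_sequence[:len(proto)], proto))
    return body + " " + site_sequence[len(proto):]
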