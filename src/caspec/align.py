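"""Read-to-region alignment.

Amplicon reads are placed on the best region of a small multi-region reference
by affine-gap semi-global dynamic programming (Gotoh): the read is aligned
end-to-end while both reference ends are free, which matches the geometry of an
amplicon read drawn from anywhere inside its amplicon.  A banded variant,
anchored by an exact k-mer seed, is the production path; the unbanded
full-matrix kernel doubles as its oracle and as the fallback when no seed is
found.

Mapping quality is a proxy, not BWA's formula: the margin between the best and
second-best region score, capped at 60; a read whose best region is unique (no
second candidate) gets 60, a perfect tie gets 0.  The retention thresholds used
downstream (>= 30 for amplicon quantification, >= 50 for GUIDE-seq) interpret
this margin exactly as a mapping-quality filter would.

Indels are left-aligned: within runs of identical bases a gap is shifted
maximally left, so positional rules applied downstream see one deterministic
coordinate per event.

Coordinates 0-based half-open; ops are (kind, length) runs with kinds
'=' match, 'X' mismatch, 'I' insertion (read-consuming), 'D' deletion
(reference-consuming).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from numba import njit

from .regions import TargetRegion

logger = logging.getLogger(__name__)

MAPQ_CAP = 60

# scoring defaults: match +2, mismatch -4, gap open -6, gap extend -1
DEFAULT_SCORING = {"match": 2, "mismatch": -4, "gap_open": -6, "gap_extend": -1}

_NEG = -(1 << 30)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode_seq(seq: str) -> np.ndarray:
    """Encode ACGTN (case-insensitive) as uint8 codes 0-4; 4 ('N') never matches."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ReadAlignment:
    """One read's placement on a region."""

    read_id: str
    region: str
    start: int                       # 0-based region coordinate of first aligned base
    ops: tuple[tuple[str, int], ...]  # (kind, length); kinds '=', 'X', 'I', 'D'
    score: int
    mapq_proxy: int
    seq: str = ""                    # read sequence (kept for SAM export)

    @property
    def ref_span(self) -> int:
        return sum(n for k, n in self.ops if k in "=XD")

    @property
    def read_span(self) -> int:
        return sum(n for k, n in self.ops if k in "=XI")

    def end(self) -> int:
        return self.start + self.ref_span


# ---------------------------------------------------------------------------
# DP kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gotoh_full(read, ref, match, mism, gap_open, gap_ext):  # pragma: no cover - jit
    """Unbanded semi-global Gotoh with traceback.

    Returns (score, start, codes) where codes walk the alignment left to right
    with 0='=', 1='X', 2='I', 3='D'.
    """
    m = read.shape[0]
    n = ref.shape[0]
    M = np.full((m + 1, n + 1), _NEG, np.int64)
    Ix = np.full((m + 1, n + 1), _NEG, np.int64)  # deletion state (consumes ref)
    Iy = np.full((m + 1, n + 1), _NEG, np.int64)  # insertion state (consumes read)
    PM = np.zeros((m + 1, n + 1), np.int8)
    PX = np.zeros((m + 1, n + 1), np.int8)
    PY = np.zeros((m + 1, n + 1), np.int8)
    for j in range(n + 1):
        M[0, j] = 0  # free start anywhere on the reference
    for i in range(1, m + 1):
        # leading read bases as insertions before the reference
        Iy[i, 0] = gap_open + (i - 1) * gap_ext
        PY[i, 0] = 0 if i == 1 else 1
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = match if (ri == ref[j - 1] and ri < 4) else mism
            bm, bx, by = M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]
            if bm >= bx and bm >= by:
                M[i, j] = bm + s
                PM[i, j] = 0
            elif bx >= by:
                M[i, j] = bx + s
                PM[i, j] = 1
            else:
                M[i, j] = by + s
                PM[i, j] = 2
            op = M[i, j - 1] + gap_open
            ex = Ix[i, j - 1] + gap_ext
            if op >= ex:
                Ix[i, j] = op
                PX[i, j] = 0
            else:
                Ix[i, j] = ex
                PX[i, j] = 1
            op = M[i - 1, j] + gap_open
            ex = Iy[i - 1, j] + gap_ext
            if op >= ex:
                Iy[i, j] = op
                PY[i, j] = 0
            else:
                Iy[i, j] = ex
                PY[i, j] = 1
    best = _NEG
    best_j = 0
    best_state = 0
    for j in range(n + 1):
        if M[m, j] > best:
            best = M[m, j]
            best_j = j
            best_state = 0
        if Iy[m, j] > best:
            best = Iy[m, j]
            best_j = j
            best_state = 2
    codes = np.empty(m + n, np.int8)
    p = 0
    i, j, state = m, best_j, best_state
    while i > 0:
        if state == 0:
            codes[p] = 0 if (read[i - 1] == ref[j - 1] and read[i - 1] < 4) else 1
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            codes[p] = 3
            state = 0 if PX[i, j] == 0 else 1
            j -= 1
        else:
            codes[p] = 2
            state = 0 if PY[i, j] == 0 else 2
            i -= 1
        p += 1
    return best, j, codes[:p][::-1].copy()


@njit(cache=True)
def _gotoh_banded(read, ref, d0, w, match, mism, gap_open, gap_ext):  # pragma: no cover - jit
    """Banded semi-global Gotoh restricted to diagonals |j - i - d0| <= w.

    Band coordinates: k = j - i - d0 + w in [0, 2w].  The diagonal predecessor
    (i-1, j-1) keeps k; the horizontal one (i, j-1) is k-1; the vertical one
    (i-1, j) is k+1.  Returns (score, start, codes) like the full kernel.
    """
    m = read.shape[0]
    n = ref.shape[0]
    width = 2 * w + 1
    M = np.full((m + 1, width), _NEG, np.int64)
    Ix = np.full((m + 1, width), _NEG, np.int64)
    Iy = np.full((m + 1, width), _NEG, np.int64)
    PM = np.zeros((m + 1, width), np.int8)
    PX = np.zeros((m + 1, width), np.int8)
    PY = np.zeros((m + 1, width), np.int8)
    for k in range(width):
        j = d0 - w + k
        if 0 <= j <= n:
            M[0, k] = 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        for k in range(width):
            j = i + d0 - w + k
            if j < 0 or j > n:
                continue
            if j == 0:
                # leading insertions before the reference start
                Iy[i, k] = gap_open + (i - 1) * gap_ext
                PY[i, k] = 0 if i == 1 else 1
                continue
            s = match if (ri == ref[j - 1] and ri < 4) else mism
            bm, bx, by = M[i - 1, k], Ix[i - 1, k], Iy[i - 1, k]
            best_prev = bm
            pm = 0
            if bx > best_prev:
                best_prev = bx
                pm = 1
            if by > best_prev:
                best_prev = by
                pm = 2
            if best_prev > _NEG:
                M[i, k] = best_prev + s
                PM[i, k] = pm
            if k > 0:
                op = M[i, k - 1] + gap_open
                ex = Ix[i, k - 1] + gap_ext
                if op >= ex:
                    if M[i, k - 1] > _NEG:
                        Ix[i, k] = op
                        PX[i, k] = 0
                else:
                    Ix[i, k] = ex
                    PX[i, k] = 1
            if k < width - 1:
                op = M[i - 1, k + 1] + gap_open
                ex = Iy[i - 1, k + 1] + gap_ext
                if op >= ex:
                    if M[i - 1, k + 1] > _NEG:
                        Iy[i, k] = op
                        PY[i, k] = 0
                else:
                    Iy[i, k] = ex
                    PY[i, k] = 1
    best = _NEG
    best_k = 0
    best_state = 0
    for k in range(width):
        j = m + d0 - w + k
        if j < 0 or j > n:
            continue
        if M[m, k] > best:
            best = M[m, k]
            best_k = k
            best_state = 0
        if Iy[m, k] > best:
            best = Iy[m, k]
            best_k = k
            best_state = 2
    codes = np.empty(m + n, np.int8)
    p = 0
    i, k, state = m, best_k, best_state
    while i > 0:
        j = i + d0 - w + k
        if state == 0:
            codes[p] = 0 if (read[i - 1] == ref[j - 1] and read[i - 1] < 4) else 1
            state = PM[i, k]
            i -= 1
        elif state == 1:
            codes[p] = 3
            state = 0 if PX[i, k] == 0 else 1
            k -= 1
        else:
            codes[p] = 2
            state = 0 if PY[i, k] == 0 else 2
            i -= 1
            k += 1
        p += 1
    start = i + d0 - w + k
    return best, start, codes[:p][::-1].copy()


def semiglobal_score(read: str, ref: str, **scoring) -> int:
    """Score-only unbanded semi-global alignment (exposed for cross-checks)."""
    sc = {**DEFAULT_SCORING, **scoring}
    score, _, _ = _gotoh_full(encode_seq(read), encode_seq(ref), sc["match"],
                              sc["mismatch"], sc["gap_open"], sc["gap_extend"])
    return int(score)


# ---------------------------------------------------------------------------
# op reconstruction and indel normalisation
# ---------------------------------------------------------------------------

_CODE2OP = "=XID"


def _codes_to_ops(codes: np.ndarray) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for c in codes:
        k = _CODE2OP[c]
        if ops and ops[-1][0] == k:
            ops[-1] = (k, ops[-1][1] + 1)
        else:
            ops.append((k, 1))
    return ops


def left_align_ops(ops: Sequence[tuple[str, int]], start: int, read: str,
                   ref: str) -> tuple[tuple[str, int], ...]:
    """Shift every indel maximally left within runs of identical bases.

    A deletion of ref[a:a+L] moves to a-1 while ref[a-1] == ref[a+L-1]; an
    insertion of read[u:u+L] at ref point p moves to p-1 while
    read[u+L-1] == ref[p-1].  Neither shift can cross the alignment start or a
    neighbouring indel, and neither changes the alignment score.
    """
    # decompose into events with read/ref cursors
    events = []  # (kind, read_pos, ref_pos, length)
    rpos, gpos = 0, start
    for kind, length in ops:
        events.append([kind, rpos, gpos, length])
        if kind in "=X":
            rpos += length
            gpos += length
        elif kind == "I":
            rpos += length
        else:
            gpos += length
    changed = False
    for idx, ev in enumerate(events):
        kind, rpos, gpos, length = ev
        if kind not in "ID":
            continue
        # room to shift: length of the immediately preceding aligned run
        room = events[idx - 1][3] if idx > 0 and events[idx - 1][0] in "=X" else 0
        shift = 0
        if kind == "D":
            a = gpos
            while shift < room and a - 1 >= start and ref[a - 1] == ref[a + length - 1]:
                a -= 1
                shift += 1
        else:
            p = gpos
            u = rpos
            while (shift < room and p - 1 >= start and u - 1 >= 0
                   and read[u + length - 1] == ref[p - 1]):
                p -= 1
                u -= 1
                shift += 1
        if shift:
            changed = True
            ev[1] -= shift
            ev[2] -= shift
    if not changed:
        return tuple((k, n) for k, n, *_ in [(e[0], e[3]) for e in events])
    # rebuild runs: aligned stretches between indels re-scored base by base
    indels = sorted(((e[0], e[1], e[2], e[3]) for e in events if e[0] in "ID"),
                    key=lambda e: (e[2], e[1]))
    out: list[tuple[str, int]] = []

    def emit_aligned(r0: int, g0: int, length: int) -> None:
        for t in range(length):
            k = "=" if read[r0 + t] == ref[g0 + t] and read[r0 + t] != "N" else "X"
            if out and out[-1][0] == k:
                out[-1] = (k, out[-1][1] + 1)
            else:
                out.append((k, 1))

    rpos, gpos = 0, start
    for kind, r0, g0, length in indels:
        emit_aligned(rpos, gpos, r0 - rpos)
        rpos, gpos = r0, g0
        out.append((kind, length))
        if kind == "I":
            rpos += length
        else:
            gpos += length
    read_len = len(read)
    emit_aligned(rpos, gpos, read_len - rpos)
    return tuple(out)


# ---------------------------------------------------------------------------
# the aligner
# ---------------------------------------------------------------------------

class RegionAligner:
    """Semi-global aligner over a set of target regions.

    Parameters
    ----------
    regions
        Mapping name -> :class:`TargetRegion` (or any object with ``name`` and
        ``sequence``), as produced by :func:`caspec.regions.build_region_index`.
    band
        Half-width of the banded DP (diagonals around the seed); must exceed
        the largest indel expected in the data.
    min_score_frac
        A read whose best score falls below ``min_score_frac * match *
        len(read)`` is reported unmapped.
    seed_k
        Length of the exact k-mer used to anchor the band; reads with no seed
        hit fall back to the unbanded kernel.
    """

    def __init__(self, regions: Mapping[str, TargetRegion] | Iterable[TargetRegion],
                 *, band: int = 25, min_score_frac: float = 0.3,
                 seed_k: int = 16, **scoring):
        if not isinstance(regions, Mapping):
            regions = {r.name: r for r in regions}
        if not regions:
            raise ValueError("empty region index")
        self.regions = dict(regions)
        self.band = int(band)
        self.min_score_frac = float(min_score_frac)
        self.seed_k = int(seed_k)
        self.scoring = {**DEFAULT_SCORING, **scoring}
        self._enc = {name: encode_seq(r.sequence) for name, r in self.regions.items()}

    def _seed_diagonal(self, read: str, region_seq: str) -> int | None:
        k = self.seed_k
        m = len(read)
        if m < k:
            return None
        for off in (0, (m - k) // 2, m - k):
            pos = region_seq.find(read[off:off + k])
            if pos >= 0:
                return pos - off
        return None

    def _align_one(self, enc_read: np.ndarray, read: str, name: str,
                   with_trace: bool):
        sc = self.scoring
        seq = self.regions[name].sequence
        d0 = self._seed_diagonal(read, seq)
        if d0 is None:
            score, start, codes = _gotoh_full(
                enc_read, self._enc[name], sc["match"], sc["mismatch"],
                sc["gap_open"], sc["gap_extend"])
        else:
            score, start, codes = _gotoh_banded(
                enc_read, self._enc[name], d0, self.band, sc["match"],
                sc["mismatch"], sc["gap_open"], sc["gap_extend"])
        return int(score), int(start), codes

    def align_read(self, read_id: str, seq: str) -> ReadAlignment | None:
        """Align one read against every region; best region wins.

        Returns ``None`` for unalignable reads (best score below the floor).
        ``mapq_proxy`` is ``min(60, best - second_best)``; a unique candidate
        region scores 60.
        """
        seq = seq.upper()
        if not seq or set(seq) - set("ACGTN"):
            raise ValueError(f"read {read_id!r}: sequence must be non-empty ACGTN")
        enc = encode_seq(seq)
        results = []
        for name in self.regions:
            score, start, codes = self._align_one(enc, seq, name, True)
            results.append((score, name, start, codes))
        results.sort(key=lambda t: (-t[0], t[1]))
        best_score, name, start, codes = results[0]
        floor = self.min_score_frac * self.scoring["match"] * len(seq)
        if best_score < floor:
            return None
        if len(results) > 1:
            mapq = min(MAPQ_CAP, best_score - results[1][0])
        else:
            mapq = MAPQ_CAP
        ops = _codes_to_ops(codes)
        ops = left_align_ops(ops, start, seq, self.regions[name].sequence)
        return ReadAlignment(read_id=read_id, region=name, start=start,
                             ops=ops, score=best_score, mapq_proxy=mapq, seq=seq)

    def align_fastq(self, path: str | Path) -> list[ReadAlignment]:
        """Align every read of a FASTQ file; unmapped reads are dropped
        (counted in the log)."""
        from .io import read_fastq
        out = []
        n_unmapped = 0
        for rid, seq, _ in read_fastq(path):
            aln = self.align_read(rid, seq)
            if aln is None:
                n_unmapped += 1
            else:
                out.append(aln)
        if n_unmapped:
            logger.info("align_fastq: %d reads unmapped", n_unmapped)
        return out


def filter_by_mapq(alignments: Iterable[ReadAlignment],
                   threshold: int) -> list[ReadAlignment]:
    """Retain alignments with ``mapq_proxy >= threshold`` (order-preserving).

    The amplicon pipeline uses threshold 30, the GUIDE-seq pipeline 50.
    """
    if threshold < 0:
        raise ValueError("mapq threshold must be >= 0")
    alignments = list(alignments)
    kept = [a for a in alignments if a.mapq_proxy >= threshold]
    logger.info("filter_by_mapq(>=%d): retained %d / %d", threshold, len(kept),
                len(alignments))
    return kept


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------

_SUPPORTED_CIGAR = {0: "M", 1: "I", 2: "D", 7: "=", 8: "X"}


def _sam_header(regions: Mapping[str, TargetRegion]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(r.sequence)}
               for name, r in regions.items()],
    })


def export_sam(alignments: Iterable[ReadAlignment],
               regions: Mapping[str, TargetRegion], path: str | Path) -> None:
    """Write alignments as plain-text SAM (ops emitted as =/X/I/D CIGAR)."""
    header = _sam_header(regions)
    names = list(regions)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.seq or None
            rec.flag = 0
            rec.reference_id = names.index(aln.region)
            rec.reference_start = aln.start
            rec.mapping_quality = aln.mapq_proxy
            rec.cigarstring = "".join(f"{n}{k}" for k, n in aln.ops)
            fh.write(rec)


def import_sam(path: str | Path,
               regions: Mapping[str, TargetRegion]) -> list[ReadAlignment]:
    """Import alignments produced by an external aligner.

    CIGAR runs are translated to ops ('M' split into =/X against the region
    sequence when the record carries its query sequence, kept as a combined
    match/mismatch run scored '=' otherwise is not attempted — M without a
    sequence is an error).  The file's MAPQ is used verbatim as
    ``mapq_proxy``.  Unknown reference names and CIGAR ops other than
    M/I/D/=/X (e.g. N, P, S, H) are hard errors naming the read.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            name = rec.reference_name
            if name not in regions:
                raise ValueError(f"SAM reference {name!r} not in region index")
            ref = regions[name].sequence
            qseq = rec.query_sequence or ""
            ops: list[tuple[str, int]] = []
            rpos, gpos = 0, rec.reference_start
            for code, length in rec.cigartuples or []:
                kind = _SUPPORTED_CIGAR.get(code)
                if kind is None:
                    raise ValueError(
                        f"read {rec.query_name!r}: unsupported CIGAR op code "
                        f"{code}")
                if kind == "M":
                    if not qseq:
                        raise ValueError(
                            f"read {rec.query_name!r}: CIGAR M needs SEQ to "
                            f"split into match/mismatch runs")
                    for t in range(length):
                        k = ("=" if qseq[rpos + t] == ref[gpos + t]
                             and qseq[rpos + t] != "N" else "X")
                        if ops and ops[-1][0] == k:
                            ops[-1] = (k, ops[-1][1] + 1)
                        else:
                            ops.append((k, 1))
                    rpos += length
                    gpos += length
                    continue
                if ops and ops[-1][0] == kind:
                    ops[-1] = (kind, ops[-1][1] + length)
                else:
                    ops.append((kind, length))
                if kind in "=X":
                    rpos += length
                    gpos += length
                elif kind == "I":
                    rpos += length
                else:
                    gpos += length
            out.append(ReadAlignment(
                read_id=rec.query_name, region=name, start=rec.reference_start,
                ops=tuple(ops), score=0, mapq_proxy=rec.mapping_quality,
                seq=qseq))
    return out
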