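"""Independent oracles used by the tests.

Everything here is coded directly from first principles (rule text, plain
dynamic programming, naive scans) without importing the implementation
modules it checks, so agreement is evidence, not tautology.
"""

from __future__ import annotations


def rule_oracle(kind: str, size: int, interval: tuple[int, int], cut_left: int,
                flank: int = 5) -> bool:
    """Positional qualification rule, by direct set arithmetic.

    ``cut_left`` is the base left of the blunt cut.  1 bp indels must be
    directly adjacent to the cut (deleted base flanks the cut; insertion sits
    in the cut); indels of size >= 2 must overlap the closed window of
    ``flank`` bases either side of the cut.
    """
    cut_flanking_bases = {cut_left, cut_left + 1}
    window_bases = set(range(cut_left - flank, cut_left + flank + 2))
    # insertion points lying inside the window (between two window bases or at
    # its closed edges)
    window_points = set(range(cut_left - flank, cut_left + flank + 2))
    if kind == "deletion":
        deleted = set(range(interval[0], interval[1]))
        if size == 1:
            return deleted.issubset(cut_flanking_bases)
        return len(deleted & window_bases) > 0
    point = interval[0]
    if size == 1:
        return point == cut_left + 1
    return point in window_points


def gotoh_score_oracle(read: str, ref: str, match: int = 2, mismatch: int = -4,
                       gap_open: int = -6, gap_extend: int = -1) -> int:
    """Unbanded affine-gap semi-global score by plain row-wise DP.

    Read fully aligned, reference ends free.  Pure Python, O(mn), score only.
    """
    m, n = len(read), len(ref)
    NEG = float("-inf")
    # three states per cell: diagonal (aligned pair), del (gap in read,
    # consumes ref), ins (gap in ref, consumes read)
    prev_d = [0.0] * (n + 1)         # row i-1, state diagonal-or-start
    prev_i = [NEG] * (n + 1)
    cur_d = [NEG] * (n + 1)
    cur_i = [NEG] * (n + 1)
    prev_x = [NEG] * (n + 1)
    cur_x = [NEG] * (n + 1)
    for i in range(1, m + 1):
        cur_d[0] = NEG
        cur_x[0] = NEG
        cur_i[0] = (gap_open if i == 1 else prev_i[0] + gap_extend)
        for j in range(1, n + 1):
            s = match if read[i - 1] == ref[j - 1] and read[i - 1] != "N" \
                else mismatch
            cur_d[j] = max(prev_d[j - 1], prev_x[j - 1], prev_i[j - 1]) + s
            cur_x[j] = max(cur_d[j - 1] + gap_open, cur_x[j - 1] + gap_extend)
            cur_i[j] = max(prev_d[j] + gap_open, prev_i[j] + gap_extend)
        prev_d, cur_d = cur_d, prev_d
        prev_x, cur_x = cur_x, prev_x
        prev_i, cur_i = cur_i, prev_i
    return int(max(max(prev_d[j], prev_i[j]) for j in range(n + 1)))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_offtarget_scan(genome: dict[str, str], protospacer: str, pam: str,
                         max_mm: int) -> set[tuple[str, int, str, int]]:
    """Per-position Hamming scan, both strands; returns
    {(contig, position, strand, mismatches)} for PAM-valid placements."""
    hits = set()
    span = len(protospacer) + len(pam)
    for contig, seq in genome.items():
        for p in range(len(seq) - span + 1):
            window = seq[p:p + span]
            for strand, oriented in (("+", window), ("-", _rc(window))):
                body, tail = oriented[:len(protospacer)], oriented[len(protospacer):]
                if not all(t in _IUPAC_SETS[c] for c, t in zip(pam, tail)):
                    continue
                mm = sum(a != b for a, b in zip(body, protospacer))
                if mm <= max_mm:
                    hits.add((contig, p, strand, mm))
    return hits


def quartiles_oracle(values: list[float]) -> tuple[float, float, float]:
    """Median/quartiles by explicit sort + linear interpolation."""
    xs = sorted(values)
    n = len(xs)

    def at(q: float) -> float:
        h = (n - 1) * q
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return at(0.5), at(0.25), at(0.75)
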