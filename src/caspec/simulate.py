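"""Synthetic data with known ground truth.

Two generators cover the two sequencing assays the pipeline analyses:

* :func:`simulate_amplicon_reads` emulates targeted amplicon deep-sequencing
  libraries — single-end reads (150 bp by default) drawn from an amplicon
  reference, a configurable fraction of which carry exactly one NHEJ-like
  indel anchored at (or jittered around) the predicted cleavage site, plus
  independent per-base substitution sequencing errors;
* :func:`simulate_guideseq_sample` emulates GUIDE-seq libraries — genome
  reads spanning the junction of an integrated dsODN tag at chosen loci, with
  PCR duplicates and a tag-free-locus background sample, against a mini-genome
  in which a protospacer-like sequence with a chosen mismatch count is planted
  at every tagged locus.

Neither generator models empirical error profiles (no quality-dependent
errors, no homopolymer artifacts) or microhomology-biased deletion spectra;
they exist to give every pipeline stage a ground truth, not to imitate a
particular instrument.

Read names encode the ground truth (edited flag, indel kind/size/anchor) as
``|key=value`` suffixes — a fixture convention for test introspection, also
written to the truth TSV.  Identical specs and seeds yield byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .indels import qualifies_params
from .io import write_fasta, write_fastq, write_tsv
from .regions import IUPAC, TargetRegion, revcomp

BASES = "ACGT"

# Default indel size spectrum: small deletions dominate NHEJ outcomes; the
# exact spectrum at any real locus is sequence-dependent and is a free
# parameter here, not a claim about any particular site.
DEFAULT_INDEL_SIZE_DIST = {-1: 0.35, -2: 0.15, -3: 0.10, -4: 0.05, -5: 0.05,
                           -7: 0.04, -10: 0.03, 1: 0.15, 2: 0.05, 3: 0.03}

DEFAULT_DSODN = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"  # arbitrary 34-mer tag

_EDGE_PAD = 10  # min distance between an indel/cut and either read end


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def make_mini_genome(n_contigs: int, length: int, seed: int) -> dict[str, str]:
    """Uniform-random A/C/G/T contigs named ``chr1..chrN``; deterministic."""
    if length < 1:
        raise ValueError("contig length must be >= 1")
    rng = _rng(seed)
    return {f"chr{i + 1}": _random_seq(rng, length) for i in range(n_contigs)}


def _concrete_pam(rng: np.random.Generator, pam: str) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(0, len(IUPAC[c]))]
                   for c in pam.upper())


def make_test_region(name: str = "region1", length: int = 250,
                     protospacer_start: int | None = None, strand: str = "+",
                     pam: str = "NGG", seed: int = 0) -> TargetRegion:
    """A random region with a protospacer + concrete PAM planted in it."""
    rng = _rng(seed)
    seq = list(_random_seq(rng, length))
    p = protospacer_start if protospacer_start is not None else (length - 23) // 2
    proto = "".join(seq[p:p + 20]) if strand == "+" else revcomp("".join(seq[p:p + 20]))
    pam_seq = _concrete_pam(rng, pam)
    if strand == "+":
        seq[p + 20:p + 23] = pam_seq
    else:
        seq[p - 3:p] = revcomp(pam_seq)
    return TargetRegion(name=name, sequence="".join(seq), protospacer=proto,
                        pam=pam, strand=strand, start=p)


# ---------------------------------------------------------------------------
# amplicon simulation
# ---------------------------------------------------------------------------

@dataclass
class AmpliconSimSpec:
    """Parameters of one simulated amplicon library."""

    region: TargetRegion
    editing_fraction: float = 0.2
    indel_size_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_SIZE_DIST))
    position_jitter: int = 0
    substitution_error_rate: float = 0.001
    read_length: int = 150
    n_reads: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.editing_fraction <= 1.0:
            raise ValueError("editing_fraction must lie in [0, 1]")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("substitution_error_rate must lie in [0, 1]")
        if self.position_jitter < 0:
            raise ValueError("position_jitter must be >= 0")
        if 0 in self.indel_size_dist:
            raise ValueError("indel size 0 is not an indel")
        total = sum(self.indel_size_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indel_size_dist probabilities sum to {total}, not 1")
        if len(self.region.sequence) < self.read_length:
            raise ValueError("region shorter than read_length")


def _amplicon_start_range(spec: AmpliconSimSpec) -> tuple[int, int]:
    region = spec.region
    cc = region.cleavage_coord
    max_del = max((-s for s in spec.indel_size_dist if s < 0), default=0)
    max_ins = max((s for s in spec.indel_size_dist if s > 0), default=0)
    reach = spec.position_jitter + max_del + max_ins + _EDGE_PAD
    lo = max(0, cc + 1 + reach - spec.read_length)
    hi = min(len(region.sequence) - spec.read_length - max_del, cc + 1 - reach)
    if lo > hi:
        bad = max(max_del, max_ins)
        raise ValueError(
            f"indel of size {bad} with jitter {spec.position_jitter} does not "
            f"fit between the cleavage site and the region/read bounds")
    return lo, hi


def _left_shift_deletion(ref: str, a: int, size: int) -> int:
    while a > 0 and ref[a - 1] == ref[a + size - 1]:
        a -= 1
    return a


def _left_shift_insertion(ref: str, point: int, ins: str) -> tuple[int, str]:
    while point > 0 and ins[-1] == ref[point - 1]:
        ins = ins[-1] + ins[:-1]
        point -= 1
    return point, ins


def simulate_amplicon_reads(spec: AmpliconSimSpec,
                            ) -> tuple[list[tuple[str, str]], list[dict]]:
    """Simulate one amplicon library.

    Returns ``(reads, truth)``: reads as (name, sequence) pairs, truth as one
    dict per read with the indel's left-aligned coordinates and whether it
    qualifies under the positional rule (flank 5, narrow adjacency).
    """
    rng = _rng(spec.seed)
    region = spec.region
    ref = region.sequence
    cc = region.cleavage_coord
    lo, hi = _amplicon_start_range(spec)
    sizes = sorted(spec.indel_size_dist)
    probs = np.array([spec.indel_size_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    reads: list[tuple[str, str]] = []
    truth: list[dict] = []
    for i in range(spec.n_reads):
        edited = bool(rng.random() < spec.editing_fraction)
        start = int(rng.integers(lo, hi + 1))
        row = {"read_id": "", "edited": int(edited), "kind": "none",
               "size": 0, "anchor": -1, "qualifies": 0}
        if not edited:
            seq = ref[start:start + spec.read_length]
            name = f"r{i:06d}|edited=0|kind=none|size=0|anchor=-1|q=0"
        else:
            signed = int(sizes[rng.choice(len(sizes), p=probs)])
            offset = int(rng.integers(-spec.position_jitter,
                                      spec.position_jitter + 1))
            anchor = cc + 1 + offset
            if signed < 0:
                size = -signed
                if anchor + size > len(ref):
                    raise ValueError(
                        f"deletion of size {size} extends past region end")
                template = ref[:anchor] + ref[anchor + size:]
                a = _left_shift_deletion(ref, anchor, size)
                kind, interval = "deletion", (a, a + size)
            else:
                size = signed
                ins = _random_seq(rng, size)
                template = ref[:anchor] + ins + ref[anchor:]
                a, _ = _left_shift_insertion(ref, anchor, ins)
                kind, interval = "insertion", (a, a)
            q = qualifies_params(size, kind, interval[0], interval[1], cc)
            seq = template[start:start + spec.read_length]
            row.update(kind=kind[:3], size=size, anchor=interval[0],
                       qualifies=int(q))
            name = (f"r{i:06d}|edited=1|kind={kind[:3]}|size={size}"
                    f"|anchor={interval[0]}|q={int(q)}")
        seq = _substitute(rng, seq, spec.substitution_error_rate)
        row["read_id"] = name.split("|")[0]
        reads.append((name, seq))
        truth.append(row)
    return reads, truth


TRUTH_COLUMNS = ["read_id", "edited", "kind", "size", "anchor", "qualifies"]


def write_amplicon_sample(spec: AmpliconSimSpec, outdir: str | Path,
                          prefix: str = "sample") -> dict[str, Path]:
    """Write FASTQ + truth TSV + region FASTA + annotation TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads, truth = simulate_amplicon_reads(spec)
    paths = {
        "fastq": outdir / f"{prefix}.fastq",
        "truth": outdir / f"{prefix}.truth.tsv",
        "fasta": outdir / f"{prefix}.regions.fasta",
        "annotations": outdir / f"{prefix}.annotations.tsv",
    }
    write_fastq(reads, paths["fastq"])
    write_tsv(truth, paths["truth"], TRUTH_COLUMNS)
    r = spec.region
    write_fasta({r.name: r.sequence}, paths["fasta"])
    write_tsv([{"region": r.name, "start": r.start, "end": r.end,
                "strand": r.strand, "protospacer": r.protospacer,
                "pam": r.pam}],
              paths["annotations"],
              ["region", "start", "end", "strand", "protospacer", "pam"])
    return paths


# ---------------------------------------------------------------------------
# GUIDE-seq simulation
# ---------------------------------------------------------------------------

@dataclass
class GuideSeqSimSpec:
    """Parameters of one simulated GUIDE-seq experiment (treatment +
    background sample over one mini-genome)."""

    genome: dict[str, str]
    protospacer: str
    pam: str = "NGG"
    dsodn_sequence: str = DEFAULT_DSODN
    true_sites: list[tuple[str, int, str, int]] = field(default_factory=list)
    reads_per_site: int = 20
    duplicate_rate: float = 0.3
    background_insertion_sites: list[tuple[str, int]] = field(default_factory=list)
    substitution_error_rate: float = 0.001
    read_length: int = 150
    seed: int = 0
    max_mismatches: int = 8
    collapse_window: int = 10

    MIN_FLANK = 15

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.dsodn_sequence) + 2 * self.MIN_FLANK > self.read_length:
            raise ValueError("dsODN too long for junction reads of this length")
        for contig, pos, strand, mm in self.true_sites:
            if contig not in self.genome:
                raise ValueError(f"true site on unknown contig {contig!r}")
            if not 30 <= pos <= len(self.genome[contig]) - 30:
                raise ValueError(f"true site {contig}:{pos} too close to contig edge")
            if strand not in "+-":
                raise ValueError("site strand must be '+' or '-'")
            if mm < 0:
                raise ValueError("mismatch count must be >= 0")
        for contig, pos in self.background_insertion_sites:
            if contig not in self.genome:
                raise ValueError(f"background site on unknown contig {contig!r}")
            for tcontig, tpos, _, _ in self.true_sites:
                if tcontig == contig and abs(tpos - pos) <= self.collapse_window:
                    raise ValueError(
                        f"background site {contig}:{pos} coincides with a true "
                        f"site (truth would be ambiguous)")


def _mutate_protospacer(rng: np.random.Generator, proto: str, n_mm: int) -> str:
    pos = rng.choice(len(proto), size=n_mm, replace=False)
    arr = list(proto)
    for p in pos:
        choices = [b for b in BASES if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def plant_target_sites(spec: GuideSeqSimSpec) -> dict[str, str]:
    """Return a copy of the genome with a protospacer-like 23-mer planted at
    every true site so that its predicted cut coincides with the integration
    coordinate (dsODN integrates in the Cas9 cut)."""
    rng = _rng(spec.seed ^ 0x5EED)
    genome = {k: list(v) for k, v in spec.genome.items()}
    for contig, pos, strand, mm in spec.true_sites:
        proto = _mutate_protospacer(rng, spec.protospacer.upper(), mm)
        pam = _concrete_pam(rng, spec.pam)
        if strand == "+":
            # cut between p+16 and p+17 -> junction j = p+17
            p = pos - 17
            genome[contig][p:p + 23] = proto + pam
        else:
            # cut between s+2 and s+3 -> junction j = s+3
            s = pos - 3
            genome[contig][s - 3:s + 20] = revcomp(proto + pam)
    return {k: "".join(v) for k, v in genome.items()}


def simulate_guideseq_sample(spec: GuideSeqSimSpec,
                             ) -> tuple[list[tuple[str, str]],
                                        list[tuple[str, str]],
                                        list[dict], dict[str, str]]:
    """Simulate a GUIDE-seq treatment + background pair.

    Treatment reads span dsODN-genome junctions at every true site *and* every
    background site (background tagging appears in both samples); the
    background sample has junction reads only at background sites.  A
    ``duplicate_rate`` fraction of reads per site are exact copies of an
    earlier read (PCR duplicates).

    Returns ``(treatment_reads, background_reads, truth_rows, genome)`` where
    ``genome`` carries the planted target sites and truth rows list each
    site's expected fate (surviving = true, mismatches <= max, not in
    background).
    """
    genome = plant_target_sites(spec)
    rng = _rng(spec.seed)
    dsodn = spec.dsodn_sequence.upper()

    def junction_reads(contig: str, pos: int, tag: str) -> tuple[list, int]:
        seq = genome[contig]
        reads = []
        templates: list[str] = []
        max_flank = spec.read_length - len(dsodn) - spec.MIN_FLANK
        for i in range(spec.reads_per_site):
            if templates and rng.random() < spec.duplicate_rate:
                read = templates[rng.integers(0, len(templates))]
            else:
                f = int(rng.integers(spec.MIN_FLANK, max_flank + 1))
                left = seq[max(0, pos - f):pos]
                right_len = spec.read_length - len(left) - len(dsodn)
                right = seq[pos:pos + right_len]
                read = _substitute(rng, left + dsodn + right,
                                   spec.substitution_error_rate)
                templates.append(read)
            reads.append((f"{tag}_{contig}_{pos}_r{i:04d}", read))
        return reads, len(set(templates))

    treatment: list[tuple[str, str]] = []
    background: list[tuple[str, str]] = []
    truth: list[dict] = []
    for contig, pos, strand, mm in spec.true_sites:
        reads, n_templates = junction_reads(contig, pos, "trt")
        treatment.extend(reads)
        truth.append({"contig": contig, "position": pos, "strand": strand,
                      "guide_mismatches": mm, "is_true_site": 1,
                      "in_background": 0, "n_templates": n_templates,
                      "expected_surviving": int(mm <= spec.max_mismatches)})
    for contig, pos in spec.background_insertion_sites:
        reads, n_templates = junction_reads(contig, pos, "trt")
        treatment.extend(reads)
        bg_reads, _ = junction_reads(contig, pos, "bkg")
        background.extend(bg_reads)
        truth.append({"contig": contig, "position": pos, "strand": ".",
                      "guide_mismatches": -1, "is_true_site": 0,
                      "in_background": 1, "n_templates": n_templates,
                      "expected_surviving": 0})
    return treatment, background, truth, genome


GUIDESEQ_TRUTH_COLUMNS = ["contig", "position", "strand", "guide_mismatches",
                          "is_true_site", "in_background", "n_templates",
                          "expected_surviving"]


def write_guideseq_sample(spec: GuideSeqSimSpec, outdir: str | Path,
                          prefix: str = "guideseq") -> dict[str, Path]:
    """Write treatment/background FASTQ, genome FASTA and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    treatment, bkg, truth, genome = simulate_guideseq_sample(spec)
    paths = {
        "treatment": outdir / f"{prefix}.treatment.fastq",
        "background": outdir / f"{prefix}.background.fastq",
        "genome": outdir / f"{prefix}.genome.fasta",
        "truth": outdir / f"{prefix}.truth.tsv",
    }
    write_fastq(treatment, paths["treatment"])
    write_fastq(bkg, paths["background"])
    write_fasta(genome, paths["genome"])
    write_tsv(truth, paths["truth"], GUIDESEQ_TRUTH_COLUMNS)
    return paths
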