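"""End-to-end stage orchestration shared by the CLI and scripted use.

Each runner takes file paths plus thresholds, produces TSV artifacts, and
drops a machine-readable provenance record (parameter hash, package version,
input checksums) next to them so any output can be re-derived from the record
alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

from . import __version__
from .align import RegionAligner, filter_by_mapq, import_sam
from .guideseq import call_guideseq_sites, render_site_alignment, scan_offtargets
from .indels import DEFAULT_FLANK, SiteEditingSummary, summarize_region
from .io import read_fasta, read_fastq, write_tsv
from .regions import build_region_index

DEEPSEQ_MIN_MAPQ = 30


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(outdir: str | Path, stage: str, params: Mapping,
                     inputs: Mapping[str, str | Path]) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {k: (str(v) if isinstance(v, Path) else v)
              for k, v in sorted(params.items())}
    record = {
        "stage": stage,
        "caspec_version": __version__,
        "parameters": params,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()).hexdigest(),
        "input_checksums": {k: _sha256(v) for k, v in sorted(inputs.items())},
    }
    path = outdir / f"{stage}.provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")
    return path


def quantify(fastq: str | Path, fasta: str | Path, annotations: str | Path,
             outdir: str | Path, *, min_mapq: int = DEEPSEQ_MIN_MAPQ,
             flank: int = DEFAULT_FLANK, adjacency_radius: int = 0,
             sam: str | Path | None = None,
             ) -> dict[str, SiteEditingSummary]:
    """Amplicon editing quantification: align (or import), filter, summarise.

    Writes ``editing_summary.tsv`` (one row per region; 1-based columns noted
    in the header) and a provenance record.  When ``sam`` is given the
    external alignments are imported instead of running the internal aligner.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = build_region_index(fasta, annotations)
    if sam is not None:
        alignments = import_sam(sam, regions)
    else:
        aligner = RegionAligner(regions)
        alignments = aligner.align_fastq(fastq)
    retained = filter_by_mapq(alignments, min_mapq)
    summaries: dict[str, SiteEditingSummary] = {}
    rows = []
    for name, region in regions.items():
        on_region = [a for a in retained if a.region == name]
        s = summarize_region(on_region, region, flank, adjacency_radius)
        summaries[name] = s
        rows.append({
            "region": name, "cleavage_coord_1based": region.cleavage_coord + 1,
            "n_reads": s.n_retained_reads, "n_qualifying": s.n_qualifying_reads,
            "pct_indels": f"{s.pct_indels:.4f}",
        })
    write_tsv(rows, outdir / "editing_summary.tsv",
              ["region", "cleavage_coord_1based", "n_reads", "n_qualifying",
               "pct_indels"],
              comments=[
                  "per-region editing summary; cleavage coordinate 1-based",
                  f"min_mapq={min_mapq} flank={flank} "
                  f"adjacency_radius={adjacency_radius}",
              ])
    inputs = {"fasta": fasta, "annotations": annotations}
    if sam is not None:
        inputs["sam"] = sam
    else:
        inputs["fastq"] = fastq
    write_provenance(outdir, "quantify",
                     {"min_mapq": min_mapq, "flank": flank,
                      "adjacency_radius": adjacency_radius}, inputs)
    return summaries


def run_guideseq(treatment: str | Path, background: str | Path,
                 genome_fasta: str | Path, protospacer: str, outdir: str | Path,
                 *, pam: str = "NGG", dsodn: str | None = None,
                 min_mapq: int = 50, min_reads: int = 2,
                 collapse_window: int = 10, max_mm: int = 8) -> list:
    """GUIDE-seq site calling from FASTQ pairs; writes TSV + BED + provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_fasta)
    trt = [(rid, seq) for rid, seq, _ in read_fastq(treatment)]
    bkg = [(rid, seq) for rid, seq, _ in read_fastq(background)]
    sites = call_guideseq_sites(
        trt, bkg, genome, protospacer, pam, dsodn, min_mapq=min_mapq,
        min_reads=min_reads, collapse_window=collapse_window, max_mm=max_mm)
    rows = []
    for s in sites:
        ta = s.target_alignment
        rows.append({
            "contig": s.contig, "position": s.position, "strand": s.strand,
            "reads": s.consolidated_read_count,
            "mismatches": ta.mismatch_count if ta else "",
            "site_sequence": ta.site_sequence if ta else "",
            "alignment": render_site_alignment(protospacer, pam,
                                               ta.site_sequence) if ta else "",
        })
    write_tsv(rows, outdir / "guideseq_sites.tsv",
              ["contig", "position", "strand", "reads", "mismatches",
               "site_sequence", "alignment"],
              comments=[
                  "dsODN integration sites (position 0-based); '.' = match "
                  "to protospacer",
                  f"min_mapq={min_mapq} min_reads={min_reads} "
                  f"collapse_window={collapse_window} max_mm={max_mm}",
              ])
    with open(outdir / "guideseq_sites.bed", "w") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t"
                     f"site\t{s.consolidated_read_count}\t{s.strand}\n")
    write_provenance(outdir, "guideseq",
                     {"protospacer": protospacer, "pam": pam,
                      "min_mapq": min_mapq, "min_reads": min_reads,
                      "collapse_window": collapse_window, "max_mm": max_mm},
                     {"treatment": treatment, "background": background,
                      "genome": genome_fasta})
    return sites


def run_scan(genome_fasta: str | Path, protospacer: str, outdir: str | Path,
             *, pam: str = "NGG", max_mm: int = 4) -> list:
    """Brute-force in-silico off-target scan; writes TSV + provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_fasta)
    cands = scan_offtargets(genome, protospacer, pam, max_mm)
    rows = [{
        "contig": c.contig, "position": c.position, "strand": c.strand,
        "mismatches": c.mismatch_count, "site_sequence": c.site_sequence,
        "alignment": render_site_alignment(protospacer, pam, c.site_sequence),
    } for c in cands]
    write_tsv(rows, outdir / "offtarget_candidates.tsv",
              ["contig", "position", "strand", "mismatches", "site_sequence",
               "alignment"],
              comments=["position 0-based, forward-strand start of the site",
                        f"pam={pam} max_mm={max_mm}"])
    write_provenance(outdir, "scan",
                     {"protospacer": protospacer, "pam": pam, "max_mm": max_mm},
                     {"genome": genome_fasta})
    return cands
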