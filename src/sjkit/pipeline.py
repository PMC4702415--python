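"""End-to-end orchestration: discover -> infer -> assemble -> orf (-> aei, assoc).

Writes GTF/FASTA/TSV outputs plus a machine-readable run manifest recording
the configuration hash, input hashes and per-stage record counts, so a rerun
with identical config and inputs yields identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

from . import __version__
from .allelic import aei_table
from .assembly import AssemblyConstraints, build_graph, enumerate_isoforms, transcript_sequence
from .coding import assess_transcript
from .exons import CoverageTrack, infer_exons, scan_polya
from .io import (
    PipelineConfig,
    read_alignments,
    read_fasta,
    write_exon_gtf,
    write_fasta,
    write_junction_tsv,
)
from .junctions import extract_junctions
from .models import FrequencyClass

log = logging.getLogger("sjkit")

_CLASS_BY_NAME = {c.name.lower(): c for c in FrequencyClass}


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    sam_paths,
    genome_path,
    out_dir,
    allelic_tsv=None,
) -> dict:
    """Run the discovery pipeline on SAM inputs; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(vars(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): _hash_file(p) for p in list(sam_paths) + [genome_path]},
        "stages": [],
    }

    genome = read_fasta(genome_path)
    region = None
    if config.region:
        chrom, _, span = config.region.partition(":")
        if span:
            lo, _, hi = span.partition("-")
            region = (chrom, int(lo) - 1, int(hi))
        else:
            region = (chrom, 0, len(genome[chrom]))

    reads = []
    skipped = 0
    for path in sam_paths:
        r, s = read_alignments(path, region)
        reads.extend(r)
        skipped += s
    manifest["stages"].append({"stage": "read", "reads": len(reads), "skipped": skipped})

    table = extract_junctions(reads, genome, min_intron=config.min_intron)
    write_junction_tsv(out / "junctions.tsv", table)
    manifest["stages"].append(
        {
            "stage": "discover",
            "junctions": len(table),
            "discarded_noncanonical": table.discarded_noncanonical,
        }
    )

    all_exons = []
    transcripts = {}
    for strand in "+-":
        stranded = table.restrict_strand(strand)
        if len(stranded) == 0:
            continue
        chrom = next(iter(stranded)).chrom
        lo = min(j.start for j in stranded) - 2000
        hi = max(j.end for j in stranded) + 2000
        coverage = CoverageTrack.from_reads(reads, chrom, max(0, lo), min(hi, len(genome[chrom])))
        exons = infer_exons(
            stranded, coverage, strand, floor_fraction=config.coverage_floor_fraction
        )
        all_exons.extend(exons)
        graph = build_graph(exons, stranded)
        constraints = AssemblyConstraints(
            exclude_classes=frozenset(
                _CLASS_BY_NAME[c] for c in config.exclude_classes
            ),
            max_low_edges=config.max_low_edges,
            allowed_end_exons=config.allowed_end_exons,
        )
        for model in enumerate_isoforms(graph, constraints):
            transcript_sequence(model, genome)
            transcripts[f"{strand}{model.id}"] = model
    write_exon_gtf(out / "exons.gtf", all_exons)
    manifest["stages"].append({"stage": "infer", "exons": len(all_exons)})
    manifest["stages"].append({"stage": "assemble", "isoforms": len(transcripts)})

    write_fasta(out / "transcripts.fa", {k: m.sequence for k, m in transcripts.items()})
    orf_rows = []
    for name, model in transcripts.items():
        summary = assess_transcript(model.sequence)
        orf_rows.append(
            f"{name}\t{len(model.sequence)}\t{summary['orf_aa']}\t"
            f"{summary['tm_count']}\t{summary['coding_call']}"
        )
    (out / "coding.tsv").write_text(
        "transcript\tlength_nt\torf_aa\ttm_count\tcoding_call\n"
        + "".join(r + "\n" for r in orf_rows)
    )
    manifest["stages"].append({"stage": "orf", "assessed": len(orf_rows)})

    if allelic_tsv is not None:
        from .io import read_allelic_tsv

        counts = read_allelic_tsv(allelic_tsv)
        results = aei_table(
            counts,
            p0=config.aei_p0,
            min_depth=config.aei_min_depth,
            alpha=config.aei_alpha,
        )
        with open(out / "aei.tsv", "w") as fh:
            fh.write("sample\tcount_a1\tcount_a2\tp_raw\tp_corrected\tfold\tsignificant\n")
            for r in results:
                fh.write(
                    f"{r.sample_id}\t{r.count_a1}\t{r.count_a2}\t{r.p_raw:.6g}\t"
                    f"{r.p_corrected:.6g}\t{r.fold}\t{r.significant}\n"
                )
        manifest["stages"].append({"stage": "aei", "tested": len(results)})

    manifest["n_stages"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
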