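"""Readers and writers for the standard formats the pipeline touches.

SAM is the alignment interchange format (no BAM requirement in the core
reader, so desk-scale fixtures stay plain text); FASTA for genomes and
transcripts, GTF/BED for gene models and tracks, TSV for reports, VCF for
genotypes (GT field) and allelic depths (AD field), YAML for configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam
import yaml

from .junctions import GappedRead, JunctionTable, classify_frequency
from .models import AllelicCount, ExonModel, TranscriptModel

__all__ = [
    "read_alignments",
    "write_sam",
    "read_fasta",
    "write_fasta",
    "write_exon_gtf",
    "write_junction_tsv",
    "write_junction_bed",
    "read_allelic_tsv",
    "read_genotype_vcf",
    "PipelineConfig",
]


def read_alignments(path, region: Optional[tuple] = None):
    """Yield :class:`GappedRead` records from a SAM file (header required).

    ``region`` is an optional (chrom, start, end) half-open filter applied to
    the alignment span. Unmapped and secondary/supplementary records are
    skipped; the generator's ``.skipped`` attribute is unavailable, so the
    function returns (reads, n_skipped) as a list and count.
    """
    reads = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            if rec.cigartuples is None:
                skipped += 1
                continue
            read = GappedRead.from_cigar(
                sample_id=_sample_of(rec),
                chrom=rec.reference_name,
                pos=rec.reference_start,
                cigar=rec.cigartuples,
            )
            if region is not None:
                chrom, start, end = region
                span_end = read.blocks[-1][1] if read.blocks else read.pos
                if read.chrom != chrom or span_end <= start or read.pos >= end:
                    continue
            reads.append(read)
    return reads, skipped


def _sample_of(rec) -> str:
    try:
        return rec.get_tag("RG")
    except KeyError:
        return "sample"


def write_sam(path, reads: Sequence[GappedRead], genome: Mapping[str, str]) -> None:
    """Write gapped reads as a minimal SAM with per-sample read groups."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
        "RG": [{"ID": s} for s in sorted({r.sample_id for r in reads})],
    }
    chrom_ids = {c: i for i, c in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(reads):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"r{i:07d}"
            rec.reference_id = chrom_ids[read.chrom]
            rec.reference_start = read.pos
            rec.mapping_quality = 60
            cigar = []
            prev_end = None
            for bstart, bend in read.blocks:
                if prev_end is not None and bstart > prev_end:
                    cigar.append((3, bstart - prev_end))  # N
                cigar.append((0, bend - bstart))  # M
                prev_end = bend
            rec.cigartuples = cigar
            length = sum(n for op, n in cigar if op == 0)
            rec.query_sequence = "A" * length
            rec.flag = 0
            rec.set_tag("RG", read.sample_id)
            out.write(rec)


def read_fasta(path) -> dict:
    seqs = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            seqs[entry.name] = entry.sequence
    return seqs


def write_fasta(path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_exon_gtf(path, exons: Sequence[ExonModel], source: str = "sjkit") -> None:
    """Exon models as GTF (1-based inclusive) with role/variant attributes."""
    with open(path, "w") as fh:
        for exon in exons:
            chrom, start1, end1 = exon.interval.to_display()
            attrs = (
                f'exon_id "{exon.id}"; variant_group "{exon.variant_group}"; '
                f'role "{exon.role.value}";'
            )
            fh.write(
                f"{chrom}\t{source}\texon\t{start1}\t{end1}\t.\t{exon.strand}\t.\t{attrs}\n"
            )


def write_junction_tsv(path, table: JunctionTable) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\ttotal_reads\tn_samples\tclass\n")
        for jx, tier in table.classified():
            fh.write(
                f"{jx.chrom}\t{jx.start}\t{jx.end}\t{jx.strand}\t"
                f"{jx.total_reads}\t{jx.n_samples}\t{tier}\n"
            )


def write_junction_bed(path, table: JunctionTable, anchor: int = 20) -> None:
    """BED12 junction track: two anchor blocks flanking each intron."""
    with open(path, "w") as fh:
        for jx, tier in table.classified():
            chrom_start = jx.start - anchor
            chrom_end = jx.end + anchor
            name = f"{tier}|{jx.total_reads}r|{jx.n_samples}s"
            fh.write(
                "\t".join(
                    [
                        jx.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        name,
                        str(min(1000, jx.total_reads)),
                        jx.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0,0,0",
                        "2",
                        f"{anchor},{anchor}",
                        f"0,{jx.end - chrom_start}",
                    ]
                )
                + "\n"
            )


def read_allelic_tsv(path) -> list:
    """TSV of (sample_id, site_id, allele1, allele2, count1, count2)."""
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            rec = dict(zip(header, parts))
            out.append(
                AllelicCount(
                    sample_id=rec["sample_id"],
                    site_id=rec["site_id"],
                    count_a1=int(rec["count1"]),
                    count_a2=int(rec["count2"]),
                )
            )
    return out


def read_genotype_vcf(path) -> dict:
    """Genotype dosage (0/1/2 variant copies, None missing) per SNP per sample."""
    out: dict = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            row = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[s] = None
                else:
                    row[s] = int(sum(1 for a in gt if a != 0))
            out[snp_id] = row
    return out


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serializable to one YAML file."""

    region: Optional[str] = None
    min_intron: int = 20
    polya_hexamers: tuple = ("AATAAA", "ATTAAA")
    dropoff_theta: float = 0.2
    dropoff_window: int = 100
    coverage_floor_fraction: float = 0.1
    max_low_edges: int = 1
    exclude_classes: tuple = ("rare",)
    allowed_end_exons: Optional[tuple] = None
    aei_p0: float = 0.5
    aei_min_depth: int = 10
    aei_alpha: float = 0.05
    assoc_alpha: float = 0.2
    candidate_covariates: tuple = ()
    seed: int = 0

    def save(self, path) -> None:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        kwargs = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in payload.items()
        }
        return cls(**kwargs)
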