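"""Domain types and coordinate conventions shared by every pipeline stage.

Coordinates are held internally as 0-based half-open intervals (the BED
convention): an interval ``[start, end)`` has ``length = end - start``.
Human-readable tables and GTF output use 1-based inclusive coordinates;
:func:`GenomicInterval.from_display` / :meth:`GenomicInterval.to_display`
convert between the two without off-by-one ambiguity.

The module also ships TSV transcriptions of the published HTR2A /
HTR2A-AS1 locus catalogues (exons, junctions, allelic counts) used as
desk-scale fixtures throughout the test-suite and acceptance checks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "ExonRole",
    "ExonModel",
    "SpliceJunction",
    "FrequencyClass",
    "TranscriptModel",
    "AllelicCount",
    "SampleRecord",
    "GenotypeRecord",
    "CANDIDATE_COVARIATES",
    "interval_length",
    "display_length",
    "collapse_variant_groups",
    "assign_variant_groups",
    "locus_span",
    "load_sense_exon_table",
    "load_antisense_exon_table",
    "load_sense_junction_table",
    "load_allelic_count_table",
    "exons_from_table",
]

#: Candidate covariates for the genotype-expression models (fixed roster).
CANDIDATE_COVARIATES = (
    "age",
    "race",
    "gender",
    "diagnosis",
    "alcohol",
    "smoking",
    "pmi",
    "ph",
    "rin",
    "suicide",
)


class InvalidIntervalError(ValueError):
    """Raised for empty or inverted genomic intervals."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidIntervalError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @classmethod
    def from_display(cls, chrom: str, start1: int, end1: int, strand: str = "+") -> "GenomicInterval":
        """Build from 1-based inclusive display coordinates."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_display(self) -> tuple[str, int, int]:
        """Return (chrom, start, end) in 1-based inclusive convention."""
        return (self.chrom, self.start + 1, self.end)

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length of an interval in nucleotides (half-open arithmetic)."""
    return iv.length()


def display_length(start1: int, end1: int) -> int:
    """Length implied by 1-based inclusive display coordinates.

    ``chr13:47,466,525-47,466,725`` spans 201 nt.
    """
    if end1 < start1:
        raise InvalidIntervalError(f"inverted display interval {start1}-{end1}")
    return end1 - start1 + 1


class ExonRole(str, enum.Enum):
    TSS_CANDIDATE = "TSS-candidate"
    INTERNAL = "internal"
    TERMINAL_CANDIDATE = "terminal-candidate"


@dataclass
class ExonModel:
    """A genomic exon with role flags and a variant-group label.

    Exons that are alternative boundary versions of one exon locus (e.g. an
    extended or truncated form) share a ``variant_group`` label; a transcript
    uses at most one member per group.
    """

    id: str
    interval: GenomicInterval
    role: ExonRole = ExonRole.INTERNAL
    roles: set = field(default_factory=set)
    variant_group: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.variant_group:
            self.variant_group = self.id
        if not self.roles:
            self.roles = {self.role}

    @property
    def strand(self) -> str:
        return self.interval.strand

    def five_prime(self) -> int:
        """Genomic coordinate of the 5' boundary in transcription orientation."""
        return self.interval.start if self.strand == "+" else self.interval.end

    def three_prime(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


class FrequencyClass(enum.IntEnum):
    """Ordered junction abundance tiers: rare < low < medium < high."""

    RARE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    def __str__(self) -> str:  # used in TSV/report output
        return self.name.lower()


@dataclass
class SpliceJunction:
    """A strand-resolved intron supported by gapped reads.

    ``donor_end`` / ``acceptor_start`` are held genomically as the 0-based
    half-open intron ``[start, end)``; transcription orientation follows from
    ``strand`` (on the minus strand the donor site sits at the genomic end).
    """

    chrom: str
    start: int
    end: int
    strand: str
    counts: dict = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_samples(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)

    @property
    def donor_site(self) -> int:
        """Genomic position of the intron's transcriptional 5' end."""
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_site(self) -> int:
        return self.end if self.strand == "+" else self.start

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class TranscriptModel:
    """An ordered exon chain with sequence/ORF/coding annotations."""

    exon_chain: list  # ExonModel, transcription order
    junctions: list = field(default_factory=list)
    sequence: str = ""
    orf: Optional[object] = None
    tm_count: Optional[int] = None
    coding_call: str = ""

    @property
    def id(self) -> str:
        return "|".join(e.id for e in self.exon_chain)

    @property
    def length_nt(self) -> int:
        return sum(e.interval.length() for e in self.exon_chain)


@dataclass(frozen=True)
class AllelicCount:
    """Reference/alternate read counts at one heterozygous site in one sample."""

    sample_id: str
    site_id: str
    count_a1: int
    count_a2: int

    def __post_init__(self) -> None:
        if self.count_a1 < 0 or self.count_a2 < 0:
            raise ValueError("allelic counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.count_a1 + self.count_a2


@dataclass
class SampleRecord:
    sample_id: str
    diagnosis: str = ""
    covariates: dict = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.covariates) - set(CANDIDATE_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass(frozen=True)
class GenotypeRecord:
    sample_id: str
    snp_id: str
    genotype: Optional[int]  # 0/1/2 copies of the variant allele, None = missing

    def __post_init__(self) -> None:
        if self.genotype is not None and self.genotype not in (0, 1, 2):
            raise ValueError(f"genotype must be 0/1/2 or None, got {self.genotype}")


# ---------------------------------------------------------------------------
# variant-group handling


def assign_variant_groups(exons: Sequence[ExonModel]) -> None:
    """Group same-strand overlapping exons that share one splice boundary.

    Used for de-novo discovered exons, where alternative donor/acceptor usage
    produces overlapping intervals anchored at a common boundary. Grouping is
    the transitive closure of "overlap and share at least one boundary", so a
    chain of boundary-sharing variants collapses to one locus. Exons carrying
    a curated group label from input are left untouched by the caller.
    """
    n = len(exons)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = exons[i], exons[j]
            if a.strand != b.strand or not a.interval.overlaps(b.interval):
                continue
            shared = {a.interval.start, a.interval.end} & {
                b.interval.start,
                b.interval.end,
            }
            if shared:
                parent[find(i)] = find(j)
    for i, exon in enumerate(exons):
        exon.variant_group = exons[find(i)].id


def collapse_variant_groups(exons: Iterable[ExonModel]) -> int:
    """Number of distinct exon loci after collapsing boundary variants."""
    return len({e.variant_group for e in exons})


def locus_span(exons: Sequence[ExonModel]) -> int:
    """Genomic span (nt) covered by an exon set on one chromosome."""
    if not exons:
        raise ValueError("locus_span of an empty exon list is undefined")
    chroms = {e.interval.chrom for e in exons}
    if len(chroms) != 1:
        raise ValueError(f"exons span multiple chromosomes: {sorted(chroms)}")
    return max(e.interval.end for e in exons) - min(e.interval.start for e in exons)


# ---------------------------------------------------------------------------
# fixture tables


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("sjkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype={"exon": str, "sample": str})


def load_sense_exon_table() -> pd.DataFrame:
    """HTR2A exon catalogue (11 rows, reverse strand, hg19 display coords)."""
    return _read_fixture("htr2a_exons.tsv")


def load_antisense_exon_table() -> pd.DataFrame:
    """HTR2A-AS1 exon catalogue (22 rows, forward strand)."""
    return _read_fixture("htr2a_as1_exons.tsv")


def load_sense_junction_table() -> pd.DataFrame:
    """HTR2A splice-junction read totals summed across 211 samples."""
    return _read_fixture("htr2a_junctions.tsv")


def load_allelic_count_table() -> pd.DataFrame:
    """Per-sample rs6313 allelic counts for the 9 significantly imbalanced samples."""
    return _read_fixture("rs6313_allelic_counts.tsv")


def exons_from_table(table: pd.DataFrame) -> list:
    """Materialize :class:`ExonModel` objects from a fixture exon table."""
    out = []
    for row in table.itertuples(index=False):
        out.append(
            ExonModel(
                id=str(row.exon),
                interval=GenomicInterval.from_display(
                    row.chrom, int(row.start), int(row.end), row.strand
                ),
                variant_group=str(row.variant_group),
                notes=str(getattr(row, "notes", "") or ""),
            )
        )
    return out
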