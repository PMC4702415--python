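"""Splice-junction discovery from gapped alignments.

A gapped alignment (CIGAR ``N`` operation) is evidence for an intron. The
transcribed strand is inferred from the canonical spliceosomal dinucleotides:
an intron whose genomic sequence begins ``GT`` and ends ``AG`` was spliced
from a plus-strand transcript, while ``CT...AC`` (the reverse complement of
``GT...AG``) was spliced from a minus-strand transcript. Gaps matching
neither pattern are discarded (strictly canonical rule) but tallied so the
cost of the filter is visible. This strand assignment is what lets reads be
attributed unambiguously to one of two genes overlapping on opposite strands.

Junction abundance is classified into ordered tiers using joint thresholds on
total reads and on the number of samples contributing at least one read:
rare (1 read / 1 sample), low (>=2 / >=2), medium (>=25 / >=25) and
high (>=100 / >=100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .models import FrequencyClass, SpliceJunction

__all__ = [
    "GappedRead",
    "JunctionTable",
    "extract_junctions",
    "aggregate",
    "classify_frequency",
    "DEFAULT_MIN_INTRON",
]

#: Gaps shorter than this are treated as deletions, not introns.
DEFAULT_MIN_INTRON = 20

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GappedRead:
    """A minimal alignment record: matched blocks plus skipped-region gaps.

    ``blocks`` are 0-based half-open genomic intervals covered by the read;
    ``gaps`` are the skipped regions between consecutive blocks.
    """

    sample_id: str
    chrom: str
    pos: int
    blocks: list  # [(start, end), ...] genomic, sorted
    gaps: list = field(default_factory=list)  # [(start, end), ...]

    @classmethod
    def from_cigar(cls, sample_id: str, chrom: str, pos: int, cigar: Sequence[tuple]) -> "GappedRead":
        """Build from pysam-style (op, length) tuples; consumes M/I/D/N/S (0/1/2/3/4)."""
        blocks, gaps = [], []
        ref = pos
        block_start = pos
        open_block = False
        for op, length in cigar:
            if op == 0:  # M (also treat =/X as matches)
                if not open_block:
                    block_start = ref
                    open_block = True
                ref += length
            elif op in (7, 8):
                if not open_block:
                    block_start = ref
                    open_block = True
                ref += length
            elif op == 2:  # D consumes reference but keeps the block open
                ref += length
            elif op == 3:  # N closes the block and opens a gap
                if open_block:
                    blocks.append((block_start, ref))
                    open_block = False
                gaps.append((ref, ref + length))
                ref += length
            elif op in (1, 4, 5):  # I / S / H consume no reference
                continue
            else:
                raise ValueError(f"unsupported CIGAR op {op}")
        if open_block:
            blocks.append((block_start, ref))
        return cls(sample_id=sample_id, chrom=chrom, pos=pos, blocks=blocks, gaps=gaps)


class JunctionTable:
    """Mapping of (chrom, intron start, intron end, strand) -> SpliceJunction."""

    def __init__(self) -> None:
        self._table: dict = {}
        self.discarded_noncanonical = 0
        self.ignored_short_gaps = 0

    def __len__(self) -> int:
        return len(self._table)

    def __iter__(self):
        return iter(sorted(self._table.values(), key=lambda j: j.key()))

    def __contains__(self, key) -> bool:
        return key in self._table

    def get(self, key) -> SpliceJunction:
        return self._table[key]

    def add_count(self, chrom: str, start: int, end: int, strand: str, sample_id: str, n: int = 1) -> None:
        key = (chrom, start, end, strand)
        jx = self._table.get(key)
        if jx is None:
            jx = SpliceJunction(chrom=chrom, start=start, end=end, strand=strand)
            self._table[key] = jx
        jx.counts[sample_id] = jx.counts.get(sample_id, 0) + n

    def restrict_strand(self, strand: str) -> "JunctionTable":
        out = JunctionTable()
        for key, jx in self._table.items():
            if jx.strand == strand:
                out._table[key] = jx
        return out

    def classified(self) -> list:
        """Junctions paired with their frequency class, deterministic order."""
        return [(jx, classify_frequency(jx.total_reads, jx.n_samples)) for jx in self]


def _gap_strand(genome_seq: str, start: int, end: int) -> str | None:
    """Canonical-splice strand call for a genomic gap, or None."""
    donor = genome_seq[start : start + 2].upper()
    acceptor = genome_seq[end - 2 : end].upper()
    plus = donor == "GT" and acceptor == "AG"
    minus = donor == "CT" and acceptor == "AC"
    if plus:  # if a pathological genome matched both, plus wins (deterministic)
        return "+"
    if minus:
        return "-"
    return None


def extract_junctions(
    reads: Iterable[GappedRead],
    genome: Mapping[str, str],
    min_intron: int = DEFAULT_MIN_INTRON,
) -> JunctionTable:
    """Collect stranded, canonically spliced junctions from gapped reads.

    Every qualifying gap of every read contributes one count to exactly one
    stranded junction (a read crossing two introns supports both). Gaps
    shorter than ``min_intron`` are treated as deletions and ignored; gaps
    with non-canonical termini are discarded and tallied.
    """
    table = JunctionTable()
    for read in reads:
        try:
            chrom_seq = genome[read.chrom]
        except KeyError:
            raise KeyError(f"chromosome {read.chrom!r} absent from genome") from None
        seq = str(chrom_seq)
        for gstart, gend in read.gaps:
            if gend - gstart < min_intron:
                table.ignored_short_gaps += 1
                continue
            strand = _gap_strand(seq, gstart, gend)
            if strand is None:
                table.discarded_noncanonical += 1
                continue
            table.add_count(read.chrom, gstart, gend, strand, read.sample_id)
    return table


def aggregate(tables: Sequence[JunctionTable]) -> JunctionTable:
    """Merge per-sample junction tables, keeping the per-sample count map.

    Raises if two input tables carry counts for the same sample id at any
    junction (double-counting guard).
    """
    out = JunctionTable()
    seen_samples: dict = {}
    for idx, table in enumerate(tables):
        out.discarded_noncanonical += table.discarded_noncanonical
        out.ignored_short_gaps += table.ignored_short_gaps
        for jx in table:
            for sample_id, n in jx.counts.items():
                prev = seen_samples.get(sample_id)
                if prev is not None and prev != idx:
                    raise ValueError(f"duplicate sample_id {sample_id!r} across tables")
                seen_samples[sample_id] = idx
                out.add_count(jx.chrom, jx.start, jx.end, jx.strand, sample_id, n)
    return out


_THRESHOLDS = (
    (FrequencyClass.HIGH, 100, 100),
    (FrequencyClass.MEDIUM, 25, 25),
    (FrequencyClass.LOW, 2, 2),
)


def classify_frequency(total_reads: int, n_samples: int) -> FrequencyClass:
    """Abundance tier from total reads and number of supporting samples.

    The highest tier whose read and sample minimums are both met; a single
    read in a single sample is rare.
    """
    if total_reads < 1 or n_samples < 1:
        raise ValueError("a junction must have at least one read in one sample")
    if total_reads < n_samples:
        raise ValueError("total_reads cannot be smaller than n_samples")
    for cls, min_reads, min_samples in _THRESHOLDS:
        if total_reads >= min_reads and n_samples >= min_samples:
            return cls
    return FrequencyClass.RARE
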