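"""Exon inference from stranded junctions plus per-base coverage.

Splice junctions pin exon boundaries exactly: every acceptor position opens
an exon and every donor position closes one. Ends that no junction defines
(first and last exons, retained introns) are extended along contiguous
coverage until depth falls below a floor fraction of the exon's internal
median depth. Role flags follow transcription orientation: an exon with no
incoming junction at its 5' boundary is a transcription-start candidate; one
with no outgoing junction at its 3' boundary is a terminal candidate.
Terminal ends are then refined by scanning for polyadenylation signal
hexamers and for a sharp coverage drop-off downstream of the last signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .junctions import JunctionTable, revcomp
from .models import ExonModel, ExonRole, GenomicInterval

__all__ = [
    "CoverageTrack",
    "PolyASite",
    "TerminalCall",
    "infer_exons",
    "scan_polya",
    "detect_dropoff",
    "call_terminal",
    "DEFAULT_POLYA_HEXAMERS",
    "EXTENDED_POLYA_HEXAMERS",
]

#: Canonical signal plus the most common non-canonical variant.
DEFAULT_POLYA_HEXAMERS = ("AATAAA", "ATTAAA")

#: The extended 12-hexamer signal set (Beaudoing et al. catalogue).
EXTENDED_POLYA_HEXAMERS = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AAGAAA", "AATATA",
    "AATACA", "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA",
)

#: Boundary-less ends extend while depth >= this fraction of internal median.
COVERAGE_FLOOR_FRACTION = 0.1

#: Coverage drop-off: downstream mean <= theta * upstream mean.
DROPOFF_THETA = 0.2
DROPOFF_WINDOW = 100


@dataclass
class CoverageTrack:
    """Strand-agnostic per-base read depth over a region ``[start, end)``."""

    chrom: str
    start: int
    depth: np.ndarray  # non-negative ints

    @property
    def end(self) -> int:
        return self.start + len(self.depth)

    def at(self, pos: int) -> int:
        if pos < self.start or pos >= self.end:
            return 0
        return int(self.depth[pos - self.start])

    def window_mean(self, lo: int, hi: int) -> float:
        """Mean depth over genomic [lo, hi), zero-padded outside the track."""
        lo_i = max(lo, self.start) - self.start
        hi_i = min(hi, self.end) - self.start
        if hi_i <= lo_i:
            return 0.0
        return float(self.depth[lo_i:hi_i].sum()) / (hi - lo)

    @classmethod
    def from_reads(cls, reads, chrom: str, start: int, end: int) -> "CoverageTrack":
        depth = np.zeros(end - start, dtype=np.int64)
        for read in reads:
            if read.chrom != chrom:
                continue
            for bstart, bend in read.blocks:
                lo, hi = max(bstart, start), min(bend, end)
                if lo < hi:
                    depth[lo - start : hi - start] += 1
        return cls(chrom=chrom, start=start, depth=depth)


@dataclass(frozen=True)
class PolyASite:
    """A polyadenylation signal hexamer, positioned at its first base
    in transcription orientation."""

    position: int
    hexamer: str
    canonical: bool


@dataclass
class TerminalCall:
    exon_id: str
    terminus: int  # genomic position of the transcript 3' end
    confident: bool
    supporting_signal: Optional[PolyASite] = None


def _extend(coverage: CoverageTrack, pos: int, direction: int, floor: float) -> int:
    """Walk from ``pos`` in ``direction`` while depth stays >= floor.

    Returns the first position past the extension (half-open friendly for
    direction=+1; for direction=-1 returns the last covered position).
    """
    cur = pos
    while True:
        nxt = cur + direction
        if nxt < coverage.start or nxt >= coverage.end:
            break
        if coverage.at(nxt) < floor:
            break
        cur = nxt
    return cur


def infer_exons(
    junctions: JunctionTable,
    coverage: CoverageTrack,
    strand: str,
    floor_fraction: float = COVERAGE_FLOOR_FRACTION,
) -> list:
    """Exon models for one strand from its junction table and coverage.

    Boundaries defined by junctions are exact; ends without a junction are
    extended along contiguous coverage at >= ``floor_fraction`` of the median
    depth between the exon's defined boundaries. Exons sharing a junction
    boundary inside one covered block are grouped as variants of one locus.
    """
    jxs = list(junctions)
    for jx in jxs:
        if jx.strand != strand:
            raise ValueError(
                f"junction {jx.key()} is not on the requested strand {strand}"
            )
        if jx.start >= jx.end:
            raise ValueError(f"inverted junction {jx.key()}")
    chrom = coverage.chrom
    # genomic-left exon starts come from intron ends; genomic-right exon ends
    # from intron starts — on both strands (roles differ, geometry does not).
    left_bounds = sorted({jx.end for jx in jxs})
    right_bounds = sorted({jx.start for jx in jxs})
    # junction-defined boundary sets in transcription orientation
    acceptor_pos = {jx.acceptor_site for jx in jxs}
    donor_pos = {jx.donor_site for jx in jxs}

    covered = coverage.depth > 0
    exons: list = []
    # candidate exon segments: pair each left boundary with the nearest right
    # boundary in the same covered block; boundary-less sides use extension.
    all_bounds = sorted(set(left_bounds) | set(right_bounds))

    def block_limits(pos: int) -> tuple[int, int]:
        """Contiguous covered block [lo, hi) containing pos (or around it)."""
        idx = min(max(pos - coverage.start, 0), len(covered) - 1)
        if not covered[idx]:
            return pos, pos
        lo = idx
        while lo > 0 and covered[lo - 1]:
            lo -= 1
        hi = idx
        while hi < len(covered) - 1 and covered[hi + 1]:
            hi += 1
        return lo + coverage.start, hi + 1 + coverage.start

    used_pairs = set()

    def add_exon(gstart: int, gend: int, left_defined: bool, right_defined: bool) -> None:
        if gend <= gstart or (gstart, gend) in used_pairs:
            return
        used_pairs.add((gstart, gend))
        iv = GenomicInterval(chrom, gstart, gend, strand)
        exon = ExonModel(id=f"{chrom}:{gstart + 1}-{gend}", interval=iv)
        roles = set()
        if strand == "+":
            if gstart not in acceptor_pos:
                roles.add(ExonRole.TSS_CANDIDATE)
            if gend not in donor_pos:
                roles.add(ExonRole.TERMINAL_CANDIDATE)
        else:
            if gend not in acceptor_pos:
                roles.add(ExonRole.TSS_CANDIDATE)
            if gstart not in donor_pos:
                roles.add(ExonRole.TERMINAL_CANDIDATE)
        if not roles:
            roles.add(ExonRole.INTERNAL)
        exon.roles = roles
        exon.role = (
            ExonRole.TSS_CANDIDATE
            if ExonRole.TSS_CANDIDATE in roles
            else ExonRole.TERMINAL_CANDIDATE
            if ExonRole.TERMINAL_CANDIDATE in roles
            else ExonRole.INTERNAL
        )
        exons.append(exon)

    # 1) internal segments bounded by junctions on both sides
    for lb in left_bounds:
        rights = [rb for rb in right_bounds if rb > lb]
        if rights:
            blo, bhi = block_limits(lb)
            nearest = rights[0]
            if nearest <= bhi:
                add_exon(lb, nearest, True, True)
                continue
        # 2) left bounded, right open: extend along coverage
        blo, bhi = block_limits(lb)
        if bhi > lb:
            seg = coverage.depth[lb - coverage.start : bhi - coverage.start]
            med = float(np.median(seg[seg > 0])) if (seg > 0).any() else 0.0
            end = _extend(coverage, lb, +1, floor_fraction * med) + 1
            add_exon(lb, end, True, False)
    # 3) right bounded, left open
    for rb in right_bounds:
        lefts = [lb for lb in left_bounds if lb < rb]
        blo, bhi = block_limits(rb - 1)
        if lefts and lefts[-1] >= blo:
            continue  # already handled as an internal segment
        if rb > blo:
            seg = coverage.depth[blo - coverage.start : rb - coverage.start]
            med = float(np.median(seg[seg > 0])) if (seg > 0).any() else 0.0
            start = _extend(coverage, rb - 1, -1, floor_fraction * med)
            add_exon(start, rb, False, True)

    exons.sort(key=lambda e: (e.interval.start, e.interval.end))
    from .models import assign_variant_groups

    assign_variant_groups(exons)
    return exons


def scan_polya(
    genome_seq: str,
    region_start: int,
    region_end: int,
    strand: str,
    hexamers: Sequence[str] = DEFAULT_POLYA_HEXAMERS,
) -> list:
    """All polyadenylation-signal hexamer occurrences on the transcribed strand.

    Positions are genomic (0-based) and refer to the first base of the
    hexamer in transcription orientation; output is ordered 5'->3'.
    """
    window = genome_seq[region_start:region_end].upper()
    sites = []
    for hexamer in hexamers:
        probe = hexamer if strand == "+" else revcomp(hexamer)
        start = 0
        while True:
            idx = window.find(probe, start)
            if idx == -1:
                break
            gpos = region_start + idx if strand == "+" else region_start + idx + 5
            sites.append(
                PolyASite(position=gpos, hexamer=hexamer, canonical=hexamer == "AATAAA")
            )
            start = idx + 1
    sites.sort(key=lambda s: s.position, reverse=(strand == "-"))
    return sites


def detect_dropoff(
    coverage: CoverageTrack,
    position: int,
    window: int = DROPOFF_WINDOW,
    theta: float = DROPOFF_THETA,
    strand: str = "+",
) -> bool:
    """True iff mean depth downstream of ``position`` falls to <= theta x upstream.

    Up/downstream follow transcription orientation. Zero upstream depth
    returns False (nothing to drop from).
    """
    if strand == "+":
        up = coverage.window_mean(position - window, position)
        down = coverage.window_mean(position, position + window)
    else:
        up = coverage.window_mean(position, position + window)
        down = coverage.window_mean(position - window, position)
    if up <= 0:
        warnings.warn("zero upstream depth at drop-off check", stacklevel=2)
        return False
    return down <= theta * up


def call_terminal(
    exon: ExonModel,
    polya: Sequence[PolyASite],
    coverage: CoverageTrack,
    window: int = DROPOFF_WINDOW,
    theta: float = DROPOFF_THETA,
) -> TerminalCall:
    """Refine a terminal-candidate exon's 3' terminus.

    The terminus is placed at the first drop-off point downstream of the last
    supporting poly-A signal within the exon; with no signal, the terminus
    falls back to the end of contiguous coverage with a low-confidence flag.
    """
    strand = exon.strand
    step = 1 if strand == "+" else -1
    lo, hi = exon.interval.start, exon.interval.end
    in_exon = [s for s in polya if lo <= s.position < hi]
    if in_exon:
        last_sig = in_exon[-1]  # polya list is 5'->3'
        scan_from = last_sig.position + (6 if strand == "+" else -6)
        pos = scan_from
        limit = coverage.end if strand == "+" else coverage.start
        while (pos < limit) if strand == "+" else (pos > limit):
            if detect_dropoff(coverage, pos, window=window, theta=theta, strand=strand):
                return TerminalCall(exon.id, pos, True, last_sig)
            pos += step
        return TerminalCall(exon.id, exon.three_prime(), True, last_sig)
    return TerminalCall(exon.id, exon.three_prime(), False, None)
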