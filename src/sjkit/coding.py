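"""Protein-coding potential assessment for transcript models.

Three independent assessments are combined:

* longest open reading frame (ATG-to-stop) over the three forward frames of
  the transcript (the strand is known, so reverse frames are not scanned);
* transmembrane-segment count by Kyte-Doolittle hydropathy (window 19,
  windowed-mean cutoff 1.6, nearby segments merged) -- the classical sliding
  window method, deterministic and parameter-transparent;
* the Fickett TESTCODE statistic, a composition/codon-position-periodicity
  score with the published probability/weight lookup tables; scores below
  0.74 are called noncoding, above 0.95 coding, otherwise ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "OrfCall",
    "TmAnnotation",
    "CodingCall",
    "find_longest_orf",
    "count_tm_domains",
    "testcode",
    "assess_transcript",
]

STOPS = {"TAA", "TAG", "TGA"}
_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class OrfCall:
    frame: int  # 0/1/2
    start: int  # offset of the A of ATG
    stop: int  # offset one past the stop codon (or seq end if open)
    peptide: str
    open_ended: bool = False

    @property
    def length_aa(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class TmAnnotation:
    tm_count: int
    segments: tuple  # ((start, end), ...) peptide intervals, half-open


@dataclass(frozen=True)
class CodingCall:
    score: float
    call: str  # coding | ambiguous | noncoding

    #: published decision thresholds for the TESTCODE statistic
    NONCODING_BELOW = 0.74
    CODING_ABOVE = 0.95


def find_longest_orf(seq: str, include_open: bool = False) -> Optional[OrfCall]:
    """Longest ATG-to-stop reading frame across the three forward frames.

    Returns ``None`` when no closed ORF exists (and ``include_open`` is
    False). Ties prefer the 5'-most start. ORFs running off the 3' end
    without a stop are only considered with ``include_open=True`` and carry
    the ``open_ended`` flag.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    best: Optional[OrfCall] = None

    def better(cand: OrfCall) -> bool:
        if best is None:
            return True
        if cand.length_aa != best.length_aa:
            return cand.length_aa > best.length_aa
        return cand.start < best.start

    for frame in range(3):
        open_start: Optional[int] = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG" and open_start is None:
                open_start = pos
            elif codon in STOPS and open_start is not None:
                peptide = str(Seq(seq[open_start:pos]).translate())
                cand = OrfCall(frame, open_start, pos + 3, peptide, False)
                if better(cand):
                    best = cand
                open_start = None
        if include_open and open_start is not None:
            tail = seq[open_start : open_start + 3 * ((len(seq) - open_start) // 3)]
            peptide = str(Seq(tail).translate())
            cand = OrfCall(frame, open_start, len(seq), peptide, True)
            if better(cand):
                best = cand
    return best


def count_tm_domains(
    peptide: str,
    window: int = 19,
    cutoff: float = 1.6,
    merge_gap: int = 5,
) -> TmAnnotation:
    """Transmembrane segments from Kyte-Doolittle windowed hydropathy.

    Every window of ``window`` residues with mean hydropathy above ``cutoff``
    marks its span; overlapping or near-adjacent spans (gap <= ``merge_gap``)
    merge into one predicted segment. Unknown residues score 0.
    """
    peptide = peptide.upper().rstrip("*")
    if len(peptide) < window:
        return TmAnnotation(0, ())
    scores = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in peptide]
    spans = []
    acc = sum(scores[:window])
    if acc / window > cutoff:
        spans.append([0, window])
    for i in range(1, len(peptide) - window + 1):
        acc += scores[i + window - 1] - scores[i - 1]
        if acc / window > cutoff:
            if spans and i <= spans[-1][1] + merge_gap:
                spans[-1][1] = i + window
            else:
                spans.append([i, i + window])
    return TmAnnotation(len(spans), tuple((a, b) for a, b in spans))


# ---------------------------------------------------------------------------
# Fickett TESTCODE
#
# Published lookup tables: for each base, the probability that a sequence is
# coding given its position parameter (max/min codon-position asymmetry) or
# content parameter (composition), plus per-base weights reflecting each
# parameter's discriminative worth. The score is the weighted sum of the
# eight looked-up probabilities.

_POSITION_PARAM_BINS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_PARAM_BINS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

TESTCODE_MIN_LENGTH = 200


def _lookup(value: float, bins: tuple, probs: tuple) -> float:
    for threshold, prob in zip(bins, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def testcode(seq: str) -> CodingCall:
    """Fickett TESTCODE coding-potential statistic.

    Requires >= 200 nt (the statistic is undefined on shorter sequences).
    Uses the three codon positions of the sequence as given; no symmetry
    between a sequence and its reverse complement is assumed.
    """
    seq = seq.upper()
    if len(seq) < TESTCODE_MIN_LENGTH:
        raise ValueError(
            f"TESTCODE requires >= {TESTCODE_MIN_LENGTH} nt, got {len(seq)}"
        )
    score = 0.0
    n = len(seq)
    for base in "ACGT":
        pos_counts = [
            sum(1 for i in range(p, n, 3) if seq[i] == base) for p in range(3)
        ]
        position_param = max(pos_counts) / (min(pos_counts) + 1)
        content_param = sum(pos_counts) / n
        score += _POSITION_WEIGHT[base] * _lookup(
            position_param, _POSITION_PARAM_BINS, _POSITION_PROB[base]
        )
        score += _CONTENT_WEIGHT[base] * _lookup(
            content_param, _CONTENT_PARAM_BINS, _CONTENT_PROB[base]
        )
    if score < CodingCall.NONCODING_BELOW:
        call = "noncoding"
    elif score > CodingCall.CODING_ABOVE:
        call = "coding"
    else:
        call = "ambiguous"
    return CodingCall(score=round(score, 4), call=call)


def assess_transcript(seq: str) -> dict:
    """Full coding-potential summary for one transcript sequence.

    Returns a dict with the longest-ORF call ('no-ORF' when none), the TM
    count of its peptide, and the TESTCODE call (None below 200 nt).
    """
    orf = find_longest_orf(seq) if len(seq) >= 3 else None
    tm = count_tm_domains(orf.peptide) if orf else TmAnnotation(0, ())
    code = testcode(seq) if len(seq) >= TESTCODE_MIN_LENGTH else None
    return {
        "orf": orf,
        "orf_aa": orf.length_aa if orf else 0,
        "coding_call": "no-ORF" if orf is None else (code.call if code else "ambiguous"),
        "tm_count": tm.tm_count,
        "testcode": code,
    }
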