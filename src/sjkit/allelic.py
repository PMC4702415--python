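"""Allelic expression imbalance (AEI) testing at heterozygous sites.

At a heterozygous SNP, RNA reads carrying each allele should occur in equal
proportion unless a cis-acting variant modulates expression of one
haplotype. Each sample is tested with an exact one-sided binomial test on
the major (more abundant) allele count -- the upper-tail probability
P(X >= k_major | n, p0) with p0 = 0.5 by default -- and Bonferroni-corrected
for the number of heterozygous samples tested at the site. At low per-sample
depth, counts may instead be pooled across samples and tested once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .models import AllelicCount

__all__ = [
    "AeiResult",
    "binomial_aei",
    "bonferroni",
    "pooled_aei",
    "fold_difference",
    "aei_table",
]


@dataclass(frozen=True)
class AeiResult:
    sample_id: str
    count_a1: int
    count_a2: int
    p_raw: float
    p_corrected: float
    fold: Optional[float]  # None encodes an infinite ratio (zero minor count)
    significant: bool


def binomial_aei(count_major: int, count_minor: int, p0: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial probability for the major allele.

    The major count is taken as max of the two arguments, so the call is
    symmetric in its arguments at p0 = 0.5. The tail is an exact log-space
    summation of the binomial PMF, not a normal approximation (and not the
    incomplete-beta shortcut, which loses precision at large n).
    """
    if count_major < 0 or count_minor < 0:
        raise ValueError("counts must be non-negative")
    n = count_major + count_minor
    if n == 0:
        raise ValueError("cannot test a site with zero reads")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    k = max(count_major, count_minor)
    xs = np.arange(k, n + 1)
    return float(np.exp(logsumexp(stats.binom.logpmf(xs, n, p0))))


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise corrected p-value: min(1, p_raw * m)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p_raw * m)


def pooled_aei(counts: Sequence[AllelicCount], p0: float = 0.5) -> tuple:
    """Pool allele counts across samples, then test the summed counts.

    Returns (p_value, total_a1, total_a2). Intended for sites where
    per-sample depth is too low for individual testing.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("pooled test needs at least one sample")
    a1 = sum(c.count_a1 for c in counts)
    a2 = sum(c.count_a2 for c in counts)
    return binomial_aei(a1, a2, p0), a1, a2


def fold_difference(a1: int, a2: int) -> Optional[float]:
    """Major/minor count ratio to 2 decimals; None when the minor count is 0."""
    if a1 < 0 or a2 < 0:
        raise ValueError("counts must be non-negative")
    if min(a1, a2) == 0:
        return None
    return round(max(a1, a2) / min(a1, a2), 2)


def aei_table(
    counts: Sequence[AllelicCount],
    p0: float = 0.5,
    min_depth: int = 10,
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> list:
    """Per-sample AEI results for one site.

    Samples below ``min_depth`` total reads are excluded. The Bonferroni
    factor is the number of samples tested (overridable with ``n_tests``
    when the heterozygous cohort is larger than the tested subset, e.g. the
    109 heterozygotes behind a 9-row significant table).
    """
    tested = [c for c in counts if c.depth >= min_depth]
    m = n_tests if n_tests is not None else len(tested)
    results = []
    for c in tested:
        p = binomial_aei(c.count_a1, c.count_a2, p0)
        pc = bonferroni(p, m) if m >= 1 else 1.0
        results.append(
            AeiResult(
                sample_id=c.sample_id,
                count_a1=c.count_a1,
                count_a2=c.count_a2,
                p_raw=p,
                p_corrected=pc,
                fold=fold_difference(c.count_a1, c.count_a2),
                significant=pc <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.sample_id))
    return results
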