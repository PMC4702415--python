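"""Synthetic loci, reads, allelic counts, genotypes and covariates.

Everything the pipeline consumes can be generated here with a known ground
truth, so every stage is testable without restricted human data. The default
locus emulates the architecture the pipeline was built for: a multi-kilobase
region hosting two genes on opposite strands -- a spliced sense gene read
right-to-left and a lower-abundance antisense gene whose exons overlap sense
exons -- with canonical GT..AG splice dinucleotides planted on each
transcribed strand, polyadenylation hexamers at the terminal exons followed
by decaying 3' coverage, and junction abundances assigned to the four
rare/low/medium/high tiers.

Companion generators produce allelic counts with a genotype-linked imbalance
factor theta (heterozygote allele-1 proportion theta/(1+theta)), and a
two-SNP genotype matrix with tunable linkage disequilibrium plus covariates
and negative-binomially distributed endpoint counts with log-normal library
sizes, mirroring a post-mortem brain cohort of ~211 subjects.

All randomness flows from a single integer seed through one generator;
(spec, seed) -> byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .junctions import GappedRead, revcomp
from .models import (
    AllelicCount,
    ExonModel,
    ExonRole,
    FrequencyClass,
    GenomicInterval,
)

__all__ = [
    "LocusSpec",
    "SimulationTruth",
    "generate_locus",
    "simulate_reads",
    "simulate_allelic",
    "simulate_genotypes",
    "TIER_RATES",
    "READ_LENGTH",
]

READ_LENGTH = 100

#: expected junction reads per sample by tier; rare is planted as exactly one
#: read in one sample (the tier's defining observation).
TIER_RATES = {
    FrequencyClass.LOW: 0.08,
    FrequencyClass.MEDIUM: 0.4,
    FrequencyClass.HIGH: 5.0,
}

#: cohort-scale defaults for the covariate/genotype simulator, matching a
#: two-diagnosis post-mortem brain cohort (n ~ 211, RIN ~ 8.15 +/- 0.85,
#: pH ~ 6.5 +/- 0.25, PMI ~ 35 +/- 21 h, ~48 % smokers).
COHORT = {
    "n_samples": 211,
    "age_mean": 45.7,
    "age_sd": 13.8,
    "ph_mean": 6.51,
    "ph_sd": 0.25,
    "rin_mean": 8.15,
    "rin_sd": 0.85,
    "pmi_mean": 34.8,
    "pmi_sd": 21.0,
    "male_frac": 0.745,
    "caucasian_frac": 0.60,
    "smoker_frac": 0.48,
    "case_frac": 0.5,
}


def _exon(id_, chrom, start, end, strand, group=None):
    return {
        "id": id_,
        "chrom": chrom,
        "start": start,
        "end": end,
        "strand": strand,
        "variant_group": group or id_,
    }


@dataclass
class LocusSpec:
    """Declarative description of a two-gene toy locus.

    The default layout: a 13 kb chromosome carrying a six-exon sense gene on
    the minus strand (one chain of high-tier junctions, terminal exon with a
    poly-A signal and decaying 3' tail) and a four-exon antisense gene on the
    plus strand whose first three exons overlap sense exons, wired with
    high/medium junctions plus one low-tier skip edge and one rare edge.
    """

    chrom: str = "chrS"
    genome_length: int = 13000
    sense_exons: tuple = (
        ("S1", 12000, 12400),
        ("S2", 10500, 10900),
        ("S3", 9000, 9400),
        ("S4", 7500, 7900),
        ("S5", 6000, 6400),
        ("S6", 4100, 4600),
    )
    antisense_exons: tuple = (
        ("A1", 5800, 6200),
        ("A2", 7600, 7800),
        ("A3", 9100, 9300),
        ("A4", 10050, 10250),
    )
    # junction: (from_exon, to_exon, tier name)
    sense_junctions: tuple = (
        ("S1", "S2", "high"),
        ("S2", "S3", "high"),
        ("S3", "S4", "high"),
        ("S4", "S5", "high"),
        ("S5", "S6", "high"),
    )
    antisense_junctions: tuple = (
        ("A1", "A2", "high"),
        ("A2", "A3", "medium"),
        ("A3", "A4", "medium"),
        ("A2", "A4", "low"),
        ("A1", "A3", "rare"),
    )
    # isoforms as exon chains with relative abundance weights
    sense_isoforms: tuple = ((("S1", "S2", "S3", "S4", "S5", "S6"), 1.0),)
    antisense_isoforms: tuple = (
        (("A1", "A2", "A3", "A4"), 0.7),
        (("A1", "A2", "A4"), 0.3),
    )
    # poly-A signal positions (genomic, first base of the hexamer footprint)
    sense_polya: int = 4150  # TTTATT on the forward genome
    antisense_polya: int = 10150  # AATAAA
    #: number of transmembrane stretches planted in the designated sense ORF
    plant_tm_domains: int = 0
    orf_transcript_offset: int = 150
    orf_codons: int = 120
    seed: int = 0

    def exon_map(self) -> dict:
        out = {}
        for id_, s, e in self.sense_exons:
            out[id_] = _exon(id_, self.chrom, s, e, "-")
        for id_, s, e in self.antisense_exons:
            out[id_] = _exon(id_, self.chrom, s, e, "+")
        return out


# hydrophobic / polar codon pools for TM planting; codons chosen with strong
# position bias so the designated ORF also scores coding-like
_ILE = "ATT"
_LEU = "CTG"
_POLAR = ("AAT", "GGT", "AGT", "CAA")
_BODY = ("GAT", "GCT", "GAA", "AAA", "CTG", "GGT")


@dataclass
class SimulationTruth:
    """Ground-truth ledger serialized alongside simulated outputs."""

    spec: dict
    genome: dict  # chrom -> sequence
    exons: dict  # id -> dict
    junctions: list  # dicts with from/to/intron coords/strand/tier
    isoforms: list  # dicts with chain/weight/strand
    polya_sites: list
    orf: dict
    junction_draws: dict = field(default_factory=dict)  # "chrom:s-e:strand" -> {sample: n}

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec,
                "genome": self.genome,
                "exons": self.exons,
                "junctions": self.junctions,
                "isoforms": self.isoforms,
                "polya_sites": self.polya_sites,
                "orf": self.orf,
                "junction_draws": self.junction_draws,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "SimulationTruth":
        d = json.loads(payload)
        return cls(**d)

    def exon_models(self, strand: Optional[str] = None) -> list:
        out = []
        for ex in self.exons.values():
            if strand is not None and ex["strand"] != strand:
                continue
            out.append(
                ExonModel(
                    id=ex["id"],
                    interval=GenomicInterval(
                        ex["chrom"], ex["start"], ex["end"], ex["strand"]
                    ),
                    variant_group=ex["variant_group"],
                )
            )
        return out


def _intron(spec: LocusSpec, exons: dict, u: str, v: str) -> tuple:
    """Genomic intron [start, end) between consecutive exons u -> v."""
    a, b = exons[u], exons[v]
    if a["strand"] == "+":
        return a["end"], b["start"]
    return b["end"], a["start"]


def generate_locus(spec: LocusSpec = LocusSpec(), seed: Optional[int] = None) -> SimulationTruth:
    """Random genome with planted gene architecture; deterministic under seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    exons = spec.exon_map()
    for ex in exons.values():
        if ex["end"] > spec.genome_length:
            raise ValueError(f"exon {ex['id']} exceeds genome length")
    # overlapping same-strand exons must share a variant group
    items = list(exons.values())
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            if (
                a["strand"] == b["strand"]
                and a["start"] < b["end"]
                and b["start"] < a["end"]
                and a["variant_group"] != b["variant_group"]
            ):
                raise ValueError(
                    f"same-strand overlap outside one variant group: {a['id']}/{b['id']}"
                )

    genome = rng.integers(0, 4, size=spec.genome_length)
    seq = np.array(list("ACGT"))[genome]

    def put(pos: int, s: str) -> None:
        seq[pos : pos + len(s)] = list(s)

    junctions = []
    for u, v, tier in spec.sense_junctions:
        s, e = _intron(spec, exons, u, v)
        put(s, "CT")  # GT..AG on the minus-strand transcript
        put(e - 2, "AC")
        junctions.append(
            {"from": u, "to": v, "start": s, "end": e, "strand": "-", "tier": tier}
        )
    for u, v, tier in spec.antisense_junctions:
        s, e = _intron(spec, exons, u, v)
        put(s, "GT")
        put(e - 2, "AG")
        junctions.append(
            {"from": u, "to": v, "start": s, "end": e, "strand": "+", "tier": tier}
        )

    put(spec.sense_polya, revcomp("AATAAA"))
    put(spec.antisense_polya, "AATAAA")
    polya_sites = [
        {"position": spec.sense_polya, "strand": "-", "hexamer": "AATAAA"},
        {"position": spec.antisense_polya, "strand": "+", "hexamer": "AATAAA"},
    ]

    # designated coding ORF on the first sense isoform
    chain = list(spec.sense_isoforms[0][0])
    tx_positions = []  # transcript offset -> genomic position (minus strand)
    for exon_id in chain:
        ex = exons[exon_id]
        tx_positions.extend(range(ex["end"] - 1, ex["start"] - 1, -1))
    if spec.plant_tm_domains > 0:
        codons = []
        for i in range(spec.plant_tm_domains):
            codons.extend([_POLAR[j % len(_POLAR)] for j in range(25)])
            codons.extend([_ILE if j % 2 else _LEU for j in range(21)])
        codons.extend([_POLAR[j % len(_POLAR)] for j in range(25)])
    else:
        codons = [_BODY[i % len(_BODY)] for i in range(spec.orf_codons)]
    orf_nt = "TAA" + "ATG" + "".join(codons) + "TAA"
    start = spec.orf_transcript_offset - 3  # include the upstream stop guard
    if start + len(orf_nt) > len(tx_positions):
        raise ValueError("ORF does not fit in the designated transcript")
    for k, base in enumerate(orf_nt):
        gpos = tx_positions[start + k]
        seq[gpos] = revcomp(base)  # minus strand: write the complement

    truth = SimulationTruth(
        spec={**asdict(spec), "seed": spec.seed if seed is None else seed},
        genome={spec.chrom: "".join(seq)},
        exons=exons,
        junctions=junctions,
        isoforms=[
            {"chain": list(c), "weight": w, "strand": "-"}
            for c, w in spec.sense_isoforms
        ]
        + [
            {"chain": list(c), "weight": w, "strand": "+"}
            for c, w in spec.antisense_isoforms
        ],
        polya_sites=polya_sites,
        orf={
            "isoform": chain,
            "tx_start": spec.orf_transcript_offset,
            "n_codons": len(codons),
            "peptide_aa": len(codons) + 1,
        },
    )
    return truth


def _junction_read(
    sample: str, chrom: str, intron: tuple, exons_by_id: dict, jx: dict
) -> GappedRead:
    """A 2x50 nt read spanning one intron, anchored in the flanking exons."""
    s, e = intron
    left_exon = exons_by_id[jx["from"] if jx["strand"] == "+" else jx["to"]]
    right_exon = exons_by_id[jx["to"] if jx["strand"] == "+" else jx["from"]]
    la = min(50, s - left_exon["start"])
    ra = min(50, right_exon["end"] - e)
    blocks = [(s - la, s), (e, e + ra)]
    return GappedRead(
        sample_id=sample, chrom=chrom, pos=s - la, blocks=blocks, gaps=[(s, e)]
    )


def simulate_reads(
    truth: SimulationTruth,
    n_samples: int = 150,
    depth: float = 5.0,
    seed: int = 0,
    tail_tau: float = 20.0,
    tail_length: int = 250,
) -> list:
    """Per-sample gapped reads realizing the planted junction tiers.

    Junction-spanning reads are drawn Poisson per sample at the tier's
    expected rate (a rare junction is planted as exactly one read in one
    random sample). Exon bodies receive uniform single-block reads at
    ``depth`` x per sample; terminal exons additionally get an
    exponentially decaying 3' tail (length ``tail_length`` nt, scale
    ``tail_tau``) emulating read-through past the cleavage site.
    Fills ``truth.junction_draws`` with the per-sample ground-truth counts.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(truth.genome))
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    exons_by_id = truth.exons
    reads: list = []
    truth.junction_draws = {}

    for jx in truth.junctions:
        key = f"{chrom}:{jx['start']}-{jx['end']}:{jx['strand']}"
        tier = FrequencyClass[jx["tier"].upper()]
        draws = {}
        if tier == FrequencyClass.RARE:
            lucky = samples[int(rng.integers(0, n_samples))]
            draws[lucky] = 1
        else:
            counts = rng.poisson(TIER_RATES[tier], size=n_samples)
            draws = {s: int(c) for s, c in zip(samples, counts) if c > 0}
        truth.junction_draws[key] = draws
        for sample, c in draws.items():
            for _ in range(c):
                reads.append(
                    _junction_read(sample, chrom, (jx["start"], jx["end"]), exons_by_id, jx)
                )

    # terminal exons: 3' end (transcription) has no outgoing junction
    donors = {(j["from"], j["strand"]) for j in truth.junctions}
    for ex in exons_by_id.values():
        n_body = rng.poisson(depth * (ex["end"] - ex["start"]) / READ_LENGTH, size=n_samples)
        span = max(1, ex["end"] - ex["start"] - READ_LENGTH + 1)
        for sample, c in zip(samples, n_body):
            for _ in range(int(c)):
                start = ex["start"] + int(rng.integers(0, span))
                end = min(start + READ_LENGTH, ex["end"])
                reads.append(
                    GappedRead(sample, chrom, start, blocks=[(start, end)], gaps=[])
                )
        if (ex["id"], ex["strand"]) not in donors:
            # decaying read-through tail past the 3' end
            step = 25
            for off in range(0, tail_length, step):
                lam = depth * (step / READ_LENGTH) * np.exp(-off / tail_tau)
                n_tail = rng.poisson(lam, size=n_samples)
                for sample, c in zip(samples, n_tail):
                    for _ in range(int(c)):
                        if ex["strand"] == "+":
                            start = ex["end"] + off
                            blocks = [(start, start + step)]
                        else:
                            start = ex["start"] - off - step
                            blocks = [(start, start + step)]
                        reads.append(
                            GappedRead(sample, chrom, blocks[0][0], blocks=blocks, gaps=[])
                        )
    reads.sort(key=lambda r: (r.chrom, r.pos, r.sample_id))
    return reads


def simulate_allelic(
    genotypes: Sequence[int],
    theta: float = 2.0,
    depth: float = 100.0,
    site_id: str = "snpA",
    seed: int = 0,
) -> list:
    """Allelic counts with imbalance factor theta for heterozygotes.

    Heterozygote (genotype 1) allele-1 reads are Binomial(n, theta/(1+theta))
    at Poisson(depth) total reads; homozygotes carry all reads on one allele
    and are excluded from testing downstream.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    prop = theta / (1.0 + theta)
    out = []
    for i, g in enumerate(genotypes):
        n = int(rng.poisson(depth))
        sid = f"s{i + 1:03d}"
        if g == 1:
            a1 = int(rng.binomial(n, prop)) if n else 0
            out.append(AllelicCount(sid, site_id, a1, n - a1))
        elif g == 0:
            out.append(AllelicCount(sid, site_id, n, 0))
        else:
            out.append(AllelicCount(sid, site_id, 0, n))
    return out


def simulate_genotypes(
    n_samples: int = COHORT["n_samples"],
    maf: float = 0.4,
    r2_target: float = 1.0,
    genotype_effect: float = 0.0,
    covariate_effects: Optional[dict] = None,
    dispersion: float = 0.5,
    base_rate: float = 2e-4,
    seed: int = 0,
) -> dict:
    """Two-SNP genotypes in target LD, covariates, and NB endpoint counts.

    Haplotypes for (snp1, snp2) are drawn with correlation r = sqrt(r2);
    the haplotype frequency of the variant-variant haplotype is
    p^2 + r*p*(1-p), which is infeasible only for r2 > 1. Endpoint counts
    follow log E[y] = log(lib) + log(base_rate) + covariates + beta_g * g1
    with NB2 dispersion ``dispersion``; library sizes are log-normal.
    ``genotype_effect`` is the per-variant-allele log fold change on snp1.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if not 0.0 <= r2_target <= 1.0:
        raise ValueError("r2_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = maf
    r = float(np.sqrt(r2_target))
    # haplotype frequencies for alleles (X, Y) each Bernoulli(p) with corr r
    d = r * p * (1.0 - p)
    f11 = p * p + d
    f10 = p * (1.0 - p) - d
    f01 = f10
    f00 = (1.0 - p) ** 2 + d
    freqs = np.array([f11, f10, f01, f00])
    if (freqs < -1e-12).any():
        raise ValueError(f"infeasible (maf, r2) pair: {maf}, {r2_target}")
    freqs = np.clip(freqs, 0.0, None)
    freqs = freqs / freqs.sum()
    haps = rng.choice(4, size=(n_samples, 2), p=freqs)
    allele1 = np.isin(haps, (0, 1)).astype(int)  # variant at snp1
    allele2 = np.isin(haps, (0, 2)).astype(int)
    g1 = allele1.sum(axis=1)
    g2 = allele2.sum(axis=1)

    idx = [f"s{i + 1:03d}" for i in range(n_samples)]
    cov = pd.DataFrame(
        {
            "age": rng.normal(COHORT["age_mean"], COHORT["age_sd"], n_samples),
            "race": rng.binomial(1, COHORT["caucasian_frac"], n_samples),
            "gender": rng.binomial(1, COHORT["male_frac"], n_samples),
            "diagnosis": rng.binomial(1, COHORT["case_frac"], n_samples),
            "alcohol": rng.binomial(1, 0.3, n_samples),
            "smoking": rng.binomial(1, COHORT["smoker_frac"], n_samples),
            "pmi": np.clip(rng.normal(COHORT["pmi_mean"], COHORT["pmi_sd"], n_samples), 2, None),
            "ph": rng.normal(COHORT["ph_mean"], COHORT["ph_sd"], n_samples),
            "rin": np.clip(rng.normal(COHORT["rin_mean"], COHORT["rin_sd"], n_samples), 5, 10),
            "suicide": rng.binomial(1, 0.13, n_samples),
        },
        index=idx,
    )
    library_size = np.exp(rng.normal(np.log(1.0e5), 0.3, n_samples))
    eta = np.log(library_size) + np.log(base_rate) + genotype_effect * g1
    for name, beta in (covariate_effects or {}).items():
        x = cov[name].to_numpy(dtype=float)
        eta = eta + beta * (x - x.mean())
    mu = np.exp(eta)
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    return {
        "genotypes": pd.DataFrame({"snp1": g1, "snp2": g2}, index=idx),
        "covariates": cov,
        "counts": pd.Series(counts, index=idx, name="endpoint"),
        "library_size": pd.Series(library_size, index=idx, name="library_size"),
    }
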