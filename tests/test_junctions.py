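"""Junction extraction, strand inference, aggregation and tier classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sjkit.junctions import (
    GappedRead,
    JunctionTable,
    aggregate,
    classify_frequency,
    extract_junctions,
    revcomp,
)
from sjkit.models import FrequencyClass


def _genome_with(intron_seq: dict, length: int = 600, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    for pos, s in intron_seq.items():
        seq[pos : pos + len(s)] = list(s)
    return {"chr1": "".join(seq)}


def _read(sample, gap, chrom="chr1"):
    s, e = gap
    return GappedRead(sample, chrom, s - 30, blocks=[(s - 30, s), (e, e + 30)], gaps=[gap])


class TestStrandInference:
    def test_gt_ag_gap_assigned_plus_strand(self):
        genome = _genome_with({100: "GT", 198: "AG"})
        table = extract_junctions([_read("s1", (100, 200))], genome)
        (jx,) = list(table)
        assert (jx.start, jx.end, jx.strand) == (100, 200, "+")

    def test_ct_ac_gap_assigned_minus_strand(self):
        genome = _genome_with({100: "CT", 198: "AC"})
        table = extract_junctions([_read("s1", (100, 200))], genome)
        (jx,) = list(table)
        assert jx.strand == "-"

    def test_gc_ag_gap_discarded_and_tallied(self):
        genome = _genome_with({100: "GC", 198: "AG"})
        table = extract_junctions([_read("s1", (100, 200))], genome)
        assert len(table) == 0
        assert table.discarded_noncanonical == 1

    def test_short_gap_treated_as_deletion(self):
        genome = _genome_with({100: "GT", 108: "AG"})
        table = extract_junctions([_read("s1", (100, 110))], genome)
        assert len(table) == 0
        assert table.ignored_short_gaps == 1

    def test_missing_chromosome_is_an_error(self):
        with pytest.raises(KeyError):
            extract_junctions([_read("s1", (100, 200), chrom="chrZ")], {"chr1": "A" * 300})

    def test_multi_gap_read_counts_once_per_junction(self):
        genome = _genome_with({100: "GT", 198: "AG", 300: "GT", 398: "AG"})
        read = GappedRead(
            "s1", "chr1", 70,
            blocks=[(70, 100), (200, 300), (400, 430)],
            gaps=[(100, 200), (300, 400)],
        )
        table = extract_junctions([read], genome)
        assert len(table) == 2
        assert all(jx.total_reads == 1 for jx in table)


class TestOracleEquivalence:
    def _naive(self, reads, genome, min_intron=20):
        """Independent per-read re-scan of the genome sequence."""
        found = {}
        discarded = 0
        for read in reads:
            seq = genome[read.chrom]
            for s, e in read.gaps:
                if e - s < min_intron:
                    continue
                two5, two3 = seq[s : s + 2].upper(), seq[e - 2 : e].upper()
                if (two5, two3) == ("GT", "AG"):
                    strand = "+"
                elif (two5, two3) == ("CT", "AC"):
                    strand = "-"
                else:
                    discarded += 1
                    continue
                key = (read.chrom, s, e, strand)
                found.setdefault(key, {}).setdefault(read.sample_id, 0)
                found[key][read.sample_id] += 1
        return found, discarded

    @pytest.mark.parametrize("seed", range(5))
    def test_extraction_matches_naive_rescan_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        genome = _genome_with({}, length=2000, seed=seed + 100)
        reads = []
        for i in range(50):
            s = int(rng.integers(50, 900))
            e = s + int(rng.integers(5, 800))
            reads.append(_read(f"s{rng.integers(1, 6)}", (s, e)))
        table = extract_junctions(reads, genome)
        expected, discarded = self._naive(reads, genome)
        got = {jx.key(): dict(jx.counts) for jx in table}
        assert got == expected

    def test_strand_symmetry_under_genome_mirroring(self, default_truth, default_reads):
        chrom = "chrS"
        genome = default_truth.genome
        L = len(genome[chrom])
        mirrored_genome = {chrom: revcomp(genome[chrom])}
        mirrored_reads = [
            GappedRead(
                r.sample_id, chrom, L - r.blocks[-1][1],
                blocks=[(L - e, L - s) for s, e in reversed(r.blocks)],
                gaps=[(L - e, L - s) for s, e in reversed(r.gaps)],
            )
            for r in default_reads
            if r.gaps
        ]
        fwd = extract_junctions([r for r in default_reads if r.gaps], genome)
        rev = extract_junctions(mirrored_reads, mirrored_genome)
        flip = {"+": "-", "-": "+"}
        expected = {
            (chrom, L - e, L - s, flip[st]): jx.total_reads
            for (chrom_, s, e, st), jx in ((j.key(), j) for j in fwd)
        }
        got = {jx.key(): jx.total_reads for jx in rev}
        assert got == expected


class TestAggregate:
    def test_totals_and_sample_counts(self):
        genome = _genome_with({100: "GT", 198: "AG"})
        tables = []
        for sample, n in (("s1", 3), ("s3", 1)):
            t = extract_junctions([_read(sample, (100, 200))] * n, genome)
            tables.append(t)
        merged = aggregate(tables)
        (jx,) = list(merged)
        assert jx.total_reads == 4
        assert jx.n_samples == 2

    def test_empty_input_gives_empty_table(self):
        assert len(aggregate([])) == 0

    def test_duplicate_sample_across_tables_rejected(self):
        genome = _genome_with({100: "GT", 198: "AG"})
        t1 = extract_junctions([_read("s1", (100, 200))], genome)
        t2 = extract_junctions([_read("s1", (100, 200))], genome)
        with pytest.raises(ValueError, match="duplicate"):
            aggregate([t1, t2])

    def test_aggregated_totals_match_simulator_ledger(self, default_truth, default_reads):
        table = extract_junctions(default_reads, default_truth.genome)
        for key, draws in default_truth.junction_draws.items():
            chrom, span, strand = key.split(":")
            s, e = map(int, span.split("-"))
            jx = table.get((chrom, s, e, strand))
            assert jx.total_reads == sum(draws.values())
            assert jx.counts == draws


class TestFrequencyClassification:
    @pytest.mark.parametrize(
        "reads,samples,expected",
        [
            (1, 1, FrequencyClass.RARE),
            (2, 2, FrequencyClass.LOW),
            (25, 24, FrequencyClass.LOW),
            (25, 25, FrequencyClass.MEDIUM),
            (100, 100, FrequencyClass.HIGH),
            (14221, 203, FrequencyClass.HIGH),
        ],
    )
    def test_tier_boundaries(self, reads, samples, expected):
        assert classify_frequency(reads, samples) == expected

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            classify_frequency(0, 0)

    @given(
        st.integers(min_value=1, max_value=500),
        st.integers(min_value=1, max_value=500),
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=0, max_value=50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_both_arguments(self, samples, extra_reads, dr, ds):
        reads = samples + extra_reads
        base = classify_frequency(reads, samples)
        assert classify_frequency(reads + dr + ds, samples + ds) >= base
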