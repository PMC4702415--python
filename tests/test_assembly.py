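"""Splice-graph construction and constrained isoform enumeration."""

import itertools

import numpy as np
import pytest

from sjkit.assembly import (
    AssemblyConstraints,
    SpliceGraph,
    build_graph,
    enumerate_isoforms,
    graph_from_catalog,
    transcript_sequence,
)
from sjkit.junctions import GappedRead, extract_junctions, revcomp
from sjkit.models import (
    ExonModel,
    ExonRole,
    FrequencyClass,
    GenomicInterval,
    TranscriptModel,
)


def _toy_graph(edges, roles, strand="+", groups=None):
    """Graph on nodes 'A'.. with explicit tiers and roles."""
    nodes = sorted({u for u, v, t in edges} | {v for u, v, t in edges} | set(roles))
    graph = SpliceGraph(strand)
    for i, n in enumerate(nodes):
        exon = ExonModel(
            n,
            GenomicInterval("chr1", 100 * (i + 1), 100 * (i + 1) + 50, strand),
            variant_group=(groups or {}).get(n, n),
        )
        exon.roles = set(roles.get(n, {ExonRole.INTERNAL}))
        exon.role = next(iter(exon.roles))
        graph.add_exon(exon)
    for u, v, tier in edges:
        graph.add_edge(u, v, None, tier)
    return graph


def _brute_force(graph, constraints):
    """Independent exhaustive DFS over all start->end node paths."""
    g = graph.g
    starts = [n for n in g if graph.exon(n).roles & set(constraints.allowed_start_roles)]
    if constraints.allowed_end_exons is not None:
        ends = set(constraints.allowed_end_exons)
    else:
        ends = {
            n
            for n in g
            if ExonRole.TERMINAL_CANDIDATE in graph.exon(n).roles or g.out_degree(n) == 0
        }
    found = set()

    def ok_path(path):
        groups = [graph.exon(n).variant_group for n in path]
        if len(set(groups)) != len(groups):
            return False
        low = 0
        for u, v in zip(path, path[1:]):
            tier = g.edges[u, v]["tier"]
            if tier in constraints.exclude_classes:
                return False
            if tier == FrequencyClass.LOW:
                low += 1
        for n in path[1:]:
            ex = graph.exon(n)
            if (
                not constraints.tss_as_internal
                and ex.roles == {ExonRole.TSS_CANDIDATE}
                and n not in ends
            ):
                return False
        return low <= constraints.max_low_edges

    def expand(path):
        if path[-1] in ends and ok_path(path):
            found.add(tuple(path))
        for succ in g.successors(path[-1]):
            if succ not in path:
                expand(path + [succ])

    for s in starts:
        expand([s])
    return found


RARE, LOW, MED, HIGH = (
    FrequencyClass.RARE,
    FrequencyClass.LOW,
    FrequencyClass.MEDIUM,
    FrequencyClass.HIGH,
)
TSS, INT, TERM = ExonRole.TSS_CANDIDATE, ExonRole.INTERNAL, ExonRole.TERMINAL_CANDIDATE


class TestEnumerate:
    def test_single_edge_graph_yields_one_model(self):
        graph = _toy_graph([("A", "B", HIGH)], {"A": {TSS}, "B": {TERM}})
        models = enumerate_isoforms(graph)
        assert [tuple(e.id for e in m.exon_chain) for m in models] == [("A", "B")]

    def test_low_edge_budget_rejects_double_low_path(self):
        graph = _toy_graph(
            [("A", "B", HIGH), ("B", "D", MED), ("B", "C", LOW), ("C", "D", LOW)],
            {"A": {TSS}, "D": {TERM}},
        )
        models = enumerate_isoforms(graph, AssemblyConstraints(max_low_edges=1))
        assert {tuple(e.id for e in m.exon_chain) for m in models} == {("A", "B", "D")}

    def test_rare_edges_always_excluded(self):
        graph = _toy_graph(
            [("A", "B", RARE), ("A", "C", HIGH)], {"A": {TSS}, "B": {TERM}, "C": {TERM}}
        )
        chains = {
            tuple(e.id for e in m.exon_chain) for m in enumerate_isoforms(graph)
        }
        assert chains == {("A", "C")}

    def test_one_variant_per_group_per_path(self):
        graph = _toy_graph(
            [("A", "B1", HIGH), ("A", "B2", HIGH), ("B1", "B2", HIGH), ("B1", "C", HIGH), ("B2", "C", HIGH)],
            {"A": {TSS}, "C": {TERM}},
            groups={"B1": "B", "B2": "B"},
        )
        chains = {tuple(e.id for e in m.exon_chain) for m in enumerate_isoforms(graph)}
        assert chains == {("A", "B1", "C"), ("A", "B2", "C")}

    def test_no_duplicate_chains(self):
        graph = _toy_graph(
            [("A", "B", HIGH), ("B", "C", MED), ("A", "C", MED)],
            {"A": {TSS}, "C": {TERM}},
        )
        models = enumerate_isoforms(graph)
        chains = [tuple(e.id for e in m.exon_chain) for m in models]
        assert len(chains) == len(set(chains)) == 2

    def test_tightening_constraints_never_adds_isoforms(self):
        rng = np.random.default_rng(5)
        graph = _random_graph(rng, 12)
        loose = {tuple(e.id for e in m.exon_chain) for m in enumerate_isoforms(graph, AssemblyConstraints(max_low_edges=2))}
        for kwargs in (
            {"max_low_edges": 1},
            {"max_low_edges": 0},
            {"max_low_edges": 2, "exclude_classes": frozenset({RARE, LOW})},
        ):
            tight = {
                tuple(e.id for e in m.exon_chain)
                for m in enumerate_isoforms(graph, AssemblyConstraints(**kwargs))
            }
            assert tight <= loose

    def test_no_valid_start_gives_empty_list(self):
        graph = _toy_graph([("A", "B", HIGH)], {"A": {INT}, "B": {TERM}})
        assert enumerate_isoforms(graph) == []


def _random_graph(rng, n_nodes):
    """Random DAG on a coordinate line with random tiers/roles/groups."""
    roles = {}
    edges = []
    names = [f"N{i:02d}" for i in range(n_nodes)]
    for i, name in enumerate(names):
        has_in = any(v == name for _, v, _ in edges)
        for j in range(i + 1, min(i + 4, n_nodes)):
            if rng.random() < 0.5:
                tier = [RARE, LOW, MED, HIGH][int(rng.integers(0, 4))]
                edges.append((name, names[j], tier))
    targets = {v for _, v, _ in edges}
    sources = {u for u, _, _ in edges}
    for name in names:
        r = set()
        if name not in targets:
            r.add(TSS)
        if name not in sources:
            r.add(TERM)
        if not r:
            r = {INT}
            if rng.random() < 0.2:
                r = {TSS}  # occasional internal TSS candidate
        roles[name] = r
    groups = {}
    for name in names:
        if rng.random() < 0.15:
            groups[name] = f"G{int(rng.integers(0, 3))}"
    return _toy_graph(edges, roles, groups=groups)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_enumeration_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        graph = _random_graph(rng, int(rng.integers(5, 26)))
        constraints = AssemblyConstraints(max_low_edges=int(rng.integers(0, 3)))
        got = {
            tuple(e.id for e in m.exon_chain)
            for m in enumerate_isoforms(graph, constraints)
        }
        assert got == _brute_force(graph, constraints)


class TestBuildGraph:
    def test_edges_from_junction_boundaries(self, default_truth, default_reads):
        table = extract_junctions(default_reads, default_truth.genome).restrict_strand("+")
        exons = default_truth.exon_models("+")
        graph = build_graph(exons, table)
        got = {(u, v) for u, v, _ in graph.edges()}
        want = {
            (j["from"], j["to"]) for j in default_truth.junctions if j["strand"] == "+"
        }
        assert got == want
        assert graph.unplaced == []

    def test_no_junctions_gives_edgeless_graph(self):
        exons = [ExonModel("a", GenomicInterval("chr1", 0, 10, "+"))]
        from sjkit.junctions import JunctionTable

        graph = build_graph(exons, JunctionTable())
        assert graph.edges() == []
        assert len(graph.g.nodes) == 1

    def test_catalog_graph_matches_printed_junction_pairs(
        self, sense_exon_table, sense_junction_table
    ):
        g_all = graph_from_catalog(sense_exon_table, sense_junction_table)
        assert g_all.number_of_edges() == 13
        g = graph_from_catalog(
            sense_exon_table, sense_junction_table, exclude_classes={RARE}
        )
        want = {
            ("0", "2"), ("0", "3"), ("1", "2"), ("1", "3"), ("2", "3"),
            ("3", "3a"), ("3", "3b"), ("3", "4"), ("3a", "3b"), ("3a", "4"),
        }
        assert set(g.edges()) == want


class TestTranscriptSequence:
    def test_single_exon_length(self):
        genome = {"chr1": "ACGT" * 100}
        model = TranscriptModel([ExonModel("e", GenomicInterval("chr1", 13, 200, "+"))])
        assert len(transcript_sequence(model, genome)) == 187
        assert model.length_nt == 187

    def test_minus_strand_reverse_complement_order(self):
        genome = {"chr1": "AAAACCCCGGGGTTTT"}
        e1 = ExonModel("e1", GenomicInterval("chr1", 8, 12, "-"))  # GGGG
        e2 = ExonModel("e2", GenomicInterval("chr1", 0, 4, "-"))  # AAAA
        model = TranscriptModel([e1, e2])  # transcription order: genomic-right first
        assert transcript_sequence(model, genome) == "CCCC" + "TTTT"

    def test_simulated_designated_transcript_round_trips(self, default_truth):
        exs = {e.id: e for e in default_truth.exon_models("-")}
        chain = default_truth.orf["isoform"]
        model = TranscriptModel([exs[i] for i in chain])
        seq = transcript_sequence(model, default_truth.genome)
        assert len(seq) == sum(exs[i].interval.length() for i in chain)
        # the planted ORF is where the truth ledger says it is
        off = default_truth.orf["tx_start"]
        assert seq[off : off + 3] == "ATG"
        assert seq[off - 3 : off] == "TAA"

    def test_exon_outside_genome_is_an_error(self):
        model = TranscriptModel([ExonModel("e", GenomicInterval("chr1", 0, 100, "+"))])
        with pytest.raises(ValueError):
            transcript_sequence(model, {"chr1": "ACGT"})
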