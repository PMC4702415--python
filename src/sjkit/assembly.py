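"""Constrained transcript-isoform enumeration on a splice graph.

Exons are nodes and junctions are directed edges (transcription order),
labelled with their abundance tier. Isoform models are all paths from an
allowed start exon (by default transcription-start candidates) to an allowed
end exon, subject to evidence constraints: rare edges are excluded outright,
at most ``max_low_edges`` low-tier edges may be used, and a path may use at
most one member of each variant group (alternative boundary versions of one
exon locus are mutually exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx

from .junctions import JunctionTable, classify_frequency, revcomp
from .models import (
    ExonModel,
    ExonRole,
    FrequencyClass,
    SpliceJunction,
    TranscriptModel,
)

__all__ = [
    "SpliceGraph",
    "AssemblyConstraints",
    "build_graph",
    "graph_from_catalog",
    "enumerate_isoforms",
    "transcript_sequence",
]


@dataclass
class AssemblyConstraints:
    """Evidence constraints for isoform enumeration."""

    exclude_classes: frozenset = frozenset({FrequencyClass.RARE})
    max_low_edges: int = 1
    allowed_start_roles: frozenset = frozenset({ExonRole.TSS_CANDIDATE})
    allowed_end_exons: Optional[tuple] = None  # explicit exon ids, else terminal candidates
    tss_as_internal: bool = False  # allow paths to pass through TSS candidates

    def __post_init__(self) -> None:
        if self.max_low_edges < 0:
            raise ValueError("max_low_edges must be >= 0")


class SpliceGraph:
    """A DAG of exons linked by classified splice junctions (one strand)."""

    def __init__(self, strand: str) -> None:
        self.strand = strand
        self.g = nx.DiGraph()
        self.unplaced: list = []

    @property
    def exons(self) -> list:
        return [self.g.nodes[n]["exon"] for n in self.g.nodes]

    def exon(self, exon_id: str) -> ExonModel:
        return self.g.nodes[exon_id]["exon"]

    def add_exon(self, exon: ExonModel) -> None:
        self.g.add_node(exon.id, exon=exon)

    def add_edge(self, u: str, v: str, junction: SpliceJunction, tier: FrequencyClass) -> None:
        self.g.add_edge(u, v, junction=junction, tier=tier)

    def edges(self) -> list:
        return [
            (u, v, d["tier"]) for u, v, d in sorted(self.g.edges(data=True))
        ]


def _tx_key(exon: ExonModel):
    """Sort key placing exons in transcription order."""
    if exon.strand == "+":
        return (exon.interval.start, exon.interval.end)
    return (-exon.interval.end, -exon.interval.start)


def build_graph(exons: Sequence[ExonModel], junctions: JunctionTable) -> SpliceGraph:
    """Link exons whose boundaries flank each junction.

    An edge runs from the exon whose 3' boundary is the junction's donor site
    to the exon whose 5' boundary is its acceptor site. Junctions that no
    exon pair flanks are recorded as unplaced rather than dropped silently.
    """
    strands = {e.strand for e in exons}
    if len(strands) > 1:
        raise ValueError("exons must be on a single strand")
    strand = strands.pop() if strands else "+"
    graph = SpliceGraph(strand)
    ordered = sorted(exons, key=_tx_key)
    for exon in ordered:
        graph.add_exon(exon)
    by_donor: dict = {}
    by_acceptor: dict = {}
    for exon in ordered:
        by_donor.setdefault(exon.three_prime(), []).append(exon)
        by_acceptor.setdefault(exon.five_prime(), []).append(exon)
    for jx in junctions:
        if jx.strand != strand:
            continue
        donors = by_donor.get(jx.donor_site, [])
        acceptors = by_acceptor.get(jx.acceptor_site, [])
        if not donors or not acceptors:
            graph.unplaced.append(jx)
            continue
        tier = classify_frequency(jx.total_reads, jx.n_samples)
        for u in donors:
            for v in acceptors:
                if _tx_key(v) <= _tx_key(u):
                    raise ValueError(
                        f"junction {jx.key()} runs against transcription order"
                    )
                graph.add_edge(u.id, v.id, jx, tier)
    if not nx.is_directed_acyclic_graph(graph.g):
        raise ValueError("splice graph is cyclic")
    return graph


def graph_from_catalog(exon_table, junction_table, exclude_classes=frozenset()):
    """Variant-group-level splice graph from curated label-based tables.

    Fixture junction tables name exons by label, with alternative-boundary
    donors printed as ``"x or y"``; each label maps to its exon's variant
    group and read/sample totals are summed per group pair. Edges whose
    summed evidence classifies into ``exclude_classes`` are dropped.
    Returns a :class:`networkx.DiGraph` over group labels.
    """
    group_of = {
        str(row.exon): str(row.variant_group)
        for row in exon_table.itertuples(index=False)
    }
    pair_totals: dict = {}
    for row in junction_table.itertuples(index=False):
        u = group_of[str(row.from_exon).split(" or ")[0]]
        v = group_of[str(row.to_exon).split(" or ")[0]]
        reads, samples = pair_totals.get((u, v), (0, 0))
        pair_totals[(u, v)] = (reads + int(row.total_reads), samples + int(row.n_samples))
    g = nx.DiGraph()
    g.add_nodes_from(sorted(set(group_of.values())))
    for (u, v), (reads, samples) in sorted(pair_totals.items()):
        tier = classify_frequency(reads, min(samples, reads))
        if tier in exclude_classes:
            continue
        g.add_edge(u, v, total_reads=reads, n_samples=samples, tier=tier)
    return g


def enumerate_isoforms(
    graph: SpliceGraph, constraints: AssemblyConstraints = AssemblyConstraints()
) -> list:
    """All isoform models satisfying the constraints, deterministically ordered.

    Depth-first enumeration over the DAG; output is ordered by the start
    exon's transcription coordinate, then lexicographically by exon chain.
    """
    g = graph.g
    starts = [
        n
        for n in g.nodes
        if graph.exon(n).roles & set(constraints.allowed_start_roles)
    ]
    if constraints.allowed_end_exons is not None:
        allowed_ends = set(constraints.allowed_end_exons)
    else:
        allowed_ends = {
            n
            for n in g.nodes
            if ExonRole.TERMINAL_CANDIDATE in graph.exon(n).roles
            or g.out_degree(n) == 0
        }
    if not starts or not allowed_ends:
        return []

    models: list = []
    seen_chains: set = set()

    def walk(node: str, path: list, groups: set, low_used: int, junctions: list) -> None:
        if node in allowed_ends:
            chain = tuple(path)
            if chain not in seen_chains:
                seen_chains.add(chain)
                models.append(
                    TranscriptModel(
                        exon_chain=[graph.exon(n) for n in path],
                        junctions=list(junctions),
                    )
                )
        for succ in sorted(g.successors(node)):
            data = g.edges[node, succ]
            tier = data["tier"]
            if tier in constraints.exclude_classes:
                continue
            nxt_low = low_used + (1 if tier == FrequencyClass.LOW else 0)
            if nxt_low > constraints.max_low_edges:
                continue
            succ_exon = graph.exon(succ)
            if succ_exon.variant_group in groups:
                continue
            if (
                not constraints.tss_as_internal
                and ExonRole.TSS_CANDIDATE in succ_exon.roles
                and succ not in allowed_ends
                and len(succ_exon.roles) == 1
            ):
                # a pure TSS exon cannot be entered mid-path
                continue
            walk(
                succ,
                path + [succ],
                groups | {succ_exon.variant_group},
                nxt_low,
                junctions + [data["junction"]],
            )

    for start in sorted(starts, key=lambda n: _tx_key(graph.exon(n))):
        exon = graph.exon(start)
        walk(start, [start], {exon.variant_group}, 0, [])

    models.sort(
        key=lambda m: (_tx_key(m.exon_chain[0]), tuple(e.id for e in m.exon_chain))
    )
    return models


def transcript_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence in transcription orientation.

    Minus-strand models concatenate the reverse complement of each exon,
    3'-most genomic exon first (the exon chain is already in transcription
    order). Sets ``model.sequence``.
    """
    parts = []
    for exon in model.exon_chain:
        iv = exon.interval
        chrom_seq = str(genome[iv.chrom])
        if iv.end > len(chrom_seq):
            raise ValueError(f"exon {exon.id} extends past end of {iv.chrom}")
        segment = chrom_seq[iv.start : iv.end].upper()
        parts.append(segment if iv.strand == "+" else revcomp(segment))
    model.sequence = "".join(parts)
    return model.sequence
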