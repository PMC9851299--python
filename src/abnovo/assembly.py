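"""Confidence-weighted de Bruijn assembly of de novo peptide predictions.

Filtered predictions are decomposed into k-mers (k = 7 by default — long
enough to avoid repeat-induced tangles in antibody chains, short enough to
keep coverage); each k-mer window accumulates its mean positional
confidence onto its node, and consecutive windows weight the connecting
edge.  Contigs are extracted as iterated heaviest paths: cycles are broken
by deleting the lightest edge on each cycle, the maximum-total-weight path
of the resulting DAG is spelled into a contig, its nodes are removed and
the process repeats.  Contigs are then locally aligned to the reference
chain and summarised as mapped-contig count, longest contig, sequence
coverage and per-column sequence accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from Bio import Align

from .formats import PredictionRecord

__all__ = [
    "build_graph",
    "extract_contigs",
    "filter_predictions",
    "Contig",
    "ContigAlignment",
    "AssemblyReport",
    "align_contig",
    "assembly_report",
]


def filter_predictions(
    predictions: Iterable[PredictionRecord], threshold: float
) -> list[PredictionRecord]:
    """Keep predictions whose peptide score reaches the confidence cutoff."""
    return [p for p in predictions if p.peptide_score >= threshold]


def build_graph(
    predictions: Iterable[PredictionRecord],
    k: int = 7,
    keep_modifications: bool = False,
) -> nx.DiGraph:
    """Accumulate prediction k-mers into a weighted de Bruijn graph.

    Node weight sums the mean positional confidence of every window
    spelling that k-mer; an edge connects consecutive windows (overlap
    k - 1) and accumulates the mean confidence of its two windows.  By
    default modifications are collapsed to their base residue — assembly
    targets the backbone sequence, and oxidation/deamidation are
    spectrum-level artifacts.  Peptides shorter than k are skipped and
    counted in the graph's ``skipped_peptides`` attribute.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    graph = nx.DiGraph(k=k, skipped_peptides=0)
    for pred in predictions:
        if keep_modifications:
            tokens = [
                code if mod is None else f"{code}[{mod}]"
                for code, mod in pred.peptide.residues
            ]
        else:
            tokens = [code for code, _ in pred.peptide.residues]
        if len(tokens) < k:
            graph.graph["skipped_peptides"] += 1
            continue
        scores = pred.positional_scores
        kmers = []
        weights = []
        for i in range(len(tokens) - k + 1):
            kmer = tuple(tokens[i : i + k])
            w = sum(scores[i : i + k]) / k
            kmers.append(kmer)
            weights.append(w)
            if graph.has_node(kmer):
                graph.nodes[kmer]["weight"] += w
            else:
                graph.add_node(kmer, weight=w)
        for (a, wa), (b, wb) in zip(zip(kmers, weights), zip(kmers[1:], weights[1:])):
            ew = (wa + wb) / 2.0
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += ew
            else:
                graph.add_edge(a, b, weight=ew)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"no peptide of length >= k={k}; graph is empty")
    # structural de Bruijn edges: any two k-mers overlapping by k-1 are
    # linked even when no single peptide spells them consecutively —
    # that is how reads from different enzymes join up.  Edges never
    # reinforced by a consecutive window keep weight 0.
    by_prefix: dict[tuple, list] = {}
    for node in graph.nodes:
        by_prefix.setdefault(node[:-1], []).append(node)
    for node in graph.nodes:
        for successor in by_prefix.get(node[1:], ()):
            if successor != node and not graph.has_edge(node, successor):
                graph.add_edge(node, successor, weight=0.0)
    return graph


@dataclass(frozen=True)
class Contig:
    sequence: str
    path_weight: float
    supporting_kmers: int


def extract_contigs(graph: nx.DiGraph, top_n: int = 20) -> list[Contig]:
    """Iterated heaviest-path extraction.

    The working graph is made acyclic by repeatedly deleting the lightest
    edge of any remaining cycle; the maximum-total-weight path (node plus
    edge weights) is found by dynamic programming over a topological
    order, spelled into a contig, and its nodes removed.  Repeats up to
    ``top_n`` times or until the graph is empty; contigs are returned by
    descending path weight.
    """
    work = graph.copy()
    _break_cycles(work)
    contigs: list[Contig] = []
    for _ in range(top_n):
        if work.number_of_nodes() == 0:
            break
        path, weight = _heaviest_path(work)
        sequence = "".join(path[0]) + "".join(kmer[-1] for kmer in path[1:])
        contigs.append(
            Contig(sequence=sequence, path_weight=weight, supporting_kmers=len(path))
        )
        work.remove_nodes_from(path)
    contigs.sort(key=lambda c: c.path_weight, reverse=True)
    return contigs


def _break_cycles(graph: nx.DiGraph) -> None:
    while True:
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        lightest = min(cycle, key=lambda e: graph[e[0]][e[1]]["weight"])
        graph.remove_edge(lightest[0], lightest[1])


def _heaviest_path(dag: nx.DiGraph) -> tuple[list, float]:
    order = list(nx.topological_sort(dag))
    best: dict = {}
    back: dict = {}
    for node in order:
        node_w = dag.nodes[node]["weight"]
        best[node] = node_w
        back[node] = None
        for pred in dag.predecessors(node):
            cand = best[pred] + dag[pred][node]["weight"] + node_w
            if cand > best[node]:
                best[node] = cand
                back[node] = pred
    end = max(best, key=lambda n: best[n])
    path = [end]
    while back[path[-1]] is not None:
        path.append(back[path[-1]])
    path.reverse()
    return path, float(best[end])


# ---------------------------------------------------------------------------
# contig-to-reference alignment and the assembly summary
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


@dataclass(frozen=True)
class ContigAlignment:
    """A contig's optimal local alignment against the reference chain."""

    contig: Contig
    ref_start: int
    ref_end: int
    aligned_columns: int
    matches: int
    score: float
    mapped: bool
    match_flags: tuple[bool, ...]

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0


def align_contig(
    contig: Contig,
    reference: str,
    min_aligned_length: int = 7,
    min_identity: float = 0.5,
    il_equivalent: bool = False,
) -> ContigAlignment:
    """Smith–Waterman local alignment of a contig to the reference.

    Scoring: match +2, mismatch -1, gap open -2, gap extend -1.  A contig
    is *mapped* when its aligned (non-gap) columns number at least
    ``min_aligned_length`` and at least ``min_identity`` of them match.
    I and L count as mismatching unless ``il_equivalent`` is set — their
    identity cannot be decided from fragment masses, but accuracy is
    reported against the literal reference by default.
    """
    if not reference:
        raise ValueError("reference sequence must be non-empty")
    query = contig.sequence
    if il_equivalent:
        query_cmp = query.replace("I", "L")
        ref_cmp = reference.replace("I", "L")
    else:
        query_cmp, ref_cmp = query, reference

    alignments = _aligner().align(ref_cmp, query_cmp)
    try:
        alignment = alignments[0]
    except IndexError:  # nothing scores positive: no local alignment at all
        return ContigAlignment(
            contig=contig, ref_start=0, ref_end=0, aligned_columns=0,
            matches=0, score=0.0, mapped=False, match_flags=(),
        )
    flags: list[bool] = []
    ref_positions: list[int] = []
    for (r0, r1), (q0, q1) in zip(*alignment.aligned):
        for dr in range(r1 - r0):
            flags.append(ref_cmp[r0 + dr] == query_cmp[q0 + dr])
            ref_positions.append(r0 + dr)
    aligned_columns = len(flags)
    matches = sum(flags)
    mapped = (
        aligned_columns >= min_aligned_length
        and matches >= min_identity * aligned_columns
        and aligned_columns > 0
    )
    return ContigAlignment(
        contig=contig,
        ref_start=min(ref_positions) if ref_positions else 0,
        ref_end=max(ref_positions) + 1 if ref_positions else 0,
        aligned_columns=aligned_columns,
        matches=matches,
        score=float(alignment.score),
        mapped=mapped,
        match_flags=tuple(flags),
    )


@dataclass(frozen=True)
class AssemblyReport:
    """The assembly summary: mapped contigs, longest contig, coverage, accuracy."""

    mapped_contigs: int
    total_contigs: int
    longest_contig: int
    longest_contig_pct: float
    covered_positions: int
    sequence_coverage_pct: float
    correct_calls: int
    aligned_calls: int
    sequence_accuracy_pct: float | None
    reference_length: int
    alignments: tuple[ContigAlignment, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "mapped_contigs": self.mapped_contigs,
            "total_contigs": self.total_contigs,
            "longest_contig": self.longest_contig,
            "longest_contig_pct": self.longest_contig_pct,
            "covered_positions": self.covered_positions,
            "sequence_coverage_pct": self.sequence_coverage_pct,
            "correct_calls": self.correct_calls,
            "aligned_calls": self.aligned_calls,
            "sequence_accuracy_pct": self.sequence_accuracy_pct,
            "reference_length": self.reference_length,
        }


def assembly_report(
    contigs: Sequence[Contig],
    reference: str,
    min_aligned_length: int = 7,
    min_identity: float = 0.5,
    il_equivalent: bool = False,
) -> AssemblyReport:
    """Align contigs and pool the coverage/accuracy summary.

    Coverage is the fraction of reference positions spanned by at least
    one mapped contig's alignment; accuracy pools correct aligned calls
    over all aligned calls of mapped contigs.  With no mapped contig the
    accuracy is undefined (None).
    """
    alignments = tuple(
        align_contig(c, reference, min_aligned_length, min_identity, il_equivalent)
        for c in contigs
    )
    mapped = [a for a in alignments if a.mapped]
    covered: set[int] = set()
    correct = 0
    aligned = 0
    for a in mapped:
        covered.update(range(a.ref_start, a.ref_end))
        correct += a.matches
        aligned += a.aligned_columns
    longest = max((len(a.contig.sequence) for a in mapped), default=0)
    ref_len = len(reference)
    return AssemblyReport(
        mapped_contigs=len(mapped),
        total_contigs=len(alignments),
        longest_contig=longest,
        longest_contig_pct=100.0 * longest / ref_len,
        covered_positions=len(covered),
        sequence_coverage_pct=100.0 * len(covered) / ref_len,
        correct_calls=correct,
        aligned_calls=aligned,
        sequence_accuracy_pct=(100.0 * correct / aligned) if aligned else None,
        reference_length=ref_len,
        alignments=alignments,
    )
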