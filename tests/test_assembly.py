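import numpy as np
import pytest

from abnovo.assembly import (
    Contig,
    align_contig,
    assembly_report,
    build_graph,
    extract_contigs,
    filter_predictions,
)
from abnovo.formats import PredictionRecord
from abnovo.masses import ModifiedPeptide
from abnovo.simulate import random_protein
from oracles import smith_waterman_score


def _pred(seq, score=100.0, sid="s"):
    p = ModifiedPeptide.from_plain(seq)
    return PredictionRecord(sid, p, score, tuple([score] * len(p)))


def _tiling_preds(protein, read_len=12, step=4, score=100.0):
    preds = []
    for i, start in enumerate(range(0, len(protein) - read_len + 1, step)):
        preds.append(_pred(protein[start : start + read_len], score, f"s{i}"))
    return preds


class TestFilterPredictions:
    def test_zero_threshold_is_identity(self):
        preds = [_pred("PEPTIDEK", 10.0), _pred("AGAGAGAG", 90.0)]
        assert filter_predictions(preds, 0.0) == preds

    def test_above_max_gives_empty(self):
        preds = [_pred("PEPTIDEK", 10.0)]
        assert filter_predictions(preds, 10.1) == []


class TestBuildGraph:
    def test_single_kmer_peptide(self):
        g = build_graph([_pred("PEPTIDE")], k=7)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_overlapping_peptides_connect(self):
        a, b = "GASTWKL", "ASTWKLV"  # overlap 6 = k-1
        g = build_graph([_pred(a), _pred(b)], k=7)
        assert g.has_edge(tuple(a), tuple(b))

    def test_duplicate_peptide_doubles_weight(self):
        g1 = build_graph([_pred("PEPTIDEK")], k=7)
        g2 = build_graph([_pred("PEPTIDEK"), _pred("PEPTIDEK")], k=7)
        for node in g1.nodes:
            assert g2.nodes[node]["weight"] == pytest.approx(
                2 * g1.nodes[node]["weight"]
            )

    def test_short_peptides_skipped_and_counted(self):
        g = build_graph([_pred("PEPTIDEK"), _pred("AG")], k=7)
        assert g.graph["skipped_peptides"] == 1

    def test_all_short_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_graph([_pred("AG")], k=7)

    def test_k_below_2_rejected(self):
        with pytest.raises(ValueError):
            build_graph([_pred("PEPTIDE")], k=1)

    def test_adding_prediction_never_decreases_weights(self):
        g1 = build_graph([_pred("PEPTIDEKW")], k=7)
        g2 = build_graph([_pred("PEPTIDEKW"), _pred("TIDEKWAG")], k=7)
        for node in g1.nodes:
            assert g2.nodes[node]["weight"] >= g1.nodes[node]["weight"]


class TestExtractContigs:
    def test_tiling_reads_reconstruct_protein(self, rng):
        protein = random_protein(60, rng)
        g = build_graph(_tiling_preds(protein), k=7)
        contigs = extract_contigs(g, top_n=20)
        assert contigs[0].sequence == protein

    def test_two_islands_give_two_contigs(self, rng):
        a = random_protein(30, rng)
        b = random_protein(30, rng)
        g = build_graph(_tiling_preds(a) + [
            _pred(b[i : i + 12], 100.0, f"t{i}") for i in range(0, 19, 4)
        ], k=7)
        contigs = extract_contigs(g, top_n=20)
        spelled = {c.sequence for c in contigs}
        assert any(a in s or s in a for s in spelled)
        assert any(b in s or s in b for s in spelled)

    def test_top_1_is_prefix_of_top_20(self, rng):
        protein = random_protein(80, rng)
        g = build_graph(_tiling_preds(protein), k=7)
        top1 = extract_contigs(g, top_n=1)
        top20 = extract_contigs(g, top_n=20)
        assert top1[0] == top20[0]

    def test_contig_kmers_exist_in_graph(self, rng):
        protein = random_protein(50, rng)
        g = build_graph(_tiling_preds(protein), k=7)
        for contig in extract_contigs(g, top_n=5):
            for i in range(len(contig.sequence) - 6):
                assert g.has_node(tuple(contig.sequence[i : i + 7]))

    def test_cyclic_repeat_terminates(self):
        # a peptide whose k-mers form a cycle (periodic sequence)
        g = build_graph([_pred("AGAGAGAGAGAGAG")], k=4)
        contigs = extract_contigs(g, top_n=5)
        assert contigs  # terminates and yields something


class TestAlignContig:
    def test_exact_substring_full_identity(self, rng):
        ref = random_protein(100, rng)
        contig = Contig(ref[20:50], 1.0, 24)
        a = align_contig(contig, ref)
        assert a.mapped and a.identity == 1.0
        assert (a.ref_start, a.ref_end) == (20, 50)
        assert all(a.match_flags)

    def test_single_mismatch_in_twenty(self, rng):
        ref = random_protein(100, rng)
        seq = list(ref[10:30])
        seq[10] = "W" if seq[10] != "W" else "G"
        a = align_contig(Contig("".join(seq), 1.0, 14), ref)
        assert a.aligned_columns == 20
        assert sum(a.match_flags) == 19

    def test_score_matches_dp_oracle_on_short_strings(self, rng):
        codes = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(30):
            a = "".join(rng.choice(list(codes), size=int(rng.integers(7, 12))))
            b = "".join(rng.choice(list(codes), size=int(rng.integers(8, 13))))
            ours = align_contig(Contig(a, 1.0, 1), b)
            assert ours.score == pytest.approx(smith_waterman_score(a, b))

    def test_foreign_contig_unmapped(self, rng):
        ref = random_protein(60, np.random.default_rng(5))
        contig = Contig("WWWWWWW", 1.0, 1)
        assert not align_contig(contig, ref.replace("W", "G")).mapped

    def test_il_equivalence_flag(self):
        ref = "GASTWKIVEDN"
        contig = Contig("GASTWKLVEDN", 1.0, 5)
        strict = align_contig(contig, ref)
        lenient = align_contig(contig, ref, il_equivalent=True)
        assert sum(strict.match_flags) == len(ref) - 1
        assert sum(lenient.match_flags) == len(ref)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_contig(Contig("PEPTIDE", 1.0, 1), "")


class TestAssemblyReport:
    def test_full_reference_contig(self, rng):
        ref = random_protein(80, rng)
        report = assembly_report([Contig(ref, 1.0, 74)], ref)
        assert report.sequence_coverage_pct == 100.0
        assert report.sequence_accuracy_pct == 100.0
        assert report.mapped_contigs == 1

    def test_no_mapped_contigs(self, rng):
        ref = random_protein(60, np.random.default_rng(5)).replace("W", "G")
        report = assembly_report([Contig("WWWWWWWW", 1.0, 2)], ref)
        assert report.sequence_coverage_pct == 0.0
        assert report.sequence_accuracy_pct is None

    def test_coverage_monotone_in_top_n(self, rng):
        protein = random_protein(120, rng)
        g = build_graph(_tiling_preds(protein, read_len=10, step=7), k=7)
        coverages = []
        for top_n in (1, 3, 5, 10, 20):
            contigs = extract_contigs(g, top_n=top_n)
            coverages.append(assembly_report(contigs, protein).sequence_coverage_pct)
        assert all(a <= b for a, b in zip(coverages, coverages[1:]))
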