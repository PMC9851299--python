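import numpy as np
import pytest

from abnovo.formats import GroundTruthRecord, PredictionRecord
from abnovo.masses import ModifiedPeptide
from abnovo.metrics import (
    aggregate_metrics,
    match_peptides,
    pr_curve,
    precision_threshold,
)
from conftest import random_peptide
from oracles import brute_force_match


def _pred(sid, seq, score=100.0):
    p = ModifiedPeptide.from_plain(seq) if isinstance(seq, str) else seq
    return PredictionRecord(sid, p, score, tuple([score] * len(p)))


def _truth(sid, seq):
    p = ModifiedPeptide.from_plain(seq) if isinstance(seq, str) else seq
    return GroundTruthRecord(sid, p, "test")


class TestMatchPeptides:
    def test_identity_full_match(self):
        p = ModifiedPeptide.from_plain("PEPTIDE")
        r = match_peptides(p, p)
        assert r.matched_aa == 7 and r.peptide_match

    def test_q_k_near_isobaric_blindness(self):
        """Q and K differ by 0.036 Da, below the 0.1 Da criterion, so a
        K-for-Q substitution still counts as a full peptide match."""
        r = match_peptides(
            ModifiedPeptide.from_plain("PEPTIDK"),
            ModifiedPeptide.from_plain("PEPTIDQ"),
        )
        assert r.matched_aa == 7 and r.peptide_match

    def test_ga_for_q_realigns_after_split(self):
        r = match_peptides(
            ModifiedPeptide.from_plain("GAPTIDE"),
            ModifiedPeptide.from_plain("QPTIDE"),
        )
        assert r.matched_aa == 5
        assert (r.pred_aa, r.truth_aa) == (7, 6)
        assert not r.peptide_match

    def test_matched_positions_bounded(self, rng):
        for _ in range(50):
            a, b = random_peptide(rng), random_peptide(rng)
            r = match_peptides(a, b)
            assert r.matched_aa <= min(r.pred_aa, r.truth_aa)

    def test_two_pointer_equals_brute_force_on_short_peptides(self, rng, tol, table):
        """The two-pointer walk must realise the maximal order-preserving
        matching; checked exhaustively on short random pairs, including
        related pairs that share prefixes."""
        for _ in range(300):
            a = random_peptide(rng, 1, 8)
            if rng.random() < 0.5:
                b = random_peptide(rng, 1, 8)
            else:  # related pair: perturb one position
                residues = list(a.residues)
                i = int(rng.integers(0, len(residues)))
                residues[i] = ("W" if residues[i][0] != "W" else "G", None)
                b = ModifiedPeptide(tuple(residues))
            assert match_peptides(a, b, tol, table).matched_aa == brute_force_match(
                a, b, tol, table
            )


class TestAggregateMetrics:
    def test_all_correct(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng)) for i in range(10)]
        preds = [_pred(r.spectrum_id, r.peptide) for r in gt]
        m = aggregate_metrics(preds, gt)
        assert (m.aa_recall, m.aa_precision, m.peptide_recall) == (1.0, 1.0, 1.0)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            aggregate_metrics([], [])

    def test_no_prediction_passes_threshold(self, rng):
        gt = [_truth("s0", random_peptide(rng))]
        preds = [_pred("s0", gt[0].peptide, score=10.0)]
        m = aggregate_metrics(preds, gt, min_confidence=50.0)
        assert m.peptide_recall == 0.0 and m.aa_recall == 0.0
        assert m.aa_precision is None
        assert m.counts["emitted_predictions"] == 0

    def test_unvalidated_predictions_excluded_and_counted(self, rng):
        gt = [_truth("s0", random_peptide(rng))]
        preds = [_pred("s0", gt[0].peptide), _pred("orphan", random_peptide(rng))]
        m = aggregate_metrics(preds, gt)
        assert m.counts["unvalidated_predictions"] == 1
        assert m.aa_precision == 1.0

    def test_recall_monotone_in_threshold(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng)) for i in range(40)]
        preds = [
            _pred(r.spectrum_id, r.peptide, score=float(rng.uniform(0, 100)))
            for r in gt
        ]
        values = [
            aggregate_metrics(preds, gt, min_confidence=t).peptide_recall
            for t in np.linspace(0, 100, 11)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_order_invariance(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng)) for i in range(20)]
        preds = [
            _pred(r.spectrum_id, random_peptide(rng), score=float(rng.uniform(0, 100)))
            for r in gt
        ]
        m1 = aggregate_metrics(preds, gt)
        m2 = aggregate_metrics(list(reversed(preds)), list(reversed(gt)))
        assert m1 == m2


class TestPRCurve:
    def test_separable_scores(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng, 8, 15)) for i in range(40)]
        preds = []
        for i, r in enumerate(gt):
            if i < 30:
                preds.append(_pred(r.spectrum_id, r.peptide, score=100.0))
            else:  # badly wrong prediction, score 0
                preds.append(_pred(r.spectrum_id, random_peptide(rng, 8, 15), 0.0))
        curve = pr_curve(preds, gt)
        positive = [p for t, p, _ in curve.points if t > 0]
        assert all(p == 1.0 for p in positive)
        assert 0.0 <= curve.auc <= 1.0

    def test_single_threshold_rectangle(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng)) for i in range(10)]
        preds = [_pred(r.spectrum_id, r.peptide, score=75.0) for r in gt[:7]]
        curve = pr_curve(preds, gt)
        assert len(curve.points) == 1
        _, precision, recall = curve.points[0]
        assert curve.auc == pytest.approx(recall * precision)

    def test_thresholds_strictly_increasing(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng)) for i in range(50)]
        preds = [
            _pred(r.spectrum_id, r.peptide, score=float(rng.uniform(0, 100)))
            for r in gt
        ]
        curve = pr_curve(preds, gt, n_thresholds=10)
        thresholds = [t for t, _, _ in curve.points]
        assert thresholds == sorted(set(thresholds))


class TestPrecisionThreshold:
    def test_all_correct_returns_zero(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng)) for i in range(10)]
        preds = [_pred(r.spectrum_id, r.peptide, score=float(rng.uniform(0, 100)))
                 for r in gt]
        result = precision_threshold(preds, gt)
        assert result.threshold == 0.0 and result.reachable

    def test_unreachable_flag(self, rng):
        gt = [_truth(f"s{i}", random_peptide(rng, 10, 15)) for i in range(10)]
        # every prediction wildly wrong: precision never reaches 50%
        preds = [
            _pred(r.spectrum_id, random_peptide(rng, 10, 15),
                  score=float(rng.uniform(0, 100)))
            for r in gt
        ]
        result = precision_threshold(preds, gt)
        assert not result.reachable
        assert result.threshold == max(p.peptide_score for p in preds)

    def test_agrees_with_exhaustive_scan(self, rng, tol, table):
        gt = [_truth(f"s{i}", random_peptide(rng, 8, 15)) for i in range(60)]
        preds = []
        for r in gt:
            correct = rng.random() < 0.4
            score = 100 * (rng.beta(8, 2) if correct else rng.beta(2, 8))
            seq = r.peptide if correct else random_peptide(rng, 8, 15)
            preds.append(_pred(r.spectrum_id, seq, score=float(score)))
        result = precision_threshold(preds, gt, target_precision=0.5)
        # independent scan over every candidate cutoff
        best = None
        for t in sorted({0.0} | {p.peptide_score for p in preds}):
            m = aggregate_metrics(preds, gt, min_confidence=t)
            if m.aa_precision is not None and m.aa_precision >= 0.5:
                best = t
                break
        assert best is not None and result.reachable
        assert result.threshold == best
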