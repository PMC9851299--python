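"""Amino-acid- and peptide-level matching, recall/precision, PR curves.

The matcher is the mass-based criterion shared by the de novo sequencing
literature: a predicted amino acid counts as correct when its residue mass
agrees with the reference within 0.1 Da *and* the cumulative prefix mass
before it agrees within 0.5 Da.  Position alignment is a two-pointer walk
over the two prefix-mass arrays; on short peptides it provably equals the
brute-force maximal order-preserving matching under the same pairwise
criterion (see the test suite).

Note the criterion is deliberately mass-blind to isobaric and near-isobaric
substitutions: I/L (identical mass) and Q/K (0.036 Da apart) compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import GroundTruthRecord, PredictionRecord
from .masses import (
    DEFAULT_MASS_TABLE,
    MassTable,
    ModifiedPeptide,
    ToleranceConfig,
    residue_masses,
)

__all__ = [
    "MatchResult",
    "MetricsSummary",
    "PRCurve",
    "ThresholdResult",
    "match_peptides",
    "aggregate_metrics",
    "pr_curve",
    "precision_threshold",
]


@dataclass(frozen=True)
class MatchResult:
    matched_aa: int
    pred_aa: int
    truth_aa: int
    peptide_match: bool
    matched_positions: tuple[tuple[int, int], ...]


def match_peptides(
    pred: ModifiedPeptide,
    truth: ModifiedPeptide,
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> MatchResult:
    """Mass-based amino-acid matching between a prediction and the truth.

    Two pointers i (prediction) and j (truth) walk the prefix-mass-before
    arrays (position 0 has prefix 0).  When the prefixes agree within
    ``prefix_mass_tol`` both advance, counting a match iff the residue
    masses agree within ``aa_mass_tol``; otherwise the pointer with the
    smaller prefix advances.  The peptide is correct iff every position of
    both peptides matched.
    """
    pm = residue_masses(pred, table)
    tm = residue_masses(truth, table)
    # prefix mass *before* each residue
    pp = np.concatenate(([0.0], np.cumsum(pm)[:-1]))
    tp = np.concatenate(([0.0], np.cumsum(tm)[:-1]))

    matched: list[tuple[int, int]] = []
    i = j = 0
    while i < len(pm) and j < len(tm):
        if abs(pp[i] - tp[j]) < tol.prefix_mass_tol:
            if abs(pm[i] - tm[j]) < tol.aa_mass_tol:
                matched.append((i, j))
            i += 1
            j += 1
        elif pp[i] < tp[j]:
            i += 1
        else:
            j += 1

    n_matched = len(matched)
    return MatchResult(
        matched_aa=n_matched,
        pred_aa=len(pm),
        truth_aa=len(tm),
        peptide_match=n_matched == len(pm) == len(tm),
        matched_positions=tuple(matched),
    )


@dataclass(frozen=True)
class MetricsSummary:
    """Fig-2-style aggregates over a prediction set.

    aa_recall: matched AAs over *all* ground-truth AAs (spectra without a
    surviving prediction contribute zero matches).
    aa_precision: matched AAs over predicted AAs of emitted predictions;
    None when no prediction was emitted.
    peptide_recall: fully correct peptides over ground-truth spectra.
    """

    aa_recall: float
    aa_precision: float | None
    peptide_recall: float
    counts: dict = field(default_factory=dict)


def aggregate_metrics(
    predictions: Iterable[PredictionRecord],
    ground_truth: Iterable[GroundTruthRecord],
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
    min_confidence: float | None = None,
) -> MetricsSummary:
    """Aggregate AA recall/precision and peptide recall over a dataset.

    Predictions whose spectrum_id has no ground truth are excluded and
    counted as unvalidated.  With ``min_confidence`` set, predictions below
    the peptide-score cutoff are treated as not emitted.
    """
    truth_by_id = {r.spectrum_id: r for r in ground_truth}
    if not truth_by_id:
        raise ValueError("ground truth is empty")

    total_truth_aa = sum(len(r.peptide) for r in truth_by_id.values())
    matched_sum = 0
    pred_aa_sum = 0
    peptide_matches = 0
    emitted = 0
    unvalidated = 0
    for pred in predictions:
        gt = truth_by_id.get(pred.spectrum_id)
        if gt is None:
            unvalidated += 1
            continue
        if min_confidence is not None and pred.peptide_score < min_confidence:
            continue
        emitted += 1
        result = match_peptides(pred.peptide, gt.peptide, tol, table)
        matched_sum += result.matched_aa
        pred_aa_sum += result.pred_aa
        peptide_matches += int(result.peptide_match)

    n_truth = len(truth_by_id)
    return MetricsSummary(
        aa_recall=matched_sum / total_truth_aa,
        aa_precision=(matched_sum / pred_aa_sum) if pred_aa_sum else None,
        peptide_recall=peptide_matches / n_truth,
        counts={
            "ground_truth_spectra": n_truth,
            "ground_truth_aa": total_truth_aa,
            "emitted_predictions": emitted,
            "unvalidated_predictions": unvalidated,
            "matched_aa": matched_sum,
            "predicted_aa": pred_aa_sum,
            "correct_peptides": peptide_matches,
        },
    )


@dataclass(frozen=True)
class PRCurve:
    """Precision–recall curve over confidence-score thresholds.

    ``points`` holds (threshold, aa_precision, aa_recall) at strictly
    increasing thresholds; ``auc`` is the trapezoidal area of precision
    over recall, anchored at recall 0 with the lowest-recall precision.
    """

    points: tuple[tuple[float, float | None, float], ...]
    auc: float


def pr_curve(
    predictions: Sequence[PredictionRecord],
    ground_truth: Sequence[GroundTruthRecord],
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
    n_thresholds: int = 50,
) -> PRCurve:
    """Sweep peptide-score thresholds and integrate precision over recall."""
    scores = sorted({p.peptide_score for p in predictions})
    if not scores:
        raise ValueError("need at least one scored prediction")
    if len(scores) > n_thresholds:
        idx = np.unique(np.linspace(0, len(scores) - 1, n_thresholds).round().astype(int))
        scores = [scores[i] for i in idx]

    points = []
    for t in scores:
        summary = aggregate_metrics(
            predictions, ground_truth, tol, table, min_confidence=t
        )
        points.append((float(t), summary.aa_precision, summary.aa_recall))

    defined = [(r, p) for _, p, r in points if p is not None]
    auc = _trapezoid_auc(defined)
    return PRCurve(points=tuple(points), auc=auc)


def _trapezoid_auc(recall_precision: list[tuple[float, float]]) -> float:
    """Trapezoid over (recall, precision), plus a rectangle anchoring the
    lowest-recall point back to recall 0."""
    if not recall_precision:
        return 0.0
    # ascending recall; at equal recall keep the higher precision first so
    # the zero-width segment contributes nothing and the anchor uses the
    # high-precision (high-threshold) end of the curve
    pts = sorted(recall_precision, key=lambda rp: (rp[0], -rp[1]))
    auc = pts[0][0] * pts[0][1]
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        auc += (r1 - r0) * (p0 + p1) / 2.0
    return float(min(max(auc, 0.0), 1.0))


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    precision: float | None
    reachable: bool


def precision_threshold(
    predictions: Sequence[PredictionRecord],
    ground_truth: Sequence[GroundTruthRecord],
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
    target_precision: float = 0.5,
) -> ThresholdResult:
    """Smallest confidence cutoff whose surviving AA precision reaches target.

    Scans threshold 0 and every observed peptide score ascending; returns
    the first cutoff at which aa_precision >= target_precision.  If even
    keeping only the top-scored predictions cannot reach the target, the
    maximal observed score is returned with ``reachable=False``.
    """
    candidates = [0.0] + sorted({p.peptide_score for p in predictions})
    best: ThresholdResult | None = None
    for t in candidates:
        summary = aggregate_metrics(
            predictions, ground_truth, tol, table, min_confidence=t
        )
        if summary.aa_precision is not None and summary.aa_precision >= target_precision:
            return ThresholdResult(t, summary.aa_precision, True)
        best = ThresholdResult(t, summary.aa_precision, False)
    return best if best is not None else ThresholdResult(0.0, None, False)


def stratified_recall(
    predictions: Sequence[PredictionRecord],
    ground_truth: Sequence[GroundTruthRecord],
    strata: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> dict[str, dict[str, dict[str, float | int]]]:
    """Peptide recall within named spectrum strata.

    ``strata`` maps an axis name (e.g. "missing_sites") to bins, each bin a
    list of spectrum ids.  Returns recall and spectrum count per bin —
    the stratifications by missing cleavage sites, noise factor and
    peptide length all reduce to this.
    """
    pred_by_id = {p.spectrum_id: p for p in predictions}
    truth_by_id = {r.spectrum_id: r for r in ground_truth}
    out: dict[str, dict[str, dict[str, float | int]]] = {}
    for axis, bins in (strata or {}).items():
        out[axis] = {}
        for label, ids in bins.items():
            ids = [i for i in ids if i in truth_by_id]
            correct = 0
            for sid in ids:
                pred = pred_by_id.get(sid)
                if pred is None:
                    continue
                if match_peptides(
                    pred.peptide, truth_by_id[sid].peptide, tol, table
                ).peptide_match:
                    correct += 1
            out[axis][label] = {
                "spectra": len(ids),
                "peptide_recall": (correct / len(ids)) if ids else float("nan"),
            }
    return out
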