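"""The 11-category taxonomy of de novo sequencing errors.

Each incorrect prediction is assigned exactly one label: a permutation of
the first and/or last three residues, an n-for-n residue replacement
(n = 1..6, with the single-residue case also covering 1-for-2 splits such
as Q vs GA), more than six wrong residues, or "other" for patterns outside
all categories (e.g. two residues replaced by four).  The decision
procedure is a fixed priority order — inversions before replacements
before the more-than-6 bucket — so a terminal 3-residue permutation, which
is formally also a 3-for-3 replacement, lands in the inversion category.

All residue comparisons are mass comparisons at the amino-acid matching
tolerance, consistent with the matcher: I/L and Q/K compare equal.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from .formats import GroundTruthRecord, PredictionRecord
from .masses import (
    DEFAULT_MASS_TABLE,
    MassTable,
    ModifiedPeptide,
    ToleranceConfig,
    residue_masses,
)
from .metrics import match_peptides

__all__ = ["ErrorType", "classify_error", "error_profile"]


class ErrorType(str, Enum):
    CORRECT = "correct"
    INVERSION_FIRST_3 = "inversion_first_3"
    INVERSION_LAST_3 = "inversion_last_3"
    INVERSION_FIRST_AND_LAST_3 = "inversion_first_and_last_3"
    REPLACE_1_BY_1_OR_2 = "replace_1_by_1_or_2"
    REPLACE_2_BY_2 = "replace_2_by_2"
    REPLACE_3_BY_3 = "replace_3_by_3"
    REPLACE_4_BY_4 = "replace_4_by_4"
    REPLACE_5_BY_5 = "replace_5_by_5"
    REPLACE_6_BY_6 = "replace_6_by_6"
    MORE_THAN_6_WRONG = "more_than_6_wrong"
    OTHER = "other"


#: The error categories proper (excludes the CORRECT sentinel).
ERROR_CATEGORIES: tuple[ErrorType, ...] = tuple(
    e for e in ErrorType if e is not ErrorType.CORRECT
)


def _positional_match(a: np.ndarray, b: np.ndarray, tol: float) -> np.ndarray:
    return np.abs(a - b) < tol


def _multiset_equal(a: np.ndarray, b: np.ndarray, tol: float) -> bool:
    """Can the masses in a be bijectively paired with b within tol?

    Windows are length 3, so testing all permutations is exact.
    """
    if len(a) != len(b):
        return False
    return any(
        all(abs(a[i] - b[p[i]]) < tol for i in range(len(a)))
        for p in permutations(range(len(b)))
    )


def classify_error(
    pred: ModifiedPeptide,
    truth: ModifiedPeptide,
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
    strict_reversal: bool = False,
) -> ErrorType:
    """Assign the single error label for a (prediction, truth) pair.

    ``strict_reversal`` narrows the inversion categories to exact reversals
    of the terminal 3 residues instead of any reordering.
    """
    result = match_peptides(pred, truth, tol, table)
    if result.peptide_match:
        return ErrorType.CORRECT

    pm = residue_masses(pred, table)
    tm = residue_masses(truth, table)
    lp, lt = len(pm), len(tm)
    aa_tol = tol.aa_mass_tol

    # --- terminal inversions (equal length only) -------------------------
    if lp == lt and lp >= 4:
        pos = _positional_match(pm, tm, aa_tol)
        first_perm = _is_permuted_window(pred, truth, pm, tm, slice(0, 3), aa_tol,
                                         strict_reversal)
        last_perm = _is_permuted_window(pred, truth, pm, tm, slice(lp - 3, lp),
                                        aa_tol, strict_reversal)
        if first_perm and pos[3:].all():
            return ErrorType.INVERSION_FIRST_3
        if last_perm and pos[: lp - 3].all():
            return ErrorType.INVERSION_LAST_3
        if lp >= 7 and first_perm and last_perm and pos[3 : lp - 3].all():
            return ErrorType.INVERSION_FIRST_AND_LAST_3

    # --- n-for-m replacements between matched anchors --------------------
    pos_len = min(lp, lt)
    prefix_len = 0
    while prefix_len < pos_len and abs(pm[prefix_len] - tm[prefix_len]) < aa_tol:
        prefix_len += 1
    suffix_len = 0
    while (
        suffix_len < pos_len
        and abs(pm[lp - 1 - suffix_len] - tm[lt - 1 - suffix_len]) < aa_tol
    ):
        suffix_len += 1
    # anchors must not overlap on either peptide; ties keep the prefix
    suffix_len = min(suffix_len, pos_len - prefix_len)
    t_window = lt - prefix_len - suffix_len
    p_window = lp - prefix_len - suffix_len
    if t_window == 1 and p_window in (1, 2):
        return ErrorType.REPLACE_1_BY_1_OR_2
    if t_window == p_window and 2 <= t_window <= 6:
        return ErrorType(f"replace_{t_window}_by_{t_window}")

    # --- bulk errors ------------------------------------------------------
    if result.truth_aa - result.matched_aa > 6:
        return ErrorType.MORE_THAN_6_WRONG
    return ErrorType.OTHER


def _is_permuted_window(
    pred: ModifiedPeptide,
    truth: ModifiedPeptide,
    pm: np.ndarray,
    tm: np.ndarray,
    window: slice,
    aa_tol: float,
    strict_reversal: bool,
) -> bool:
    """True when the windows hold the same residue masses in a different order."""
    pw, tw = pm[window], tm[window]
    if _positional_match(pw, tw, aa_tol).all():
        return False
    if strict_reversal:
        return _positional_match(pw[::-1], tw, aa_tol).all()
    return _multiset_equal(pw, tw, aa_tol)


def error_profile(
    predictions: Iterable[PredictionRecord],
    ground_truth: Iterable[GroundTruthRecord],
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> dict:
    """Count and normalize the error categories over a prediction set.

    Returns total predictions, total errors and, when errors exist, each
    category's share of the total errors (shares sum to 1).
    """
    truth_by_id = {r.spectrum_id: r for r in ground_truth}
    labels: Counter[ErrorType] = Counter()
    total = 0
    for pred in predictions:
        gt = truth_by_id.get(pred.spectrum_id)
        if gt is None:
            continue
        total += 1
        labels[classify_error(pred.peptide, gt.peptide, tol, table)] += 1

    n_errors = total - labels[ErrorType.CORRECT]
    profile = {
        "total_predictions": total,
        "total_errors": n_errors,
        "counts": {e.value: labels[e] for e in ERROR_CATEGORIES},
        "shares": {
            e.value: (labels[e] / n_errors if n_errors else 0.0)
            for e in ERROR_CATEGORIES
        },
    }
    return profile
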