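import numpy as np
import pytest

from abnovo.errors import ERROR_CATEGORIES, ErrorType, classify_error, error_profile
from abnovo.formats import GroundTruthRecord, PredictionRecord
from abnovo.masses import ModifiedPeptide, neutral_mass
from abnovo.simulate import (
    MASS_MATCHED_SPLITS,
    CorruptionError,
    corrupt_peptide,
)
from conftest import random_peptide


def _pp(seq):
    return ModifiedPeptide.from_plain(seq)


class TestClassifyError:
    def test_identical_is_correct(self):
        assert classify_error(_pp("PEPTIDE"), _pp("PEPTIDE")) is ErrorType.CORRECT

    def test_inversion_first_3(self):
        assert (
            classify_error(_pp("TSAPEPK"), _pp("ASTPEPK"))
            is ErrorType.INVERSION_FIRST_3
        )

    def test_inversion_last_3(self):
        assert (
            classify_error(_pp("PEPKAST"), _pp("PEPKTSA"))
            is ErrorType.INVERSION_LAST_3
        )

    def test_inversion_both_ends(self):
        assert (
            classify_error(_pp("TSAWKEP"), _pp("ASTWPEK"))
            is ErrorType.INVERSION_FIRST_AND_LAST_3
        )

    def test_two_for_four_replacement_is_other(self):
        # 2 residues replaced by 4: the canonical out-of-category pattern
        assert classify_error(_pp("PEGSGSTIDE"), _pp("PEWKTIDE")) is ErrorType.OTHER

    def test_single_replacement(self):
        assert (
            classify_error(_pp("PEWTIDE"), _pp("PEGTIDE"))
            is ErrorType.REPLACE_1_BY_1_OR_2
        )

    def test_one_for_two_split(self):
        # Q read as GA: near-isobaric 1-for-2 replacement
        assert (
            classify_error(_pp("PEGATIDE"), _pp("PEQTIDE"))
            is ErrorType.REPLACE_1_BY_1_OR_2
        )

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_n_for_n_replacement(self, n, rng):
        truth = random_peptide(rng, 10, 14)
        pred = corrupt_peptide(truth, ErrorType(f"replace_{n}_by_{n}"), rng)
        assert classify_error(pred, truth) is ErrorType(f"replace_{n}_by_{n}")

    def test_terminal_permutation_outranks_replacement(self):
        """A permutation of the first three residues is formally also a
        3-for-3 replacement; the priority order must put it in the
        inversion category."""
        truth, pred = _pp("ASTPEPK"), _pp("TSAPEPK")
        assert classify_error(pred, truth) is ErrorType.INVERSION_FIRST_3

    def test_strict_reversal_flag(self):
        # ABC -> BCA is a rotation, not a reversal
        rotated = classify_error(
            _pp("STAPEPK"), _pp("ASTPEPK"), strict_reversal=True
        )
        assert rotated is not ErrorType.INVERSION_FIRST_3
        reversed_ = classify_error(
            _pp("TSAPEPK"), _pp("ASTPEPK"), strict_reversal=True
        )
        assert reversed_ is ErrorType.INVERSION_FIRST_3

    def test_more_than_6_wrong(self, rng):
        truth = random_peptide(rng, 9, 15)
        pred = corrupt_peptide(truth, ErrorType.MORE_THAN_6_WRONG, rng)
        assert classify_error(pred, truth) is ErrorType.MORE_THAN_6_WRONG

    def test_classifier_is_total(self, rng):
        for _ in range(100):
            a, b = random_peptide(rng, 4, 16), random_peptide(rng, 4, 16)
            assert classify_error(a, b) in ErrorType


class TestCorruptPeptide:
    @pytest.mark.parametrize("error_type", [e for e in ERROR_CATEGORIES])
    def test_round_trip_classification(self, error_type, rng):
        """classify(corrupt(p, e), p) = e for every category, on many
        random applicable peptides."""
        done = 0
        while done < 60:
            p = random_peptide(rng, 8, 18)
            try:
                corrupted = corrupt_peptide(p, error_type, rng)
            except CorruptionError:
                continue
            assert classify_error(corrupted, p) is error_type
            done += 1

    def test_no_error_is_identity(self, rng):
        p = random_peptide(rng)
        assert corrupt_peptide(p, ErrorType.CORRECT, rng) == p

    def test_too_short_peptide_rejected(self, rng):
        with pytest.raises(CorruptionError):
            corrupt_peptide(_pp("AGW"), ErrorType.INVERSION_FIRST_3, rng)
        with pytest.raises(CorruptionError):
            corrupt_peptide(_pp("AGWPEP"), ErrorType.MORE_THAN_6_WRONG, rng)

    def test_mass_matched_split_conserves_mass(self, table):
        """Every pooled 1-to-2 split stays within 0.5 Da of the original
        residue, mirroring genuinely mass-ambiguous calls (Q vs GA)."""
        for code, splits in MASS_MATCHED_SPLITS.items():
            original = table.residue_masses[code]
            for split in splits:
                total = sum(table.residue_masses[aa] for aa in split)
                assert abs(total - original) < 0.5

    def test_split_corruption_conserves_peptide_mass(self, rng, table):
        truth = _pp("PEQTIDEK")
        found_split = False
        for _ in range(50):
            pred = corrupt_peptide(truth, ErrorType.REPLACE_1_BY_1_OR_2, rng)
            if len(pred) == len(truth) + 1:
                found_split = True
                assert abs(neutral_mass(pred) - neutral_mass(truth)) < 0.5
        assert found_split


class TestErrorProfile:
    def test_all_correct_empty_profile(self, rng):
        gt = [
            GroundTruthRecord(f"s{i}", random_peptide(rng), "t") for i in range(10)
        ]
        preds = [
            PredictionRecord(r.spectrum_id, r.peptide, 90.0, (90.0,) * len(r.peptide))
            for r in gt
        ]
        profile = error_profile(preds, gt)
        assert profile["total_errors"] == 0
        assert all(v == 0 for v in profile["counts"].values())

    def test_shares_sum_to_one(self, rng):
        gt, preds = [], []
        for i in range(60):
            truth = random_peptide(rng, 8, 16)
            gt.append(GroundTruthRecord(f"s{i}", truth, "t"))
            e = [ErrorType.INVERSION_LAST_3, ErrorType.REPLACE_3_BY_3,
                 ErrorType.MORE_THAN_6_WRONG][i % 3]
            try:
                pred = corrupt_peptide(truth, e, np.random.default_rng(i))
            except CorruptionError:
                pred = truth
            preds.append(
                PredictionRecord(f"s{i}", pred, 50.0, (50.0,) * len(pred))
            )
        profile = error_profile(preds, gt)
        if profile["total_errors"]:
            assert sum(profile["shares"].values()) == pytest.approx(1.0, abs=1e-9)
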