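"""ROC/AUC computation, Youden cutoff selection and threshold derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from atnpipe.core import CsfPanel, SubjectRecord, ValidationError
from atnpipe.simulate import DistributionalSpec, generate_distributional
from atnpipe.thresholds import derive_thresholds, roc_auc, youden_cutoff

from conftest import brute_force_auc, exhaustive_youden


def _make_pet_subjects(values, labels):
    return [
        SubjectRecord(
            subject_id=f"T{i}",
            syndrome="MCI",
            csf=CsfPanel(abeta42=v, ptau=50.0, ttau=400.0),
            pet_visual="positive" if lab else "negative",
        )
        for i, (v, lab) in enumerate(zip(values, labels))
    ]


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0], "lower_is_positive")
        assert res.auc == 1.0
        assert res.n_positive == 3 and res.n_negative == 3

    def test_identical_multisets_give_half(self):
        res = roc_auc([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0], "higher_is_positive")
        assert res.auc == 0.5

    def test_interleaved_case_half_by_pair_counting(self):
        # positives {1,3,5} vs negatives {2,4}: 3 wins / 6 pairs
        res = roc_auc([1, 3, 5, 2, 4], [1, 1, 1, 0, 0], "higher_is_positive")
        assert res.auc == 0.5

    def test_ci_brackets_auc_and_may_exceed_unit_interval(self):
        res = roc_auc([1, 2, 3, 10, 11], [1, 1, 1, 0, 0], "lower_is_positive")
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.ci_high >= 1.0  # unclipped normal bound at perfect separation

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValidationError, match="degenerate reference"):
            roc_auc([1, 2, 3], [1, 1, 1], "higher_is_positive")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length mismatch"):
            roc_auc([1, 2, 3], [1, 0], "higher_is_positive")

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=30),
        st.data(),
    )
    def test_matches_brute_force_pair_counting(self, values, data):
        n = len(values)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        for direction in ("lower_is_positive", "higher_is_positive"):
            res = roc_auc(values, labels, direction)
            assert res.auc == pytest.approx(
                brute_force_auc(values, labels, direction), abs=1e-12
            )

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            values = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            res = roc_auc(values, labels, "higher_is_positive")
            assert res.auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    def test_direction_reversal_complements_auc(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=25)
        labels = np.r_[np.ones(10), np.zeros(15)].astype(int)
        lo = roc_auc(values, labels, "lower_is_positive").auc
        hi = roc_auc(values, labels, "higher_is_positive").auc
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_hanley_ci_option(self):
        values = [1, 2, 3, 10, 4, 11, 12]
        labels = [1, 1, 1, 1, 0, 0, 0]
        delong = roc_auc(values, labels, "lower_is_positive", ci_method="delong")
        hanley = roc_auc(values, labels, "lower_is_positive", ci_method="hanley")
        assert delong.auc == hanley.auc
        assert (delong.ci_low, delong.ci_high) != (hanley.ci_low, hanley.ci_high)


class TestYoudenCutoff:
    def test_perfectly_separating_cutoff(self):
        res = youden_cutoff([100, 200, 300, 400], [1, 1, 0, 0], "lower_is_positive")
        assert 200 < res.cutoff <= 300
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.youden == 1.0

    def test_all_values_equal_flagged_non_discriminative(self):
        res = youden_cutoff([5.0] * 6, [1, 1, 1, 0, 0, 0], "higher_is_positive")
        assert res.youden == 0.0
        assert res.flag == "non-discriminative"

    def test_all_positive_reference_rejected(self):
        with pytest.raises(ValidationError, match="degenerate reference"):
            youden_cutoff([1, 2, 3], [1, 1, 1], "higher_is_positive")

    def test_youden_is_sens_plus_spec_minus_one(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        res = youden_cutoff(values, labels, "higher_is_positive")
        assert res.youden == res.sensitivity + res.specificity - 1.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=3, max_size=25),
        st.data(),
    )
    def test_matches_exhaustive_scan(self, values, data):
        n = len(values)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        for direction in ("lower_is_positive", "higher_is_positive"):
            res = youden_cutoff(values, labels, direction)
            cut, sens, spec = exhaustive_youden(values, labels, direction)
            assert res.sensitivity == pytest.approx(sens, abs=1e-12)
            assert res.specificity == pytest.approx(spec, abs=1e-12)
            assert res.cutoff == pytest.approx(cut, abs=1e-9) or (
                np.isinf(cut) and np.isinf(res.cutoff) and cut == res.cutoff
            )

    def test_shift_invariance_moves_cutoff_only(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=40)
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        base = youden_cutoff(values + 0.8 * labels, labels, "higher_is_positive")
        shifted = youden_cutoff(values + 0.8 * labels + 100.0, labels, "higher_is_positive")
        assert shifted.auc == pytest.approx(base.auc, abs=1e-12)
        assert shifted.cutoff == pytest.approx(base.cutoff + 100.0, abs=1e-6)


class TestDeriveThresholds:
    def test_recovers_generative_separation_boundary(self):
        cohort = generate_distributional(DistributionalSpec(seed=42, n=2000))
        results = derive_thresholds(cohort)
        abeta = results["abeta42"]
        assert abeta.direction == "lower_is_positive"
        assert abeta.cutoff is not None
        assert 542.2 < abeta.cutoff < 842.3  # between the generative group means

    def test_shuffled_reference_flags_markers_non_discriminative(self):
        cohort = generate_distributional(DistributionalSpec(seed=9, n=120))
        rng = np.random.default_rng(9)
        flagged = 0
        n_shuffles = 20
        for _ in range(n_shuffles):
            reads = [s.pet_visual for s in cohort]
            rng.shuffle(reads)
            shuffled = [
                SubjectRecord(
                    subject_id=s.subject_id, syndrome=s.syndrome, csf=s.csf,
                    pet_visual=read,
                )
                for s, read in zip(cohort, reads)
            ]
            results = derive_thresholds(shuffled)
            if all(r.flag == "insufficient accuracy" for r in results.values()):
                flagged += 1
        assert flagged >= 0.9 * n_shuffles

    def test_interval_violation_excluded(self, caplog):
        import datetime as dt
        near = _make_pet_subjects([400, 500, 800, 900], [1, 1, 0, 0])
        far = SubjectRecord(
            subject_id="FAR", syndrome="MCI",
            csf=CsfPanel(abeta42=100.0, ptau=50.0, ttau=400.0),
            pet_visual="negative",
            lp_date=dt.date(2015, 1, 1), pet_date=dt.date(2017, 1, 1),
        )
        with caplog.at_level("INFO", logger="atnpipe.thresholds"):
            results = derive_thresholds([*near, far])
        assert results["abeta42"].n_negative == 2  # FAR excluded
        assert any("FAR" in rec.message for rec in caplog.records)

    def test_empty_subcohort_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            derive_thresholds([])

    def test_insufficient_accuracy_withdraws_cutoff(self):
        rng = np.random.default_rng(13)
        values = rng.normal(500, 50, size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        subjects = _make_pet_subjects(values, labels)
        results = derive_thresholds(subjects)
        assert results["abeta42"].flag == "insufficient accuracy"
        assert results["abeta42"].cutoff is None
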