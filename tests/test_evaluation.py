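"""Severity-comparison pipeline: CAP coding, linkage, cross-tab, evaluate."""

from dataclasses import replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from wardflow.errors import MissingField, NoSeverityRecorded
from wardflow.evaluation import (
    crosstab_severity,
    diagnose_cap,
    evaluate,
    link_reviews,
    max_severity,
)
from wardflow.simulate import SimConfig, simulate_cohort, simulate_reviews
from wardflow.store import ReplayStore

T0 = datetime(2022, 4, 1)


class TestDiagnoseCap:
    @pytest.mark.parametrize(
        "code,expected",
        [("J18.1", True), ("J12.0", True), ("J15.9", True), ("I21.0", False), ("J45.9", False)],
    )
    def test_primary_code_membership(self, code, expected):
        assert diagnose_cap({"primary_diagnosis": code}) is expected

    def test_absent_code_raises(self):
        with pytest.raises(MissingField):
            diagnose_cap({})
        with pytest.raises(MissingField):
            diagnose_cap({"primary_diagnosis": float("nan")})


class TestMaxSeverity:
    def test_no_severity_raises(self, cap_plan):
        from wardflow.engine import Journey

        j = Journey(admission_id="X", current="triage", admitted_at=T0)
        with pytest.raises(NoSeverityRecorded):
            max_severity(j)


class TestLinkReviews:
    def admissions(self):
        return pd.DataFrame(
            [
                {"admission_id": "A1", "patient_id": "P1",
                 "admitted_at": T0, "discharged_at": T0 + timedelta(days=3)},
                {"admission_id": "A2", "patient_id": "P2",
                 "admitted_at": T0, "discharged_at": T0 + timedelta(days=2)},
            ]
        )

    def review(self, patient, adm_dt, rev_dt=None, band="Low"):
        return {
            "patient_id": patient,
            "admission_datetime": adm_dt,
            "review_datetime": rev_dt or adm_dt + timedelta(hours=4),
            "curb65": 1,
            "severity": band,
        }

    def test_review_shortly_after_admission_matches(self):
        reviews = pd.DataFrame([self.review("P1", T0 + timedelta(hours=2))])
        matched, unmatched = link_reviews(self.admissions(), reviews)
        assert matched["admission_id"].tolist() == ["A1"]
        assert unmatched == ["A2"]

    def test_review_days_after_discharge_is_unmatched(self):
        reviews = pd.DataFrame([self.review("P1", T0 + timedelta(days=6))])
        matched, unmatched = link_reviews(self.admissions(), reviews)
        assert len(matched) == 0
        assert set(unmatched) == {"A1", "A2"}

    def test_window_tolerance_is_inclusive(self):
        reviews = pd.DataFrame([self.review("P1", T0 - timedelta(hours=24))])
        matched, _ = link_reviews(self.admissions(), reviews, tolerance_hours=24)
        assert matched["admission_id"].tolist() == ["A1"]
        matched, _ = link_reviews(self.admissions(), reviews, tolerance_hours=12)
        assert len(matched) == 0

    def test_earliest_review_wins(self):
        reviews = pd.DataFrame(
            [
                self.review("P1", T0 + timedelta(hours=3), T0 + timedelta(hours=20), band="High"),
                self.review("P1", T0 + timedelta(hours=2), T0 + timedelta(hours=6), band="Low"),
            ]
        )
        matched, _ = link_reviews(self.admissions(), reviews)
        assert len(matched) == 1
        assert matched.iloc[0]["reviewer_band"] == "Low"  # earlier review kept

    def test_one_to_one_spillover_to_second_admission(self):
        adm = pd.DataFrame(
            [
                {"admission_id": "A1", "patient_id": "P1",
                 "admitted_at": T0, "discharged_at": T0 + timedelta(days=1)},
                {"admission_id": "A2", "patient_id": "P1",
                 "admitted_at": T0 + timedelta(days=1, hours=6),
                 "discharged_at": T0 + timedelta(days=2)},
            ]
        )
        # the second review is inside both admissions' tolerance windows but
        # A1 is already taken by the earlier review, so it spills to A2
        reviews = pd.DataFrame(
            [
                self.review("P1", T0 + timedelta(hours=2), T0 + timedelta(hours=3)),
                self.review("P1", T0 + timedelta(days=1, hours=7), T0 + timedelta(days=1, hours=9)),
            ]
        )
        matched, _ = link_reviews(adm, reviews)
        assert sorted(matched["admission_id"]) == ["A1", "A2"]


class TestCrossTab:
    def test_hand_tally(self):
        tab = crosstab_severity([("Low", "Low"), ("Moderate", "High"), ("High", "High")])
        assert tab.agreement_count == 2
        assert tab.engine_high_underscored == 1
        assert tab.counts[1, 2] == 1
        assert tab.counts.sum() == 3

    def test_empty_pairs(self):
        tab = crosstab_severity([])
        assert tab.counts.sum() == 0
        assert tab.agreement_fraction == 0.0

    def test_all_identical_pairs(self):
        tab = crosstab_severity([("High", "High")] * 7)
        assert tab.agreement_fraction == 1.0
        assert np.trace(tab.counts) == 7

    def test_invalid_band_rejected(self):
        from wardflow.errors import InvalidValue

        with pytest.raises(InvalidValue):
            crosstab_severity([("Low", "Extreme")])


class TestEvaluate:
    def test_closed_loop_error_free_reviewer_is_diagonal(self, small_cohort, small_store):
        cfg, _, truth, _ = small_cohort
        cfg0 = replace(cfg, reviewer_error=0.0, review_score_missing=0.0, review_fraction=1.0)
        reviews = simulate_reviews(truth, cfg0)
        report = evaluate(small_store, reviews)
        assert report.agreement_fraction == 1.0
        off_diag = report.crosstab.counts.sum() - np.trace(report.crosstab.counts)
        assert off_diag == 0
        assert report.n_reviewed == report.n_cap

    def test_marginals_and_splits_are_consistent(self, small_cohort, small_store):
        cfg, _, truth, reviews = small_cohort
        report = evaluate(small_store, reviews)
        assert report.n_reviewed + report.n_not_reviewed == report.n_cap
        assert report.crosstab.counts.sum() == report.n_with_reviewer_score
        assert report.n_with_reviewer_score <= report.n_reviewed

    def test_cohort_without_cap_yields_empty_report(self, cap_plan):
        cfg = SimConfig(n_admissions=15, seed=3, cap_fraction=0.0)
        messages, truth = simulate_cohort(cfg)
        reviews = simulate_reviews(truth, cfg)
        report = evaluate(ReplayStore.from_messages(messages), reviews)
        assert report.n_cap == 0
        assert report.n_reviewed == 0
        assert report.crosstab.counts.sum() == 0

    def test_summary_text_contains_headline_numbers(self, small_cohort, small_store):
        cfg, _, _, reviews = small_cohort
        report = evaluate(small_store, reviews)
        text = report.summary_text()
        assert f"{report.n_cap} CAP" in text
        assert "Reviewer band (rows)" in text
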