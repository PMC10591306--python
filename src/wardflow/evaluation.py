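"""Retrospective severity-comparison pipeline.

Mirrors the quality-improvement analysis: identify CAP admissions by coded
diagnosis, replay each admission hourly through the plan, take the highest
engine-determined severity band per stay, link the manual review records by
patient id and admission datetime, and tally reviewer-band x engine-band
pairs into a 3x3 cross-tab with agreement and discordance summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from datetime import timedelta
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .capplan import CAP_ICD_PREFIXES, build_cap_plan, cap_message_schemas
from .curb65 import SEVERITY_BANDS, band_index, max_band
from .engine import Engine, Journey
from .errors import InvalidValue, MissingField, NoSeverityRecorded
from .plan import Plan
from .store import ReplayStore

logger = logging.getLogger(__name__)


def diagnose_cap(record: Mapping[str, Any], cap_prefixes: Sequence[str] = CAP_ICD_PREFIXES) -> bool:
    """True iff the admission's primary-position ICD-10 code is in the CAP set."""
    code = record.get("primary_diagnosis")
    if code is None or (isinstance(code, float) and code != code):
        raise MissingField("primary_diagnosis")
    return any(str(code).startswith(p) for p in cap_prefixes)


def max_severity(journey: Journey) -> str:
    """Highest severity band recorded over the admission (Low < Moderate < High)."""
    bands = [value for _, value in journey.state_history("severity")]
    if not bands:
        raise NoSeverityRecorded(journey.admission_id)
    return max_band(bands)


def link_reviews(
    admissions: pd.DataFrame,
    reviews: pd.DataFrame,
    tolerance_hours: float = 24.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Match review records to admissions by patient id and datetime.

    A review matches an admission when patient ids are equal and the review's
    recorded admission datetime falls within the admission interval extended
    by ``tolerance_hours`` on both sides. Matching is one-to-one with
    earliest-review-wins tie-breaking; a review matching several admissions
    is kept on the first (a warning is logged).

    Returns (matched table, list of unmatched admission ids).
    """
    tol = timedelta(hours=tolerance_hours)
    matched_rows: list[dict] = []
    used_admissions: set[str] = set()
    if len(reviews):
        reviews = reviews.sort_values("review_datetime", kind="stable")
    by_patient: dict[Any, list] = {}
    for adm in admissions.itertuples(index=False):
        by_patient.setdefault(adm.patient_id, []).append(adm)

    for rev in reviews.itertuples(index=False) if len(reviews) else []:
        candidates = []
        for adm in by_patient.get(rev.patient_id, []):
            lo = _dt(adm.admitted_at) - tol
            hi = _dt(adm.discharged_at) + tol
            if lo <= _dt(rev.admission_datetime) <= hi:
                candidates.append(adm)
        if not candidates:
            continue
        if len(candidates) > 1:
            logger.warning(
                "review for patient %s matches %d admissions; keeping the first",
                rev.patient_id, len(candidates),
            )
        adm = next((c for c in candidates if c.admission_id not in used_admissions), None)
        if adm is None or adm.admission_id in used_admissions:
            continue
        used_admissions.add(adm.admission_id)
        matched_rows.append(
            {
                "admission_id": adm.admission_id,
                "patient_id": rev.patient_id,
                "review_datetime": rev.review_datetime,
                "reviewer_curb65": rev.curb65,
                "reviewer_band": rev.severity,
            }
        )
    matched = pd.DataFrame(
        matched_rows,
        columns=["admission_id", "patient_id", "review_datetime", "reviewer_curb65", "reviewer_band"],
    )
    unmatched = [
        a for a in admissions["admission_id"].tolist() if a not in used_admissions
    ]
    return matched, unmatched


@dataclass
class SeverityCrossTab:
    """Reviewer-band x engine-band contingency table with tallies."""

    counts: np.ndarray  # 3x3, rows = reviewer band, cols = engine band
    n_reviewed: int = 0
    n_with_reviewer_score: int = 0
    n_not_reviewed: int = 0
    unreviewed_by_engine_band: np.ndarray = dc_field(
        default_factory=lambda: np.zeros(3, dtype=int)
    )

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        assert self.counts.shape == (3, 3)
        assert int(self.counts.sum()) == self.n_with_reviewer_score

    @property
    def agreement_count(self) -> int:
        return int(np.trace(self.counts))

    @property
    def agreement_fraction(self) -> float:
        n = int(self.counts.sum())
        return self.agreement_count / n if n else 0.0

    @property
    def engine_high_underscored(self) -> int:
        """Engine High, reviewer Low or Moderate."""
        return int(self.counts[0, 2] + self.counts[1, 2])

    @property
    def reviewer_above_engine(self) -> int:
        return int(sum(
            self.counts[r, e] for r in range(3) for e in range(3) if r > e
        ))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(SEVERITY_BANDS, name="reviewer"),
            columns=pd.Index(SEVERITY_BANDS, name="engine"),
        )


def crosstab_severity(pairs: Iterable[tuple[str, str]]) -> SeverityCrossTab:
    """Tally (reviewer band, engine band) pairs into a cross-tab."""
    counts = np.zeros((3, 3), dtype=int)
    n = 0
    for reviewer_band, engine_band in pairs:
        counts[band_index(reviewer_band), band_index(engine_band)] += 1
        n += 1
    return SeverityCrossTab(counts=counts, n_reviewed=n, n_with_reviewer_score=n)


@dataclass
class EvaluationReport:
    """Counts and percentages of the severity-comparison analysis."""

    n_admissions: int
    n_cap: int
    n_reviewed: int
    n_with_reviewer_score: int
    n_not_reviewed: int
    crosstab: SeverityCrossTab
    per_admission: pd.DataFrame

    @property
    def pct_reviewed(self) -> float:
        return 100.0 * self.n_reviewed / self.n_cap if self.n_cap else 0.0

    @property
    def agreement_fraction(self) -> float:
        return self.crosstab.agreement_fraction

    @property
    def disagreement_fraction(self) -> float:
        return 1.0 - self.agreement_fraction if self.n_with_reviewer_score else 0.0

    @property
    def pct_engine_high_underscored(self) -> float:
        n = self.n_with_reviewer_score
        return 100.0 * self.crosstab.engine_high_underscored / n if n else 0.0

    @property
    def unreviewed_moderate_or_high(self) -> int:
        return int(self.crosstab.unreviewed_by_engine_band[1:].sum())

    def summary_text(self) -> str:
        lines = [
            f"Admissions: {self.n_admissions} total, {self.n_cap} CAP",
            f"Reviewed: {self.n_reviewed} ({self.pct_reviewed:.1f}% of CAP), "
            f"{self.n_with_reviewer_score} with a comparable manual score",
            f"Severity agreement: {self.crosstab.agreement_count} "
            f"({100.0 * self.agreement_fraction:.1f}% of compared pairs)",
            f"Engine High but reviewer Low/Moderate: {self.crosstab.engine_high_underscored} "
            f"({self.pct_engine_high_underscored:.1f}%)",
            f"Reviewer above engine: {self.crosstab.reviewer_above_engine}",
            f"Not reviewed: {self.n_not_reviewed} "
            f"({100.0 * self.n_not_reviewed / self.n_cap if self.n_cap else 0.0:.1f}% of CAP); "
            f"moderate/high among them: {self.unreviewed_moderate_or_high}",
            "",
            "Reviewer band (rows) x engine band (columns):",
            self.crosstab.to_frame().to_string(),
        ]
        return "\n".join(lines)


def evaluate(
    store: ReplayStore,
    reviews: pd.DataFrame,
    plan: Plan | None = None,
    cap_prefixes: Sequence[str] = CAP_ICD_PREFIXES,
    tolerance_hours: float = 24.0,
) -> EvaluationReport:
    """Run the full pipeline: CAP identification, hourly replay, review
    linkage and the severity cross-tabulation."""
    plan = plan or build_cap_plan(cap_prefixes=cap_prefixes)
    engine = Engine(plan, message_schemas=cap_message_schemas())
    engine.run_replay(store)

    rows = []
    for row in store.admissions.itertuples(index=False):
        record = row._asdict()
        try:
            is_cap = diagnose_cap(record, cap_prefixes)
        except MissingField:
            is_cap = False
        journey = engine.journeys.get(row.admission_id)
        engine_band = None
        if journey is not None:
            try:
                engine_band = max_severity(journey)
            except NoSeverityRecorded:
                engine_band = None
        rows.append(
            {
                "admission_id": row.admission_id,
                "patient_id": record.get("patient_id"),
                "is_cap": is_cap,
                "engine_band": engine_band,
                "admitted_at": row.admitted_at,
                "discharged_at": row.discharged_at,
            }
        )
    table = pd.DataFrame(rows)
    cap_table = table[table["is_cap"]].copy()

    matched, unmatched_ids = link_reviews(
        cap_table, reviews, tolerance_hours=tolerance_hours
    ) if len(cap_table) else (pd.DataFrame(columns=["admission_id", "reviewer_band"]), [])

    merged = matched.merge(
        cap_table[["admission_id", "engine_band"]], on="admission_id", how="left"
    ) if len(matched) else matched
    pairs = [
        (r, e)
        for r, e in zip(merged.get("reviewer_band", []), merged.get("engine_band", []))
        if _present(r) and _present(e)
    ]
    crosstab = crosstab_severity(pairs)
    crosstab.n_reviewed = len(matched)

    unreviewed = cap_table[cap_table["admission_id"].isin(unmatched_ids)]
    by_band = np.zeros(3, dtype=int)
    for band in unreviewed["engine_band"]:
        if _present(band):
            by_band[band_index(band)] += 1
    crosstab.n_not_reviewed = len(unreviewed)
    crosstab.unreviewed_by_engine_band = by_band

    per_admission = cap_table.merge(
        matched[["admission_id", "reviewer_band", "reviewer_curb65"]],
        on="admission_id",
        how="left",
    ) if len(matched) else cap_table.assign(reviewer_band=None, reviewer_curb65=None)

    return EvaluationReport(
        n_admissions=len(table),
        n_cap=len(cap_table),
        n_reviewed=len(matched),
        n_with_reviewer_score=len(pairs),
        n_not_reviewed=len(unreviewed),
        crosstab=crosstab,
        per_admission=per_admission,
    )


def _present(v) -> bool:
    return v is not None and v == v


def _dt(value):
    if hasattr(value, "to_pydatetime"):
        return value.to_pydatetime()
    return value
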