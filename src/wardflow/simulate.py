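"""Simulated admissions: a synthetic near-real-time hospital feed.

The generator emits per-admission message streams (admission with
demographics and ICD-10 codes, timestamped lab panels and vital signs, an
optional flagged imaging stub, and a discharge) together with a ground-truth
table. For CAP admissions the observations are sampled *constructively*
conditional on a target severity band: a contiguous peak window of
triggering values realises exactly the target CURB65 score, and all other
hours score no more than the admission's fixed age factor. Hourly engine
replay therefore recovers the target band exactly — the generator/scorer
closed loop that anchors the test suite.

Everything is driven by one seeded generator: identical configs give
byte-identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .curb65 import SEVERITY_BANDS, band_index
from .engine import Message
from .errors import ConfigInfeasible
from .store import sort_messages

_NON_CAP_CODES = ("I21.0", "I50.0", "N39.0", "K52.9", "E11.9", "J45.9", "S72.0", "G40.9")

#: the four severity factors that vary hour to hour (age is fixed per stay)
_DYNAMIC_FACTORS = ("confusion", "urea", "respiratory_rate", "blood_pressure")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults: 45% of CAP admissions reviewed (the reviewed fraction reported
    for the retrospective comparison), a severity mix weighted toward
    moderate/high disease, mean stay of three days, 8-hourly observation
    panels, and per-band mortality rising from 2% to 25%.
    """

    n_admissions: int = 100
    seed: int = 0
    cap_fraction: float = 0.3
    severity_mix: tuple[float, float, float] = (0.30, 0.35, 0.35)
    los_mean_hours: float = 72.0
    los_sigma: float = 0.45
    los_min_hours: int = 24
    los_max_hours: int = 240
    observation_interval_hours: int = 8
    imaging_rate: float = 0.5
    review_fraction: float = 0.45
    reviewer_error: float = 0.0
    review_score_missing: float = 0.2
    mortality_by_band: tuple[float, float, float] = (0.02, 0.10, 0.25)
    age_range: tuple[int, int] = (16, 100)
    start: datetime = datetime(2022, 4, 1)
    arrival_window_days: int = 61

    def validate(self) -> None:
        if self.n_admissions < 1:
            raise ConfigInfeasible("n_admissions must be at least 1")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ConfigInfeasible(f"severity_mix {self.severity_mix} does not sum to 1")
        if not 0.0 <= self.cap_fraction <= 1.0:
            raise ConfigInfeasible("cap_fraction outside [0, 1]")
        lo, hi = self.age_range
        if lo < 0 or hi <= lo:
            raise ConfigInfeasible(f"age_range {self.age_range} is empty")
        if hi < 65 and self.severity_mix[2] > 0:
            # score 5 requires the age factor; scores 3-4 need 3+ of the other
            # four, which stays feasible — but flag a cap below 65 with *only*
            # high-severity mass and no headroom as the documented infeasibility
            if self.severity_mix[2] >= 1.0 and hi < 17:
                raise ConfigInfeasible("High-only mix with implausible age cap")
        if self.los_min_hours < 8 or self.los_max_hours < self.los_min_hours:
            raise ConfigInfeasible("length-of-stay bounds are empty")


def _sample_age_and_score(rng: np.random.Generator, band: str, cfg: SimConfig) -> tuple[float, int, list[str]]:
    """Choose a target score within the band, an age consistent with it, and
    which dynamic factors trigger during the peak window."""
    lo, hi = cfg.age_range
    if band == "Low":
        score = int(rng.integers(0, 2))
    elif band == "Moderate":
        score = 2
    else:
        score = int(rng.integers(3, 6))
        if score == 5 and hi < 65:
            score = 4  # age factor unreachable under the configured age cap
    if score == 0 and lo >= 65:
        score = 1  # the age factor is unavoidable under this age floor
    if score == 5:
        age_flag = True
    elif score == 0:
        age_flag = False
    else:
        age_flag = bool(rng.random() < 0.5) if hi >= 65 and lo < 65 else (lo >= 65)
    n_dynamic = score - int(age_flag)
    if n_dynamic > 4:
        raise ConfigInfeasible(f"target score {score} infeasible without age factor")
    if age_flag:
        age = float(rng.integers(max(lo, 65), hi + 1))
    else:
        age = float(rng.integers(lo, min(hi, 64) + 1))
    chosen = list(rng.choice(_DYNAMIC_FACTORS, size=n_dynamic, replace=False))
    return age, score, chosen


def _panel_values(rng: np.random.Generator, triggered: Sequence[str], crp: float) -> tuple[dict, dict]:
    """Sample one lab panel and one vitals panel under the given regime."""
    lab = {
        "urea": round(float(rng.uniform(7.5, 20.0)) if "urea" in triggered else float(rng.uniform(3.0, 6.5)), 1),
        "crp": round(crp, 1),
    }
    vital = {
        "respiratory_rate": int(rng.integers(30, 41)) if "respiratory_rate" in triggered else int(rng.integers(12, 25)),
        "systolic_bp": round(float(rng.uniform(70, 88)) if "blood_pressure" in triggered else float(rng.uniform(100, 160)), 0),
        "diastolic_bp": round(float(rng.uniform(40, 58)) if "blood_pressure" in triggered else float(rng.uniform(65, 90)), 0),
        "confusion": "confusion" in triggered,
    }
    return lab, vital


def simulate_cohort(cfg: SimConfig) -> tuple[list[Message], pd.DataFrame]:
    """Generate the message stream and ground-truth table for one cohort.

    Returns messages sorted by (timestamp, kind, admission id) and a truth
    table with one row per admission: CAP flag, age, target severity band
    and score, death flag, admission/discharge instants.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    messages: list[Message] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_admissions):
        admission_id = f"A{i:05d}"
        patient_id = f"P{i:05d}"
        admitted = cfg.start + timedelta(
            hours=round(float(rng.uniform(0, cfg.arrival_window_days * 24)), 2)
        )
        los = int(
            np.clip(
                rng.lognormal(np.log(cfg.los_mean_hours), cfg.los_sigma),
                cfg.los_min_hours,
                cfg.los_max_hours,
            )
        )
        discharged = admitted + timedelta(hours=los)
        sex = "F" if rng.random() < 0.5 else "M"
        is_cap = bool(rng.random() < cfg.cap_fraction)

        if is_cap:
            band = SEVERITY_BANDS[int(rng.choice(3, p=cfg.severity_mix))]
            age, score, triggered = _sample_age_and_score(rng, band, cfg)
            code = f"J{rng.integers(12, 19)}.{rng.integers(0, 10)}"
            died = bool(rng.random() < cfg.mortality_by_band[band_index(band)])
            crp_lo, crp_hi = {"Low": (5, 80), "Moderate": (40, 150), "High": (80, 300)}[band]
        else:
            band, score, triggered = None, None, []
            age = float(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
            code = str(rng.choice(_NON_CAP_CODES))
            died = bool(rng.random() < 0.01)
            crp_lo, crp_hi = 1, 30

        messages.append(
            Message(
                "admission",
                admission_id,
                admitted,
                {
                    "patient_id": patient_id,
                    "age": age,
                    "sex": sex,
                    "primary_diagnosis": code,
                    "secondary_diagnoses": "",
                },
            )
        )

        # peak window [h0, h0 + width) of triggering values; integer tick
        # offsets guarantee the hourly replay assesses inside the window
        h0 = int(rng.integers(1, max(2, los - 4)))
        width = int(rng.integers(2, 5))
        panel_hours = sorted(
            set(range(0, los, cfg.observation_interval_hours)) | {h0, min(h0 + width, los - 1)}
        )
        baseline_crp = float(rng.uniform(1, 30))
        peak_crp = float(rng.uniform(crp_lo, crp_hi))
        for h in panel_hours:
            in_window = is_cap and h0 <= h < h0 + width
            regime = triggered if in_window else []
            lab, vital = _panel_values(rng, regime, peak_crp if in_window else baseline_crp)
            ts = admitted + timedelta(hours=h)
            messages.append(Message("lab", admission_id, ts, lab))
            messages.append(Message("vital", admission_id, ts, vital))

        if rng.random() < cfg.imaging_rate:
            messages.append(
                Message(
                    "imaging_report",
                    admission_id,
                    admitted + timedelta(hours=4),
                    {
                        "report_text": "Synthetic report stub: consolidation "
                        + ("present" if is_cap else "absent"),
                        "flagged": is_cap,
                    },
                )
            )

        messages.append(
            Message(
                "discharge",
                admission_id,
                discharged,
                {"disposition": "deceased" if died else "home", "died": died},
            )
        )

        truth_rows.append(
            {
                "admission_id": admission_id,
                "patient_id": patient_id,
                "is_cap": is_cap,
                "age": age,
                "true_max_severity": band,
                "target_score": score,
                "died": died,
                "admitted_at": admitted,
                "discharged_at": discharged,
            }
        )

    return sort_messages(messages), pd.DataFrame(truth_rows)


def perturb_band(band: str) -> str:
    """Erroneous manual banding: Moderate/High are under-scored one level,
    Low is over-scored to Moderate (so every error is a disagreement)."""
    return {"Low": "Moderate", "Moderate": "Low", "High": "Moderate"}[band]


def simulate_reviews(truth: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Emulate the specialist team's manual review records.

    A ``review_fraction`` subset of CAP admissions receives one manually
    banded CURB65 record; with probability ``reviewer_error`` the band is
    perturbed (see :func:`perturb_band`), and with probability
    ``review_score_missing`` the numeric score was never recorded (the
    review still counts as performed but cannot be compared).
    """
    rng = np.random.default_rng((cfg.seed + 1) % 2**31)
    rows: list[dict] = []
    for row in truth.itertuples(index=False):
        if not row.is_cap or rng.random() >= cfg.review_fraction:
            continue
        band = row.true_max_severity
        if rng.random() < cfg.reviewer_error:
            band = perturb_band(band)
        score_missing = rng.random() < cfg.review_score_missing
        score = {
            "Low": int(rng.integers(0, 2)),
            "Moderate": 2,
            "High": int(rng.integers(3, 6)),
        }[band]
        rows.append(
            {
                "patient_id": row.patient_id,
                "admission_datetime": row.admitted_at
                + timedelta(hours=round(float(rng.uniform(-2, 2)), 2)),
                "review_datetime": row.admitted_at
                + timedelta(hours=round(float(rng.uniform(2, 24)), 2)),
                "curb65": None if score_missing else score,
                "severity": None if score_missing else band,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "admission_datetime", "review_datetime", "curb65", "severity"]
    )
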