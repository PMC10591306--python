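"""Demonstration mortality classifier trained on synthetic cohorts.

This is an illustrative gradient-boosted model over the simulated schema —
it stands in for a locally trained in-hospital/30-day mortality model and
exists so that the predictive-algorithm machinery (encoder, threshold,
metadata, explanations, serialization) can be exercised end to end. Its
features are per-admission aggregates of the simulated observations: age,
worst urea, worst respiratory rate, lowest systolic pressure, any recorded
confusion, and peak CRP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .algorithms import FeatureEncoder, PredictiveAlgorithm
from .capplan import mortality_schema
from .errors import DegenerateLabels
from .metadata import compute_metadata
from .store import ReplayStore

FEATURES = ("age", "urea", "respiratory_rate", "systolic_bp", "confusion", "crp")


def mortality_training_table(store: ReplayStore, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-CAP-admission feature aggregates + death label from a cohort."""
    obs = store.observations
    cap_ids = set(truth.loc[truth["is_cap"], "admission_id"])
    rows = []
    by_adm = {aid: grp for aid, grp in obs.groupby("admission_id", sort=False)} if len(obs) else {}
    for row in truth.itertuples(index=False):
        if row.admission_id not in cap_ids:
            continue
        grp = by_adm.get(row.admission_id)
        series: dict[str, list] = {}
        if grp is not None:
            for f, v in zip(grp["field"], grp["value"]):
                series.setdefault(f, []).append(v)

        def _agg(name, fn, default):
            vals = [float(v) for v in series.get(name, [])]
            return fn(vals) if vals else default

        rows.append(
            {
                "admission_id": row.admission_id,
                "age": float(row.age),
                "urea": _agg("urea", max, 5.0),
                "respiratory_rate": int(_agg("respiratory_rate", max, 16)),
                "systolic_bp": _agg("systolic_bp", min, 120.0),
                "confusion": any(
                    v in (True, "True", "true", 1, "1") for v in series.get("confusion", [])
                ),
                "crp": _agg("crp", max, 5.0),
                "died": bool(row.died),
            }
        )
    return pd.DataFrame(rows)


def train_mortality_model(
    table: pd.DataFrame, seed: int = 0, threshold: float = 0.5, holdout_fraction: float = 0.25
) -> PredictiveAlgorithm:
    """Fit the demonstration classifier and wrap it as a plan algorithm.

    Metadata (AUC, sensitivity, specificity, accuracy, PPV) is computed on a
    held-out fraction of the table and cached on the returned algorithm.
    """
    y = table["died"].astype(int).to_numpy()
    if len(set(y.tolist())) < 2:
        raise DegenerateLabels("training table contains a single outcome class")
    X = table[list(FEATURES)].astype(float).to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(table))
    n_hold = max(1, int(len(table) * holdout_fraction))
    hold, fit = idx[:n_hold], idx[n_hold:]
    if len(set(y[fit].tolist())) < 2 or len(set(y[hold].tolist())) < 2:
        hold, fit = idx, idx  # tiny tables: metadata on the training data

    model = XGBClassifier(
        n_estimators=60,
        max_depth=3,
        learning_rate=0.2,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )
    model.fit(X[fit], y[fit])

    scales = X[fit].std(axis=0)
    algo = PredictiveAlgorithm(
        name="cap_mortality",
        schema=mortality_schema(),
        encoder=FeatureEncoder(features=FEATURES, scales=tuple(np.where(scales > 0, scales, 1.0))),
        model=model,
        threshold=threshold,
    )
    records = table.iloc[hold][list(FEATURES)].to_dict("records")
    compute_metadata(algo, records, y[hold], computed_on="synthetic-holdout")
    return algo
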