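"""Model metadata: cached performance metrics for embedded classifiers.

Metrics are computed once on labelled data (discrimination via ROC AUC,
plus threshold-dependent sensitivity, specificity, accuracy and positive
predictive value) and cached on the algorithm so that rendered panels never
need the model at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score

from .algorithms import PredictiveAlgorithm
from .errors import DegenerateLabels, InvalidValue
from .schema import validate_record


@dataclass
class ModelMetadata:
    """Performance indicators of a binary classifier, each in [0, 1]."""

    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    positive_predictive_value: float
    computed_on: str = ""
    cached: bool = False

    METRICS = ("auc", "sensitivity", "specificity", "accuracy", "positive_predictive_value")

    def __post_init__(self):
        for m in self.METRICS:
            v = getattr(self, m)
            if not 0.0 <= float(v) <= 1.0:
                raise InvalidValue(m, f"{v} outside [0, 1]")
            setattr(self, m, float(v))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelMetadata":
        return cls(**dict(d))


def _ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den else 0.0


def metadata_from_counts(
    tp: int, fn: int, tn: int, fp: int, auc: float = 0.0, computed_on: str = ""
) -> ModelMetadata:
    """Metadata from a confusion table: sens = TP/(TP+FN), spec = TN/(TN+FP),
    acc = (TP+TN)/n, PPV = TP/(TP+FP)."""
    return ModelMetadata(
        auc=auc,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + fn + tn + fp),
        positive_predictive_value=_ratio(tp, tp + fp),
        computed_on=computed_on,
    )


def compute_metadata(
    algo: PredictiveAlgorithm,
    records: Sequence[Mapping[str, Any]],
    labels: Sequence[int],
    computed_on: str = "",
) -> ModelMetadata:
    """Score ``records``, threshold at ``algo.threshold`` and cache metrics.

    Raises :class:`DegenerateLabels` when only one class is present (AUC is
    undefined). The result is stored on ``algo.metadata`` with
    ``cached=True``; recomputation on identical data reproduces it.
    """
    if len(records) == 0:
        raise DegenerateLabels("no labelled data supplied")
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise DegenerateLabels("labelled data contains a single class")
    algo.check_dimensions()
    X = np.vstack([algo.encoder.encode(validate_record(algo.schema, r)) for r in records])
    probs = np.asarray(algo.model.predict_proba(X))[:, 1]
    preds = (probs >= algo.threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y, preds, labels=[0, 1]).ravel()
    meta = metadata_from_counts(
        tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp),
        auc=float(roc_auc_score(y, probs)),
        computed_on=computed_on,
    )
    meta.cached = True
    algo.metadata = meta
    return meta
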