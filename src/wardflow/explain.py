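"""Local explanations via a weighted linear surrogate.

For one record, the classifier is probed on random perturbations around the
record (Gaussian noise scaled by per-feature dispersions for numeric
features, uniform resampling for booleans). A ridge-regularised linear
model is fitted to the probed probabilities with exponential distance
weights; its coefficients are the signed per-feature contributions. The
procedure is deterministic given the seed.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
from sklearn.linear_model import Ridge

from .algorithms import PredictiveAlgorithm
from .errors import InsufficientSamples
from .schema import validate_record


def explain_local(
    algo: PredictiveAlgorithm,
    record: Mapping[str, Any],
    n_perturbations: int = 2000,
    seed: int = 0,
    kernel_width: float | None = None,
    ridge_alpha: float = 1.0,
) -> dict[str, float]:
    """Signed per-feature contributions for one prediction.

    Parameters
    ----------
    n_perturbations
        Number of perturbed samples; must be at least the feature count.
    kernel_width
        Width of the exponential distance kernel on the standardised
        perturbation scale; defaults to ``0.75 * sqrt(n_features)``.

    Returns a mapping feature name -> surrogate coefficient (slope of the
    local linear fit in raw feature units).
    """
    vr = validate_record(algo.schema, record)
    x = algo.encoder.encode(vr)
    d = x.size
    if n_perturbations < d:
        raise InsufficientSamples(
            f"{n_perturbations} perturbations for {d} features"
        )
    scales = np.asarray(algo.encoder.scales if algo.encoder.scales else np.ones(d), dtype=float)
    scales = np.where(scales > 0, scales, 1.0)
    kinds = {f.name: f.kind for f in algo.schema.fields}

    rng = np.random.default_rng(seed)
    Z = np.tile(x, (n_perturbations, 1))
    for j, name in enumerate(algo.encoder.features):
        if kinds.get(name) == "boolean":
            Z[:, j] = rng.integers(0, 2, size=n_perturbations).astype(float)
        else:
            Z[:, j] = x[j] + rng.normal(0.0, scales[j], size=n_perturbations)

    dist = np.sqrt((((Z - x) / scales) ** 2).sum(axis=1))
    width = kernel_width if kernel_width is not None else 0.75 * np.sqrt(d)
    weights = np.exp(-(dist**2) / width**2)

    probs = np.asarray(algo.model.predict_proba(Z))[:, 1]
    surrogate = Ridge(alpha=ridge_alpha)
    surrogate.fit(Z, probs, sample_weight=weights)
    return {name: float(c) for name, c in zip(algo.encoder.features, surrogate.coef_)}
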