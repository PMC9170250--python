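"""Forced-fusion (maximum-likelihood cue combination) predictions.

When two cues are mandatorily integrated, the combined estimate is the
reliability-weighted average of the unisensory estimates, so the combined
discrimination threshold and the visual weight follow in closed form from
the unisensory thresholds:

    sigma_com = sqrt(sigma_a^2 sigma_v^2 / (sigma_a^2 + sigma_v^2))
    w_v       = (1/sigma_v^2) / (1/sigma_v^2 + 1/sigma_a^2)

The measured visual weight is read off the shift of cue-conflict
psychometric functions plotted against the mean stimulus location: with
cues straddling the mean at +- delta/2, the fused percept's PSE sits at
(2 w_v - 1) delta / 2, so the PSE difference between the +delta and -delta
conflict conditions identifies w_v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FusionPrediction",
    "predict_combined_threshold",
    "predict_visual_weight",
    "measured_visual_weight",
    "fusion_prediction",
]


@dataclass
class FusionPrediction:
    sigma_com: float
    w_v: float
    w_a: float
    clipped: bool = False


def _check_positive(sigma_a, sigma_v):
    if sigma_a <= 0 or sigma_v <= 0:
        raise ValueError("unisensory thresholds must be positive")


def predict_combined_threshold(sigma_a: float, sigma_v: float) -> float:
    """Optimal combined threshold from the two unisensory thresholds."""
    _check_positive(sigma_a, sigma_v)
    return float(np.sqrt(sigma_a**2 * sigma_v**2 / (sigma_a**2 + sigma_v**2)))


def predict_visual_weight(sigma_a: float, sigma_v: float) -> float:
    """Reliability-weighted visual weight; auditory weight is 1 - w_v."""
    _check_positive(sigma_a, sigma_v)
    return float((1.0 / sigma_v**2) / (1.0 / sigma_v**2 + 1.0 / sigma_a**2))


def measured_visual_weight(mu_plus: float, mu_minus: float, delta: float):
    """Visual weight implied by measured conflict-condition PSEs.

    ``mu_plus``/``mu_minus`` are the PSEs (vs mean stimulus location) at
    disparity +delta and -delta.  Returns ``(w_v, clipped)``: the raw
    estimate clipped to [0, 1] and a flag for whether clipping occurred.
    """
    if delta == 0:
        raise ValueError("measured weight is undefined at zero disparity")
    w = 0.5 + (mu_plus - mu_minus) / (2.0 * delta)
    clipped = not 0.0 <= w <= 1.0
    return float(np.clip(w, 0.0, 1.0)), clipped


def fusion_prediction(sigma_a: float, sigma_v: float) -> FusionPrediction:
    w_v = predict_visual_weight(sigma_a, sigma_v)
    return FusionPrediction(
        sigma_com=predict_combined_threshold(sigma_a, sigma_v), w_v=w_v, w_a=1.0 - w_v
    )
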