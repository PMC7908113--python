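"""Post-transplant utility of a transplanted waitlist patient.

The utility realized by a patient who joined the waitlist with initial
dialysis survivability ``h0`` (years), waited ``w`` years, and received a
kidney of quality ``q_t`` factorizes as

    U(q_t, h0, w) = B(h0, q_t) * D(h0, w),

where the benefit is a logistic function of kidney quality,

    B(h0, q_t) = m(h0) / (1 + exp(-beta * (q_t - alpha))),

scaled by ``m(h0)``, the life-years gained by a patient of health ``h0``
from a perfect kidney (``q_t = 1``) with no wait, and the waiting-time
deterioration factor is

    D(h0, w) = (1 - w / h0) ** gamma,

equal to 1 at ``w = 0`` and 0 when the patient runs out of time
(``w = h0``).  ``gamma = 1`` gives linear decline, ``gamma < 1``
accelerating decline.

The scale function ``m`` is not identified without post-transplant
survival data; the shipped default is affine, ``m(h0) = m0 + m1 * h0``
with ``m0 = 10``, ``m1 = 5``, a calibration chosen so ``m(1) = 15``
life-years puts simulated utilities on a clinically plausible scale.
Every threshold-optimization result is invariant to rescaling ``m`` at
fixed ``h0``, so this calibration affects reported utilities only, never
optimal policies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UtilityParameters", "benefit", "deterioration", "utility"]


@dataclass(frozen=True)
class UtilityParameters:
    """Parameters (alpha, beta, gamma) of the utility model plus the
    affine benefit-scale m(h0) = m0 + m1*h0.

    alpha: logistic midpoint on the quality axis (default 0.4).
    beta: logistic steepness (default 8).
    gamma: waiting-deterioration exponent (default 0.5).
    """

    alpha: float = 0.4
    beta: float = 8.0
    gamma: float = 0.5
    m0: float = 10.0
    m1: float = 5.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.m0 < 0 or self.m1 < 0:
            raise ValueError("m0 and m1 must be non-negative (m increasing, positive)")
        if self.m0 == 0 and self.m1 == 0:
            raise ValueError("m(h0) must be positive")

    def m(self, h0):
        """Benefit scale: life-years from a perfect, immediate transplant."""
        return self.m0 + self.m1 * np.asarray(h0, dtype=float)


def _check_quality(q_t) -> np.ndarray:
    q_t = np.asarray(q_t, dtype=float)
    if np.any(q_t < 0) or np.any(q_t > 1):
        raise ValueError("q_t must lie in [0, 1]")
    return q_t


def benefit(h0, q_t, params: UtilityParameters):
    """Logistic benefit B(h0, q_t) = m(h0) / (1 + exp(-beta (q_t - alpha)))."""
    h0 = np.asarray(h0, dtype=float)
    if np.any(h0 <= 0):
        raise ValueError("h0 must be positive")
    q_t = _check_quality(q_t)
    out = params.m(h0) / (1.0 + np.exp(-params.beta * (q_t - params.alpha)))
    return float(out) if out.ndim == 0 else out


def deterioration(h0, w, gamma: float):
    """Waiting deterioration D = (1 - w/h0)**gamma, in [0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    h0 = np.asarray(h0, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(h0 <= 0):
        raise ValueError("h0 must be positive")
    if np.any(w < 0) or np.any(w > h0):
        raise ValueError("w must lie in [0, h0]")
    out = (1.0 - w / h0) ** gamma
    return float(out) if out.ndim == 0 else out


def utility(h0, q_t, w, params: UtilityParameters):
    """Post-transplant utility U = B(h0, q_t) * D(h0, w), in life-years.

    Zero when the patient's time runs out (w = h0); patients who are
    never transplanted contribute 0 to downstream utility averages.
    """
    return benefit(h0, q_t, params) * deterioration(h0, w, params.gamma)
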