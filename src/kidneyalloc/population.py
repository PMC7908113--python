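"""Patient and kidney population samplers and arrival processes.

One blood-type queue is fed by two independent homogeneous Poisson
streams: patients joining the waitlist at rate ``lambda`` per year and
compatible deceased-donor kidneys arriving at rate ``mu`` per year
(``mu < lambda`` under the current organ shortage).

A patient joins with an unobservable initial health ``h0`` — the years
she can survive on dialysis — drawn from Weibull(scale=a, shape=b), and
with a personal kidney-quality acceptance threshold ``k ~ Unif(0, 1)``.
Healthier patients can afford to wait for better organs, so (h0, k) are
positively rank-correlated; the dependence is induced by a Gaussian
copula whose Pearson parameter ``r = 2 sin(pi rho_s / 6)`` reproduces a
target Spearman rank correlation ``rho_s`` exactly under the monotone
marginal transforms.

Kidney quality at procurement is ``q0 = 1 - KDPI ~ Unif(0, 1)`` (KDPI is
percentile-scaled, hence uniform by construction).  For a blood-type-A
queue, arriving kidneys come from type-A and type-O donors in a fixed
94%/6% split; donor type is bookkeeping only and has no effect on the
single-queue dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special

__all__ = [
    "PopulationParameters",
    "PatientDraw",
    "spearman_to_pearson",
    "sample_patient",
    "sample_patients",
    "sample_kidney_quality",
    "sample_donor_types",
    "generate_arrivals",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson parameter of a bivariate Gaussian copula achieving Spearman
    rank correlation ``rho_s``: r = 2 sin(pi * rho_s / 6)."""
    if not -1.0 < rho_s < 1.0:
        raise ValueError(f"Spearman rho must lie in (-1, 1), got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class PopulationParameters:
    """Supply/demand rates and sampling distributions of one queue.

    Attributes
    ----------
    lambda_patients:
        Patient arrival rate (patients/year).
    mu_kidneys:
        Kidney arrival rate (kidneys/year).
    weibull_scale, weibull_shape:
        Scale a (years) and shape b of the initial-health distribution
        H0 ~ Weibull(a, b).  Defaults a=8, b=2 give mean ~7.09 years
        and ~89.5% of patients below 12 years.
    spearman_rho:
        Target Spearman rank correlation between h0 and the acceptance
        threshold k, in (-1, 1).  Default 0.2.
    supply_split:
        Donor-blood-type composition of the kidney stream (fractions
        summing to 1); default 94% type A, 6% type O for the A-queue.
    """

    lambda_patients: float
    mu_kidneys: float
    weibull_scale: float = 8.0
    weibull_shape: float = 2.0
    spearman_rho: float = 0.2
    supply_split: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.94, "O": 0.06}
    )

    def __post_init__(self) -> None:
        if self.lambda_patients <= 0:
            raise ValueError("lambda_patients must be positive")
        if self.mu_kidneys < 0:
            raise ValueError("mu_kidneys must be non-negative")
        if self.weibull_scale <= 0 or self.weibull_shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        if not -1.0 < self.spearman_rho < 1.0:
            raise ValueError("spearman_rho must lie in (-1, 1)")
        total = sum(self.supply_split.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"supply_split fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.supply_split.values()):
            raise ValueError("supply_split fractions must be non-negative")

    @property
    def mean_h0(self) -> float:
        """Analytic mean of H0: a * Gamma(1 + 1/b)."""
        return self.weibull_scale * math.gamma(1.0 + 1.0 / self.weibull_shape)


@dataclass(frozen=True)
class PatientDraw:
    """One sampled patient: initial health h0 (years) and threshold k."""

    h0: float
    k: float


def sample_patients(
    params: PopulationParameters, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` correlated (h0, k) pairs.

    Marginals: h0 ~ Weibull(scale=a, shape=b), k ~ Unif(0, 1).  The
    sample Spearman correlation converges to ``params.spearman_rho``.

    Returns (h0, k) as float arrays of length ``n``.
    """
    r = spearman_to_pearson(params.spearman_rho)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    u1 = special.ndtr(z1)
    k = special.ndtr(z2)
    # Weibull quantile transform; clip away u == 1 to avoid inf
    u1 = np.clip(u1, 1e-16, 1.0 - 1e-16)
    h0 = params.weibull_scale * (-np.log1p(-u1)) ** (1.0 / params.weibull_shape)
    return h0, k


def sample_patient(params: PopulationParameters, rng: np.random.Generator) -> PatientDraw:
    """Draw a single patient (see :func:`sample_patients`)."""
    h0, k = sample_patients(params, 1, rng)
    return PatientDraw(h0=float(h0[0]), k=float(k[0]))


def sample_kidney_quality(rng: np.random.Generator, n: int | None = None):
    """Initial kidney quality q0 = 1 - KDPI ~ Unif(0, 1); 1 is best."""
    if n is None:
        return float(rng.random())
    return rng.random(n)


def sample_donor_types(
    params: PopulationParameters, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Donor blood types for ``n`` kidneys, drawn from the supply split."""
    types = list(params.supply_split.keys())
    probs = np.array([params.supply_split[t] for t in types], dtype=float)
    return rng.choice(np.array(types, dtype=object), size=n, p=probs)


def generate_arrivals(
    rate: float, horizon: float, rng: np.random.Generator, start: float = 0.0
) -> np.ndarray:
    """Event times of a homogeneous Poisson process on (start, start+horizon].

    Inter-arrival gaps are i.i.d. Exponential(rate); the returned times
    are strictly increasing and the count is Poisson(rate * horizon).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if rate == 0:
        return np.empty(0)
    times: list[np.ndarray] = []
    t = start
    end = start + horizon
    # draw in chunks sized to overshoot the horizon with high probability
    chunk = max(16, int(rate * horizon + 6.0 * math.sqrt(rate * horizon) + 10))
    while t <= end:
        gaps = rng.exponential(1.0 / rate, size=chunk)
        arr = t + np.cumsum(gaps)
        times.append(arr)
        t = arr[-1]
    out = np.concatenate(times)
    return out[out <= end]
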