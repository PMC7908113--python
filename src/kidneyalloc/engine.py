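"""Discrete-event simulation of one blood-type kidney waitlist.

The queue is first-come-first-served by waitlist arrival time.  Patients
arrive by a Poisson process, wait, and leave either by transplant or by
removal when their waiting time ``w`` reaches their dialysis
survivability ``h0`` (death or becoming too sick to transplant).
Kidneys arrive by an independent Poisson process and are offered to the
waitlist in groups of ``g`` patients per one-hour round, losing a
fraction ``delta`` of quality per unsuccessful round.  A patient whose
threshold ``k`` does not exceed the kidney's current quality ``q_t``
will accept; an acceptable offer actually converts to a transplant with
probability ``p_transplant`` (patient availability times transplant
center readiness).  A kidney that exhausts the waitlist or exceeds the
cold-ischemia cap is discarded.

Offer rounds (hours) are instantaneous on the patient-health clock
(years); this separation of timescales is exact for the rates modeled
here.  Within a round, one uniform variate is consumed per
threshold-eligible patient in position order and the first draw below
``p_transplant`` takes the organ; this fixed consumption order makes
event logs bit-reproducible under a given seed.

The queue length stabilizes at the census where transplant plus removal
throughput balances patient arrivals; metrics are reported over a
post-warmup window only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .population import (
    PopulationParameters,
    generate_arrivals,
    sample_donor_types,
    sample_kidney_quality,
    sample_patients,
)
from .quality import DecayParameters
from .utility import UtilityParameters, utility

__all__ = [
    "EngineConfig",
    "TargetPatient",
    "PatientRecord",
    "KidneyRecord",
    "SimulationResult",
    "SimulationMetrics",
    "offer_kidney",
    "run_simulation",
    "compute_metrics",
]

MONTHS_PER_YEAR = 12.0

# patient status codes used in the log
WAITING, TRANSPLANTED, REMOVED = "waiting", "transplanted", "removed"


@dataclass(frozen=True)
class EngineConfig:
    """Configuration of one simulation run.

    g: offer group size (patients considered per round).
    p_patient_factors / p_center_factors: the two factors whose product
        is the probability that an acceptable offer converts to a
        transplant; defaults multiply to 0.8.
    decay: cold-ischemia decay law (delta, round duration, CIT cap).
    horizon_months / warmup_months: total simulated time and the burn-in
        discarded before computing metrics.
    initial_waitlist_size: patients pre-loaded at t=0 with back-dated
        arrivals (see :func:`run_simulation`).
    """

    g: int = 5
    p_patient_factors: float = 0.8
    p_center_factors: float = 1.0
    decay: DecayParameters = field(default_factory=DecayParameters)
    horizon_months: float = 500.0
    warmup_months: float = 200.0
    initial_waitlist_size: int = 1000

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("g must be >= 1")
        p = self.p_transplant
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p_transplant must lie in (0, 1], got {p}")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if not 0.0 <= self.warmup_months < self.horizon_months:
            raise ValueError("need 0 <= warmup_months < horizon_months")
        if self.initial_waitlist_size < 0:
            raise ValueError("initial_waitlist_size must be >= 0")

    @property
    def p_transplant(self) -> float:
        return self.p_patient_factors * self.p_center_factors


@dataclass(frozen=True)
class TargetPatient:
    """A tagged patient inserted into the initial waitlist at a fixed
    position with a fixed acceptance threshold (used by the threshold
    sweep).  The simulation may stop as soon as this patient departs."""

    h0: float
    k: float
    position: int  # 1-based initial waitlist position

    def __post_init__(self) -> None:
        if self.h0 <= 0:
            raise ValueError("target h0 must be positive")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("target k must lie in [0, 1]")
        if self.position < 1:
            raise ValueError("target position must be >= 1")


@dataclass(frozen=True)
class PatientRecord:
    """One waitlisted patient, as logged."""

    id: int
    arrival_time: float
    h0: float
    k: float
    status: Literal["waiting", "transplanted", "removed"]
    departure_time: float  # nan while waiting


@dataclass(frozen=True)
class KidneyRecord:
    """One procured kidney, as logged."""

    id: int
    arrival_time: float
    q0: float
    donor_blood_type: str
    outcome: Literal["transplanted", "discarded"]
    accepting_position: int | None  # 1-based waitlist index
    accepting_patient: int | None
    cit_at_placement: float  # hours (rounds * round_duration)
    quality_at_placement: float


def offer_kidney(
    q0: float,
    thresholds: np.ndarray,
    config: EngineConfig,
    rng: np.random.Generator,
) -> tuple[str, int | None, int, float]:
    """Offer one fresh kidney down an ordered waitlist.

    ``thresholds`` are the acceptance thresholds of the waiting patients
    in position order.  Groups of ``config.g`` are evaluated per round;
    after each unsuccessful round the quality decays by ``delta`` and
    one hour of CIT accrues.  Returns
    ``(outcome, accepting_index, rounds_used, quality_at_resolution)``
    where ``accepting_index`` is the 0-based waitlist position (None on
    discard) and ``rounds_used`` counts rounds including the accepting
    one.  An empty waitlist yields an immediate discard with 0 rounds.
    """
    n = len(thresholds)
    decay = config.decay
    q = q0
    if n == 0:
        return "discarded", None, 0, q
    g = config.g
    p = config.p_transplant
    one_minus_delta = 1.0 - decay.delta
    max_rounds = decay.max_rounds
    start = 0
    r = 0
    while start < n and r < max_rounds:
        group = thresholds[start : start + g]
        eligible = np.flatnonzero(group <= q)
        if eligible.size:
            u = rng.random(eligible.size)
            hits = np.flatnonzero(u < p)
            if hits.size:
                return "transplanted", start + int(eligible[hits[0]]), r + 1, q
        start += g
        r += 1
        q *= one_minus_delta
    return "discarded", None, r, q


def _initial_waitlist(
    pop: PopulationParameters,
    config: EngineConfig,
    rng: np.random.Generator,
    target: TargetPatient | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Build (arrival, h0, k) arrays for the t=0 waitlist, in position
    order, plus the index of the target patient (-1 if none).

    Without a target: ``initial_waitlist_size`` patients with fresh
    (h0, k) draws and arrivals back-dated uniformly over one mean
    residence time (census / lambda, by Little's law).

    With a target: exactly ``position - 1`` competitors ahead of the
    target, back-dated by vanishing offsets that only fix the order; the
    target arrives at t=0 so its waiting-time clock starts at 0.
    """
    if target is not None:
        n_ahead = target.position - 1
        h0, k = sample_patients(pop, n_ahead, rng)
        # offsets fix FCFS order only; competitors' clocks effectively start at 0
        arrivals = -1e-9 * np.arange(n_ahead, 0, -1)
        arrivals = np.append(arrivals, 0.0)
        h0 = np.append(h0, target.h0)
        k = np.append(k, target.k)
        return arrivals, h0, k, n_ahead
    n0 = config.initial_waitlist_size
    if n0 == 0:
        return np.empty(0), np.empty(0), np.empty(0), -1
    h0, k = sample_patients(pop, n0, rng)
    residence = n0 / pop.lambda_patients
    arrivals = np.sort(rng.uniform(-residence, 0.0, size=n0))
    return arrivals, h0, k, -1


@dataclass
class SimulationResult:
    """Event log of one run: per-patient and per-kidney tables.

    patients columns: id, arrival, h0, k, status, departure,
    quality_at_placement (nan unless transplanted).
    kidneys columns: id, arrival, q0, donor_type, outcome,
    accepting_position (1-based; -1 on discard), accepting_patient,
    rounds, cit_hours, quality_at_placement.
    """

    patients: pd.DataFrame
    kidneys: pd.DataFrame
    config: EngineConfig
    pop: PopulationParameters
    target_index: int = -1

    @property
    def target(self) -> pd.Series | None:
        if self.target_index < 0:
            return None
        return self.patients.iloc[self.target_index]


def run_simulation(
    pop: PopulationParameters,
    config: EngineConfig,
    seed: int | np.random.SeedSequence,
    target: TargetPatient | None = None,
    stop_when_target_departs: bool = True,
) -> SimulationResult:
    """Run one queue for ``config.horizon_months`` simulated months.

    Five independent substreams (kidney arrivals, patient arrivals,
    patient attributes, kidney qualities, acceptance draws) are spawned
    from ``seed``, so runs are bit-reproducible and experiments across
    group sizes can share arrival streams (common random numbers).

    Removals are processed exactly when a patient's waiting time reaches
    h0; offer rounds are instantaneous on the year clock.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_karr, s_parr, s_pattr, s_kq, s_acc, s_init = ss.spawn(6)
    rng_init = np.random.default_rng(s_init)
    rng_acc = np.random.default_rng(s_acc)

    horizon = config.horizon_months / MONTHS_PER_YEAR

    # kidney stream
    k_times = generate_arrivals(pop.mu_kidneys, horizon, np.random.default_rng(s_karr)) \
        if pop.mu_kidneys > 0 else np.empty(0)
    rng_kq = np.random.default_rng(s_kq)
    k_q0 = sample_kidney_quality(rng_kq, len(k_times))
    k_types = sample_donor_types(pop, len(k_times), rng_kq)

    # patient stream
    p_times = generate_arrivals(pop.lambda_patients, horizon, np.random.default_rng(s_parr))
    p_h0_new, p_k_new = sample_patients(pop, len(p_times), np.random.default_rng(s_pattr))

    init_arr, init_h0, init_k, target_index = _initial_waitlist(pop, config, rng_init, target)

    n_init = len(init_arr)
    n_total = n_init + len(p_times)
    pa_arrival = np.concatenate([init_arr, p_times])
    pa_h0 = np.concatenate([init_h0, p_h0_new])
    pa_k = np.concatenate([init_k, p_k_new])
    pa_expiry = pa_arrival + pa_h0
    pa_status = np.zeros(n_total, dtype=np.int8)  # 0 wait, 1 transplant, 2 removed
    pa_departure = np.full(n_total, np.nan)
    pa_qpl = np.full(n_total, np.nan)

    # kidney log arrays
    nk = len(k_times)
    ko_outcome = np.zeros(nk, dtype=np.int8)  # 0 discard, 1 transplant
    ko_position = np.full(nk, -1, dtype=np.int64)
    ko_patient = np.full(nk, -1, dtype=np.int64)
    ko_rounds = np.zeros(nk, dtype=np.int64)
    ko_qpl = np.full(nk, np.nan)

    wl = np.arange(n_init, dtype=np.int64)  # active waitlist, FCFS order
    next_patient = n_init
    round_hours = config.decay.round_duration_hours

    track_target = target is not None and stop_when_target_departs

    for j in range(nk):
        t = k_times[j]
        # admit patients who arrived by t (appended in arrival order)
        first = next_patient
        while next_patient < n_total and pa_arrival[next_patient] <= t:
            next_patient += 1
        if next_patient > first:
            wl = np.concatenate([wl, np.arange(first, next_patient, dtype=np.int64)])
        # process removals due before t (w reached h0)
        if wl.size:
            expired = pa_expiry[wl] <= t
            if expired.any():
                gone = wl[expired]
                pa_status[gone] = 2
                pa_departure[gone] = pa_expiry[gone]
                wl = wl[~expired]
        if track_target and pa_status[target_index] != 0:
            break
        outcome, pos, rounds, q_res = offer_kidney(k_q0[j], pa_k[wl], config, rng_acc)
        ko_rounds[j] = rounds
        ko_qpl[j] = q_res
        if outcome == "transplanted":
            pid = wl[pos]
            ko_outcome[j] = 1
            ko_position[j] = pos + 1
            ko_patient[j] = pid
            pa_status[pid] = 1
            pa_departure[pid] = t
            pa_qpl[pid] = q_res
            wl = np.delete(wl, pos)
            if track_target and pid == target_index:
                break

    # admit any remaining arrivals, then final removal sweep up to horizon
    if next_patient < n_total:
        wl = np.concatenate([wl, np.arange(next_patient, n_total, dtype=np.int64)])
    if wl.size:
        expired = pa_expiry[wl] <= horizon
        gone = wl[expired]
        pa_status[gone] = 2
        pa_departure[gone] = pa_expiry[gone]

    status_names = np.array([WAITING, TRANSPLANTED, REMOVED])
    patients = pd.DataFrame(
        {
            "id": np.arange(n_total),
            "arrival": pa_arrival,
            "h0": pa_h0,
            "k": pa_k,
            "status": status_names[pa_status],
            "departure": pa_departure,
            "quality_at_placement": pa_qpl,
        }
    )
    kidneys = pd.DataFrame(
        {
            "id": np.arange(nk),
            "arrival": k_times,
            "q0": k_q0,
            "donor_type": k_types,
            "outcome": np.where(ko_outcome == 1, "transplanted", "discarded"),
            "accepting_position": ko_position,
            "accepting_patient": ko_patient,
            "rounds": ko_rounds,
            "cit_hours": ko_rounds * round_hours,
            "quality_at_placement": ko_qpl,
        }
    )
    return SimulationResult(
        patients=patients, kidneys=kidneys, config=config, pop=pop,
        target_index=target_index,
    )


@dataclass(frozen=True)
class SimulationMetrics:
    """Post-warmup summary of one run.

    Rates: utilization/discard are fractions of kidneys arriving in the
    window; removal and transplant rates are annual throughputs divided
    by the mean census, in %/year (the realized per-patient removal and
    transplant hazards of the queue).
    """

    window_years: float
    n_kidneys: int
    n_transplants: int
    n_removals: int
    kidney_utilization_rate: float
    kidney_discard_rate: float
    waitlist_removal_rate: float
    transplant_rate: float
    mean_census: float
    census_trajectory: pd.DataFrame  # columns: month, census
    mean_accepted_position: float
    max_accepted_position: int
    mean_accepted_quality: float
    mean_transplant_utility: float  # nan if no UtilityParameters given


def compute_metrics(
    result: SimulationResult,
    warmup_months: float | None = None,
    horizon_months: float | None = None,
    utility_params: UtilityParameters | None = None,
) -> SimulationMetrics:
    """Tally metrics over the reporting window (warmup, horizon] months.

    Kidneys are attributed to the window by arrival time; transplants
    and removals by event time; the census is sampled at each month
    boundary inside the window.
    """
    cfg = result.config
    warmup_months = cfg.warmup_months if warmup_months is None else warmup_months
    horizon_months = cfg.horizon_months if horizon_months is None else horizon_months
    t0 = warmup_months / MONTHS_PER_YEAR
    t1 = horizon_months / MONTHS_PER_YEAR
    if t1 <= t0:
        raise ValueError("reporting window is empty")
    years = t1 - t0

    kid = result.kidneys
    in_win = (kid["arrival"].to_numpy() > t0) & (kid["arrival"].to_numpy() <= t1)
    kw = kid.loc[in_win]
    n_kid = len(kw)
    if n_kid == 0:
        raise ValueError("no kidney arrivals in the reporting window")
    tx_mask = kw["outcome"].to_numpy() == "transplanted"
    n_tx = int(tx_mask.sum())
    utilization = n_tx / n_kid

    pat = result.patients
    dep = pat["departure"].to_numpy()
    status = pat["status"].to_numpy()
    rem_in = (status == REMOVED) & (dep > t0) & (dep <= t1)
    n_rem = int(rem_in.sum())

    # monthly census: arrivals(<=t) - departures(<=t)
    arr_sorted = np.sort(pat["arrival"].to_numpy())
    dep_all = np.where(np.isnan(dep), np.inf, dep)
    dep_sorted = np.sort(dep_all)
    months = np.arange(np.ceil(warmup_months) + 1, np.floor(horizon_months) + 1)
    tm = months / MONTHS_PER_YEAR
    census = np.searchsorted(arr_sorted, tm, side="right") - np.searchsorted(
        dep_sorted, tm, side="right"
    )
    mean_census = float(census.mean())
    trajectory = pd.DataFrame({"month": months, "census": census})

    removal_rate = (n_rem / years) / mean_census * 100.0
    tx_events = (status == TRANSPLANTED) & (dep > t0) & (dep <= t1)
    n_tx_events = int(tx_events.sum())
    transplant_rate = (n_tx_events / years) / mean_census * 100.0

    pos = kw.loc[tx_mask, "accepting_position"].to_numpy()
    qpl = kw.loc[tx_mask, "quality_at_placement"].to_numpy()
    mean_pos = float(pos.mean()) if n_tx else float("nan")
    max_pos = int(pos.max()) if n_tx else 0
    mean_q = float(qpl.mean()) if n_tx else float("nan")

    mean_u = float("nan")
    if utility_params is not None and n_tx_events:
        tp = pat.loc[tx_events]
        w = tp["departure"].to_numpy() - tp["arrival"].to_numpy()
        u = utility(tp["h0"].to_numpy(), tp["quality_at_placement"].to_numpy(),
                    w, utility_params)
        mean_u = float(np.mean(u))

    return SimulationMetrics(
        window_years=years,
        n_kidneys=n_kid,
        n_transplants=n_tx,
        n_removals=n_rem,
        kidney_utilization_rate=utilization,
        kidney_discard_rate=1.0 - utilization,
        waitlist_removal_rate=removal_rate,
        transplant_rate=transplant_rate,
        mean_census=mean_census,
        census_trajectory=trajectory,
        mean_accepted_position=mean_pos,
        max_accepted_position=max_pos,
        mean_accepted_quality=mean_q,
        mean_transplant_utility=mean_u,
    )
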