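import numpy as np
import pandas as pd
import pytest

from kidneyalloc import (
    EngineConfig,
    DecayParameters,
    PopulationParameters,
    SimulationResult,
    TargetPatient,
    compute_metrics,
    offer_kidney,
    run_simulation,
)


def oracle_offer(q0, thresholds, g, p, delta, max_rounds, rng):
    """Independent round-by-round reference: walk every (round, position,
    decision) tuple in pure Python, consuming one uniform per
    threshold-eligible patient in position order."""
    n = len(thresholds)
    q = q0
    if n == 0:
        return "discarded", None, 0, q
    rounds = 0
    start = 0
    while start < n and rounds < max_rounds:
        accepted = None
        for pos in range(start, min(start + g, n)):
            if thresholds[pos] <= q:
                u = rng.random()
                if accepted is None and u < p:
                    accepted = pos
        if accepted is not None:
            return "transplanted", accepted, rounds + 1, q
        start += g
        rounds += 1
        q *= 1.0 - delta
    return "discarded", None, rounds, q


@pytest.mark.parametrize("g", [1, 3, 5, 7, 20, 50])
@pytest.mark.parametrize("case_seed", range(10))
def test_offer_matches_bruteforce_oracle(g, case_seed):
    """Engine offer resolution is bit-identical to the independent
    enumeration oracle on frozen 20-patient instances."""
    setup = np.random.default_rng(1000 + case_seed)
    thresholds = setup.random(20)
    q0 = float(setup.random())
    cfg = EngineConfig(g=g)
    got = offer_kidney(q0, thresholds, cfg, np.random.default_rng(case_seed))
    want = oracle_offer(
        q0, thresholds, g, cfg.p_transplant, cfg.decay.delta,
        cfg.decay.max_rounds, np.random.default_rng(case_seed),
    )
    assert got == want


def test_offer_unconditional_acceptance():
    cfg = EngineConfig(g=5, p_patient_factors=1.0, p_center_factors=1.0)
    out = offer_kidney(0.9, np.array([0.0]), cfg, np.random.default_rng(0))
    assert out == ("transplanted", 0, 1, 0.9)


def test_offer_unconditional_rejection():
    """All thresholds above any attainable quality: discard after
    min(ceil(N/g), max_rounds) rounds."""
    cfg = EngineConfig(g=5)
    n = 12
    out = offer_kidney(0.99, np.ones(n), cfg, np.random.default_rng(0))
    assert out[0] == "discarded"
    assert out[1] is None
    assert out[2] == int(np.ceil(n / 5))
    big = offer_kidney(0.99, np.ones(1000), cfg, np.random.default_rng(0))
    assert big[2] == cfg.decay.max_rounds


def test_offer_empty_waitlist_flagged_discard():
    out = offer_kidney(0.5, np.empty(0), EngineConfig(), np.random.default_rng(0))
    assert out == ("discarded", None, 0, 0.5)


def test_run_is_deterministic(region6, small_config):
    a = run_simulation(region6, small_config, seed=42)
    b = run_simulation(region6, small_config, seed=42)
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.kidneys, b.kidneys)


def test_conservation(region6, small_config):
    """Every kidney is transplanted or discarded; every departed patient
    is transplanted or removed; transplant links reconcile exactly."""
    res = run_simulation(region6, small_config, seed=7)
    kid, pat = res.kidneys, res.patients
    assert set(kid.outcome.unique()) <= {"transplanted", "discarded"}
    n_tx_kid = (kid.outcome == "transplanted").sum()
    assert n_tx_kid + (kid.outcome == "discarded").sum() == len(kid)
    counts = pat.status.value_counts()
    assert counts.sum() == len(pat)
    assert counts.get("transplanted", 0) == n_tx_kid
    # transplanted patients depart strictly before running out of time
    tx = pat[pat.status == "transplanted"]
    assert (tx.departure < tx.arrival + tx.h0).all()
    # removed patients depart exactly when w = h0
    rm = pat[pat.status == "removed"]
    assert np.allclose(rm.departure, rm.arrival + rm.h0)
    # each transplanted kidney maps to a distinct transplanted patient
    acceptors = kid.loc[kid.outcome == "transplanted", "accepting_patient"]
    assert acceptors.is_unique
    assert (pat.loc[acceptors, "status"] == "transplanted").all()


def test_no_kidneys_limit(small_config):
    """Supply-free limit: no transplants; every patient whose time runs
    out within the horizon is removed at w = h0."""
    pop = PopulationParameters(lambda_patients=378, mu_kidneys=0.0)
    res = run_simulation(pop, small_config, seed=1)
    assert len(res.kidneys) == 0
    pat = res.patients
    assert (pat.status != "transplanted").all()
    horizon = small_config.horizon_months / 12
    should_expire = pat.arrival + pat.h0 <= horizon
    assert (pat.loc[should_expire, "status"] == "removed").all()
    assert (pat.loc[~should_expire, "status"] == "waiting").all()


def test_huge_group_resolves_in_one_round(region6):
    cfg = EngineConfig(g=100_000, horizon_months=24, warmup_months=0,
                       initial_waitlist_size=300)
    res = run_simulation(region6, cfg, seed=3)
    assert (res.kidneys.rounds <= 1).all()


def test_target_patient_is_tracked(region6):
    cfg = EngineConfig(horizon_months=13, warmup_months=0, initial_waitlist_size=0)
    target = TargetPatient(h0=1.0, k=0.5, position=10)
    res = run_simulation(region6, cfg, seed=11, target=target)
    row = res.target
    assert row is not None
    assert row["h0"] == 1.0 and row["k"] == 0.5
    assert row["status"] in ("transplanted", "removed")
    if row["status"] == "removed":
        assert row["departure"] == pytest.approx(1.0)


def _tiny_result():
    """Hand-built event log with known tallies (1-year window)."""
    patients = pd.DataFrame(
        {
            "id": [0, 1, 2, 3, 4],
            "arrival": [-0.5, 0.1, 0.2, 0.3, 0.35],
            "h0": [10.0, 0.5, 4.0, 5.0, 0.05],
            "k": [0.5] * 5,
            "status": ["waiting", "removed", "transplanted", "transplanted", "removed"],
            "departure": [np.nan, 0.6, 0.4, 0.9, 0.4],
            "quality_at_placement": [np.nan, np.nan, 0.8, 0.6, np.nan],
        }
    )
    kidneys = pd.DataFrame(
        {
            "id": [0, 1, 2],
            "arrival": [0.4, 0.9, 0.95],
            "q0": [0.85, 0.7, 0.1],
            "donor_type": ["A", "A", "O"],
            "outcome": ["transplanted", "transplanted", "discarded"],
            "accepting_position": [2, 1, -1],
            "accepting_patient": [2, 3, -1],
            "rounds": [2, 3, 10],
            "cit_hours": [2.0, 3.0, 10.0],
            "quality_at_placement": [0.8, 0.6, 0.06],
        }
    )
    pop = PopulationParameters(lambda_patients=5, mu_kidneys=3)
    cfg = EngineConfig(horizon_months=12, warmup_months=0, initial_waitlist_size=0)
    return SimulationResult(patients=patients, kidneys=kidneys, config=cfg, pop=pop)


def test_metrics_match_manual_tally():
    res = _tiny_result()
    m = compute_metrics(res, warmup_months=0, horizon_months=12)
    assert m.n_kidneys == 3
    assert m.kidney_utilization_rate == pytest.approx(2 / 3)
    assert m.kidney_discard_rate == pytest.approx(1 / 3)
    assert m.n_removals == 2
    assert m.mean_accepted_position == pytest.approx(1.5)
    assert m.max_accepted_position == 2
    assert m.mean_accepted_quality == pytest.approx(0.7)
    # independent census tally at each month boundary
    census = []
    for month in range(1, 13):
        t = month / 12
        waiting = 0
        for _, p in res.patients.iterrows():
            dep = p.departure if not np.isnan(p.departure) else np.inf
            if p.arrival <= t < dep:
                waiting += 1
        census.append(waiting)
    assert m.census_trajectory["census"].tolist() == census
    mean_census = np.mean(census)
    assert m.mean_census == pytest.approx(mean_census)
    assert m.waitlist_removal_rate == pytest.approx(2 / mean_census * 100)
    assert m.transplant_rate == pytest.approx(2 / mean_census * 100)


def test_metrics_zero_removals():
    res = _tiny_result()
    res.patients.loc[res.patients.status == "removed", "status"] = "waiting"
    res.patients.loc[res.patients.status == "waiting", "departure"] = np.nan
    m = compute_metrics(res, warmup_months=0, horizon_months=12)
    assert m.n_removals == 0
    assert m.waitlist_removal_rate == 0.0


def test_metrics_empty_window_rejected():
    res = _tiny_result()
    with pytest.raises(ValueError):
        compute_metrics(res, warmup_months=12, horizon_months=12)


def test_engine_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(g=0)
    with pytest.raises(ValueError):
        EngineConfig(p_patient_factors=0.0)
    with pytest.raises(ValueError):
        EngineConfig(horizon_months=100, warmup_months=100)


def test_p_transplant_is_product_of_factors():
    cfg = EngineConfig(p_patient_factors=0.9, p_center_factors=0.5)
    assert cfg.p_transplant == pytest.approx(0.45)
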