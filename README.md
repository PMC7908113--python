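# kidneyalloc

Simulation and optimization of deceased-donor kidney allocation.

End-stage renal disease patients wait years for a deceased-donor
kidney; many die waiting or see organs discarded while they wait.
`kidneyalloc` models one blood-type waitlist as a queue with
abandonment and studies three questions:

1. **What minimum kidney quality should a patient accept?**  Accepting
   early means a mediocre organ; holding out means more time on
   dialysis and the risk of running out of time.
2. **Which regions should a patient list in**, given a budget, a
   travel-distance limit, and a floor on regional transplant outcomes?
3. **How much would faster, better-informed offer processing improve
   utilization, transplant rates and waitlist mortality?**

## Model

Patients join at Poisson rate λ/year with dialysis survivability
`h0 ~ Weibull(a=8, b=2)` (removal exactly when waiting time `w` reaches
`h0`) and an acceptance threshold `k ~ Unif(0,1)`, rank-correlated with
`h0` (Spearman ρ = 0.2, Gaussian copula).  Kidneys arrive at Poisson
rate μ/year with quality `q0 = 1 − KDPI ~ Unif(0,1)` and are offered to
the waitlist in groups of `g` patients per one-hour round, decaying as
`q_t = q0 (1 − δ)^t` with δ = 0.05/h and a 48-hour discard cap.  A
patient with `k ≤ q_t` accepts; an accepted offer converts to a
transplant with probability `p = 0.8`.  A transplanted patient realizes

    U(q_t, h0, w) = m(h0) / (1 + e^{−β(q_t − α)}) · (1 − w/h0)^γ

life-years (α = 0.4, β = 8, γ = 0.5).  Multiple-region listing solves

    max Σ U_i r_i   s.t.  Σ c_i r_i ≤ C,  d_i r_i ≤ D,  p_i ≥ P on
    selected regions,  r_i ∈ {0,1},  home region forced in

by exact enumeration over the 11 US transplantation regions.  See
`docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

Optimal acceptance threshold for a blood-type-A patient with one
life-year on dialysis at waitlist position 100 in region 6
(μ = 270 kidneys/yr, λ = 378 patients/yr):

```bash
$ kidneyalloc sweep --region 6 --h0 1 --position 100 --replicates 100 --seed 0
k* = 0.65  expected utility = 9.76
```

She should decline any kidney below quality 0.65; that policy is worth
about 9.8 expected life-years (on the package's `m(1) = 15` calibration
scale — argmaxes are invariant to that calibration).  Region listing
under a $15,000 budget, a 1500-mile range and a 75% five-year-survival
floor:

```bash
$ kidneyalloc optimize --budget 15000 --max-distance 1500 --min-survival 0.75 --home 6
{
  "selected_regions": [4, 5, 6, 8],
  "objective_life_years": 47.9,
  "total_cost": 14987.7,
  "region_costs": {"4": 3398.8, "5": 8028.0, "6": 0.0, "8": 3560.9}
}
```

Exactly three non-home regions are feasible (4, 5 and 8; region 5 the
most valuable at 13.5 life-years) and all three fit the budget
together, for $14,987.70 of the $15,000.

The information-sharing study varies the offer group size `g` (patients
evaluated per hour of cold ischemia; `g` at the census = perfect
information) over paired seeds:

```bash
$ kidneyalloc infoshare --region 6 --g 5,10,100000 --seeds 20 --seed 0
     g  transplant_improvement_pct  ...  mortality_reduction_pct
     5                        0.00  ...                     0.00
    10                       54.63  ...                    11.39
100000                      256.65  ...                    40.04
```

Doubling the effective offer speed already raises the transplant rate
by ~55% and perfect information more than triples it, while cutting
waitlist mortality by ~40% — because faster offering prevents both
cold-ischemia decay and the pile-up of hard-to-match patients at the
front of the queue.

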