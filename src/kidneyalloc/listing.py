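"""Multiple-region listing as a constrained 0/1 selection problem.

A waitlisted patient may register in transplant centers of several
regions.  Each region ``i`` carries an expected post-transplant utility
``U_i(k_i*)`` (from the per-region threshold sweep), an out-of-pocket
cost ``c_i`` (periodic evaluations plus travel and a short stay), a
distance ``d_i`` and a five-year survival performance ``p_i``.  The
patient chooses a 0/1 vector ``r`` maximizing total utility

    max sum_i U_i r_i
    s.t. sum_i c_i r_i <= C,   d_i <= D and p_i >= P for selected i,
         r_home = 1,

with budget ``C``, travel-distance limit ``D`` and minimum performance
``P``.  With 11 regions the problem is solved exactly by enumeration
over subsets of the feasible non-home regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "RegionListingAttributes",
    "ListingConstraints",
    "ListingCostModel",
    "ListingSolution",
    "region_cost",
    "feasible_regions",
    "optimize_listing",
]

REQUIRED_COLUMNS = (
    "region",
    "cost_of_living_month",
    "expected_wait_years",
    "n_evaluations",
    "evaluation_cost",
    "survival_5yr",
    "distance_miles",
    "utility",
)


@dataclass(frozen=True)
class RegionListingAttributes:
    """One region's listing attributes (one row of the listing table)."""

    region: int
    cost_of_living_month: float  # $/month in the region's major city
    expected_wait_years: float
    n_evaluations: int
    evaluation_cost: float  # $ total over the expected evaluations
    survival_5yr: float  # fraction in [0, 1]
    distance_miles: float  # air miles from home
    utility: float  # U_i(k_i*), life-years

    def __post_init__(self) -> None:
        if min(self.cost_of_living_month, self.evaluation_cost,
               self.distance_miles) < 0:
            raise ValueError("costs and distance must be non-negative")
        if not 0.0 <= self.survival_5yr <= 1.0:
            raise ValueError("survival_5yr must lie in [0, 1]")


@dataclass(frozen=True)
class ListingCostModel:
    """Out-of-pocket cost of a non-home listing: evaluation cost plus
    per-mile travel plus ``stay_days`` of the destination's cost of
    living.  The home region is free (already listed, insurance covers
    its evaluations)."""

    travel_rate_per_mile: float = 0.0
    stay_days: float = 3.0

    def __post_init__(self) -> None:
        if self.travel_rate_per_mile < 0 or self.stay_days < 0:
            raise ValueError("cost model rates must be non-negative")


@dataclass(frozen=True)
class ListingConstraints:
    """Budget C ($), maximum travel distance D (miles), minimum regional
    five-year survival P (fraction), and the patient's home region."""

    budget: float
    max_distance: float
    min_performance: float
    home_region: int

    def __post_init__(self) -> None:
        if self.budget < 0 or self.max_distance < 0:
            raise ValueError("budget and max_distance must be non-negative")
        if self.min_performance < 0.0:
            raise ValueError("min_performance must be non-negative")


@dataclass(frozen=True)
class ListingSolution:
    """Optimal listing set (region ids, home included), its summed
    utility, total cost, and per-region costs of the selected set."""

    selected: tuple[int, ...]
    objective: float
    total_cost: float
    region_costs: dict[int, float]


def region_cost(
    attrs: RegionListingAttributes,
    cost_model: ListingCostModel,
    home_region: int,
) -> float:
    """Cost of adding one region's listing; 0 for the home region."""
    if attrs.region == home_region:
        return 0.0
    return (
        attrs.evaluation_cost
        + cost_model.travel_rate_per_mile * attrs.distance_miles
        + cost_model.stay_days * attrs.cost_of_living_month / 30.0
    )


def _validate_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"listing table missing columns: {sorted(missing)}")


def feasible_regions(table: pd.DataFrame, constraints: ListingConstraints) -> list[int]:
    """Regions individually satisfying the distance and performance
    filters; the home region is always feasible."""
    _validate_table(table)
    out = []
    for _, row in table.iterrows():
        region = int(row["region"])
        if region == constraints.home_region:
            out.append(region)
            continue
        if (
            row["distance_miles"] <= constraints.max_distance
            and row["survival_5yr"] >= constraints.min_performance
        ):
            out.append(region)
    return out


def optimize_listing(
    table: pd.DataFrame,
    constraints: ListingConstraints,
    cost_model: ListingCostModel | None = None,
) -> ListingSolution:
    """Exact maximizer of summed utility by subset enumeration.

    The home region is forced into every solution at zero cost.  The
    distance/performance filters apply to selected regions only; the
    budget caps the summed cost of the selected set.  Among optima the
    lexicographically smallest region set is returned.
    """
    _validate_table(table)
    cm = cost_model if cost_model is not None else ListingCostModel()
    home = constraints.home_region
    if home not in set(table["region"].astype(int)):
        raise ValueError(f"home region {home} not in table")

    attrs = {
        int(row["region"]): RegionListingAttributes(
            region=int(row["region"]),
            cost_of_living_month=float(row["cost_of_living_month"]),
            expected_wait_years=float(row["expected_wait_years"]),
            n_evaluations=int(row["n_evaluations"]),
            evaluation_cost=float(row["evaluation_cost"]),
            survival_5yr=float(row["survival_5yr"]),
            distance_miles=float(row["distance_miles"]),
            utility=float(row["utility"]),
        )
        for _, row in table.iterrows()
    }
    costs = {r: region_cost(a, cm, home) for r, a in attrs.items()}
    candidates = sorted(r for r in feasible_regions(table, constraints) if r != home)

    best: tuple[float, tuple[int, ...]] | None = None
    for size in range(len(candidates) + 1):
        for combo in combinations(candidates, size):
            cost = sum(costs[r] for r in combo)
            if cost > constraints.budget:
                continue
            obj = attrs[home].utility + sum(attrs[r].utility for r in combo)
            key = tuple(sorted((home,) + combo))
            if best is None or obj > best[0] + 1e-12 or (
                abs(obj - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (obj, key)
    assert best is not None  # home-only subset always feasible (cost 0)
    selected = best[1]
    total = sum(costs[r] for r in selected)
    return ListingSolution(
        selected=selected,
        objective=best[0],
        total_cost=total,
        region_costs={r: costs[r] for r in selected},
    )
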