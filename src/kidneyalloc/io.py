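"""Packaged fixtures and run configuration.

Two small CSV tables ship with the package:

* ``region_rates.csv`` — per-region annual kidney supply (``mu_a``) and
  patient arrival (``lambda_a``) rates for the blood-type-A queue over
  the 11 US transplantation regions (2019 estimates).
* ``region_listing.csv`` — per-region listing attributes for the
  multiple-region listing problem: monthly cost of living, expected
  wait, evaluation count and cost, five-year survival, air distance
  from the reference home region (6), and the sweep-derived expected
  utility U_i(k_i*).

Run configuration is a strict YAML/JSON mapping; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .engine import EngineConfig
from .policy import SweepConfig
from .quality import DecayParameters
from .utility import UtilityParameters

__all__ = [
    "load_region_rates",
    "load_listing_table",
    "RunConfig",
    "load_config",
    "dump_config",
]

N_REGIONS = 11


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("kidneyalloc.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_region_rates(path: str | Path | None = None) -> pd.DataFrame:
    """Per-region supply/demand rates (columns region, mu_a, lambda_a)."""
    df = pd.read_csv(path) if path is not None else _read_fixture("region_rates.csv")
    expected = {"region", "mu_a", "lambda_a"}
    if set(df.columns) != expected:
        raise ValueError(f"region rate table must have columns {sorted(expected)}")
    if len(df) != N_REGIONS:
        raise ValueError(f"expected {N_REGIONS} regions, got {len(df)}")
    for col in ("mu_a", "lambda_a"):
        bad = df.index[df[col] <= 0]
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"non-positive rate in column '{col}', row {row} "
                f"(region {df.loc[row, 'region']})"
            )
    return df


def load_listing_table(path: str | Path | None = None) -> pd.DataFrame:
    """Per-region listing attributes in the schema used by
    :mod:`kidneyalloc.listing`."""
    df = pd.read_csv(path) if path is not None else _read_fixture("region_listing.csv")
    from .listing import REQUIRED_COLUMNS

    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"listing table missing columns: {sorted(missing)}")
    if len(df) != N_REGIONS:
        raise ValueError(f"expected {N_REGIONS} regions, got {len(df)}")
    if ((df["survival_5yr"] < 0) | (df["survival_5yr"] > 1)).any():
        raise ValueError("survival_5yr must lie in [0, 1]")
    neg = df[["cost_of_living_month", "evaluation_cost", "distance_miles"]] < 0
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        row = int(neg[col].idxmax())
        raise ValueError(f"negative value in column '{col}', row {row}")
    return df


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration grouping the module sub-configs."""

    scenario: str = "default"
    seed: int = 0
    region: int = 6
    spearman_rho: float = 0.2
    engine: EngineConfig = field(default_factory=EngineConfig)
    utility: UtilityParameters = field(default_factory=UtilityParameters)
    sweep: SweepConfig = field(default_factory=SweepConfig)


_SECTION_TYPES = {
    "engine": EngineConfig,
    "utility": UtilityParameters,
    "sweep": SweepConfig,
}
_TOP_KEYS = {"scenario", "seed", "region", "spearman_rho"} | set(_SECTION_TYPES)


def _build_section(cls, data: dict):
    if cls is EngineConfig and "decay" in data:
        data = dict(data)
        data["decay"] = DecayParameters(**data["decay"])
    if cls is SweepConfig and "threshold_grid" in data:
        data = dict(data)
        data["threshold_grid"] = tuple(data["threshold_grid"])
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run configuration; unknown keys are errors."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key in ("scenario", "seed", "region", "spearman_rho"):
        if key in raw:
            kwargs[key] = raw[key]
    for key, cls in _SECTION_TYPES.items():
        if key in raw:
            if not isinstance(raw[key], dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            try:
                kwargs[key] = _build_section(cls, raw[key])
            except TypeError as exc:
                raise ValueError(f"bad keys in config section '{key}': {exc}") from exc
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML (round-trips with load_config)."""
    data = asdict(config)
    data["sweep"]["threshold_grid"] = list(data["sweep"]["threshold_grid"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
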