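"""Pipeline configuration and ingestion filters.

The config gathers everything the five stages need: synthetic-world sizes,
the climate model, the generating niche, SDM thresholds, occurrence and
catchment filters, and the root seed.  It round-trips through YAML so runs
are fully described by one file plus one integer.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .synthetic_world import (
    CatchmentNetwork,
    ClimateConfig,
    NicheTruth,
    OccurrenceSet,
)
from .traits_tpc import ThermalTraits

__all__ = [
    "WorldConfig",
    "SDMConfig",
    "FilterConfig",
    "PipelineConfig",
    "filter_occurrences",
    "filter_catchments",
]

logger = logging.getLogger("thermoscape")


@dataclass(frozen=True)
class WorldConfig:
    """Synthetic-world sizes and noise levels."""

    n_catchments: int = 500
    n_regions: int = 6
    dam_fraction: float = 0.15
    n_obs_per_trait: int = 5
    obs_noise_C: float = 0.5
    species: str = "Salmo synthetica"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dam_fraction <= 1.0:
            raise ConfigError("dam_fraction must lie in [0, 1]")


#: Default ground-truth niche: a cold-water salmonid-like profile, with the
#: adult/juvenile windows spanning roughly 0-25 degC and eggs restricted to
#: a much colder incubation window.
_DEFAULT_NICHE_TRAITS = {
    "adult": (0.0, 16.0, 25.0),
    "juvenile": (0.0, 15.0, 24.0),
    "egg": (0.0, 8.0, 16.0),
}


@dataclass(frozen=True)
class NicheConfig:
    stage_traits: dict = field(default_factory=lambda: dict(_DEFAULT_NICHE_TRAITS))
    presence_steepness: float = 25.0
    baseline_prevalence: float = 0.95

    def truth(self, species: str) -> NicheTruth:
        traits = {
            stage: ThermalTraits(species=species, life_stage=stage, ct_min=v[0], t_opt=v[1], ct_max=v[2])
            for stage, v in self.stage_traits.items()
        }
        return NicheTruth(
            stage_traits=traits,
            presence_steepness=self.presence_steepness,
            baseline_prevalence=self.baseline_prevalence,
        )


@dataclass(frozen=True)
class SDMConfig:
    auc_floor: float = 0.65
    corr_cap: float = 0.7
    auc_cutoff: float = 0.85
    n_splits: int = 100
    split_frac: float = 0.8
    tuning_budget: int = 30
    whitelist: tuple = ("altitude", "cropland_frac")

    def __post_init__(self) -> None:
        for name in ("corr_cap", "auc_cutoff", "split_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class FilterConfig:
    """Occurrence-record and catchment ingestion filters."""

    min_year: int = 1971
    max_uncertainty_km: float = 5.0
    basis_of_record: str = "human observation"
    min_area_km2: float = 3000.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 42
    world: WorldConfig = field(default_factory=WorldConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    niche: NicheConfig = field(default_factory=NicheConfig)
    sdm: SDMConfig = field(default_factory=SDMConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    trait_rule: str = "narrowest"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sdm"]["whitelist"] = list(self.sdm.whitelist)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        if "world" in data:
            kwargs["world"] = WorldConfig(**data.pop("world"))
        if "climate" in data:
            c = data.pop("climate")
            kwargs["climate"] = c if isinstance(c, ClimateConfig) else ClimateConfig(**c)
        if "niche" in data:
            n = dict(data.pop("niche"))
            if "stage_traits" in n:
                n["stage_traits"] = {k: tuple(v) for k, v in n["stage_traits"].items()}
            kwargs["niche"] = NicheConfig(**n)
        if "sdm" in data:
            s = dict(data.pop("sdm"))
            if "whitelist" in s:
                s["whitelist"] = tuple(s["whitelist"])
            kwargs["sdm"] = SDMConfig(**s)
        if "filters" in data:
            kwargs["filters"] = FilterConfig(**data.pop("filters"))
        kwargs.update(data)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# ingestion filters


def filter_occurrences(records: pd.DataFrame, filters: FilterConfig) -> OccurrenceSet:
    """Apply the three occurrence-record filters and deduplicate.

    A record is retained if its year is at or after ``min_year``, its
    coordinate uncertainty does not exceed ``max_uncertainty_km``, and its
    basis of record matches (case-insensitive).  Records missing any of the
    three metadata fields are dropped and logged.  Surviving records are
    collapsed to one presence per catchment.
    """
    required = ["catchment_id", "year", "coordinate_uncertainty_km", "basis_of_record"]
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        from .errors import SchemaError

        raise SchemaError(f"occurrence records missing columns: {missing_cols}")
    n_raw = len(records)
    complete = records.dropna(subset=required)
    if len(complete) < n_raw:
        logger.info("dropped %d occurrence records with missing metadata", n_raw - len(complete))
    ok = complete[
        (complete["year"] >= filters.min_year)
        & (complete["coordinate_uncertainty_km"] <= filters.max_uncertainty_km)
        & (complete["basis_of_record"].str.lower() == filters.basis_of_record.lower())
    ]
    logger.info("occurrence filter: %d raw -> %d passing records", n_raw, len(ok))
    if ok.empty:
        raise DataError("no occurrence records survived the ingestion filters")
    present = frozenset(ok["catchment_id"].unique())
    return OccurrenceSet(present=present, records=ok.reset_index(drop=True))


def filter_catchments(network: CatchmentNetwork, min_area_km2: float = 3000.0) -> CatchmentNetwork:
    """Drop undersized catchments and their incident edges.

    Removing nodes from a forest leaves a forest, so the per-region tree
    property degrades gracefully into (possibly several) trees per region;
    the result is re-validated.
    """
    keep = network.catchments[network.catchments["area_km2"] >= min_area_km2]
    if keep.empty:
        raise DataError(f"no catchment has area >= {min_area_km2} km2")
    kept_ids = set(keep["catchment_id"])
    edges = frozenset(e for e in network.edges if e[0] in kept_ids and e[1] in kept_ids)
    filtered = CatchmentNetwork(catchments=keep.reset_index(drop=True), edges=edges)
    filtered.validate(min_area_km2=min_area_km2)
    n_dropped = len(network.catchments) - len(keep)
    if n_dropped:
        logger.info("catchment filter: dropped %d catchments below %g km2", n_dropped, min_area_km2)
    return filtered
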