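"""Seeded generators for a synthetic catchment world.

The generators emulate the statistical structure of a global catchment-scale
study system: a forest of dendritic river networks partitioned into regions,
monthly water temperatures for a baseline and a warmed future period,
static covariates, dams on a fraction of network edges, replicated
laboratory trait observations, and presence/absence sampled from a known
thermal niche.  Everything is a pure function of (parameters, seed), so
downstream stages are testable and parameter recovery can be checked against
the generating truth.

Geographic realism is explicitly not attempted: no projections, no basin
shapes, no hydrological routing.  What matters for the analysis is the
acyclic river connectivity, the latitude/seasonality structure of water
temperature (with the seasonal cycle six months out of phase between the
hemispheres), and a recoverable presence signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import rng_for
from .errors import ConfigError, DataError
from .traits_tpc import LIFE_STAGES, TPC, ThermalTraits

__all__ = [
    "Edge",
    "CatchmentNetwork",
    "EnvironmentTable",
    "ClimateConfig",
    "NicheTruth",
    "OccurrenceSet",
    "generate_network",
    "generate_environment",
    "place_dams",
    "generate_traits",
    "sample_occurrences",
]

Edge = tuple[str, str]

PERIODS = ("baseline", "future")

#: Static (period-independent) covariates attached to every catchment.
STATIC_COVARIATES = (
    "altitude",
    "mean_winter_discharge",
    "forest_frac",
    "cropland_frac",
    "builtup_frac",
)


def make_edge(a: str, b: str) -> Edge:
    """Canonical (sorted) representation of an undirected edge."""
    if a == b:
        raise ValueError(f"self-loop edge on {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CatchmentNetwork:
    """Catchment table plus undirected river-adjacency edges.

    Within each region the edges form a tree (dendritic network); no edge
    crosses regions, so the whole edge set is a forest.
    """

    catchments: pd.DataFrame  # catchment_id, region, area_km2, lat, lon
    edges: frozenset  # of Edge

    def catchment_ids(self) -> list[str]:
        return list(self.catchments["catchment_id"])

    def region_of(self) -> dict[str, str]:
        return dict(zip(self.catchments["catchment_id"], self.catchments["region"]))

    def lat_of(self) -> dict[str, float]:
        return dict(zip(self.catchments["catchment_id"], self.catchments["lat"]))

    def validate(self, min_area_km2: float | None = None) -> None:
        """Check all structural invariants; raise DataError on violation."""
        ids = set(self.catchments["catchment_id"])
        if len(ids) != len(self.catchments):
            raise DataError("duplicate catchment ids")
        region = self.region_of()
        for a, b in self.edges:
            if a not in ids or b not in ids:
                raise DataError(f"edge ({a}, {b}) references unknown catchment")
            if a == b:
                raise DataError(f"self-loop on {a}")
            if region[a] != region[b]:
                raise DataError(f"edge ({a}, {b}) crosses regions")
        if min_area_km2 is not None and (self.catchments["area_km2"] < min_area_km2).any():
            raise DataError(f"catchment areas below {min_area_km2} km2 present")
        # each region must be a forest: acyclic <=> edges <= nodes - components
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(self.edges)
        if len(self.edges) != len(ids) - nx.number_connected_components(g):
            raise DataError("edge set contains a cycle")


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the synthetic monthly water-temperature model.

    Monthly water temperature is a latitude-dependent annual mean plus a
    seasonal sinusoid (peaking in July in the northern hemisphere and in
    January in the southern) plus Gaussian noise.  The future period adds a
    uniform warming offset; the 2.2 degC default is the global mean warming
    of the RCP6.0 pathway by 2100.
    """

    mean_temp_at_equator_C: float = 25.0
    lat_gradient_C_per_deg: float = 0.30
    seasonal_amplitude_C: float = 6.0
    warming_offset_C: float = 2.2
    noise_sd_C: float = 0.5

    REQUIRED = (
        "mean_temp_at_equator_C",
        "lat_gradient_C_per_deg",
        "seasonal_amplitude_C",
        "warming_offset_C",
        "noise_sd_C",
    )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ClimateConfig":
        missing = [k for k in cls.REQUIRED if k not in mapping]
        if missing:
            raise ConfigError(f"climate config missing fields: {missing}")
        return cls(**{k: float(mapping[k]) for k in cls.REQUIRED})


@dataclass(frozen=True)
class EnvironmentTable:
    """Monthly water temperatures per period plus static covariates."""

    temperature: pd.DataFrame  # catchment_id, period, month, water_temp_C
    covariates: pd.DataFrame  # catchment_id, name, value

    def temps_wide(self, period: str) -> pd.DataFrame:
        """Catchment x month (1..12) temperature matrix for one period."""
        sub = self.temperature[self.temperature["period"] == period]
        wide = sub.pivot(index="catchment_id", columns="month", values="water_temp_C")
        return wide.reindex(columns=range(1, 13))

    def covariates_wide(self) -> pd.DataFrame:
        return self.covariates.pivot(index="catchment_id", columns="name", values="value")

    def validate(self, network: CatchmentNetwork | None = None) -> None:
        counts = self.temperature.groupby(["catchment_id", "period"]).size()
        if not (counts == 12).all():
            raise DataError("each catchment/period must have exactly 12 monthly records")
        names = self.covariates.groupby("catchment_id")["name"].apply(frozenset)
        if names.nunique() > 1:
            raise DataError("covariate name sets differ across catchments")
        if network is not None:
            missing = set(network.catchment_ids()) - set(self.temperature["catchment_id"])
            if missing:
                raise DataError(f"temperature records missing for catchments: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class NicheTruth:
    """Ground-truth thermal niche used to generate traits and occurrences."""

    stage_traits: Mapping[str, ThermalTraits]
    presence_steepness: float = 25.0
    baseline_prevalence: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_prevalence <= 1.0:
            raise ValueError("baseline_prevalence must lie in [0, 1]")
        if self.presence_steepness <= 0:
            raise ValueError("presence_steepness must be positive")
        missing = [s for s in LIFE_STAGES if s not in self.stage_traits]
        if missing:
            raise ValueError(f"niche truth missing life stages: {missing}")


@dataclass(frozen=True)
class OccurrenceSet:
    """Catchments marked present, optionally with raw record metadata."""

    present: frozenset
    records: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.present)


# ---------------------------------------------------------------------------
# generators


def _latitude_bands(n_regions: int) -> list[tuple[float, float]]:
    """Disjoint latitude bands, alternating NH and SH so both hemispheres
    are populated whenever there are at least two regions."""
    n_nh = (n_regions + 1) // 2
    n_sh = n_regions - n_nh
    nh_edges = np.linspace(10.0, 68.0, n_nh + 1)
    sh_edges = np.linspace(-68.0, -10.0, n_sh + 1) if n_sh else np.empty(0)
    bands: list[tuple[float, float]] = []
    for i in range(n_regions):
        if i % 2 == 0 or n_sh == 0:
            j = i // 2
            bands.append((float(nh_edges[j]), float(nh_edges[j + 1])))
        else:
            j = i // 2
            bands.append((float(sh_edges[j]), float(sh_edges[j + 1])))
    return bands


def generate_network(
    n_catchments: int,
    n_regions: int,
    seed: int,
    min_area_km2: float = 3000.0,
) -> CatchmentNetwork:
    """Generate a forest of random dendritic trees, one per region.

    Each region's tree is grown by random attachment (node i attaches to a
    uniformly chosen earlier node), which yields the branching, acyclic
    topology river-dispersal logic depends on.  Regions occupy disjoint
    latitude bands alternating between the hemispheres.  All areas are at or
    above ``min_area_km2``, mirroring the ingestion filter applied to real
    catchment data.
    """
    if n_catchments < 1 or n_regions < 1:
        raise ValueError("n_catchments and n_regions must be positive")
    if n_catchments < n_regions:
        raise ValueError("need at least one catchment per region")
    rng = np.random.default_rng(seed)

    sizes = np.full(n_regions, n_catchments // n_regions)
    sizes[: n_catchments % n_regions] += 1
    bands = _latitude_bands(n_regions)

    rows = []
    edges: set[Edge] = set()
    idx = 0
    for r, (size, (lat_lo, lat_hi)) in enumerate(zip(sizes, bands)):
        region = f"R{r + 1}"
        ids = [f"C{idx + k:05d}" for k in range(size)]
        idx += size
        lon0 = -170.0 + 35.0 * r
        lats = rng.uniform(lat_lo, lat_hi, size)
        lons = rng.uniform(lon0, lon0 + 30.0, size)
        areas = min_area_km2 + rng.lognormal(mean=8.0, sigma=1.0, size=size)
        for k, cid in enumerate(ids):
            rows.append(
                {
                    "catchment_id": cid,
                    "region": region,
                    "area_km2": float(areas[k]),
                    "lat": float(lats[k]),
                    "lon": float(lons[k]),
                }
            )
            if k > 0:
                parent = ids[int(rng.integers(0, k))]
                edges.add(make_edge(cid, parent))

    network = CatchmentNetwork(catchments=pd.DataFrame(rows), edges=frozenset(edges))
    network.validate(min_area_km2=min_area_km2)
    return network


def generate_environment(
    network: CatchmentNetwork,
    climate: ClimateConfig | Mapping,
    seed: int,
) -> EnvironmentTable:
    """Monthly baseline and future water temperatures plus static covariates.

    The deterministic part of the signal is
    ``mean(lat) + amplitude * cos(2*pi*(month - peak)/12)`` with the peak in
    July north of the equator and January south of it, so the hemisphere
    seasonal inversion the seasonal summaries rely on holds exactly when
    noise is zero.  The future period equals the baseline signal plus the
    warming offset (plus its own noise draws).
    """
    if not isinstance(climate, ClimateConfig):
        climate = ClimateConfig.from_mapping(climate)
    rng = np.random.default_rng(seed)

    cat = network.catchments
    months = np.arange(1, 13)
    temp_rows = []
    annual_means = {}
    for _, row in cat.iterrows():
        lat = row["lat"]
        mean_t = climate.mean_temp_at_equator_C - climate.lat_gradient_C_per_deg * abs(lat)
        peak = 7 if lat >= 0 else 1
        signal = mean_t + climate.seasonal_amplitude_C * np.cos(2 * np.pi * (months - peak) / 12.0)
        annual_means[row["catchment_id"]] = mean_t
        for period in PERIODS:
            offset = climate.warming_offset_C if period == "future" else 0.0
            noise = (
                rng.normal(0.0, climate.noise_sd_C, 12) if climate.noise_sd_C > 0 else np.zeros(12)
            )
            for m, t in zip(months, signal + offset + noise):
                temp_rows.append(
                    {
                        "catchment_id": row["catchment_id"],
                        "period": period,
                        "month": int(m),
                        "water_temp_C": float(t),
                    }
                )

    cov_rows = []
    for _, row in cat.iterrows():
        cid = row["catchment_id"]
        mean_t = annual_means[cid]
        altitude = max(0.0, rng.normal(900.0 - 25.0 * mean_t, 150.0))
        discharge = row["area_km2"] * np.exp(rng.normal(-3.0, 0.5))
        forest = float(np.clip(0.25 + 0.004 * abs(row["lat"]) + rng.normal(0, 0.08), 0, 1))
        cropland = float(np.clip(0.45 - 0.5 * forest + rng.normal(0, 0.08), 0, 1))
        builtup = float(np.clip(rng.normal(0.05, 0.03), 0, 1))
        for name, value in zip(
            STATIC_COVARIATES, (altitude, discharge, forest, cropland, builtup)
        ):
            cov_rows.append({"catchment_id": cid, "name": name, "value": float(value)})

    env = EnvironmentTable(
        temperature=pd.DataFrame(temp_rows), covariates=pd.DataFrame(cov_rows)
    )
    env.validate(network)
    return env


def place_dams(network: CatchmentNetwork, dam_fraction: float, seed: int) -> frozenset:
    """Place dams on ``round(dam_fraction * n_edges)`` randomly chosen edges."""
    if not 0.0 <= dam_fraction <= 1.0:
        raise ValueError("dam_fraction must lie in [0, 1]")
    edges = sorted(network.edges)
    n_dams = int(round(dam_fraction * len(edges)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges), size=n_dams, replace=False) if n_dams else []
    return frozenset(edges[i] for i in chosen)


def generate_traits(
    truth: NicheTruth,
    n_obs_per_trait: int,
    obs_noise_C: float,
    seed: int,
    species: str = "Salmo synthetica",
) -> pd.DataFrame:
    """Replicated laboratory trait observations: truth plus Gaussian noise.

    One record per (life stage, trait, replicate), each attributed to a
    distinct synthetic source study.
    """
    if n_obs_per_trait < 1:
        raise ValueError("n_obs_per_trait must be >= 1")
    if obs_noise_C < 0:
        raise ValueError("obs_noise_C must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for stage in LIFE_STAGES:
        traits = truth.stage_traits[stage]
        for trait, true_value in (
            ("ct_min", traits.ct_min),
            ("t_opt", traits.t_opt),
            ("ct_max", traits.ct_max),
        ):
            noise = rng.normal(0.0, obs_noise_C, n_obs_per_trait) if obs_noise_C > 0 else np.zeros(
                n_obs_per_trait
            )
            for i in range(n_obs_per_trait):
                rows.append(
                    {
                        "species": species,
                        "life_stage": stage,
                        "trait": trait,
                        "value_C": float(true_value + noise[i]),
                        "source": f"study_{stage}_{trait}_{i + 1}",
                    }
                )
    return pd.DataFrame(rows)


def presence_probability(
    network: CatchmentNetwork, environment: EnvironmentTable, truth: NicheTruth
) -> pd.Series:
    """Per-catchment presence probability under the generating niche.

    The annual-mean adult survivorship ``v`` (baseline temperatures) is
    passed through a logistic link centred at v = 0.5 and rescaled so that
    perfect habitat (v = 1) maps exactly to ``baseline_prevalence``.  The
    probability is therefore monotone non-decreasing in ``v``.
    """
    adult = TPC(truth.stage_traits["adult"])
    temps = environment.temps_wide("baseline").reindex(network.catchment_ids())
    if temps.isna().any().any():
        raise DataError("baseline temperatures missing for some catchments")
    v = pd.Series(
        np.mean(adult(temps.to_numpy()), axis=1), index=temps.index, name="tpc_annual_mean"
    )
    k = truth.presence_steepness
    link = expit(k * (v - 0.5)) / expit(k * 0.5)
    return truth.baseline_prevalence * link


def sample_occurrences(
    network: CatchmentNetwork,
    environment: EnvironmentTable,
    truth: NicheTruth,
    seed: int,
) -> OccurrenceSet:
    """Sample presences independently per catchment from the niche truth.

    Each presence is given compliant record metadata (year, coordinate
    uncertainty, basis of record) so the downstream ingestion filters can be
    exercised end-to-end.
    """
    prob = presence_probability(network, environment, truth)
    rng = np.random.default_rng(seed)
    draws = rng.random(len(prob))
    present = frozenset(prob.index[draws < prob.to_numpy()])
    rec_rows = [
        {
            "catchment_id": cid,
            "year": int(rng.integers(1985, 2021)),
            "coordinate_uncertainty_km": float(rng.uniform(0.1, 5.0)),
            "basis_of_record": "human observation",
        }
        for cid in sorted(present)
    ]
    records = pd.DataFrame(
        rec_rows, columns=["catchment_id", "year", "coordinate_uncertainty_km", "basis_of_record"]
    )
    return OccurrenceSet(present=present, records=records)
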