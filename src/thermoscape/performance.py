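"""Thermal performance assessment over scenario ranges.

For every catchment in a scenario's presence set, each life stage's TPC is
evaluated against that catchment's monthly water temperatures (baseline
temperatures for the baseline reference range, future temperatures for the
three dispersal scenarios).  Monthly rates are then aggregated to seasonal,
annual and spawning-season means, latitudinal profiles, and a correlation
between modelled habitat suitability and performance.

Hemispheres are handled throughout: a catchment with centroid latitude >= 0
is northern.  Seasons are named after the northern-hemisphere months
(winter = Dec-Feb, ...); for southern catchments the same month sets are
kept but the label carries the local season in brackets ("winter (summer)").
The spawning season for eggs spans five months: October-February in the
north and April-August in the south, six months out of phase.  Egg rates
are computed only within the spawning season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dispersal import ScenarioRange
from .errors import DataError
from .synthetic_world import CatchmentNetwork, EnvironmentTable
from .traits_tpc import TPC, tpc_evaluate

__all__ = [
    "SeasonDefinition",
    "assemble_surface",
    "monthly_summary",
    "seasonal_summary",
    "latitudinal_profile",
    "suitability_performance_correlation",
]

#: NH season opposite to each named month-set, for southern labels.
_OPPOSITE = {"winter": "summer", "spring": "autumn", "summer": "winter", "autumn": "spring"}


@dataclass(frozen=True)
class SeasonDefinition:
    """Month sets for the four seasons and the hemisphere spawning windows."""

    seasons: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "winter": frozenset({12, 1, 2}),
            "spring": frozenset({3, 4, 5}),
            "summer": frozenset({6, 7, 8}),
            "autumn": frozenset({9, 10, 11}),
        }
    )
    spawning_nh: frozenset = frozenset({10, 11, 12, 1, 2})
    spawning_sh: frozenset = frozenset({4, 5, 6, 7, 8})

    def __post_init__(self) -> None:
        months = sorted(m for s in self.seasons.values() for m in s)
        if months != list(range(1, 13)):
            raise ValueError("the four seasons must partition months 1..12")
        if len(self.spawning_nh) != 5 or len(self.spawning_sh) != 5:
            raise ValueError("spawning seasons must span 5 months")

    def spawning(self, hemisphere: str) -> frozenset:
        return self.spawning_nh if hemisphere == "N" else self.spawning_sh

    def season_of(self, month: int) -> str:
        for name, months in self.seasons.items():
            if month in months:
                return name
        raise ValueError(f"month {month} outside 1..12")


def hemisphere_of(lat: float) -> str:
    return "N" if lat >= 0 else "S"


_SCENARIO_PERIOD = {
    "baseline": "baseline",
    "no_dispersal": "future",
    "free_dispersal": "future",
    "restricted_dispersal": "future",
}

SURFACE_COLUMNS = ["scenario", "catchment_id", "life_stage", "month", "rate", "lat", "hemisphere"]


def assemble_surface(
    ranges: Sequence[ScenarioRange],
    environment: EnvironmentTable,
    tpcs: Mapping[str, TPC],
    network: CatchmentNetwork,
    seasons: SeasonDefinition | None = None,
) -> pd.DataFrame:
    """Survivorship rate per (scenario, catchment, life stage, month).

    The baseline reference range is evaluated against baseline temperatures;
    the dispersal scenarios against future temperatures.  Adult and juvenile
    records cover all 12 months; egg records only the hemisphere-appropriate
    spawning months.
    """
    seasons = seasons or SeasonDefinition()
    lat_of = network.lat_of()
    temps = {p: environment.temps_wide(p) for p in ("baseline", "future")}
    rows = []
    for srange in ranges:
        period = _SCENARIO_PERIOD[srange.scenario]
        wide = temps[period]
        for cid in sorted(srange.present):
            if cid not in wide.index or wide.loc[cid].isna().any():
                raise DataError(
                    f"missing {period} temperature record for catchment {cid}"
                )
            lat = lat_of[cid]
            hemi = hemisphere_of(lat)
            series = wide.loc[cid]
            for stage, tpc in tpcs.items():
                months = (
                    sorted(seasons.spawning(hemi)) if stage == "egg" else range(1, 13)
                )
                for m in months:
                    rows.append(
                        (
                            srange.scenario,
                            cid,
                            stage,
                            int(m),
                            tpc_evaluate(tpc, float(series[m])),
                            lat,
                            hemi,
                        )
                    )
    return pd.DataFrame(rows, columns=SURFACE_COLUMNS)


def _hemisphere_slice(surface: pd.DataFrame, hemisphere: str) -> pd.DataFrame:
    sub = surface[surface["hemisphere"] == hemisphere]
    if sub.empty:
        warnings.warn(f"no surface records in hemisphere {hemisphere!r}; returning empty table")
    return sub


def monthly_summary(surface: pd.DataFrame, hemisphere: str) -> pd.DataFrame:
    """Unweighted mean rate over catchments, per scenario, stage and month."""
    sub = _hemisphere_slice(surface, hemisphere)
    if sub.empty:
        return pd.DataFrame(columns=["scenario", "life_stage", "month", "mean_rate", "n_catchments"])
    out = (
        sub.groupby(["scenario", "life_stage", "month"], as_index=False)
        .agg(mean_rate=("rate", "mean"), n_catchments=("catchment_id", "nunique"))
        .sort_values(["scenario", "life_stage", "month"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def seasonal_summary(
    surface: pd.DataFrame,
    seasons: SeasonDefinition | None = None,
    hemisphere: str = "N",
) -> pd.DataFrame:
    """Seasonal, annual and spawning-season mean rates per scenario and stage.

    Every catchment-month cell weighs equally.  Adult and juvenile rows get
    the four seasons plus an annual row; eggs get a single spawning row.
    Southern rows keep the NH month-set name and carry the local season in
    brackets in the ``label`` column.
    """
    seasons = seasons or SeasonDefinition()
    sub = _hemisphere_slice(surface, hemisphere)
    cols = ["scenario", "life_stage", "timeframe", "label", "mean_rate", "n_cells"]
    if sub.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (scenario, stage), grp in sub.groupby(["scenario", "life_stage"]):
        if stage == "egg":
            rows.append((scenario, stage, "spawning", "spawning", grp["rate"].mean(), len(grp)))
            continue
        for name, months in seasons.seasons.items():
            cells = grp[grp["month"].isin(months)]
            label = name if hemisphere == "N" else f"{name} ({_OPPOSITE[name]})"
            rows.append((scenario, stage, name, label, cells["rate"].mean(), len(cells)))
        rows.append((scenario, stage, "annual", "annual", grp["rate"].mean(), len(grp)))
    return pd.DataFrame(rows, columns=cols)


def latitudinal_profile(surface: pd.DataFrame, bin_width_deg: float = 1.0) -> pd.DataFrame:
    """Mean annual (spawning for eggs) rate per fixed-width latitude bin.

    Each catchment's rate is first averaged over its months, then catchment
    means are averaged within each bin; empty bins are omitted.
    """
    if bin_width_deg <= 0:
        raise ValueError("bin_width_deg must be positive")
    if surface.empty:
        raise DataError("cannot profile an empty performance surface")
    per_catchment = (
        surface.groupby(["scenario", "life_stage", "catchment_id"], as_index=False)
        .agg(annual_rate=("rate", "mean"), lat=("lat", "first"))
    )
    bin_idx = np.floor(per_catchment["lat"] / bin_width_deg)
    per_catchment["lat_bin_center"] = (bin_idx + 0.5) * bin_width_deg
    out = (
        per_catchment.groupby(["scenario", "life_stage", "lat_bin_center"], as_index=False)
        .agg(mean_annual_rate=("annual_rate", "mean"), n_catchments=("catchment_id", "nunique"))
        .sort_values(["scenario", "life_stage", "lat_bin_center"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def suitability_performance_correlation(
    probabilities: pd.Series,
    surface: pd.DataFrame,
    stage: str,
    scenario: str = "baseline",
) -> dict[str, float]:
    """Pearson correlation between habitat suitability and performance.

    Tests the implicit SDM assumption that highly suitable catchments also
    support higher performance.  Pairs are formed over the catchments of the
    given scenario range (baseline presences by default): consensus
    probability against the annual mean rate (adult/juvenile) or the
    spawning-season mean rate (egg — automatic, since egg records only exist
    within the spawning season).
    """
    sub = surface[(surface["scenario"] == scenario) & (surface["life_stage"] == stage)]
    if sub.empty:
        raise DataError(f"no surface records for scenario={scenario!r}, stage={stage!r}")
    perf = sub.groupby("catchment_id")["rate"].mean()
    common = perf.index.intersection(probabilities.index)
    if len(common) < 3:
        raise DataError("need at least 3 paired observations for a correlation")
    x = probabilities.loc[common].to_numpy(dtype=float)
    y = perf.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined: zero variance in suitability or performance")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(common))}
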