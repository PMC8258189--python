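"""Life-stage thermal traits and the thermal performance curve (TPC).

A TPC maps water temperature to survivorship, a rate in [0, 1].  It is
parameterised by three laboratory-derived traits per life stage:

* ``ct_min`` — critical minimum temperature for survival,
* ``t_opt`` — optimum temperature (upper limit of the optimum range),
* ``ct_max`` — critical maximum temperature for survival.

The curve rises slowly below the optimum as a Gaussian with width
``sigma_p = (t_opt - ct_min) / 4`` and drops rapidly above it as a downward
parabola that reaches zero at ``ct_max``:

    P(T) = exp(-((T - t_opt) / (2 * sigma_p))**2)          ct_min <= T <= t_opt
    P(T) = 1 - ((T - t_opt) / (t_opt - ct_max))**2         t_opt  <  T <= ct_max
    P(T) = 0                                               otherwise

The asymmetric shape (slow rise, rapid drop) reflects slower biochemical
reactions at cold temperatures versus protein degradation and oxygen
limitation near the upper thermal limit.  By default performance is clamped
to zero outside [ct_min, ct_max]; the unclamped Gaussian tail below
``ct_min`` (which equals exp(-4) ~ 0.018 at ``ct_min``) can be retained for
sensitivity analysis via ``clamp=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, TraitConsistencyError

__all__ = [
    "LIFE_STAGES",
    "TRAIT_NAMES",
    "ThermalTraits",
    "TPC",
    "finalize_traits",
    "tpc_evaluate",
    "performance_series",
    "read_trait_observations",
    "write_finalized_traits",
]

LIFE_STAGES = ("adult", "juvenile", "egg")
TRAIT_NAMES = ("ct_min", "t_opt", "ct_max")


@dataclass(frozen=True)
class ThermalTraits:
    """Final thermal tolerance traits for one species and life stage (degC)."""

    species: str
    life_stage: str
    ct_min: float
    t_opt: float
    ct_max: float

    def __post_init__(self) -> None:
        if not (self.ct_min < self.t_opt < self.ct_max):
            raise TraitConsistencyError(
                f"{self.species}/{self.life_stage}: require ct_min < t_opt < ct_max, "
                f"got ct_min={self.ct_min}, t_opt={self.t_opt}, ct_max={self.ct_max}"
            )


@dataclass(frozen=True)
class TPC:
    """A thermal performance (survivorship) curve induced by final traits."""

    traits: ThermalTraits
    clamp: bool = True

    @property
    def sigma_p(self) -> float:
        """Width of the Gaussian rise below the optimum: (t_opt - ct_min) / 4."""
        return (self.traits.t_opt - self.traits.ct_min) / 4.0

    def __call__(self, temperature_C):
        return tpc_evaluate(self, temperature_C)

    def unclamped(self) -> "TPC":
        return replace(self, clamp=False)


def finalize_traits(
    observations: pd.DataFrame,
    species: str,
    life_stage: str,
    rule: str = "narrowest",
) -> ThermalTraits:
    """Collapse replicated laboratory observations into final traits.

    Observations come from heterogeneous studies (ILT and CTM methodologies,
    different acclimation regimes).  Under the default ``"narrowest"`` rule
    the final ``ct_min`` is the maximum of the observed minima and the final
    ``ct_max`` the minimum of the observed maxima, i.e. the tolerance window
    every study supports.  ``t_opt`` is the maximum observed optimum (the
    upper limit of the reported optimum range).  ``rule="widest"`` instead
    takes min-of-ct_min / max-of-ct_max.

    Raises
    ------
    DataError
        If any of the three traits has no observation for the stage.
    TraitConsistencyError
        If the aggregated traits violate ct_min < t_opt < ct_max; the message
        names the offending life stage.
    """
    if rule not in ("narrowest", "widest"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    sub = observations[
        (observations["species"] == species) & (observations["life_stage"] == life_stage)
    ]
    values: dict[str, float] = {}
    for trait in TRAIT_NAMES:
        obs = sub.loc[sub["trait"] == trait, "value_C"]
        if obs.empty:
            raise DataError(
                f"no {trait} observation for {species}/{life_stage}; cannot finalize traits"
            )
        if trait == "ct_min":
            values[trait] = float(obs.max() if rule == "narrowest" else obs.min())
        elif trait == "ct_max":
            values[trait] = float(obs.min() if rule == "narrowest" else obs.max())
        else:  # t_opt: upper limit of the reported optimum range
            values[trait] = float(obs.max())
    return ThermalTraits(species=species, life_stage=life_stage, **values)


def tpc_evaluate(tpc: TPC, temperature_C):
    """Survivorship rate(s) in [0, 1] at the given temperature(s).

    Accepts a scalar or array; returns a float for scalar input.  Total over
    all real temperatures: values outside [ct_min, ct_max] map to 0 when the
    curve is clamped (the default).
    """
    tr = tpc.traits
    temp = np.asarray(temperature_C, dtype=float)
    scalar = temp.ndim == 0
    temp = np.atleast_1d(temp)

    rise = np.exp(-(((temp - tr.t_opt) / (2.0 * tpc.sigma_p)) ** 2))
    fall = 1.0 - ((temp - tr.t_opt) / (tr.t_opt - tr.ct_max)) ** 2
    rate = np.where(temp <= tr.t_opt, rise, np.maximum(fall, 0.0))
    if tpc.clamp:
        rate = np.where((temp < tr.ct_min) | (temp > tr.ct_max), 0.0, rate)
    return float(rate[0]) if scalar else rate


def performance_series(tpc: TPC, monthly_temps) -> np.ndarray:
    """Element-wise TPC evaluation over a 12-month temperature series."""
    temps = np.asarray(monthly_temps, dtype=float)
    if temps.shape != (12,):
        raise ValueError(f"expected exactly 12 monthly temperatures, got shape {temps.shape}")
    return tpc_evaluate(tpc, temps)


# ---------------------------------------------------------------------------
# table I/O

_OBS_COLUMNS = ["species", "life_stage", "trait", "value_C", "source"]


def read_trait_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"traits table missing columns: {missing}")
    return df


def write_finalized_traits(traits: list[ThermalTraits], path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "species": t.species,
                "life_stage": t.life_stage,
                "ct_min": t.ct_min,
                "t_opt": t.t_opt,
                "ct_max": t.ct_max,
            }
            for t in traits
        ]
    ).sort_values(["species", "life_stage"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.10g")
    return df
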