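"""CSV/JSON readers and writers for every pipeline table.

Writers sort rows and fix the float format so that identical inputs produce
byte-identical files; readers validate the declared column sets and rebuild
the in-memory domain objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .synthetic_world import CatchmentNetwork, EnvironmentTable, OccurrenceSet, make_edge

FLOAT_FMT = "%.10g"


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing columns: {missing}")


def _write(df: pd.DataFrame, path, sort_by: list[str]) -> None:
    df.sort_values(sort_by, kind="mergesort").to_csv(path, index=False, float_format=FLOAT_FMT)


# -- network ----------------------------------------------------------------

def write_network(network: CatchmentNetwork, outdir: Path) -> None:
    _write(network.catchments, outdir / "catchments.csv", ["catchment_id"])
    edges = pd.DataFrame(sorted(network.edges), columns=["catchment_id_a", "catchment_id_b"])
    edges.to_csv(outdir / "edges.csv", index=False)


def read_network(outdir: Path) -> CatchmentNetwork:
    cat = pd.read_csv(outdir / "catchments.csv")
    _require(cat, ["catchment_id", "region", "area_km2", "lat", "lon"], "catchments.csv")
    edges_df = pd.read_csv(outdir / "edges.csv")
    _require(edges_df, ["catchment_id_a", "catchment_id_b"], "edges.csv")
    edges = frozenset(
        make_edge(a, b) for a, b in zip(edges_df["catchment_id_a"], edges_df["catchment_id_b"])
    )
    return CatchmentNetwork(catchments=cat, edges=edges)


# -- environment ------------------------------------------------------------

def write_environment(env: EnvironmentTable, outdir: Path) -> None:
    _write(env.temperature, outdir / "temps.csv", ["catchment_id", "period", "month"])
    _write(env.covariates, outdir / "covariates.csv", ["catchment_id", "name"])


def read_environment(outdir: Path) -> EnvironmentTable:
    temps = pd.read_csv(outdir / "temps.csv")
    _require(temps, ["catchment_id", "period", "month", "water_temp_C"], "temps.csv")
    cov = pd.read_csv(outdir / "covariates.csv")
    _require(cov, ["catchment_id", "name", "value"], "covariates.csv")
    return EnvironmentTable(temperature=temps, covariates=cov)


# -- dams -------------------------------------------------------------------

def write_dams(dams: frozenset, outdir: Path) -> None:
    df = pd.DataFrame(sorted(dams), columns=["catchment_id_a", "catchment_id_b"])
    df.to_csv(outdir / "dams.csv", index=False)


def read_dams(outdir: Path) -> frozenset:
    df = pd.read_csv(outdir / "dams.csv")
    if df.empty:
        return frozenset()
    _require(df, ["catchment_id_a", "catchment_id_b"], "dams.csv")
    return frozenset(
        make_edge(a, b) for a, b in zip(df["catchment_id_a"], df["catchment_id_b"])
    )


# -- occurrences ------------------------------------------------------------

def write_occurrences(occ: OccurrenceSet, outdir: Path) -> None:
    if occ.records is not None:
        _write(occ.records, outdir / "occurrences.csv", ["catchment_id"])
    else:
        pd.DataFrame({"catchment_id": sorted(occ.present)}).to_csv(
            outdir / "occurrences.csv", index=False
        )


def read_occurrence_records(outdir: Path) -> pd.DataFrame:
    df = pd.read_csv(outdir / "occurrences.csv")
    _require(df, ["catchment_id"], "occurrences.csv")
    return df


# -- json -------------------------------------------------------------------

def write_json(data: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())
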