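"""Future range scenarios on the river network, with dams as barriers.

Three scenarios translate a predicted future range into an attainable one:

* ``no_dispersal`` — the future range equals the current (baseline) range;
  identifies currently occupied catchments exposed to future conditions.
* ``free_dispersal`` — a predicted presence is kept only if its catchment
  is connected through the river network to a catchment with a baseline
  presence (a catchment that is itself a baseline presence trivially
  qualifies via a zero-length path).
* ``restricted_dispersal`` — as free dispersal, but edges carrying a dam
  are removed from the network first, so fragmentation can cut predicted
  habitat off from the current range.

Paths may pass through catchments that are not themselves suitable; only
connectivity to the baseline range matters.  Dams block traversal in both
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import DataError
from .synthetic_world import CatchmentNetwork, OccurrenceSet

__all__ = [
    "SCENARIOS",
    "ScenarioRange",
    "build_connectivity",
    "apply_scenario",
    "range_change",
]

SCENARIOS = ("no_dispersal", "free_dispersal", "restricted_dispersal")

#: Accepted scenario tokens for a performance surface; "baseline" tags the
#: current-period reference range alongside the three future scenarios.
SURFACE_SCENARIOS = ("baseline",) + SCENARIOS


@dataclass(frozen=True)
class ScenarioRange:
    """Presence set attained under one scenario."""

    scenario: str
    present: frozenset

    def __post_init__(self) -> None:
        if self.scenario not in SURFACE_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def n_presences(self) -> int:
        return len(self.present)


def build_connectivity(
    network: CatchmentNetwork, dams: frozenset = frozenset(), barriers_active: bool = False
) -> nx.Graph:
    """Traversal graph: the river network, minus dam edges when barriers act."""
    unknown = set(dams) - set(network.edges)
    if unknown:
        raise DataError(f"dam edges not present in the network: {sorted(unknown)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(network.catchment_ids())
    g.add_edges_from(network.edges - dams if barriers_active else network.edges)
    return g


def apply_scenario(
    predicted: OccurrenceSet | frozenset,
    baseline: OccurrenceSet | frozenset,
    graph: nx.Graph,
    scenario: str,
) -> ScenarioRange:
    """Filter the predicted range by scenario rules on the given graph.

    For the dispersal scenarios the caller passes the graph with or without
    dam edges; the filtering rule itself is identical: keep a predicted
    presence iff its connected component contains a baseline presence.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    pred = predicted.present if isinstance(predicted, OccurrenceSet) else frozenset(predicted)
    base = baseline.present if isinstance(baseline, OccurrenceSet) else frozenset(baseline)
    if scenario == "no_dispersal":
        return ScenarioRange(scenario=scenario, present=base)
    missing = (pred | base) - set(graph.nodes)
    if missing:
        raise DataError(f"catchments absent from the connectivity graph: {sorted(missing)[:5]}")
    comp_of: dict = {}
    for i, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            comp_of[node] = i
    reachable_comps = {comp_of[b] for b in base}
    kept = frozenset(c for c in pred if comp_of[c] in reachable_comps)
    return ScenarioRange(scenario=scenario, present=kept)


def range_change(n_baseline: int, n_scenario: int) -> int:
    """Signed percent change in presence count, rounded to the nearest
    integer (halves away from zero)."""
    if n_baseline <= 0:
        raise ValueError("n_baseline must be positive")
    x = 100.0 * (n_scenario - n_baseline) / n_baseline
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)
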