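"""Translate a predicted future range into attainable ranges.

A predicted presence only counts if the species can reach it: under free
dispersal it must be river-connected to a currently occupied catchment,
under restricted dispersal dam-bearing edges are removed first.
"""

import thermoscape as ts
from thermoscape.synthetic_world import make_edge

network = ts.generate_network(200, 2, seed=1)
env = ts.generate_environment(network, ts.ClimateConfig(), seed=2)
truth = ts.NicheConfig().truth("Salmo synthetica")
baseline = ts.sample_occurrences(network, env, truth, seed=3)
dams = ts.place_dams(network, dam_fraction=0.25, seed=4)

# stand-in predicted future range: presences of a second stochastic draw
predicted = ts.sample_occurrences(network, env, truth, seed=5)

free_graph = ts.build_connectivity(network, dams, barriers_active=False)
dam_graph = ts.build_connectivity(network, dams, barriers_active=True)

n_base = len(baseline.present)
print(f"baseline presences: {n_base}, predicted future: {len(predicted.present)}")
for scenario, graph in (
    ("no_dispersal", free_graph),
    ("free_dispersal", free_graph),
    ("restricted_dispersal", dam_graph),
):
    attained = ts.apply_scenario(predicted, baseline, graph, scenario)
    change = ts.range_change(n_base, attained.n_presences)
    print(f"  {scenario:21s} n={attained.n_presences:3d}  change vs baseline {change:+d}%")
print("(restricted is nested in free: dams can only cut habitat off)")
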