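# thermoscape

Climate-change range forecasting for riverine ectotherms that couples
**species distribution model (SDM) ensembles** with **life-stage thermal
performance curves (TPCs)** on a **catchment network with dispersal
barriers**. The package is aimed at ecologists who want to go beyond
presence/absence projections and ask *how well* a species would actually
perform — month by month, life stage by life stage — in the habitat a
niche model says it could occupy, and whether it can physically get there
through a fragmented river network.

Because the original occurrence/hydrology data sources require large
downloads, the package ships a seeded synthetic-world generator that
reproduces the statistical structure the analysis assumes (dendritic
catchment networks in both hemispheres, seasonal water temperatures with a
warmed future, covariates, dams, replicated trait observations, presences
drawn from a known thermal niche). Every stage is therefore testable
end-to-end, and parameter recovery can be checked against the generating
truth.

## The model

**Thermal performance.** Survivorship as a function of water temperature
*T* is parameterised per life stage (adult, juvenile, egg) by the critical
thermal limits CT<sub>min</sub>, CT<sub>max</sub> and the optimum
T<sub>opt</sub>:

```
P(T) = exp(-((T - Topt) / (2*sigma_p))^2),  sigma_p = (Topt - CTmin)/4     CTmin <= T <= Topt
P(T) = 1 - ((T - Topt) / (Topt - CTmax))^2                                 Topt  <  T <= CTmax
P(T) = 0                                                                   otherwise
```

Final traits are aggregated from replicated laboratory observations
(narrowest-window rule: max of CT<sub>min</sub>, min of CT<sub>max</sub>,
max of T<sub>opt</sub> observations).

**Distribution.** Catchment-level presence/absence is modelled by an
ensemble of four learner families (elastic-net logistic regression, random
forest, gradient boosting, spline-basis additive logistic model), each
tuned by random hyperparameter search under 5-fold CV on a stratified 80%
partition. Predictive skill is validated over repeated stratified 80/20
splits; the presence threshold minimises |sensitivity − specificity| and
skill is summarised by AUC and the true skill statistic
TSS = sensitivity + specificity − 1. Learners with mean validation
AUC > 0.85 are averaged (mean probability) into the consensus.

**Dispersal.** Future ranges are filtered by river connectivity under three
scenarios: *no dispersal* (future range = current range), *free dispersal*
(predicted presences must connect through the network to a currently
occupied catchment), *restricted dispersal* (same, after removing
dam-bearing edges).

**Assessment.** Scenario ranges × monthly temperatures × stage TPCs yield a
performance surface, summarised monthly, seasonally (hemisphere-aware;
southern seasons six months out of phase), annually, over the spawning
season for eggs (Oct–Feb north, Apr–Aug south), along latitude, and as the
Pearson correlation between modelled habitat suitability and performance.

## Worked example

`python examples/05_full_pipeline.py` runs all five stages on a 300-catchment
world (seed 7, reduced validation effort) and prints:

```
outputs in runs/demo:
  consensus mean validation AUC: 0.860
  included learners: ['spline_gam']
  free_dispersal        n=210  change +1%
  no_dispersal          n=208  change +0%
  restricted_dispersal  n=207  change +0%
  NH adult summer survivorship by scenario:
scenario
baseline                0.626
free_dispersal          0.523
no_dispersal            0.456
restricted_dispersal    0.525
  suitability-performance r (adult): 0.74 (p=3.7e-37)
```

Reading this: the ensemble separates occupied from unoccupied catchments
well (AUC 0.86 at this reduced size); warming pushes currently occupied
northern-hemisphere catchments past the adult thermal optimum in summer
(mean survivorship 0.626 → 0.456 if the species cannot move), and dispersal
to newly suitable habitat recovers part of that loss (0.523); habitat
suitability and thermal performance are strongly positively correlated, as
niche-model logic implicitly assumes. The other examples
(`examples/01..04`) exercise each stage in isolation.

The same pipeline is available from the shell:

```bash
thermoscape all --seed 42 --outdir runs/full          # every stage
thermoscape simulate|sdm|scenarios|performance ...    # individual stages
```

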