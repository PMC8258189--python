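"""Fit, validate and apply the consensus species distribution model.

Covariates are screened by univariate AUC and pairwise correlation, four
learner families are tuned by random search with 5-fold CV, validated over
repeated stratified 80/20 splits, and those with mean validation AUC > 0.85
are averaged into the consensus.
"""

import thermoscape as ts

network = ts.generate_network(400, 4, seed=1)
env = ts.generate_environment(network, ts.ClimateConfig(), seed=2)
truth = ts.NicheConfig().truth("Salmo synthetica")
occ = ts.sample_occurrences(network, env, truth, seed=3)

features = ts.assemble_features(env, network, "baseline")
labels = ts.labels_from_occurrences(features, occ)
print(f"{labels.sum()} presences / {len(labels)} catchments")

variables = ts.select_variables(features, labels, whitelist=("altitude", "cropland_frac"))
print(f"selected covariates: {variables}")
X = features[variables]

tuned = [ts.tune_and_fit(s, X, labels, seed=4) for s in ts.default_learner_specs(budget=10)]
report = ts.validate_models(tuned, X, labels, n_splits=10, seed=5)
for t in tuned:
    print(f"  {t.name:14s} holdout AUC {t.holdout_auc:.3f}  mean val AUC {report.mean_auc(t.name):.3f}")

consensus = ts.build_consensus(report, tuned, X, labels, seed=6)
print(f"consensus members: {consensus.member_names}, threshold {consensus.threshold:.3f}")
print("consensus validation:", {m: round(s.mean, 3) for m, s in consensus.validation.items()})

# predicted range today vs under the warmed future covariates
for period in ("baseline", "future"):
    feats = ts.assemble_features(env, network, period)[variables]
    predicted = ts.predict_range(consensus, feats)
    print(f"predicted {period} range: {len(predicted)} catchments")
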