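"""End-to-end orchestration of the five pipeline stages.

Stage order: synthetic world -> trait finalisation -> SDM ensemble ->
dispersal scenarios -> performance assessment.  Each stage reads its inputs
from and writes its outputs to a run directory, so stages can be re-run
individually (as the CLI subcommands do) or chained by :func:`run_pipeline`.
A manifest records the config hash, seed and package version; re-running
with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import derive_seed
from .config import FilterConfig, PipelineConfig, filter_catchments, filter_occurrences
from .dispersal import SCENARIOS, ScenarioRange, apply_scenario, build_connectivity, range_change
from .errors import ThermoscapeError
from .io import (
    FLOAT_FMT,
    read_dams,
    read_environment,
    read_network,
    read_occurrence_records,
    write_dams,
    write_environment,
    write_json,
    write_network,
    write_occurrences,
)
from .performance import (
    SeasonDefinition,
    assemble_surface,
    latitudinal_profile,
    monthly_summary,
    seasonal_summary,
    suitability_performance_correlation,
)
from .sdm_ensemble import (
    assemble_features,
    build_consensus,
    default_learner_specs,
    labels_from_occurrences,
    predict_range,
    select_variables,
    tune_and_fit,
    validate_models,
)
from .synthetic_world import (
    OccurrenceSet,
    generate_environment,
    generate_network,
    generate_traits,
    place_dams,
    sample_occurrences,
)
from .traits_tpc import (
    LIFE_STAGES,
    TPC,
    finalize_traits,
    read_trait_observations,
    write_finalized_traits,
)

logger = logging.getLogger("thermoscape")

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_sdm",
    "stage_scenarios",
    "stage_performance",
]


def _stage_guard(stage: str):
    """Re-raise stage errors with the stage name prepended."""

    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ThermoscapeError):
                raise type(exc)(f"[stage {stage}] {exc}") from exc
            return False

    return _Guard()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    """Generate and write the synthetic world tables."""
    with _stage_guard("simulate"):
        seed = config.seed
        network = generate_network(
            config.world.n_catchments,
            config.world.n_regions,
            derive_seed(seed, "network"),
            min_area_km2=config.filters.min_area_km2,
        )
        network = filter_catchments(network, config.filters.min_area_km2)
        env = generate_environment(network, config.climate, derive_seed(seed, "environment"))
        dams = place_dams(network, config.world.dam_fraction, derive_seed(seed, "dams"))
        truth = config.niche.truth(config.world.species)
        traits = generate_traits(
            truth,
            config.world.n_obs_per_trait,
            config.world.obs_noise_C,
            derive_seed(seed, "traits"),
            species=config.world.species,
        )
        occ = sample_occurrences(network, env, truth, derive_seed(seed, "occurrences"))
        logger.info(
            "simulate: %d catchments, %d edges, %d dams, %d presences",
            len(network.catchments),
            len(network.edges),
            len(dams),
            len(occ),
        )
        write_network(network, outdir)
        write_environment(env, outdir)
        write_dams(dams, outdir)
        traits.sort_values(["life_stage", "trait", "source"], kind="mergesort").to_csv(
            outdir / "traits.csv", index=False, float_format=FLOAT_FMT
        )
        write_occurrences(occ, outdir)


def _finalized_tpcs(config: PipelineConfig, outdir: Path) -> dict[str, TPC]:
    observations = read_trait_observations(outdir / "traits.csv")
    finalized = [
        finalize_traits(observations, config.world.species, stage, rule=config.trait_rule)
        for stage in LIFE_STAGES
    ]
    write_finalized_traits(finalized, outdir / "finalized_traits.csv")
    return {t.life_stage: TPC(t) for t in finalized}


def stage_sdm(config: PipelineConfig, outdir: Path) -> None:
    """Trait finalisation plus the full SDM ensemble fit and prediction."""
    with _stage_guard("sdm"):
        network = read_network(outdir)
        env = read_environment(outdir)
        _finalized_tpcs(config, outdir)

        records = read_occurrence_records(outdir)
        occ = filter_occurrences(records, config.filters)
        features_base = assemble_features(env, network, "baseline")
        labels = labels_from_occurrences(features_base, occ)
        logger.info("sdm: %d catchments, %d presences after filtering", len(labels), labels.sum())

        variables = select_variables(
            features_base,
            labels,
            whitelist=config.sdm.whitelist,
            auc_floor=config.sdm.auc_floor,
            corr_cap=config.sdm.corr_cap,
        )
        logger.info("sdm: selected variables %s", variables)
        X = features_base[variables]

        seed = config.seed
        tuned = [
            tune_and_fit(spec, X, labels, derive_seed(seed, "sdm"))
            for spec in default_learner_specs(budget=config.sdm.tuning_budget)
        ]
        report = validate_models(
            tuned,
            X,
            labels,
            n_splits=config.sdm.n_splits,
            frac=config.sdm.split_frac,
            seed=derive_seed(seed, "sdm-validate"),
        )
        consensus = build_consensus(
            report, tuned, X, labels,
            auc_cutoff=config.sdm.auc_cutoff,
            seed=derive_seed(seed, "sdm-consensus"),
        )
        logger.info(
            "sdm: consensus members %s, threshold %.4f",
            consensus.member_names,
            consensus.threshold,
        )

        report_dict = report.as_dict()
        report_dict["consensus"] = {
            m: s.as_dict() for m, s in consensus.validation.items()
        }
        report_dict["included_learners"] = consensus.member_names
        report_dict["threshold"] = consensus.threshold
        report_dict["selected_variables"] = variables
        report_dict["tuning"] = {
            t.name: {"params": t.params, "cv_auc": t.cv_auc, "holdout_auc": t.holdout_auc}
            for t in tuned
        }
        write_json(report_dict, outdir / "validation_report.json")

        prob_rows = []
        range_rows = []
        for period in ("baseline", "future"):
            feats = assemble_features(env, network, period)[variables]
            probs = consensus.predict_proba(feats)
            for cid, p in probs.items():
                prob_rows.append({"catchment_id": cid, "period": period, "probability": p})
                range_rows.append(
                    {
                        "catchment_id": cid,
                        "period": period,
                        "present": int(p >= consensus.threshold),
                    }
                )
        pd.DataFrame(prob_rows).sort_values(["period", "catchment_id"], kind="mergesort").to_csv(
            outdir / "consensus_probabilities.csv", index=False, float_format=FLOAT_FMT
        )
        pd.DataFrame(range_rows).sort_values(["period", "catchment_id"], kind="mergesort").to_csv(
            outdir / "predicted_range.csv", index=False
        )


def _load_ranges(config: PipelineConfig, outdir: Path) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Baseline occurrence set and the predicted future range from disk."""
    records = read_occurrence_records(outdir)
    baseline = filter_occurrences(records, config.filters)
    pred = pd.read_csv(outdir / "predicted_range.csv")
    future = OccurrenceSet(
        present=frozenset(
            pred.loc[(pred["period"] == "future") & (pred["present"] == 1), "catchment_id"]
        )
    )
    return baseline, future


def stage_scenarios(config: PipelineConfig, outdir: Path) -> None:
    """Apply the three dispersal scenarios and write range accounting."""
    with _stage_guard("scenarios"):
        network = read_network(outdir)
        dams = read_dams(outdir)
        baseline, future = _load_ranges(config, outdir)

        free_graph = build_connectivity(network, dams, barriers_active=False)
        dam_graph = build_connectivity(network, dams, barriers_active=True)
        ranges = {
            "no_dispersal": apply_scenario(future, baseline, free_graph, "no_dispersal"),
            "free_dispersal": apply_scenario(future, baseline, free_graph, "free_dispersal"),
            "restricted_dispersal": apply_scenario(
                future, baseline, dam_graph, "restricted_dispersal"
            ),
        }

        rows = [
            {"scenario": name, "catchment_id": cid}
            for name in SCENARIOS
            for cid in sorted(ranges[name].present)
        ]
        pd.DataFrame(rows, columns=["scenario", "catchment_id"]).to_csv(
            outdir / "scenario_ranges.csv", index=False
        )
        n_base = len(baseline.present)
        summary = {
            "species": config.world.species,
            "n_baseline": n_base,
            "n_predicted_future": len(future.present),
            "scenarios": {
                name: {
                    "n_presences": ranges[name].n_presences,
                    "percent_change": range_change(n_base, ranges[name].n_presences),
                }
                for name in SCENARIOS
            },
        }
        write_json(summary, outdir / "range_summary.json")
        logger.info("scenarios: %s", summary["scenarios"])


def stage_performance(config: PipelineConfig, outdir: Path) -> None:
    """Performance surface, summaries, latitudinal profile and correlation."""
    with _stage_guard("performance"):
        network = read_network(outdir)
        env = read_environment(outdir)
        baseline, _ = _load_ranges(config, outdir)
        finalized = pd.read_csv(outdir / "finalized_traits.csv")
        from .traits_tpc import ThermalTraits

        tpcs = {
            row["life_stage"]: TPC(
                ThermalTraits(
                    species=row["species"],
                    life_stage=row["life_stage"],
                    ct_min=row["ct_min"],
                    t_opt=row["t_opt"],
                    ct_max=row["ct_max"],
                )
            )
            for _, row in finalized.iterrows()
        }
        scen = pd.read_csv(outdir / "scenario_ranges.csv")
        ranges = [ScenarioRange(scenario="baseline", present=baseline.present)] + [
            ScenarioRange(
                scenario=name,
                present=frozenset(scen.loc[scen["scenario"] == name, "catchment_id"]),
            )
            for name in SCENARIOS
        ]
        seasons = SeasonDefinition()
        surface = assemble_surface(ranges, env, tpcs, network, seasons)
        surface.to_csv(outdir / "performance_surface.csv", index=False, float_format=FLOAT_FMT)

        monthly = []
        seasonal = []
        for hemi in ("N", "S"):
            m = monthly_summary(surface, hemi)
            m.insert(0, "hemisphere", hemi)
            monthly.append(m)
            s = seasonal_summary(surface, seasons, hemi)
            s.insert(0, "hemisphere", hemi)
            seasonal.append(s)
        pd.concat(monthly, ignore_index=True).to_csv(
            outdir / "monthly_summary.csv", index=False, float_format=FLOAT_FMT
        )
        pd.concat(seasonal, ignore_index=True).to_csv(
            outdir / "seasonal_summary.csv", index=False, float_format=FLOAT_FMT
        )
        latitudinal_profile(surface, bin_width_deg=1.0).to_csv(
            outdir / "latitudinal_profile.csv", index=False, float_format=FLOAT_FMT
        )

        probs = pd.read_csv(outdir / "consensus_probabilities.csv")
        base_probs = probs[probs["period"] == "baseline"].set_index("catchment_id")["probability"]
        correlations = {
            stage: suitability_performance_correlation(base_probs, surface, stage)
            for stage in LIFE_STAGES
        }
        write_json(correlations, outdir / "correlation.json")


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all five stages into ``outdir`` and write the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, outdir)
    stage_sdm(config, outdir)
    stage_scenarios(config, outdir)
    stage_performance(config, outdir)
    manifest = {
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "thermoscape_version": __version__,
        "seed_scheme": "derive_seed(root, *stage_keys) via numpy SeedSequence + CRC32",
        "config": config.to_dict(),
    }
    write_json(manifest, outdir / "manifest.json")
    return outdir
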