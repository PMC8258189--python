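"""Species distribution model ensemble: variable selection, tuning,
validation, threshold selection, and mean-probability consensus.

The workflow mirrors standard ensemble SDM practice at the catchment scale:

1. Candidate covariates are screened by univariate AUC (floor 0.65) and
   pairwise Pearson correlation (cap 0.7); literature-motivated variables
   can be whitelisted past the AUC floor but must still clear the
   correlation cap.
2. Each learner family is tuned by random search: candidate hyperparameter
   draws are scored by mean AUC over five stratified folds of a stratified
   80% partition, the winner is refit on that partition, and the held-out
   20% provides an independent tuning-test AUC.
3. Predictive accuracy is validated by repeated stratified 80/20 splits
   (100 by default): per split each learner is refit on the calibration
   part, a presence/absence threshold is chosen on calibration predictions
   by minimising |sensitivity - specificity|, and AUC, sensitivity,
   specificity and TSS (= sensitivity + specificity - 1) are measured on
   the validation part.
4. Learners whose mean validation AUC exceeds 0.85 form the consensus:
   occurrence probability is the arithmetic mean of member probabilities,
   binarised at a threshold fit on full-data consensus predictions.

Learner families are pluggable behind a fit/predict-probability contract;
the defaults are regularised logistic regression, random forest,
gradient-boosted trees and a spline-basis additive logistic model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from ._util import derive_seed
from .errors import ConsensusError, DataError, SchemaError
from .synthetic_world import CatchmentNetwork, EnvironmentTable, OccurrenceSet

__all__ = [
    "LearnerSpec",
    "TunedLearner",
    "MetricSummary",
    "ValidationReport",
    "ConsensusModel",
    "assemble_features",
    "select_variables",
    "compute_auc",
    "select_threshold",
    "confusion_metrics",
    "tune_and_fit",
    "validate_models",
    "build_consensus",
    "predict_range",
    "default_learner_specs",
]

METRICS = ("auc", "sensitivity", "specificity", "tss")


# ---------------------------------------------------------------------------
# feature assembly


def assemble_features(
    environment: EnvironmentTable, network: CatchmentNetwork, period: str
) -> pd.DataFrame:
    """Candidate covariate matrix for one period, indexed by catchment.

    Temperature-derived covariates (annual mean, autumn mean, annual range,
    seasonality) are recomputed from the period's monthly series, so future
    features carry the warming signal; static covariates (altitude, land
    cover, discharge) are shared between periods.
    """
    temps = environment.temps_wide(period).reindex(network.catchment_ids())
    if temps.isna().any().any():
        missing = temps.index[temps.isna().any(axis=1)].tolist()
        raise DataError(f"temperature records missing for catchments: {missing[:5]}")
    arr = temps.to_numpy()
    derived = pd.DataFrame(
        {
            "mean_annual_temp": arr.mean(axis=1),
            "mean_autumn_temp": arr[:, 8:11].mean(axis=1),  # Sep-Nov columns
            "annual_temp_range": arr.max(axis=1) - arr.min(axis=1),
            "temp_seasonality": arr.std(axis=1, ddof=0),
        },
        index=temps.index,
    )
    static = environment.covariates_wide().reindex(temps.index)
    features = pd.concat([derived, static], axis=1)
    features.index.name = "catchment_id"
    return features


def labels_from_occurrences(features: pd.DataFrame, occurrences: OccurrenceSet) -> np.ndarray:
    """Binary label vector aligned to the feature rows.

    Every catchment not marked present is treated as an absence: at the
    coarse catchment scale an unrecorded catchment is likely a true absence,
    so no pseudo-absence sampling is performed.
    """
    return features.index.isin(occurrences.present).astype(int)


# ---------------------------------------------------------------------------
# metrics


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("labels must contain both presences and absences")
    return labels


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties count 1/2)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Sensitivity, specificity and TSS at a threshold (present iff score >= t)."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    pos = labels == 1
    sensitivity = float(np.mean(pred[pos]))
    specificity = float(np.mean(~pred[~pos]))
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "tss": sensitivity + specificity - 1.0,
    }


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def select_threshold(scores, labels) -> float:
    """Probability threshold minimising |sensitivity - specificity|.

    Candidates are the midpoints of consecutive sorted unique scores plus
    one candidate below the minimum and one above the maximum.  Ties are
    broken by larger TSS, then by larger threshold.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    cands = _threshold_candidates(scores)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    # count of scores >= t via searchsorted on the sorted class scores
    sens = (len(pos) - np.searchsorted(pos, cands, side="left")) / len(pos)
    spec = np.searchsorted(neg, cands, side="left") / len(neg)
    diff = np.abs(sens - spec)
    tss = sens + spec - 1.0
    # lexicographic: min diff, then max tss, then max threshold
    order = np.lexsort((-cands, -tss, diff))
    return float(cands[order[0]])


# ---------------------------------------------------------------------------
# variable selection


def univariate_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Direction-free univariate AUC: max(AUC, 1 - AUC) of the raw covariate."""
    a = compute_auc(values, labels)
    return max(a, 1.0 - a)


def select_variables(
    candidates: pd.DataFrame,
    labels,
    whitelist: Sequence[str] = (),
    auc_floor: float = 0.65,
    corr_cap: float = 0.7,
) -> list[str]:
    """Greedy covariate screen by univariate AUC and pairwise correlation.

    Candidates are visited in order of descending univariate AUC (name as a
    deterministic tie-break).  A variable is retained if it clears the AUC
    floor or is whitelisted, and its absolute Pearson correlation with every
    already-retained variable is below the cap.  Whitelisted variables are
    exempt from the floor only, never from the correlation cap.
    """
    if candidates.shape[1] == 0:
        raise DataError("no candidate variables supplied")
    labels = _check_two_classes(labels)
    aucs = {c: univariate_auc(candidates[c].to_numpy(), labels) for c in candidates.columns}
    ordered = sorted(candidates.columns, key=lambda c: (-aucs[c], c))
    corr = candidates.corr(method="pearson").abs()
    selected: list[str] = []
    for name in ordered:
        if aucs[name] < auc_floor and name not in whitelist:
            continue
        if all(corr.loc[name, kept] < corr_cap for kept in selected):
            selected.append(name)
    return selected


# ---------------------------------------------------------------------------
# learners


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family: estimator builder plus a hyperparameter search space."""

    name: str
    builder: Callable[..., object]  # builder(random_state=..., **params) -> estimator
    param_space: Mapping[str, Sequence]
    budget: int = 30

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("tuning budget must be >= 1")

    def space_size(self) -> int:
        size = 1
        for values in self.param_space.values():
            size *= len(values)
        return size

    def enumerate_space(self) -> list[dict]:
        keys = list(self.param_space)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.param_space[k] for k in keys))
        ]


@dataclass
class TunedLearner:
    """A learner family with its tuned hyperparameters and tuning scores."""

    name: str
    spec: LearnerSpec
    params: dict
    estimator: object  # fitted on the 80% tuning partition
    cv_auc: float
    holdout_auc: float

    def fit_new(self, features: pd.DataFrame, labels: np.ndarray, random_state: int):
        est = self.spec.builder(random_state=random_state, **self.params)
        est.fit(features.to_numpy(), np.asarray(labels))
        return est


def _proba(estimator, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    return estimator.predict_proba(X)[:, 1]


def _build_logistic(random_state: int, C: float = 1.0, l1_ratio: float = 0.5) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegression(
                    solver="saga",
                    C=C,
                    l1_ratio=l1_ratio,
                    max_iter=5000,
                    random_state=random_state,
                ),
            ),
        ]
    )


def _build_spline_gam(random_state: int, n_knots: int = 6, C: float = 1.0) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=n_knots, degree=3)),
            ("clf", LogisticRegression(C=C, max_iter=2000, random_state=random_state)),
        ]
    )


def default_learner_specs(budget: int = 30) -> list[LearnerSpec]:
    """The four default learner families behind the ensemble.

    A tractable stand-in set for the larger model zoos used in large-scale
    SDM studies; the consensus mechanics are agnostic to the families.
    """
    return [
        LearnerSpec(
            name="elastic_logit",
            builder=_build_logistic,
            param_space={"C": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.0, 0.25, 0.5, 0.75, 1.0]},
            budget=budget,
        ),
        LearnerSpec(
            name="random_forest",
            builder=lambda random_state, **p: RandomForestClassifier(
                random_state=random_state, **p
            ),
            param_space={
                "n_estimators": [100, 200],
                "max_depth": [None, 4, 8, 16],
                "max_features": ["sqrt", 0.5, 1.0],
                "min_samples_leaf": [1, 3, 5],
            },
            budget=budget,
        ),
        LearnerSpec(
            name="gbm",
            builder=lambda random_state, **p: GradientBoostingClassifier(
                random_state=random_state, **p
            ),
            param_space={
                "n_estimators": [100, 200],
                "learning_rate": [0.03, 0.1, 0.3],
                "max_depth": [2, 3, 4],
                "subsample": [0.7, 1.0],
            },
            budget=budget,
        ),
        LearnerSpec(
            name="spline_gam",
            builder=_build_spline_gam,
            param_space={"n_knots": [4, 6, 8], "C": [0.1, 1.0, 10.0]},
            budget=budget,
        ),
    ]


def tune_and_fit(
    spec: LearnerSpec, features: pd.DataFrame, labels, seed: int
) -> TunedLearner:
    """Random hyperparameter search with 5-fold CV on a stratified 80% split.

    Draws ``spec.budget`` distinct configurations (capped with a warning at
    the size of the enumerable space), scores each by mean AUC over five
    stratified folds of the 80% tuning partition, refits the best on the
    full 80%, and reports AUC on the withheld 20%.
    """
    labels = _check_two_classes(labels)
    X = features
    space = spec.enumerate_space()
    n_draw = spec.budget
    if n_draw > len(space):
        warnings.warn(
            f"{spec.name}: tuning budget {spec.budget} exceeds enumerable space "
            f"({len(space)} configurations); evaluating all of them"
        )
        n_draw = len(space)
    rng = np.random.default_rng(derive_seed(seed, "tune", spec.name))
    draw_idx = rng.choice(len(space), size=n_draw, replace=False)

    idx_train, idx_hold = train_test_split(
        np.arange(len(X)),
        test_size=0.2,
        stratify=labels,
        random_state=derive_seed(seed, "tune-split", spec.name),
    )
    X_train, y_train = X.iloc[idx_train], labels[idx_train]
    X_hold, y_hold = X.iloc[idx_hold], labels[idx_hold]

    folds = StratifiedKFold(
        n_splits=5, shuffle=True, random_state=derive_seed(seed, "tune-cv", spec.name)
    )
    fold_indices = list(folds.split(X_train, y_train))
    best: tuple[float, int, dict] | None = None
    for rank, i in enumerate(draw_idx):
        params = space[i]
        fold_aucs = []
        for tr, te in fold_indices:
            est = spec.builder(
                random_state=derive_seed(seed, "tune-fit", spec.name), **params
            )
            est.fit(X_train.iloc[tr].to_numpy(), y_train[tr])
            fold_aucs.append(compute_auc(_proba(est, X_train.iloc[te]), y_train[te]))
        mean_auc = float(np.mean(fold_aucs))
        # deterministic tie-break: first drawn configuration wins
        if best is None or mean_auc > best[0]:
            best = (mean_auc, rank, params)

    cv_auc, _, best_params = best
    final = spec.builder(random_state=derive_seed(seed, "tune-final", spec.name), **best_params)
    final.fit(X_train.to_numpy(), y_train)
    holdout_auc = compute_auc(_proba(final, X_hold), y_hold)
    return TunedLearner(
        name=spec.name,
        spec=spec,
        params=dict(best_params),
        estimator=final,
        cv_auc=cv_auc,
        holdout_auc=holdout_auc,
    )


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class MetricSummary:
    min: float
    mean: float
    max: float

    @classmethod
    def of(cls, values: Sequence[float]) -> "MetricSummary":
        arr = np.asarray(values, dtype=float)
        lo, hi = float(arr.min()), float(arr.max())
        # pairwise summation can land the mean one ULP outside [min, max]
        mean = float(np.clip(arr.mean(), lo, hi))
        return cls(min=lo, mean=mean, max=hi)

    def as_dict(self) -> dict[str, float]:
        return {"min": self.min, "mean": self.mean, "max": self.max}


@dataclass
class ValidationReport:
    """Min/mean/max of AUC, sensitivity, specificity and TSS over splits.

    Stores the per-split calibration/validation probabilities so consensus
    metrics can be recomputed for any member subset without refitting.
    """

    learners: dict[str, dict[str, MetricSummary]]
    consensus: dict[str, MetricSummary]
    n_splits: int
    split_frac: float
    _split_cache: dict = field(default_factory=dict, repr=False)

    def mean_auc(self, name: str) -> float:
        return self.learners[name]["auc"].mean

    def consensus_summary(self, member_names: Sequence[str]) -> dict[str, MetricSummary]:
        """Consensus metrics recomputed over a member subset from cached splits."""
        per_metric: dict[str, list[float]] = {m: [] for m in METRICS}
        for s in range(self.n_splits):
            cache = self._split_cache[s]
            cal = np.mean([cache["cal_probs"][n] for n in member_names], axis=0)
            val = np.mean([cache["val_probs"][n] for n in member_names], axis=0)
            thr = select_threshold(cal, cache["y_cal"])
            per_metric["auc"].append(compute_auc(val, cache["y_val"]))
            cm = confusion_metrics(val, cache["y_val"], thr)
            for m in ("sensitivity", "specificity", "tss"):
                per_metric[m].append(cm[m])
        return {m: MetricSummary.of(v) for m, v in per_metric.items()}

    def as_dict(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "split_frac": self.split_frac,
            "learners": {
                name: {m: s.as_dict() for m, s in metrics.items()}
                for name, metrics in self.learners.items()
            },
            "consensus": {m: s.as_dict() for m, s in self.consensus.items()},
        }


def validate_models(
    learners: Sequence[TunedLearner],
    features: pd.DataFrame,
    labels,
    n_splits: int = 100,
    frac: float = 0.8,
    seed: int = 0,
) -> ValidationReport:
    """Repeated stratified calibration/validation splits.

    Per split: refit every learner on the calibration fraction, choose the
    presence threshold on calibration predictions, and score AUC,
    sensitivity, specificity and TSS on the validation fraction.  The
    consensus row averages member probabilities before thresholding.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    labels = _check_two_classes(labels)
    names = [l.name for l in learners]
    per_learner: dict[str, dict[str, list[float]]] = {
        n: {m: [] for m in METRICS} for n in names
    }
    cache: dict[int, dict] = {}

    for s in range(n_splits):
        idx_cal, idx_val = train_test_split(
            np.arange(len(features)),
            train_size=frac,
            stratify=labels,
            random_state=derive_seed(seed, "validate", s),
        )
        X_cal, y_cal = features.iloc[idx_cal], labels[idx_cal]
        X_val, y_val = features.iloc[idx_val], labels[idx_val]
        cal_probs: dict[str, np.ndarray] = {}
        val_probs: dict[str, np.ndarray] = {}
        for learner in learners:
            est = learner.fit_new(X_cal, y_cal, derive_seed(seed, "validate-fit", learner.name, s))
            cal_probs[learner.name] = _proba(est, X_cal)
            val_probs[learner.name] = _proba(est, X_val)
            thr = select_threshold(cal_probs[learner.name], y_cal)
            per_learner[learner.name]["auc"].append(
                compute_auc(val_probs[learner.name], y_val)
            )
            cm = confusion_metrics(val_probs[learner.name], y_val, thr)
            for m in ("sensitivity", "specificity", "tss"):
                per_learner[learner.name][m].append(cm[m])
        cache[s] = {
            "cal_probs": cal_probs,
            "val_probs": val_probs,
            "y_cal": y_cal,
            "y_val": y_val,
        }

    report = ValidationReport(
        learners={
            n: {m: MetricSummary.of(v) for m, v in metrics.items()}
            for n, metrics in per_learner.items()
        },
        consensus={},
        n_splits=n_splits,
        split_frac=frac,
        _split_cache=cache,
    )
    report.consensus = report.consensus_summary(names)
    return report


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusModel:
    """Mean-probability ensemble of the learners that cleared the AUC cutoff."""

    members: list[tuple[str, object]]  # (name, estimator fitted on full data)
    threshold: float
    variables: list[str]
    auc_cutoff: float
    validation: dict[str, MetricSummary]

    @property
    def member_names(self) -> list[str]:
        return [n for n, _ in self.members]

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        missing = [v for v in self.variables if v not in features.columns]
        if missing:
            raise SchemaError(f"feature table missing selected variables: {missing}")
        X = features[self.variables]
        probs = np.mean([_proba(est, X) for _, est in self.members], axis=0)
        return pd.Series(probs, index=features.index, name="probability")


def build_consensus(
    report: ValidationReport,
    learners: Sequence[TunedLearner],
    features: pd.DataFrame,
    labels,
    auc_cutoff: float = 0.85,
    seed: int = 0,
) -> ConsensusModel:
    """Assemble the consensus from learners with mean validation AUC > cutoff.

    Members are refit on the full data; the binarisation threshold is chosen
    on the full-data consensus probabilities.  Raises ConsensusError if no
    learner clears the cutoff (review the cutoff or the learner set).
    """
    labels = _check_two_classes(labels)
    members = [l for l in learners if report.mean_auc(l.name) > auc_cutoff]
    if not members:
        raise ConsensusError(
            f"no learner exceeded mean validation AUC {auc_cutoff}; "
            "review auc_cutoff or the learner set"
        )
    fitted = [
        (l.name, l.fit_new(features, labels, derive_seed(seed, "consensus-fit", l.name)))
        for l in members
    ]
    model = ConsensusModel(
        members=fitted,
        threshold=0.5,  # placeholder until computed below
        variables=list(features.columns),
        auc_cutoff=auc_cutoff,
        validation=report.consensus_summary([l.name for l in members]),
    )
    probs = model.predict_proba(features)
    model.threshold = select_threshold(probs.to_numpy(), labels)
    return model


def predict_range(consensus: ConsensusModel, features: pd.DataFrame) -> OccurrenceSet:
    """Catchments whose consensus probability reaches the threshold."""
    probs = consensus.predict_proba(features)
    present = frozenset(probs.index[probs.to_numpy() >= consensus.threshold])
    return OccurrenceSet(present=present)
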