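"""Gradient-boosted risk-factor identification for significant transitions.

For one significant transition cell, children from the same source
cluster are split into a "transition of interest" class (destination =
the flagged elevated cluster) and a "control transition" class
(destination = non-elevated).  A regularised XGBoost classifier is
tuned by exhaustive grid search (5-fold stratified CV, combined
accuracy/F1 score, scale_pos_weight fixed to the inverse class ratio)
on an 80/20 stratified split, after a participant-level missingness
filter, train-fitted KNN imputation, and train-fitted min-max scaling.
Candidate risk factors are the features passing a gain-importance
threshold sweep (refit on train, scored on test) AND whose permutation
importance on the test split exceeds a zero-gain noise floor; the
intersection is reported as "genuine".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import MinMaxScaler
from xgboost import XGBClassifier

__all__ = [
    "ModelConfig",
    "TransitionContrast",
    "RiskFactorResult",
    "build_contrast",
    "filter_missingness",
    "split_train_test",
    "impute_knn",
    "scale_minmax",
    "tune_model",
    "gain_importance",
    "select_by_threshold",
    "permutation_survival",
    "genuine_risk_factors",
    "identify_risk_factors",
]


def _default_grid() -> dict[str, list]:
    return {
        "n_estimators": [100, 200],
        "learning_rate": [0.1, 0.3],
        "max_depth": [3, 5],
        "min_child_weight": [1],
        "gamma": [0.0],
        "reg_alpha": [0.0, 1.0],
    }


@dataclass
class ModelConfig:
    """Hyperparameter grid and pipeline settings."""

    grid: dict[str, list] = field(default_factory=_default_grid)
    cv_folds: int = 5
    test_fraction: float = 0.2
    missingness_threshold: float = 0.30
    knn_k: int = 5
    permutation_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        for key, values in self.grid.items():
            if not values:
                raise ValueError(f"empty grid for {key!r}")


@dataclass
class TransitionContrast:
    """Binary outcome for one transition cell: 1 = transition of
    interest (elevated destination), 0 = control (non-elevated)."""

    source: object
    destination: object
    control: object
    child_ids: np.ndarray
    outcomes: np.ndarray


@dataclass
class RiskFactorResult:
    """Per-feature importances and flags plus held-out model metrics."""

    table: pd.DataFrame  # index: feature; gain, mean_drop, selected, survives, genuine
    accuracy: float
    f1: float
    best_params: dict
    contrast: TransitionContrast | None = None

    @property
    def genuine(self) -> list[str]:
        return list(self.table.index[self.table["genuine"]])


def build_contrast(
    linked: pd.DataFrame,
    source,
    destination,
    non_elevated,
) -> TransitionContrast:
    """Assemble the binary outcome for one flagged cell.

    ``linked`` is a :func:`~sdqtransitions.transitions.link_waves` table.
    Children from ``source`` going to ``destination`` are positives,
    those going to ``non_elevated`` are controls; any other destination
    is excluded from the contrast.
    """
    cell = linked[linked["group_source"] == source]
    pos = cell[cell["group_dest"] == destination]
    neg = cell[cell["group_dest"] == non_elevated]
    if len(pos) == 0:
        raise ValueError("transition-of-interest class is empty")
    if len(neg) == 0:
        raise ValueError("control-transition class is empty")
    ids = np.concatenate([pos["child_id"].to_numpy(), neg["child_id"].to_numpy()])
    outcomes = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return TransitionContrast(source, destination, non_elevated, ids, outcomes)


def filter_missingness(
    covariates: pd.DataFrame, threshold: float = 0.30
) -> pd.DataFrame:
    """Drop participants missing more than ``threshold`` of the features
    (strictly more; a child at exactly the threshold is retained)."""
    features = [c for c in covariates.columns if c != "child_id"]
    frac = covariates[features].isna().mean(axis=1)
    return covariates.loc[frac <= threshold].reset_index(drop=True)


def split_train_test(
    X: pd.DataFrame,
    y: np.ndarray,
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified train/test split (train first in the return order)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=fraction, stratify=y, random_state=seed
    )
    return X_train, X_test, y_train, y_test


def impute_knn(
    train: pd.DataFrame, test: pd.DataFrame, k: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KNN-impute missing cells; the imputer is fit on train only."""
    all_missing = [c for c in train.columns if train[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping features with no observed train values: {all_missing}")
        train = train.drop(columns=all_missing)
        test = test.drop(columns=all_missing)
    imputer = KNNImputer(n_neighbors=k)
    train_imp = pd.DataFrame(
        imputer.fit_transform(train), columns=train.columns, index=train.index
    )
    test_imp = pd.DataFrame(
        imputer.transform(test), columns=test.columns, index=test.index
    )
    return train_imp, test_imp


def scale_minmax(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max scale with train-fitted bounds; test values may leave
    [0, 1]; constant train features map to 0 with a warning."""
    constant = [c for c in train.columns if train[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"constant train features mapped to 0: {constant}")
    scaler = MinMaxScaler(clip=False)
    train_s = pd.DataFrame(
        scaler.fit_transform(train), columns=train.columns, index=train.index
    )
    test_s = pd.DataFrame(
        scaler.transform(test), columns=test.columns, index=test.index
    )
    return train_s, test_s


def _combined_score(y_true, y_pred) -> float:
    return 0.5 * (accuracy_score(y_true, y_pred) + f1_score(y_true, y_pred, zero_division=0))


def _classifier(params: dict, y_train: np.ndarray, seed: int) -> XGBClassifier:
    n_pos = int(np.sum(y_train == 1))
    n_neg = int(np.sum(y_train == 0))
    return XGBClassifier(
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        scale_pos_weight=n_neg / n_pos,
        **params,
    )


def tune_model(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    config: ModelConfig,
) -> tuple[dict, XGBClassifier, pd.DataFrame]:
    """Exhaustive grid search with stratified 5-fold CV.

    The selection score is the unweighted mean of accuracy and F1; the
    positive-class weight is fixed to n_negative/n_positive throughout.
    Returns the winning parameters, the model refit on the full train
    split, and the CV score table.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training outcome must contain both classes")
    keys = sorted(config.grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(config.grid[k] for k in keys))]
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    rows = []
    best_score, best_params = -np.inf, None
    for params in combos:
        scores = []
        for tr_idx, va_idx in skf.split(X_train, y_train):
            model = _classifier(params, y_train[tr_idx], config.seed)
            model.fit(X_train.iloc[tr_idx], y_train[tr_idx])
            pred = model.predict(X_train.iloc[va_idx])
            scores.append(_combined_score(y_train[va_idx], pred))
        mean_score = float(np.mean(scores))
        rows.append({**params, "cv_score": mean_score})
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    final = _classifier(best_params, y_train, config.seed)
    final.fit(X_train, y_train)
    return best_params, final, pd.DataFrame(rows)


def gain_importance(model: XGBClassifier, feature_names=None) -> pd.Series:
    """Per-feature gain importance; features never split on get gain 0."""
    booster = model.get_booster()
    raw = booster.get_score(importance_type="gain")
    if feature_names is None:
        feature_names = model.feature_names_in_
    gains = pd.Series(0.0, index=list(feature_names))
    for key, val in raw.items():
        name = key if key in gains.index else list(feature_names)[int(key[1:])]
        gains[name] = float(val)
    return gains


def select_by_threshold(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    gains: pd.Series,
    best_params: dict,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Sweep gain thresholds, refitting on train and scoring on test.

    For each distinct gain value the features at or above it are kept,
    the model refit on the train split, and the combined accuracy/F1
    computed on the test split; the best-scoring feature set wins, ties
    broken toward fewer features.  All-zero gains yield an empty
    selection with a warning.
    """
    if (gains <= 0).all():
        warnings.warn("all gain importances are zero; no features selected")
        return [], pd.DataFrame(columns=["threshold", "n_features", "score"])
    thresholds = sorted(set(gains[gains > 0]), reverse=True)
    rows = []
    best = (-np.inf, np.inf, None)  # (score, n_features, set)
    for t in thresholds:
        selected = list(gains.index[gains >= t])
        model = _classifier(best_params, y_train, seed)
        model.fit(X_train[selected], y_train)
        score = _combined_score(y_test, model.predict(X_test[selected]))
        rows.append({"threshold": t, "n_features": len(selected), "score": score})
        if (score, -len(selected)) > (best[0], -best[1]):
            best = (score, len(selected), selected)
    return best[2], pd.DataFrame(rows)


def permutation_survival(
    model: XGBClassifier,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    gains: pd.Series,
    repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean test-accuracy drop per shuffled feature, with a survival flag.

    Each feature's test column is shuffled ``repeats`` times and the mean
    accuracy decrease recorded.  A feature survives when its mean drop is
    positive and exceeds a noise floor: the larger of (a) the 95th
    percentile of the drops observed for zero-gain features and (b) an
    empirical-null floor mirrored from the negative drops (shuffling a
    non-informative feature perturbs accuracy symmetrically around zero,
    so the magnitudes of the negative drops calibrate chance).  Boosted
    ensembles typically give every feature a little gain, leaving the
    zero-gain set empty; the mirrored floor keeps the criterion
    calibrated in that case.
    """
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    perm = permutation_importance(
        model,
        X_test,
        np.asarray(y_test),
        scoring="accuracy",
        n_repeats=repeats,
        random_state=seed,
        n_jobs=1,
    )
    drops = pd.Series(perm.importances_mean, index=X_test.columns)
    zero_gain = gains.index[gains == 0]
    floor = float(np.percentile(drops[zero_gain], 95)) if len(zero_gain) else 0.0
    # the mirrored floor is estimated from only ~half the features, so it
    # uses the 1% tail of the empirical null rather than 5%
    negative = drops[drops < 0]
    if len(negative):
        floor = max(floor, float(np.percentile(-negative, 99)))
    floor = max(floor, 0.0)
    return pd.DataFrame(
        {"mean_drop": drops, "survives": (drops > 0) & (drops > floor)}
    )


def genuine_risk_factors(
    gains: pd.Series,
    selected: list[str],
    permutation: pd.DataFrame,
    accuracy: float,
    f1: float,
    best_params: dict,
    contrast: TransitionContrast | None = None,
    no_information_rate: float | None = None,
) -> RiskFactorResult:
    """Intersect threshold-selected features with permutation survivors.

    If ``no_information_rate`` (the majority-class share of the test
    split) is given and the model's test accuracy does not beat it, no
    feature is flagged genuine: a model that cannot outperform the
    trivial classifier provides no evidence for any risk factor.
    """
    table = pd.DataFrame({"gain": gains})
    table["mean_drop"] = permutation["mean_drop"]
    table["selected"] = table.index.isin(selected)
    table["survives"] = permutation["survives"].reindex(table.index).fillna(False)
    table["genuine"] = table["selected"] & table["survives"]
    if no_information_rate is not None and accuracy <= no_information_rate:
        table["genuine"] = False
    table = table.sort_values("gain", ascending=False)
    return RiskFactorResult(
        table=table, accuracy=accuracy, f1=f1, best_params=best_params, contrast=contrast
    )


def identify_risk_factors(
    covariates: pd.DataFrame,
    contrast: TransitionContrast,
    config: ModelConfig | None = None,
) -> RiskFactorResult:
    """Full per-cell pipeline: filter, split, impute, scale, tune,
    threshold sweep, permutation survival.

    ``covariates`` is a child-level table with a ``child_id`` column; all
    other columns are candidate features (categoricals already encoded).
    Imputation and scaling parameters are functions of the train split
    only.  The reported accuracy/F1 come from the selected-feature model
    on the test split (the sweep's own optimistic selection — flagged in
    the method docs).
    """
    if config is None:
        config = ModelConfig()
    cov = filter_missingness(covariates, config.missingness_threshold)
    cov = cov.set_index("child_id")
    keep = pd.Index(contrast.child_ids).intersection(cov.index)
    order = [i for i, cid in enumerate(contrast.child_ids) if cid in set(keep)]
    X = cov.loc[contrast.child_ids[order]]
    y = contrast.outcomes[order]

    X_train, X_test, y_train, y_test = split_train_test(
        X, y, fraction=config.test_fraction, seed=config.seed
    )
    X_train, X_test = impute_knn(X_train, X_test, k=config.knn_k)
    X_train, X_test = scale_minmax(X_train, X_test)

    best_params, model, _cv = tune_model(X_train, y_train, config)
    gains = gain_importance(model)
    selected, _sweep = select_by_threshold(
        X_train, y_train, X_test, y_test, gains, best_params, seed=config.seed
    )
    perm = permutation_survival(
        model, X_test, y_test, gains, repeats=config.permutation_repeats, seed=config.seed
    )
    if selected:
        refit = _classifier(best_params, y_train, config.seed)
        refit.fit(X_train[selected], y_train)
        pred = refit.predict(X_test[selected])
    else:
        pred = model.predict(X_test)
    acc = accuracy_score(y_test, pred)
    f1 = f1_score(y_test, pred, zero_division=0)
    nir = max(np.mean(y_test), 1 - np.mean(y_test))
    return genuine_risk_factors(
        gains, selected, perm, acc, f1, best_params, contrast,
        no_information_rate=float(nir),
    )
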