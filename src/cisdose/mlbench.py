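"""Model-comparison harness for exposure-effect exploration.

The procedure, not any individual learner, is the point: preprocess
(one-hot categoricals, min-max numerics learned on the training partition),
split 70/30 stratified on the response, tune each of eight classifier
families by random hyperparameter search under five-fold cross-validated
accuracy, refit the winning configuration per family, score every family
on the held-out test set (accuracy / recall / precision, positive class =
clinical benefit), and quantify feature relevance on the best model by
permutation importance (mean and SD of the accuracy drop over five seeded
permutations per feature).

The classifier families are scikit-learn / xgboost estimators behind a
uniform adapter; the "generalized linear model" family (lambda/alpha
hyperparameters) maps to elastic-net-penalized logistic regression and
the "logistic regression" family (step-size hyperparameter) to SGD
logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "FeatureTable",
    "preprocess",
    "stratified_split",
    "benchmark",
    "permutation_importance",
    "MODEL_FAMILIES",
]

DEFAULT_SEARCH_BUDGET = 20   # random configurations per family
DEFAULT_CV_FOLDS = 5
DEFAULT_REPEATS = 5          # permutation-importance repeats


@dataclass
class FeatureTable:
    """Encoded design matrix with the response and fitted scaling."""

    X: pd.DataFrame
    y: pd.Series
    numeric_columns: list
    scaling: dict  # column -> (min, max) learned on the fit partition


# ---------------------------------------------------------------------------
# preprocessing & split
# ---------------------------------------------------------------------------

def preprocess(raw: pd.DataFrame, response: str = "clinical_benefit",
               fit_index=None) -> FeatureTable:
    """One-hot categoricals and min-max numerics into [0, 1].

    Min-max parameters are learned on ``fit_index`` rows only (all rows when
    omitted) and applied everywhere; a constant column maps to 0.

    Raises
    ------
    ValueError
        On missing responses or a non-numeric value in a numeric column.
    """
    if raw[response].isna().any():
        raise ValueError("missing response values are not allowed")
    y = raw[response].astype(bool)
    feats = raw.drop(columns=[response])
    if "patient_id" in feats.columns:
        feats = feats.drop(columns=["patient_id"])

    numeric_cols, categorical_cols = [], []
    for col in feats.columns:
        dtype = feats[col].dtype
        if dtype.name in ("category", "bool"):
            categorical_cols.append(col)
        elif dtype == object:
            # mostly-numeric object columns are numeric with parse errors;
            # genuinely textual columns are categorical
            coerced = pd.to_numeric(feats[col], errors="coerce")
            numeric_frac = coerced.notna().mean()
            if numeric_frac == 1.0:
                feats[col] = coerced
                numeric_cols.append(col)
            elif numeric_frac >= 0.5:
                row = int(np.argmax(coerced.isna().values))
                raise ValueError(
                    f"non-numeric value {feats[col].iloc[row]!r} in numeric "
                    f"column {col!r} at row {row}"
                )
            else:
                categorical_cols.append(col)
        else:
            numeric_cols.append(col)

    fit_rows = feats if fit_index is None else feats.loc[fit_index]
    scaling = {}
    out = {}
    for col in numeric_cols:
        lo, hi = float(fit_rows[col].min()), float(fit_rows[col].max())
        scaling[col] = (lo, hi)
        if hi > lo:
            out[col] = (feats[col].astype(float) - lo) / (hi - lo)
        else:
            out[col] = pd.Series(0.0, index=feats.index)
    X = pd.DataFrame(out, index=feats.index)
    for col in categorical_cols:
        dummies = pd.get_dummies(feats[col].astype(str), prefix=col, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return FeatureTable(X=X, y=y, numeric_columns=numeric_cols, scaling=scaling)


def stratified_split(table: FeatureTable, train_fraction: float = 0.7,
                     seed: int = 0):
    """70/30 split stratified on the response; reproducible by seed."""
    counts = table.y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both response classes need at least 2 members "
                         "for a stratified split")
    idx_train, idx_test = train_test_split(
        table.X.index, train_size=train_fraction, stratify=table.y.values,
        random_state=int(seed) % (2 ** 32),
    )
    return idx_train, idx_test


# ---------------------------------------------------------------------------
# model families and their searched hyperparameters
# ---------------------------------------------------------------------------

def _sample_params(family: str, rng: np.random.Generator) -> dict:
    if family == "naive_bayes":
        return {"var_smoothing": float(10.0 ** rng.uniform(-11, -5))}
    if family == "logistic_regression":
        return {"eta0": float(10.0 ** rng.uniform(-3, 0))}
    if family == "neural_network":
        n_layers = int(rng.integers(1, 4))
        n_units = int(rng.integers(4, 33))
        return {"hidden_layer_sizes": (n_units,) * n_layers}
    if family == "decision_tree":
        return {"min_samples_leaf": int(rng.integers(1, 13))}
    if family == "gradient_boosted_trees":
        return {"n_estimators": int(rng.integers(20, 301))}
    if family == "random_forest":
        return {"max_depth": int(rng.integers(2, 11)),
                "n_estimators": int(rng.integers(20, 301)),
                "min_samples_leaf": int(rng.integers(1, 9))}
    if family == "xgboost":
        return {"learning_rate": float(10.0 ** rng.uniform(-2, -0.3)),
                "max_depth": int(rng.integers(2, 9))}
    if family == "glm":
        lam = float(10.0 ** rng.uniform(-3, 2))
        return {"C": 1.0 / lam, "l1_ratio": float(rng.uniform(0.0, 1.0))}
    raise KeyError(family)


def _build(family: str, params: dict, seed: int):
    if family == "naive_bayes":
        return GaussianNB(**params)
    if family == "logistic_regression":
        return SGDClassifier(loss="log_loss", learning_rate="constant",
                             max_iter=2000, tol=1e-4, random_state=seed,
                             **params)
    if family == "neural_network":
        return MLPClassifier(max_iter=400, random_state=seed, **params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "xgboost":
        return XGBClassifier(n_estimators=100, random_state=seed,
                             eval_metric="logloss", verbosity=0, **params)
    if family == "glm":
        return LogisticRegression(penalty="elasticnet", solver="saga",
                                  max_iter=5000, random_state=seed, **params)
    raise KeyError(family)


#: fixed evaluation order; ties on test accuracy resolve to the first entry
MODEL_FAMILIES = (
    "glm",
    "naive_bayes",
    "random_forest",
    "neural_network",
    "decision_tree",
    "gradient_boosted_trees",
    "logistic_regression",
    "xgboost",
)


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

def _cv_accuracy(family: str, params: dict, X: np.ndarray, y: np.ndarray,
                 cv_folds: int, seed: int) -> float:
    """Mean accuracy over stratified folds; degenerate folds are reshuffled."""
    for reshuffle in range(5):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=seed + reshuffle)
        accs = []
        degenerate = False
        for tr, va in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                degenerate = True
                break
            model = _build(family, params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            accs.append(accuracy_score(y[va], model.predict(X[va])))
        if not degenerate:
            return float(np.mean(accs))
        warnings.warn(f"degenerate single-class fold for {family}; reshuffling")
    return float(np.mean(accs)) if accs else 0.0


def benchmark(train_X: pd.DataFrame, train_y: pd.Series,
              test_X: pd.DataFrame, test_y: pd.Series,
              cv_folds: int = DEFAULT_CV_FOLDS,
              search_budget: int = DEFAULT_SEARCH_BUDGET,
              seed: int = 0,
              families=MODEL_FAMILIES) -> tuple[pd.DataFrame, dict]:
    """Random-search tuning and held-out scoring of every classifier family.

    Returns the score table (model, accuracy, recall, precision, best flag,
    no_positive_predictions flag) sorted in the fixed family order, and the
    fitted best-configuration estimators keyed by family.
    """
    Xtr, ytr = train_X.values, train_y.values.astype(int)
    Xte, yte = test_X.values, test_y.values.astype(int)
    rng = np.random.default_rng(seed)

    rows, fitted = [], {}
    for family in families:
        best_cfg, best_cv = None, -np.inf
        for _ in range(search_budget):
            params = _sample_params(family, rng)
            cv = _cv_accuracy(family, params, Xtr, ytr, cv_folds, seed)
            if cv > best_cv:
                best_cv, best_cfg = cv, params
        model = _build(family, best_cfg, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        pred = model.predict(Xte)
        no_pos = not np.any(pred == 1)
        rows.append({
            "model": family,
            "accuracy": float(accuracy_score(yte, pred)),
            "recall": float(recall_score(yte, pred, zero_division=0)),
            "precision": float(precision_score(yte, pred, zero_division=0)),
            "cv_accuracy": best_cv,
            "no_positive_predictions": bool(no_pos),
        })
        fitted[family] = model
    scores = pd.DataFrame(rows)
    best_idx = int(scores["accuracy"].idxmax())  # first max in family order
    scores["best"] = [i == best_idx for i in range(len(scores))]
    return scores, fitted


# ---------------------------------------------------------------------------
# permutation feature importance
# ---------------------------------------------------------------------------

def permutation_importance(model, X: pd.DataFrame, y: pd.Series,
                           repeats: int = DEFAULT_REPEATS,
                           seed: int = 0) -> pd.DataFrame:
    """Mean and SD of the accuracy drop when each feature is shuffled.

    Only the evaluation copy is permuted; the fitted model is untouched.
    Returns a frame (feature, mean_drop, sd) sorted by mean drop.
    """
    if len(X) < 2:
        raise ValueError("importance is undefined on a single-row test set")
    rng = np.random.default_rng(seed)
    yv = y.values.astype(int)
    baseline = accuracy_score(yv, model.predict(X.values))
    rows = []
    for col in X.columns:
        drops = []
        for _ in range(repeats):
            Xp = X.values.copy()
            j = X.columns.get_loc(col)
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(baseline - accuracy_score(yv, model.predict(Xp)))
        rows.append({"feature": col, "mean_drop": float(np.mean(drops)),
                     "sd": float(np.std(drops, ddof=1))})
    return (pd.DataFrame(rows)
            .sort_values("mean_drop", ascending=False)
            .reset_index(drop=True))
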