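"""Hybrid machine-learning benchmark: ANOVA selection x 8 classifiers.

Implements outcome binarization from MoCA, the 7 feature-set combinations
of the clinical/radiomic/deep tables, leakage-safe z-scoring and ANOVA
top-k selection inside each cross-validation fold, hyperparameter tuning
(Bayesian expected-improvement, random search, or none), the stratified
80/20 hold-out + 5-fold CV protocol, the full benchmark grid with heatmap
tables, and fold-paired t-tests between configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .core import ExperimentResult, FeatureTable, OutcomeLabels

CLASSIFIER_NAMES = ("AdaC", "BagC", "GBC", "RandF", "XGBC", "MLP", "KNN", "ETC")

COMBO_NAMES = ("CF", "RF", "DF", "RF+DF", "CF+RF", "CF+DF", "CF+RF+DF")


# ---------------------------------------------------------------------------
# outcome binarization
# ---------------------------------------------------------------------------

def binarize_moca(score: float, cutoff: float = 26.0) -> str:
    """'normal' when the MoCA score strictly exceeds the cutoff, else 'abnormal'."""
    if not np.isfinite(score):
        raise ValueError(f"MoCA score must be finite, got {score}")
    return "normal" if score > cutoff else "abnormal"


def labels_from_moca(
    scores: pd.Series, cutoff: float = 26.0
) -> tuple[OutcomeLabels, list]:
    """Binary labels (1 = abnormal) from MoCA; missing scores excluded with a log."""
    excluded = list(scores.index[~np.isfinite(scores)])
    valid = scores.dropna()
    labels = (valid <= cutoff).astype(int)
    return OutcomeLabels(labels), excluded


# ---------------------------------------------------------------------------
# feature-set combinations
# ---------------------------------------------------------------------------

def build_combos(
    cf: FeatureTable, rf: FeatureTable, df: FeatureTable
) -> dict[str, FeatureTable]:
    """The 7 combinations of the three base tables, keyed by canonical name."""
    base = {"CF": cf, "RF": rf, "DF": df}
    combos: dict[str, FeatureTable] = {}
    for name in COMBO_NAMES:
        parts = [base[p] for p in name.split("+")]
        combos[name] = parts[0] if len(parts) == 1 else FeatureTable.concat(parts)
    return combos


# ---------------------------------------------------------------------------
# ANOVA selection
# ---------------------------------------------------------------------------

def anova_f_scores(X: np.ndarray | FeatureTable, y: np.ndarray) -> np.ndarray:
    """Per-feature one-way ANOVA F statistic between the two outcome groups."""
    if isinstance(X, FeatureTable):
        X = X.values()
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError(f"class {classes[np.argmin(counts)]} has fewer than 2 members")
    f, _ = f_classif(X, y)
    return np.nan_to_num(f, nan=0.0)


def select_top_k(scores: np.ndarray, names: list[str], k: int) -> list[str]:
    """Names of the k highest-F features; ties keep the earlier column."""
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} scored features")
    order = np.argsort(-np.asarray(scores), kind="stable")
    return [names[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# classifiers and tuning
# ---------------------------------------------------------------------------

def make_classifier(name: str, seed: int, params: dict | None = None):
    params = params or {}
    if name == "AdaC":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "BagC":
        return BaggingClassifier(random_state=seed, **params)
    if name == "GBC":
        return GradientBoostingClassifier(random_state=seed, **params)
    if name == "RandF":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "XGBC":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss",
            verbosity=0, **params,
        )
    if name == "MLP":
        return MLPClassifier(random_state=seed, max_iter=500, **params)
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "ETC":
        return ExtraTreesClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")


#: small per-classifier search spaces: name -> {param: list of values}
SEARCH_SPACES: dict[str, dict[str, list]] = {
    "AdaC": {"n_estimators": [25, 50, 100, 200], "learning_rate": [0.1, 0.5, 1.0]},
    "BagC": {"n_estimators": [10, 25, 50, 100], "max_samples": [0.5, 0.75, 1.0]},
    "GBC": {"n_estimators": [50, 100, 200], "learning_rate": [0.01, 0.1, 0.3],
            "max_depth": [2, 3, 4]},
    "RandF": {"n_estimators": [50, 100, 200], "max_depth": [None, 4, 8],
              "max_features": ["sqrt", "log2"]},
    "XGBC": {"n_estimators": [50, 100, 200], "learning_rate": [0.01, 0.1, 0.3],
             "max_depth": [2, 3, 5]},
    "MLP": {"hidden_layer_sizes": [(32,), (64,), (64, 32)],
            "alpha": [1e-4, 1e-3, 1e-2]},
    "KNN": {"n_neighbors": [3, 5, 7, 11], "weights": ["uniform", "distance"]},
    "ETC": {"n_estimators": [50, 100, 200], "max_depth": [None, 4, 8],
            "max_features": ["sqrt", "log2"]},
}


def _cv_score(name: str, params: dict, X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """3-fold accuracy of one candidate on the tuning data only."""
    folds = min(3, int(np.bincount(y).min()))
    if folds < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = make_classifier(name, seed, params)
        clf.fit(X[tr], y[tr])
        accs.append(float((clf.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def tune_classifier(
    name: str, X: np.ndarray, y: np.ndarray,
    method: str = "bayesian", budget: int = 25, seed: int = 0,
) -> dict:
    """Pick hyperparameters for one classifier on training data only.

    ``bayesian`` runs Gaussian-process expected-improvement search over the
    enumerated space, ``random`` samples uniformly, ``none`` returns the
    library defaults.  All methods are deterministic under the seed.
    """
    if method == "none":
        return {}
    space = SEARCH_SPACES[name]
    keys = list(space)
    grid = list(itertools.product(*(space[k] for k in keys)))
    rng = np.random.default_rng(seed)
    if len(grid) <= budget:
        candidates = list(range(len(grid)))
        scores = [_cv_score(name, dict(zip(keys, grid[i])), X, y, seed) for i in candidates]
        best = candidates[int(np.argmax(scores))]
        return dict(zip(keys, grid[best]))

    if method == "random":
        picks = rng.choice(len(grid), size=budget, replace=False)
        scores = [_cv_score(name, dict(zip(keys, grid[i])), X, y, seed) for i in picks]
        return dict(zip(keys, grid[picks[int(np.argmax(scores))]]))

    if method != "bayesian":
        raise ValueError(f"unknown tuner method {method!r}")

    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    # numeric encoding of each grid point: its index within each value list
    enc = np.array([
        [space[k].index(v) / max(1, len(space[k]) - 1) for k, v in zip(keys, pt)]
        for pt in grid
    ])
    n_init = min(max(4, budget // 4), budget)
    tried = list(rng.choice(len(grid), size=n_init, replace=False))
    scores = [_cv_score(name, dict(zip(keys, grid[i])), X, y, seed) for i in tried]
    while len(tried) < budget:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-3, normalize_y=True, random_state=seed
        )
        gp.fit(enc[tried], np.asarray(scores))
        rest = [i for i in range(len(grid)) if i not in tried]
        mu, sd = gp.predict(enc[rest], return_std=True)
        best_y = max(scores)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best_y) / np.maximum(sd, 1e-9)
            ei = (mu - best_y) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
        nxt = rest[int(np.argmax(ei))]
        tried.append(nxt)
        scores.append(_cv_score(name, dict(zip(keys, grid[nxt])), X, y, seed))
    return dict(zip(keys, grid[tried[int(np.argmax(scores))]]))


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class HMLSConfig:
    k_grid: tuple[int, ...] = (10, 20, 30, 40)
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    holdout_fraction: float = 0.20
    cv_folds: int = 5
    tuner_method: str = "bayesian"  # "bayesian" | "random" | "none"
    tuner_budget: int = 25
    seed: int = 0

    def validate(self) -> None:
        if any(k < 1 for k in self.k_grid):
            raise ValueError("k grid values must be >= 1")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def evaluate_config(
    combo_name: str,
    table: FeatureTable,
    y: OutcomeLabels | np.ndarray,
    classifier_name: str,
    k: int,
    config: HMLSConfig | None = None,
) -> ExperimentResult:
    """One benchmark cell under the hold-out + CV protocol.

    Within each CV fold the z-scoring parameters, ANOVA scores, tuned
    hyperparameters and the fitted model all derive from that fold's
    training portion only; the fold model is scored on the held fold and on
    the single 20% hold-out set.
    """
    config = config or HMLSConfig()
    config.validate()
    yv = y.values() if isinstance(y, OutcomeLabels) else np.asarray(y, int)
    X = table.values()
    names = table.columns
    if len(set(yv)) < 2:
        raise ValueError("both classes must be present")
    if len(yv) < 25:
        raise ValueError(f"protocol requires at least 25 subjects, got {len(yv)}")
    k = min(k, len(names))

    idx = np.arange(len(X))
    train_idx, hold_idx = train_test_split(
        idx, test_size=config.holdout_fraction, stratify=yv, random_state=config.seed
    )
    result = ExperimentResult(combo=combo_name, classifier=classifier_name, k=k)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    for fold, (tr, te) in enumerate(skf.split(train_idx, yv[train_idx])):
        tr_idx, te_idx = train_idx[tr], train_idx[te]
        if len(set(yv[tr_idx])) < 2 or len(set(yv[te_idx])) < 2:
            raise ValueError(f"fold {fold} is degenerate (single class)")
        scaler = StandardScaler().fit(X[tr_idx])
        Xtr = scaler.transform(X[tr_idx])
        scores = anova_f_scores(Xtr, yv[tr_idx])
        selected = select_top_k(scores, names, k)
        cols = [names.index(c) for c in selected]
        params = tune_classifier(
            classifier_name, Xtr[:, cols], yv[tr_idx],
            config.tuner_method, config.tuner_budget, config.seed + fold,
        )
        clf = make_classifier(classifier_name, config.seed + fold, params)
        clf.fit(Xtr[:, cols], yv[tr_idx])
        Xte = scaler.transform(X[te_idx])[:, cols]
        Xho = scaler.transform(X[hold_idx])[:, cols]
        result.cv_accuracies.append(float((clf.predict(Xte) == yv[te_idx]).mean()))
        result.holdout_accuracies.append(float((clf.predict(Xho) == yv[hold_idx]).mean()))
        result.tuned_params = params

    # reported selection: ANOVA on the full 80% training portion (reporting only)
    scaler = StandardScaler().fit(X[train_idx])
    scores = anova_f_scores(scaler.transform(X[train_idx]), yv[train_idx])
    result.selected_features = select_top_k(scores, names, k)
    result.selected_family_counts = table.family_counts(result.selected_features)
    return result


@dataclass
class GridResult:
    results: list[ExperimentResult]
    table: pd.DataFrame  # one row per (combo, classifier, k)
    best_per_combo: pd.DataFrame

    def heatmap_table(self, k: int, metric: str = "cv_mean") -> pd.DataFrame:
        sub = self.table[self.table["k"] == k]
        return sub.pivot(index="combo", columns="classifier", values=metric)


def run_grid(
    combos: dict[str, FeatureTable],
    y: OutcomeLabels | np.ndarray,
    config: HMLSConfig | None = None,
) -> GridResult:
    """Full cross of combos x classifiers x k; failures recorded, grid continues.

    Best cell per combo is the argmax of mean CV accuracy with ties going
    to the smaller k (then earlier classifier order).
    """
    config = config or HMLSConfig()
    config.validate()
    results: list[ExperimentResult] = []
    for combo_name, table in combos.items():
        for clf_name in config.classifiers:
            for k in config.k_grid:
                try:
                    res = evaluate_config(combo_name, table, y, clf_name, k, config)
                except Exception as exc:
                    res = ExperimentResult(combo=combo_name, classifier=clf_name,
                                           k=k, error=str(exc))
                results.append(res)
    rows = pd.DataFrame([r.as_row() for r in results])
    ok = rows[rows["error"] == ""].copy()
    best_rows = []
    for combo_name in combos:
        sub = ok[ok["combo"] == combo_name]
        if sub.empty:
            continue
        sub = sub.sort_values(["cv_mean", "k"], ascending=[False, True], kind="stable")
        best_rows.append(sub.iloc[0])
    best = pd.DataFrame(best_rows).reset_index(drop=True)
    return GridResult(results=results, table=rows, best_per_combo=best)


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on fold-wise accuracy differences.

    Identical vectors give (0, 1); constant nonzero differences give an
    infinite-t sentinel with p = 0.
    """
    a, b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
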