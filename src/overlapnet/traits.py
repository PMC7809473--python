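"""Four-class social-trait prediction from latent subnetwork expressions.

Targets are sex x (more/less social) classes per trait: traits are
median-split (ties to "less"), crossed with sex, and classified one-vs-rest
from the 15 latent embeddings plus standardized age. Hyperparameters are
tuned on inner folds only; accuracies come from outer held-out folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier

from .autoencoders import CVPlan
from .errors import (
    ClassImbalanceError,
    ConstantTraitError,
    EstimatorError,
    LengthMismatchError,
)

CLASS_NAMES = ("female_more", "female_less", "male_more", "male_less")

LOGISTIC_C_GRID = np.logspace(-3, 3, 7)
FOREST_GRID = {
    "estimator__max_depth": [2, 6],
    "estimator__min_samples_split": [2, 6],
    "estimator__min_samples_leaf": [2, 6],
}


def dichotomize_trait(values, trait_config: dict | None = None):
    """Median-split a trait into more(1)/less(0); ties at the median go to less.

    Already-binary {0, 1} traits pass through (1 = "more social" unless the
    config sets ``polarity_positive: 0``). Returns (binary array, median).
    """
    values = np.asarray(values, dtype=float)
    config = trait_config or {}
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ConstantTraitError(f"trait has a single value {uniq.tolist()}")
    if set(uniq.tolist()) <= {0.0, 1.0}:
        binary = values.astype(int)
        if config.get("polarity_positive", 1) == 0:
            binary = 1 - binary
        return binary, 0.5
    median = float(np.median(values))
    return (values > median).astype(int), median


@dataclass
class FourClassLabels:
    classes: np.ndarray  # per-participant class name
    trait_id: str = ""
    median: float | None = None
    tie_rule: str = "ties_to_less"

    def __post_init__(self):
        self.classes = np.asarray(self.classes)

    @property
    def counts(self) -> pd.Series:
        return pd.Series(self.classes).value_counts().reindex(CLASS_NAMES, fill_value=0)

    def to_sex_social(self) -> tuple[np.ndarray, np.ndarray]:
        """Invert back to (sex female=1, more_social=1)."""
        sex = np.array([c.startswith("female") for c in self.classes], dtype=int)
        more = np.array([c.endswith("more") for c in self.classes], dtype=int)
        return sex, more


def make_four_class_labels(sex, more_less, trait_id: str = "",
                           median: float | None = None) -> FourClassLabels:
    """Cross sex (1 = female) with more/less social (1 = more)."""
    sex = np.asarray(sex, dtype=int)
    more_less = np.asarray(more_less, dtype=int)
    if sex.shape != more_less.shape:
        raise LengthMismatchError(
            f"sex has length {sex.shape}, more/less has length {more_less.shape}"
        )
    names = np.where(sex == 1,
                     np.where(more_less == 1, "female_more", "female_less"),
                     np.where(more_less == 1, "male_more", "male_less"))
    labels = FourClassLabels(classes=names, trait_id=trait_id, median=median)
    empty = [c for c, n in labels.counts.items() if n == 0]
    if empty:
        warnings.warn(f"empty classes: {empty}; one-vs-rest training proceeds", stacklevel=2)
    return labels


@dataclass
class TraitPredictionReport:
    trait_id: str
    estimator: str
    fold_accuracies: np.ndarray
    chance: float
    class_names: list[str]
    feature_names: list[str]
    coef_mean: pd.DataFrame | None  # classes x features (logistic only)
    coef_sd: pd.DataFrame | None
    fold_coefs: list[pd.DataFrame] | None
    chosen_params: list[dict]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=0))


def _build_features(embeddings: np.ndarray, age: np.ndarray | None):
    embeddings = np.asarray(embeddings, dtype=float)
    names = [f"subnetwork_{k + 1}" for k in range(embeddings.shape[1])]
    if age is None:
        return embeddings, names
    age = np.asarray(age, dtype=float).reshape(-1, 1)
    if age.shape[0] != embeddings.shape[0]:
        raise LengthMismatchError("age and embeddings row counts differ")
    return np.hstack([embeddings, age]), names + ["age"]


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _make_estimator(estimator: str, inner_folds: int, seed: int, light: bool):
    if estimator == "logistic":
        cs = LOGISTIC_C_GRID if not light else LOGISTIC_C_GRID[::3]
        cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        return OneVsRestClassifier(
            LogisticRegressionCV(Cs=cs, cv=cv, scoring="accuracy", max_iter=2000)
        )
    if estimator == "forest":
        base = OneVsRestClassifier(
            RandomForestClassifier(n_estimators=100 if not light else 25,
                                   random_state=seed)
        )
        cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        return GridSearchCV(base, FOREST_GRID, cv=cv, n_jobs=None)
    raise EstimatorError(f"unknown estimator {estimator!r}")


def nested_cv_classify(
    embeddings: np.ndarray,
    age: np.ndarray | None,
    labels: FourClassLabels,
    estimator: str = "logistic",
    cv_plan: CVPlan | None = None,
    seed: int = 0,
    light: bool = False,
    stratify: bool = True,
) -> TraitPredictionReport:
    """Nested-CV one-vs-rest classification of the four sex-by-sociality groups.

    Features (embeddings + age) are standardized on each outer training fold.
    For the logistic estimator, per-class l2 strength is tuned on inner folds
    (7-point log grid from 1e-3 to 1e3); for the random forest, depth/split/
    leaf sizes on {2, 6}. ``light=True`` thins the grids (used for
    permutation nulls).
    """
    cv_plan = cv_plan or CVPlan()
    x, feature_names = _build_features(embeddings, age)
    y = labels.classes
    if x.shape[0] != y.shape[0]:
        raise LengthMismatchError("features and labels row counts differ")
    fold_maker = StratifiedKFold if stratify else KFold
    outer = fold_maker(n_splits=cv_plan.outer_folds, shuffle=True, random_state=seed)
    accs, fold_coefs, chosen = [], [], []
    present_classes = np.unique(y)
    for fold_i, (tr, te) in enumerate(outer.split(x, y)):
        if np.unique(y[tr]).size < present_classes.size:
            raise ClassImbalanceError(f"outer fold {fold_i} training set misses a class")
        x_tr, x_te = _standardize(x[tr], x[te])
        clf = _make_estimator(estimator, cv_plan.inner_folds, seed + fold_i, light)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(x_tr, y[tr])
            accs.append(float(np.mean(clf.predict(x_te) == y[te])))
            if estimator == "logistic":
                coef = np.vstack([est.coef_.ravel() for est in clf.estimators_])
                if coef.shape[0] == 1 and len(clf.classes_) == 2:
                    coef = np.vstack([-coef, coef])  # binary OvR fits one estimator
                fold_coefs.append(pd.DataFrame(coef, index=list(clf.classes_),
                                               columns=feature_names))
                chosen.append({"C": [float(np.ravel(est.C_)[0]) for est in clf.estimators_]})
            else:
                chosen.append({k.replace("estimator__", ""): v
                               for k, v in clf.best_params_.items()})
    coef_mean = coef_sd = None
    if fold_coefs:
        order = fold_coefs[0].index
        stack = np.stack([fc.loc[order].to_numpy() for fc in fold_coefs])
        coef_mean = pd.DataFrame(stack.mean(axis=0), index=order, columns=feature_names)
        coef_sd = pd.DataFrame(stack.std(axis=0, ddof=0), index=order, columns=feature_names)
    return TraitPredictionReport(
        trait_id=labels.trait_id,
        estimator=estimator,
        fold_accuracies=np.array(accs),
        chance=1.0 / max(present_classes.size, 1),
        class_names=list(present_classes),
        feature_names=feature_names,
        coef_mean=coef_mean,
        coef_sd=coef_sd,
        fold_coefs=fold_coefs or None,
        chosen_params=chosen,
    )


def summarize_weights(reports: dict[str, TraitPredictionReport]) -> dict[str, pd.DataFrame]:
    """Across-trait weight profile per class and subnetwork.

    Returns signed and absolute mean/SD tables (rows: class, columns:
    subnetwork features; age excluded) plus a long-format per-trait table.
    """
    linear = {t: r for t, r in reports.items() if r.coef_mean is not None}
    if not linear:
        raise EstimatorError("weight summaries need linear (logistic) reports")
    first = next(iter(linear.values()))
    feats = [f for f in first.feature_names if f != "age"]
    classes = first.coef_mean.index
    signed = np.stack([r.coef_mean.loc[classes, feats].to_numpy() for r in linear.values()])
    out = {
        "signed_mean": pd.DataFrame(signed.mean(axis=0), index=classes, columns=feats),
        "signed_sd": pd.DataFrame(signed.std(axis=0, ddof=0), index=classes, columns=feats),
        "abs_mean": pd.DataFrame(np.abs(signed).mean(axis=0), index=classes, columns=feats),
        "abs_sd": pd.DataFrame(np.abs(signed).std(axis=0, ddof=0), index=classes, columns=feats),
    }
    rows = []
    for trait, r in linear.items():
        for cls in classes:
            for feat in feats:
                rows.append({
                    "trait": trait, "class": cls, "feature": feat,
                    "weight_mean": r.coef_mean.loc[cls, feat],
                    "weight_sd_folds": r.coef_sd.loc[cls, feat],
                })
    out["per_trait"] = pd.DataFrame(rows)
    return out


@dataclass
class ChanceReport:
    value: float
    mode: str
    max_class_frequency: float | None = None
    ci: tuple[float, float] | None = None
    permutation_accuracies: np.ndarray | None = None


def chance_level(
    labels: FourClassLabels,
    mode: str = "analytic",
    n_perm: int = 200,
    seed: int = 0,
    embeddings: np.ndarray | None = None,
    age: np.ndarray | None = None,
    estimator: str = "logistic",
    cv_plan: CVPlan | None = None,
    light: bool = True,
) -> ChanceReport:
    """Chance accuracy: 1/K analytically, or a label-permutation null.

    Permutation mode reruns the nested-CV estimator on shuffled labels
    ``n_perm`` times (thinned grids by default) and reports the null mean
    with a 2.5-97.5 percentile interval.
    """
    counts = labels.counts
    n_classes = int((counts > 0).sum())
    analytic = 1.0 / n_classes
    max_freq = float(counts.max() / counts.sum())
    if mode == "analytic":
        return ChanceReport(value=analytic, mode=mode, max_class_frequency=max_freq)
    if mode != "permutation":
        raise ValueError(f"unknown chance mode {mode!r}")
    if embeddings is None:
        raise ValueError("permutation mode needs the feature matrix")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = FourClassLabels(rng.permutation(labels.classes),
                                   trait_id=labels.trait_id)
        rep = nested_cv_classify(embeddings, age, shuffled, estimator=estimator,
                                 cv_plan=cv_plan, seed=seed + 7919 * (p + 1),
                                 light=light)
        accs[p] = rep.mean_accuracy
    lo, hi = np.percentile(accs, [2.5, 97.5])
    return ChanceReport(value=float(accs.mean()), mode=mode,
                        max_class_frequency=max_freq, ci=(float(lo), float(hi)),
                        permutation_accuracies=accs)
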