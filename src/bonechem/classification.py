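"""Supervised provenance-classification harness.

Reproduces the study's protocol: a stratified 70/30 split, per-family
random hyperparameter search (10 candidate configurations) scored by
mean Cohen's kappa under repeated stratified cross-validation (10 folds
x 10 repeats), refit of the winning configuration on the full training
partition, and a hold-out metric panel: accuracy with an exact
Clopper-Pearson 95% interval, kappa, and one-vs-rest sensitivity,
specificity and balanced accuracy per class.

Nine model families are supported (NNET, SVM, KNN, RF, DTC, LDA, MDA,
PLS, NB). Model fitting delegates to scikit-learn estimators (plus two
thin wrappers: Gaussian-mixture discriminant analysis and PLS-DA); the
protocol, selection logic and metrics are owned here. Features are
centred and scaled with statistics learned on the training data only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MODEL_FAMILIES",
    "SplitSpec",
    "ModelEval",
    "EvalReport",
    "stratified_split",
    "tune_and_train",
    "cohen_kappa",
    "accuracy_ci",
    "evaluate",
    "run_protocol",
    "summary_frame",
]

META_COLUMNS = ("sample_id", "unit")


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0
    group_col: str = "unit"


@dataclass
class ModelEval:
    family: str
    params: dict
    cv_kappa: float
    candidates: list  # [(params, mean CV kappa), ...] over the search
    model: object  # fitted scaler+estimator pipeline
    classes: list


@dataclass
class EvalReport:
    accuracy: float
    kappa: float
    accuracy_ci_low: float
    accuracy_ci_high: float
    per_class: pd.DataFrame  # sensitivity / specificity / balanced accuracy
    confusion: pd.DataFrame
    n_test: int
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# custom estimators

class MixtureDiscriminantClassifier(BaseEstimator, ClassifierMixin):
    """Discriminant analysis with a Gaussian mixture per class.

    Each class density is a mixture of ``subclasses`` Gaussians with a
    tied within-class covariance; prediction maximises class prior times
    class likelihood.
    """

    def __init__(self, subclasses=3, reg_covar=1e-4, random_state=0):
        self.subclasses = subclasses
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.models_, self.log_priors_ = [], []
        for cls in self.classes_:
            Xc = X[y == cls]
            k = max(1, min(self.subclasses, len(Xc) // 2))
            gm = GaussianMixture(
                n_components=k,
                covariance_type="tied",
                reg_covar=self.reg_covar,
                random_state=self.random_state,
                n_init=1,
            ).fit(Xc)
            self.models_.append(gm)
            self.log_priors_.append(math.log(len(Xc) / len(X)))
        return self

    def _joint(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack(
            [
                gm.score_samples(X) + lp
                for gm, lp in zip(self.models_, self.log_priors_)
            ]
        )

    def predict(self, X):
        return self.classes_[np.argmax(self._joint(X), axis=1)]


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial least squares discriminant analysis: PLS regression on the
    one-hot class indicator, predicting the largest fitted response."""

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        Y = np.column_stack([(y == c).astype(float) for c in self.classes_])
        ncomp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=ncomp, scale=False).fit(X, Y)
        return self

    def predict(self, X):
        scores = self.pls_.predict(np.asarray(X, dtype=float))
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# model family registry: build(params, seed) and sample(rng, n_features)

def _choice(rng, values):
    return values[int(rng.integers(len(values)))]


MODEL_FAMILIES = {
    "NNET": {
        "build": lambda p, seed: MLPClassifier(
            hidden_layer_sizes=(p["size"],), alpha=p["decay"], solver="lbfgs",
            max_iter=250, random_state=seed,
        ),
        "sample": lambda rng, nf: {
            "size": _choice(rng, [1, 3, 5, 7, 9, 11, 13, 15, 17, 19]),
            "decay": _choice(rng, [0.0, 1e-4, 1e-3, 1e-2, 0.1, 0.3, 0.5]),
        },
    },
    "SVM": {
        "build": lambda p, seed: SVC(
            C=p["C"], gamma=p["gamma"], kernel="rbf", max_iter=100000, random_state=seed
        ),
        "sample": lambda rng, nf: {
            "C": float(2.0 ** rng.uniform(-2, 8)),
            "gamma": float(10.0 ** rng.uniform(-3, 0.0)),
        },
    },
    "KNN": {
        "build": lambda p, seed: KNeighborsClassifier(n_neighbors=p["k"]),
        "sample": lambda rng, nf: {"k": _choice(rng, [1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21])},
    },
    "RF": {
        "build": lambda p, seed: RandomForestClassifier(
            n_estimators=100, max_features=p["mtry"], random_state=seed
        ),
        "sample": lambda rng, nf: {"mtry": int(rng.integers(1, max(nf, 1) + 1))},
    },
    "DTC": {
        "build": lambda p, seed: DecisionTreeClassifier(
            min_samples_split=p["min_split"], ccp_alpha=p["ccp_alpha"], random_state=seed
        ),
        "sample": lambda rng, nf: {
            "min_split": int(rng.integers(2, 21)),
            "ccp_alpha": float(_choice(rng, [0.0, 1e-3, 5e-3, 1e-2, 2e-2, 5e-2])),
        },
    },
    "LDA": {
        # no tunable hyperparameters, matching the reference protocol
        "build": lambda p, seed: LinearDiscriminantAnalysis(),
        "sample": None,
    },
    "MDA": {
        "build": lambda p, seed: MixtureDiscriminantClassifier(
            subclasses=p["subclasses"], random_state=seed
        ),
        "sample": lambda rng, nf: {"subclasses": int(rng.integers(2, 6))},
    },
    "PLS": {
        "build": lambda p, seed: PLSDAClassifier(n_components=p["ncomp"]),
        "sample": lambda rng, nf: {"ncomp": int(rng.integers(1, min(nf, 8) + 1))},
    },
    "NB": {
        "build": lambda p, seed: GaussianNB(var_smoothing=p["var_smoothing"]),
        "sample": lambda rng, nf: {"var_smoothing": float(10.0 ** rng.uniform(-10, -4))},
    },
}


# ---------------------------------------------------------------------------
# protocol pieces

def feature_matrix(table, feature_cols=None):
    feature_cols = feature_cols or [c for c in table.columns if c not in META_COLUMNS]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["unit"].to_numpy()
    return X, y, feature_cols


def stratified_split(table: pd.DataFrame, spec: SplitSpec = None):
    """Seeded stratified train/test split of a labelled feature table."""
    spec = spec or SplitSpec()
    labels = table[spec.group_col]
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every unit needs at least 2 samples to stratify")
    if counts.size < 2:
        raise ValueError("need at least 2 units to split")
    train_idx, test_idx = train_test_split(
        np.arange(len(table)),
        train_size=spec.train_fraction,
        stratify=labels,
        random_state=spec.seed,
    )
    return (
        table.iloc[np.sort(train_idx)].reset_index(drop=True),
        table.iloc[np.sort(test_idx)].reset_index(drop=True),
    )


def cohen_kappa(confusion):
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from a square
    confusion matrix. Degenerate p_e = 1 (all mass in one cell) is 0 by
    convention."""
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or (m < 0).any():
        raise ValueError("confusion must be a square nonnegative matrix")
    n = m.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    if math.isclose(pe, 1.0):
        return 0.0
    return float((po - pe) / (1.0 - pe))


def accuracy_ci(correct, total, level=0.95):
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if not 0 <= correct <= total or total < 1:
        raise ValueError("need 0 <= correct <= total, total >= 1")
    alpha = 1.0 - level
    low = 0.0 if correct == 0 else float(beta_dist.ppf(alpha / 2, correct, total - correct + 1))
    high = 1.0 if correct == total else float(
        beta_dist.ppf(1 - alpha / 2, correct + 1, total - correct)
    )
    return low, high


def _cv_kappa(pipe, X, y, folds, repeats, seed):
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    classes = np.unique(y)
    kappas = []
    for tr, te in cv.split(X, y):
        est = clone(pipe).fit(X[tr], y[tr])
        pred = est.predict(X[te])
        kappas.append(cohen_kappa(confusion_matrix(y[te], pred, labels=classes)))
    return float(np.mean(kappas))


def tune_and_train(
    train: pd.DataFrame,
    family: str,
    n_candidates=10,
    cv_folds=10,
    cv_repeats=10,
    seed=0,
    feature_cols=None,
) -> ModelEval:
    """Random hyperparameter search scored by repeated-CV mean kappa.

    ``n_candidates`` configurations are drawn from the family's search
    space (families without tunables evaluate a single candidate); the
    best is refit on the full training partition behind a train-fitted
    standardiser.
    """
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(MODEL_FAMILIES)}")
    X, y, feature_cols = feature_matrix(train, feature_cols)
    if np.unique(y).size < 2:
        raise ValueError("training data has a single class")
    spec = MODEL_FAMILIES[family]
    rng = np.random.default_rng([seed, sum(map(ord, family))])
    if spec["sample"] is None:
        param_sets = [{}]
    else:
        # distinct draws; a discrete space smaller than n_candidates just
        # yields fewer candidates
        param_sets, seen = [], set()
        for _ in range(50 * n_candidates):
            if len(param_sets) >= n_candidates:
                break
            p = spec["sample"](rng, len(feature_cols))
            key = tuple(sorted(p.items()))
            if key in seen:
                continue
            seen.add(key)
            param_sets.append(p)
    # stratified folds cannot exceed the smallest class count
    counts = np.unique(y, return_counts=True)[1]
    folds = int(min(cv_folds, counts.min()))
    if folds < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    results = []
    for p in param_sets:
        pipe = Pipeline(
            [("scale", StandardScaler()), ("clf", spec["build"](p, seed))]
        )
        results.append((p, _cv_kappa(pipe, X, y, folds, cv_repeats, seed)))
    best_params, best_kappa = max(results, key=lambda t: t[1])
    model = Pipeline(
        [("scale", StandardScaler()), ("clf", spec["build"](best_params, seed))]
    ).fit(X, y)
    return ModelEval(
        family=family,
        params=best_params,
        cv_kappa=best_kappa,
        candidates=results,
        model=model,
        classes=list(np.unique(y)),
    )


def evaluate(model_eval: ModelEval, test: pd.DataFrame, feature_cols=None) -> EvalReport:
    """Hold-out metric panel: accuracy + exact CI, kappa, and one-vs-rest
    sensitivity/specificity/balanced accuracy per class."""
    X, y, _ = feature_matrix(test, feature_cols)
    unseen = set(np.unique(y)) - set(model_eval.classes)
    if unseen:
        raise ValueError(f"test labels unseen in training: {sorted(unseen)}")
    classes = model_eval.classes
    pred = model_eval.model.predict(X)
    cm = confusion_matrix(y, pred, labels=classes)
    n = int(cm.sum())
    correct = int(np.trace(cm))
    low, high = accuracy_ci(correct, n)
    rows = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        rows[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": 0.5 * (sens + spec),
        }
    return EvalReport(
        accuracy=correct / n,
        kappa=cohen_kappa(cm),
        accuracy_ci_low=low,
        accuracy_ci_high=high,
        per_class=pd.DataFrame(rows).T,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        n_test=n,
    )


def run_protocol(
    table,
    families=None,
    seed=0,
    n_candidates=10,
    cv_folds=10,
    cv_repeats=10,
    train_fraction=0.70,
    feature_cols=None,
):
    """Full protocol over one split: tune, refit and evaluate each family.

    Returns {family: (ModelEval, EvalReport)}.
    """
    families = families or list(MODEL_FAMILIES)
    train, test = stratified_split(table, SplitSpec(train_fraction, seed))
    out = {}
    for fam in families:
        ev = tune_and_train(
            train, fam, n_candidates, cv_folds, cv_repeats, seed, feature_cols
        )
        out[fam] = (ev, evaluate(ev, test, feature_cols))
    return out


def summary_frame(results):
    """Accuracy/kappa/CI summary table, families as columns."""
    cols = {}
    for fam, (_, rep) in results.items():
        cols[fam] = {
            "Accuracy": rep.accuracy,
            "Kappa": rep.kappa,
            "Accuracy lower": rep.accuracy_ci_low,
            "Accuracy upper": rep.accuracy_ci_high,
        }
    return pd.DataFrame(cols)
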