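"""Point-of-care pre-screening models.

The target outcome is LI/HI chart disagreement: does measuring total
cholesterol change the subject's chart-based risk band?  A model that
predicts this label from pre-cholesterol information decides, at point
of care, whether a cholesterol test is worth running.

Three trainers follow the same protocol (70:30 split outside, 4-fold
cross-validated hyperparameter choice inside, refit on the full
training set): an L1-regularized logistic regression, a linear-kernel
SVM and a random forest tuned on out-of-bag samples.  The published
two-feature logistic score

    logit(c) = -5.6554 + 0.0416 * age + 0.0132 * SBP

ships as the default :class:`POCScreener`, usable without any training
data.  Thresholds on the score scale are chosen by maximizing F-beta
(beta = 1, 2, 3) over every distinct cut of the training scores.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .charts import Cohort
from .disagreement import ComparisonRecord
from .metrics import confusion, fbeta, precision, roc_auc, sensitivity, specificity

# ---------------------------------------------------------------------------
# Published age+SBP score

@dataclass(frozen=True)
class POCCoefficients:
    """Intercept and slopes of the published age+SBP logistic score."""

    intercept: float = -5.6554
    beta_age: float = 0.0416   # per year
    beta_sbp: float = 0.0132   # per mmHg


DEFAULT_POC_COEFFICIENTS = POCCoefficients()


def poc_logit(age: float, sbp: float,
              coeffs: POCCoefficients = DEFAULT_POC_COEFFICIENTS) -> float:
    """Linear predictor of the published score."""
    return coeffs.intercept + coeffs.beta_age * age + coeffs.beta_sbp * sbp


def poc_probability(age: float, sbp: float,
                    coeffs: POCCoefficients = DEFAULT_POC_COEFFICIENTS) -> float:
    """Probability that a cholesterol test changes the risk band."""
    return float(expit(poc_logit(age, sbp, coeffs)))


def classify_needs_tc(prob: float, threshold: float) -> bool:
    """Recommend a cholesterol test when the score reaches the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0,1], got {threshold}")
    return prob >= threshold


class POCScreener(BaseEstimator, ClassifierMixin):
    """The published two-feature score as a ready-made classifier.

    Needs no training: ``fit`` only records the feature layout.  ``X``
    may be a DataFrame with ``age`` and ``sbp`` columns or an (n, 2)
    array ordered (age, sbp).
    """

    def __init__(self, coeffs: POCCoefficients = DEFAULT_POC_COEFFICIENTS,
                 threshold: float = 0.5):
        self.coeffs = coeffs
        self.threshold = threshold

    def fit(self, X=None, y=None) -> "POCScreener":
        self.classes_ = np.array([False, True])
        return self

    @staticmethod
    def _age_sbp(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            return X["age"].to_numpy(float), X["sbp"].to_numpy(float)
        X = np.asarray(X, dtype=float)
        return X[:, 0], X[:, 1]

    def decision_function(self, X) -> np.ndarray:
        age, sbp = self._age_sbp(X)
        c = self.coeffs
        return c.intercept + c.beta_age * age + c.beta_sbp * sbp

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return expit(self.decision_function(X)) >= self.threshold


# ---------------------------------------------------------------------------
# Feature table (the 10 pre-cholesterol candidate predictors)

FEATURE_COLUMNS = ["gender", "age", "smoker", "hist_diabetes", "hist_high_chol",
                   "bmi", "sbp", "dbp", "on_htn_treatment", "glucose"]
CONTINUOUS_FEATURES = ["age", "bmi", "sbp", "dbp", "glucose"]


def cohort_features(cohort: Cohort) -> pd.DataFrame:
    """Encode a cohort as the 10-column candidate-predictor matrix."""
    rows = []
    for s in cohort:
        if s.bmi is None or s.glucose is None:
            raise ValueError(f"subject {s.id!r} lacks bmi/glucose needed for the feature table")
        rows.append({
            "gender": 1.0 if s.gender == "male" else 0.0,
            "age": s.age,
            "smoker": float(s.smoker),
            "hist_diabetes": float(s.diabetes),
            "hist_high_chol": float(bool(s.hist_high_chol)),
            "bmi": s.bmi,
            "sbp": s.sbp,
            "dbp": s.dbp,
            "on_htn_treatment": float(s.on_htn_treatment),
            "glucose": s.glucose,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS, index=[s.id for s in cohort])


def build_feature_table(
    cohort: Cohort, records: Sequence[ComparisonRecord]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the model matrix and the discordance label.

    None of the candidate features derives from total cholesterol: the
    score must be computable before the cholesterol test it gates.
    """
    by_id = {r.subject_id: r for r in records}
    scored = [s for s in cohort if s.id in by_id]
    X = cohort_features(scored)
    labels = np.asarray([by_id[s.id].discordant for s in scored], dtype=bool)
    return X, labels


def split_train_test(
    X: pd.DataFrame, y: np.ndarray, ratio: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified, reproducible train/test split (default 70:30)."""
    if len(X) == 0:
        raise ValueError("cannot split an empty table")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie in (0,1), got {ratio}")
    return train_test_split(X, y, train_size=ratio, random_state=seed, stratify=y)


# ---------------------------------------------------------------------------
# F-beta threshold selection

@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    fbeta: float
    sensitivity: float
    specificity: float


def select_threshold_max_fbeta(
    scores: Sequence[float], labels: Sequence[bool], beta: float
) -> ThresholdChoice:
    """Exhaustive F-beta maximization over every distinct score cut.

    A subject is called positive when its score reaches the cut.  Ties
    in F-beta resolve toward the cut with higher sensitivity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    best: Optional[ThresholdChoice] = None
    for cut in np.unique(s):
        c = confusion(s >= cut, y)
        f = fbeta(np.nan_to_num(precision(c)), sensitivity(c), beta)
        cand = ThresholdChoice(float(cut), f, sensitivity(c), specificity(c))
        if best is None or f > best.fbeta + 1e-12 or (
                abs(f - best.fbeta) <= 1e-12 and cand.sensitivity > best.sensitivity):
            best = cand
    return best


def fbeta_threshold_set(scores, labels, betas=(1, 2, 3)) -> dict[float, ThresholdChoice]:
    return {b: select_threshold_max_fbeta(scores, labels, b) for b in betas}


# ---------------------------------------------------------------------------
# Trainers

def _cv_auc(estimator, X: np.ndarray, y: np.ndarray, folds: int, seed: int,
            grid: Sequence[float], param: str) -> list[float]:
    """Per-fold best grid value by validation AUC (tie -> smaller value)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    chosen = []
    for tr, va in skf.split(X, y):
        best_v, best_auc = None, -np.inf
        for v in grid:
            est = clone(estimator).set_params(**{param: v})
            est.fit(X[tr], y[tr])
            if hasattr(est, "decision_function"):
                sc = est.decision_function(X[va])
            else:
                sc = est.predict_proba(X[va])[:, 1]
            a = roc_auc(sc, y[va])
            if a > best_auc + 1e-12:
                best_v, best_auc = v, a
        chosen.append(best_v)
    return chosen


class L1LogisticScreener(BaseEstimator, ClassifierMixin):
    """L1-regularized logistic regression with CV-averaged strength.

    Per fold, the best inverse regularization strength ``C`` on a
    30-point log-spaced grid is chosen by validation AUC; the four
    fold winners are averaged on the log scale (it is a multiplicative
    parameter) and the model is refit on the full training set at the
    averaged strength.  Features are standardized internally; reported
    coefficients are on the raw feature scale.

    Attributes
    ----------
    C_ : float
        The averaged inverse regularization strength.
    coef_raw_ : pandas.Series
        Raw-scale coefficients indexed by feature name.
    selected_features_ : list of str
        Features surviving the L1 penalty (nonzero coefficient).
    cv_record_ : dict
        Per-fold chosen C values (the tuning record).
    """

    def __init__(self, folds: int = 4, n_grid: int = 30,
                 c_min: float = 1e-3, c_max: float = 1e3,
                 random_state: Optional[int] = None):
        self.folds = folds
        self.n_grid = n_grid
        self.c_min = c_min
        self.c_max = c_max
        self.random_state = random_state

    def _base(self, C: float = 1.0) -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C,
                                      max_iter=2000)),
        ])

    def fit(self, X: pd.DataFrame, y: Sequence[bool]) -> "L1LogisticScreener":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=bool)
        if y.all() or not y.any():
            raise ValueError("training labels must contain both classes")
        grid = np.logspace(np.log10(self.c_min), np.log10(self.c_max), self.n_grid)
        seed = 0 if self.random_state is None else self.random_state
        chosen = _cv_auc(self._base(), X.to_numpy(float), y, self.folds, seed,
                         grid, "lr__C")
        self.C_ = float(np.exp(np.mean(np.log(chosen))))
        self.cv_record_ = {"fold_C": [float(c) for c in chosen],
                           "grid": [float(g) for g in grid]}
        self.pipeline_ = self._base(self.C_).fit(X.to_numpy(float), y)
        self.feature_names_ = list(X.columns)
        scale = self.pipeline_.named_steps["scale"].scale_
        coef_std = self.pipeline_.named_steps["lr"].coef_.ravel()
        self.coef_raw_ = pd.Series(coef_std / scale, index=self.feature_names_)
        self.intercept_ = float(
            self.pipeline_.named_steps["lr"].intercept_[0]
            - np.sum(coef_std * self.pipeline_.named_steps["scale"].mean_ / scale))
        self.selected_features_ = [f for f, c in self.coef_raw_.items() if c != 0.0]
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.pipeline_.decision_function(pd.DataFrame(X).to_numpy(float))

    def predict_proba(self, X) -> np.ndarray:
        return self.pipeline_.predict_proba(pd.DataFrame(X).to_numpy(float))

    def predict(self, X) -> np.ndarray:
        return self.pipeline_.predict(pd.DataFrame(X).to_numpy(float))


class LinearSVMScreener(BaseEstimator, ClassifierMixin):
    """Linear-kernel SVM with C chosen by internal 4-fold CV on AUC.

    The capacity grid doubles from 2^-5 to 2^15; features are
    standardized with training-set statistics; decision values are
    exposed for ROC construction.  The liblinear solver is used: for a
    strictly linear kernel it fits the same separating hyperplane
    family as the kernelized solver at a fraction of the cost, which
    matters at the top of the capacity grid.
    """

    def __init__(self, folds: int = 4, c_exp_min: int = -5, c_exp_max: int = 15,
                 random_state: Optional[int] = None):
        self.folds = folds
        self.c_exp_min = c_exp_min
        self.c_exp_max = c_exp_max
        self.random_state = random_state

    def _base(self, C: float = 1.0) -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=C, max_iter=20000)),
        ])

    def fit(self, X: pd.DataFrame, y: Sequence[bool]) -> "LinearSVMScreener":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=bool)
        if y.all() or not y.any():
            raise ValueError("training labels must contain both classes")
        grid = [2.0 ** e for e in range(self.c_exp_min, self.c_exp_max + 1)]
        seed = 0 if self.random_state is None else self.random_state
        chosen = _cv_auc(self._base(), X.to_numpy(float), y, self.folds, seed,
                         grid, "svm__C")
        # winners across folds summarized by mean CV AUC: pick the grid value
        # chosen most often (tie -> smaller C) for the refit
        vals, counts = np.unique(chosen, return_counts=True)
        self.C_ = float(vals[np.argmax(counts)])
        self.cv_record_ = {"fold_C": [float(c) for c in chosen],
                           "grid": [float(g) for g in grid]}
        self.pipeline_ = self._base(self.C_).fit(X.to_numpy(float), y)
        self.feature_names_ = list(X.columns)
        scaler = self.pipeline_.named_steps["scale"]
        coef_std = self.pipeline_.named_steps["svm"].coef_.ravel()
        self.coef_raw_ = pd.Series(coef_std / scaler.scale_, index=self.feature_names_)
        self.intercept_ = float(
            self.pipeline_.named_steps["svm"].intercept_[0]
            - np.sum(coef_std * scaler.mean_ / scaler.scale_))
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.pipeline_.decision_function(pd.DataFrame(X).to_numpy(float))

    def predict(self, X) -> np.ndarray:
        return self.pipeline_.predict(pd.DataFrame(X).to_numpy(float))


def _bootstrap_indices(tree_random_state: int, n: int) -> np.ndarray:
    # matches the forest's own bootstrap draw for each tree
    return np.random.RandomState(tree_random_state).randint(0, n, n)


class RandomForestScreener(BaseEstimator, ClassifierMixin):
    """Random forest tuned on out-of-bag (OOB) AUC.

    Tree count and per-split candidate-feature count are chosen over
    documented grids by the AUC of the OOB decision function; the OOB
    samples of each tree also yield permutation importances (mean
    decrease in OOB accuracy when one feature is shuffled), the
    variable-importance measure reported for the forest.
    """

    def __init__(self, n_estimators_grid: Sequence[int] = (250, 500),
                 max_features_grid: Sequence[int] = (1, 2, 3, 4),
                 random_state: Optional[int] = None):
        self.n_estimators_grid = n_estimators_grid
        self.max_features_grid = max_features_grid
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: Sequence[bool]) -> "RandomForestScreener":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=bool)
        if y.all() or not y.any():
            raise ValueError("training labels must contain both classes")
        Xa = X.to_numpy(float)
        best = None
        for n_est in self.n_estimators_grid:
            for mf in self.max_features_grid:
                rf = RandomForestClassifier(
                    n_estimators=n_est, max_features=mf, oob_score=True,
                    random_state=self.random_state, n_jobs=1)
                rf.fit(Xa, y)
                oob = rf.oob_decision_function_[:, 1]
                oob = np.where(np.isnan(oob), 0.5, oob)
                a = roc_auc(oob, y)
                if best is None or a > best[0] + 1e-12:
                    best = (a, n_est, mf, rf, oob)
        self.oob_auc_, self.n_estimators_, self.max_features_, self.forest_, \
            self.oob_scores_ = best
        self.feature_names_ = list(X.columns)
        self.importances_ = self._oob_permutation_importance(Xa, y)
        self.cv_record_ = {"n_estimators": int(self.n_estimators_),
                           "max_features": int(self.max_features_),
                           "oob_auc": float(self.oob_auc_)}
        self.classes_ = np.array([False, True])
        return self

    def _oob_permutation_importance(self, X: np.ndarray, y: np.ndarray) -> pd.Series:
        n, p = X.shape
        rng = np.random.default_rng(0 if self.random_state is None
                                    else self.random_state)
        decreases = np.zeros(p)
        used = np.zeros(p)
        for tree in self.forest_.estimators_:
            oob = np.ones(n, dtype=bool)
            oob[_bootstrap_indices(tree.random_state, n)] = False
            if oob.sum() < 2:
                continue
            Xo, yo = X[oob], y[oob]
            base = np.mean(tree.predict(Xo) == yo)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                decreases[j] += base - np.mean(tree.predict(Xp) == yo)
                used[j] += 1
        return pd.Series(decreases / np.maximum(used, 1), index=self.feature_names_)

    def predict_proba(self, X) -> np.ndarray:
        return self.forest_.predict_proba(pd.DataFrame(X).to_numpy(float))

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return self.forest_.predict(pd.DataFrame(X).to_numpy(float))


# ---------------------------------------------------------------------------
# Training-protocol wrappers and the model document

@dataclass
class TrainedModel:
    """A fitted screener plus the record needed to reproduce it."""

    kind: str                     # "rlr" | "svm" | "rf"
    estimator: BaseEstimator
    seed: int
    feature_names: list[str]
    tuning: dict
    train_hash: str
    thresholds: dict = field(default_factory=dict)  # beta -> ThresholdChoice

    def training_scores(self, X: pd.DataFrame) -> np.ndarray:
        if self.kind == "rf":
            return self.estimator.oob_scores_
        return self.estimator.decision_function(X)

    def to_json(self) -> str:
        doc = {
            "format": "whoish-cvd-model/1",
            "kind": self.kind,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "tuning": self.tuning,
            "train_hash": self.train_hash,
            "thresholds": {str(b): asdict(t) for b, t in self.thresholds.items()},
        }
        if self.kind in ("rlr", "svm"):
            doc["coefficients"] = {f: float(c) for f, c in
                                   self.estimator.coef_raw_.items()}
            doc["intercept"] = self.estimator.intercept_
        if self.kind == "rf":
            doc["importances"] = {f: float(v) for f, v in
                                  self.estimator.importances_.items()}
        return json.dumps(doc, indent=2)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())


def _hash_table(X: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _finish(kind: str, est, X: pd.DataFrame, y: np.ndarray, seed: int,
            betas=(1, 2, 3)) -> TrainedModel:
    model = TrainedModel(
        kind=kind, estimator=est, seed=seed,
        feature_names=list(X.columns), tuning=dict(est.cv_record_),
        train_hash=_hash_table(X, y))
    scores = model.training_scores(X)
    model.thresholds = fbeta_threshold_set(scores, y, betas)
    return model


def train_rlr(X: pd.DataFrame, y: np.ndarray, folds: int = 4, seed: int = 0) -> TrainedModel:
    est = L1LogisticScreener(folds=folds, random_state=seed).fit(X, y)
    return _finish("rlr", est, X, y, seed)


def train_svm(X: pd.DataFrame, y: np.ndarray, folds: int = 4, seed: int = 0) -> TrainedModel:
    est = LinearSVMScreener(folds=folds, random_state=seed).fit(X, y)
    return _finish("svm", est, X, y, seed)


def train_rf(X: pd.DataFrame, y: np.ndarray, seed: int = 0) -> TrainedModel:
    est = RandomForestScreener(random_state=seed).fit(X, y)
    return _finish("rf", est, X, y, seed)


TRAINERS = {"rlr": train_rlr, "svm": train_svm, "rf": train_rf}


def evaluate_model(model: TrainedModel, X_test: pd.DataFrame,
                   y_test: np.ndarray) -> dict:
    """Out-of-sample AUC plus Se/Sp at the training-chosen thresholds."""
    scores = model.estimator.decision_function(X_test)
    out = {"auc": roc_auc(scores, y_test)}
    for b, t in model.thresholds.items():
        c = confusion(scores >= t.threshold, y_test)
        out[f"f{b}_sensitivity"] = sensitivity(c)
        out[f"f{b}_specificity"] = specificity(c)
    return out
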