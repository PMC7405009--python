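"""Six classifier configurations behind one train/predict contract.

These are commodity algorithms delegated to scikit-learn; the wrappers pin
the hyperparameters of the study design and make every source of ensemble
randomness a function of an explicit seed:

===================== ==========================================================
model_id              configuration
===================== ==========================================================
lda                   linear discriminant, SVD solver (rank-deficiency safe)
svm_lin               SVC, polynomial kernel order 1, scale 1, box constraint 1
svm_quad              SVC, polynomial kernel order 2, scale 1, box constraint 1
subspace_discriminant random-subspace ensemble of LDAs, 30 learning cycles
random_forest         Gini splits, <= 100 splits per tree, 30 bagged trees
knn                   1-nearest-neighbour, Euclidean, equal weights
===================== ==========================================================

No internal feature standardisation is applied by default — pre-processing
is the pipeline's job, so predictions are a pure function of the features
given (``standardize=True`` is available where absolute kernel scale
matters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_IDS = (
    "lda",
    "svm_lin",
    "svm_quad",
    "subspace_discriminant",
    "random_forest",
    "knn",
)

_DEFAULTS: dict[str, dict] = {
    "lda": {"solver": "svd", "shrinkage": None},
    "svm_lin": {"poly_order": 1, "kernel_scale": 1.0, "box_constraint": 1.0,
                "multiclass": "ovo"},
    "svm_quad": {"poly_order": 2, "kernel_scale": 1.0, "box_constraint": 1.0,
                 "multiclass": "ovo"},
    "subspace_discriminant": {"n_cycles": 30, "subspace_size": None},
    "random_forest": {"n_trees": 30, "max_splits": 100, "criterion": "gini"},
    "knn": {"k": 1, "metric": "euclidean", "weights": "uniform"},
}


@dataclass
class ClassifierSpec:
    model_id: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    standardize: bool = False


@dataclass
class FittedModel:
    spec: ClassifierSpec
    classes: np.ndarray
    n_features: int
    estimator: object  # opaque fitted sklearn estimator


def make_spec(model_id: str, seed: int = 0, standardize: bool = False,
              **overrides) -> ClassifierSpec:
    """Build a ClassifierSpec with the study defaults, applying overrides."""
    if model_id not in _DEFAULTS:
        raise ValueError(f"unknown model_id '{model_id}'; valid: {', '.join(MODEL_IDS)}")
    params = dict(_DEFAULTS[model_id])
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(
            f"unknown hyperparameter(s) for {model_id}: {sorted(unknown)}; "
            f"valid: {sorted(params)}"
        )
    params.update(overrides)
    return ClassifierSpec(model_id=model_id, hyperparameters=params,
                          seed=seed, standardize=standardize)


def _build_estimator(spec: ClassifierSpec, n_features: int):
    hp = {**_DEFAULTS[spec.model_id], **spec.hyperparameters}
    seed = int(spec.seed) % (2**31)
    if spec.model_id == "lda":
        if hp["shrinkage"] is None:
            est = LinearDiscriminantAnalysis(solver=hp["solver"])
        else:
            est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=hp["shrinkage"])
    elif spec.model_id in ("svm_lin", "svm_quad"):
        gamma = 1.0 / float(hp["kernel_scale"]) ** 2
        est = SVC(
            kernel="poly",
            degree=int(hp["poly_order"]),
            gamma=gamma,
            coef0=1.0,
            C=float(hp["box_constraint"]),
        )
        if hp["multiclass"] == "ovr":
            est = OneVsRestClassifier(est)
        elif hp["multiclass"] != "ovo":
            raise ValueError("multiclass must be 'ovo' or 'ovr'")
    elif spec.model_id == "subspace_discriminant":
        size = hp["subspace_size"]
        if size is None:
            size = max(1, round(n_features / 2))
        est = BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(solver="svd"),
            n_estimators=int(hp["n_cycles"]),
            max_features=int(size),
            bootstrap=False,
            bootstrap_features=False,
            random_state=seed,
        )
    elif spec.model_id == "random_forest":
        est = RandomForestClassifier(
            n_estimators=int(hp["n_trees"]),
            criterion=hp["criterion"],
            max_leaf_nodes=int(hp["max_splits"]) + 1,  # splits = leaves - 1
            bootstrap=True,
            random_state=seed,
        )
    elif spec.model_id == "knn":
        est = KNeighborsClassifier(
            n_neighbors=int(hp["k"]), metric=hp["metric"], weights=hp["weights"]
        )
    else:  # pragma: no cover - guarded by make_spec
        raise ValueError(f"unknown model_id '{spec.model_id}'")
    if spec.standardize:
        est = make_pipeline(StandardScaler(), est)
    return est


def fit(spec: ClassifierSpec, X, y) -> FittedModel:
    """Train the configured model; deterministic given (spec.seed, X, y)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} rows in X but {y.shape[0]} labels")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    est = _build_estimator(spec, X.shape[1])
    est.fit(X, y)
    return FittedModel(spec=spec, classes=classes, n_features=X.shape[1],
                       estimator=est)


def predict(model: FittedModel, X) -> np.ndarray:
    """Predict one label per row; rejects feature-width mismatches."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width "
            f"{model.n_features}"
        )
    return np.asarray(model.estimator.predict(X))
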