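"""Repeated stratified nested cross-validation and confusion-matrix metrics.

The validation protocol: the sample set is split into ``outer_folds``
stratified parts; each part serves once as the test set for a model trained
on the rest.  On every outer training partition an inner stratified
``inner_folds`` cross-validation selects hyperparameters from an optional
grid (the study design fixes hyperparameters, so the default grid is a
singleton and the inner loop reduces to a validation estimate).  The whole
procedure is repeated ``repetitions`` times with re-randomised folds; the
headline number is the mean +/- sd over repetitions of the *balanced*
accuracy (unweighted mean of per-class sensitivities — robust to the very
unequal class sizes), and the per-repetition test-set confusion matrices
are accumulated into one K x K table.

Terminology note: alongside sensitivity (row-wise recall) the accumulated
tables report the column-wise *predictive value*, diagonal / column sum —
the quantity some chemometric reports label "specificity".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from . import preprocess as pp
from .spectra_io import SpectraSet


@dataclass
class NestedCVConfig:
    outer_folds: int = 4
    inner_folds: int = 10
    repetitions: int = 100
    seed: int = 0
    inner_grid: dict | None = None  # model_id -> list of hyperparameter dicts
    compute_inner_validation: bool = False

    def __post_init__(self):
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = actual class, columns = predicted class."""

    labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.labels = list(self.labels)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if labels is None:
            labels = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(labels, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def sensitivity(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall in %, 100 * diagonal / row sum."""
    rows = cm.counts.sum(axis=1)
    empty = np.flatnonzero(rows == 0)
    if empty.size:
        raise ValueError(
            f"no actual instances of class(es) {[cm.labels[i] for i in empty]}"
        )
    return 100.0 * np.diag(cm.counts) / rows


def predictive_value(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class precision in %, 100 * diagonal / column sum.

    This column-wise quantity is what some study reports print under the
    header "specificity".
    """
    cols = cm.counts.sum(axis=0)
    empty = np.flatnonzero(cols == 0)
    if empty.size:
        raise ValueError(
            f"no predictions for class(es) {[cm.labels[i] for i in empty]}"
        )
    return 100.0 * np.diag(cm.counts) / cols


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean sensitivity in %: unweighted mean of per-class recalls."""
    return float(sensitivity(cm).mean())


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace / total in %."""
    return 100.0 * float(np.trace(cm.counts)) / cm.total


@dataclass
class EvaluationResult:
    per_repetition_balanced_accuracy: np.ndarray  # fractions in [0, 1]
    mean_pct: float
    sd_pct: float
    sd_defined: bool
    accumulated: ConfusionMatrix
    sensitivity_pct: np.ndarray
    predictive_value_pct: np.ndarray
    inner_validation_pct: float | None = None


def _seed_for(*parts) -> int:
    """Deterministic 31-bit seed from a tuple of integers."""
    ss = np.random.SeedSequence([int(p) % (2**31) for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified folds.

    Per class, fold counts differ by at most one; deterministic given seed.
    """
    y = np.asarray(y)
    if k > y.size:
        raise ValueError(f"cannot make {k} folds from {y.size} samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    labels, counts = np.unique(y, return_counts=True)
    if counts.min() == 0:
        raise ValueError("every class must be nonempty")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = fold
    return assignment


def _select_hyperparameters(X, y, spec, candidates, inner_folds, seed):
    """Pick the candidate with the best inner-CV mean balanced accuracy.

    Ties break to the earliest candidate in grid order.
    """
    best_score, best = -np.inf, None
    for i, params in enumerate(candidates):
        cand = clf.make_spec(spec.model_id, seed=spec.seed,
                             standardize=spec.standardize,
                             **{**spec.hyperparameters, **params})
        scores = []
        folds = stratified_folds(y, inner_folds, _seed_for(seed, i))
        for f in range(inner_folds):
            tr, te = folds != f, folds == f
            if np.unique(y[tr]).size < 2:
                raise ValueError(
                    "a class is absent from an inner training partition; "
                    "use fewer inner folds"
                )
            model = clf.fit(cand, X[tr], y[tr])
            cm = ConfusionMatrix.from_predictions(y[te], clf.predict(model, X[te]),
                                                  labels=sorted(np.unique(y)))
            # a fold can miss small classes entirely: score only occupied rows
            rows = cm.counts.sum(axis=1)
            recalls = np.diag(cm.counts)[rows > 0] / rows[rows > 0]
            scores.append(recalls.mean())
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best = score, cand
    return best, best_score


def nested_cv_once(X, y, spec: clf.ClassifierSpec, cfg: NestedCVConfig,
                   repetition_seed: int):
    """One pass of the nested CV: every sample predicted exactly once.

    Returns (y_pred, mean inner validation score or None).
    """
    X, y = np.asarray(X, dtype=float), np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if counts.min() < cfg.outer_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{cfg.outer_folds} outer folds; use fewer folds"
        )
    folds = stratified_folds(y, cfg.outer_folds, repetition_seed)
    y_pred = np.empty_like(y)
    inner_scores = []
    grid = (cfg.inner_grid or {}).get(spec.model_id, [{}])
    for f in range(cfg.outer_folds):
        tr, te = folds != f, folds == f
        if np.unique(y[tr]).size < labels.size:
            raise ValueError(
                "a class is absent from an outer training partition; "
                "use fewer outer folds"
            )
        fold_spec = clf.ClassifierSpec(
            spec.model_id, dict(spec.hyperparameters),
            seed=_seed_for(repetition_seed, 7, f), standardize=spec.standardize,
        )
        if len(grid) > 1 or cfg.compute_inner_validation:
            fold_spec, score = _select_hyperparameters(
                X[tr], y[tr], fold_spec, grid, cfg.inner_folds,
                _seed_for(repetition_seed, f),
            )
            inner_scores.append(score)
        model = clf.fit(fold_spec, X[tr], y[tr])
        y_pred[te] = clf.predict(model, X[te])
    return y_pred, (float(np.mean(inner_scores)) if inner_scores else None)


def run_evaluation(X, y, spec: clf.ClassifierSpec,
                   cfg: NestedCVConfig) -> EvaluationResult:
    """Repeat the nested CV and accumulate test-set confusion matrices."""
    y = np.asarray(y)
    labels = sorted(np.unique(y).tolist())
    accumulated = np.zeros((len(labels), len(labels)), dtype=np.int64)
    per_rep = np.empty(cfg.repetitions)
    inner_vals = []
    for rep in range(cfg.repetitions):
        rep_seed = _seed_for(cfg.seed, rep)
        y_pred, inner = nested_cv_once(X, y, spec, cfg, rep_seed)
        cm = ConfusionMatrix.from_predictions(y, y_pred, labels=labels)
        accumulated += cm.counts
        per_rep[rep] = balanced_accuracy(cm) / 100.0
        if inner is not None:
            inner_vals.append(inner)
    acc_cm = ConfusionMatrix(labels, accumulated)
    # lenient column metric for the summary: a class that is never predicted
    # gets NaN rather than aborting the whole evaluation
    cols = accumulated.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pv = np.where(cols > 0, 100.0 * np.diag(accumulated) / np.maximum(cols, 1),
                      np.nan)
    sd_defined = cfg.repetitions > 1
    return EvaluationResult(
        per_repetition_balanced_accuracy=per_rep,
        mean_pct=float(per_rep.mean() * 100.0),
        sd_pct=float(per_rep.std(ddof=1) * 100.0) if sd_defined else 0.0,
        sd_defined=sd_defined,
        accumulated=acc_cm,
        sensitivity_pct=sensitivity(acc_cm),
        predictive_value_pct=pv,
        inner_validation_pct=(100.0 * float(np.mean(inner_vals))
                              if inner_vals else None),
    )


def select_subset(s: SpectraSet, species=None) -> SpectraSet:
    """Restrict a raw SpectraSet to the given species before pre-processing.

    Doing the subset first makes every subset-scoped operation (notably the
    MSC mean reference) use only the selected spectra.
    """
    if species is None:
        return s
    mask = s.meta["species"].isin(list(species)).to_numpy()
    if not mask.any():
        raise ValueError(f"no spectra match species {list(species)}")
    return SpectraSet(
        wavenumbers=s.wavenumbers,
        absorbance=s.absorbance[mask],
        meta=s.meta.loc[mask].reset_index(drop=True),
        provenance=list(s.provenance),
    )


def labels_from_meta(meta: pd.DataFrame, label: str = "species") -> np.ndarray:
    """Class labels for evaluation: species, or an Italy-vs-rest origin rule."""
    if label == "species":
        return meta["species"].to_numpy()
    if label == "origin_italy":
        return np.where(meta["origin"] == "Italy", "Italian", "non-Italian")
    raise ValueError("label must be 'species' or 'origin_italy'")


def grid_experiment(s: SpectraSet, approaches, specs, cfg: NestedCVConfig,
                    species=None, label: str = "species"):
    """Run every (approach, model) cell of an experiment grid.

    ``s`` is the raw replicate-level SpectraSet; the optional species subset
    is taken first so pre-processing (and its MSC reference) is scoped to
    the subset.  Returns (results DataFrame, dict of accumulated confusion
    matrices keyed by (approach, model_id)).
    """
    subset = select_subset(s, species)
    rows, matrices = [], {}
    for ai, approach in enumerate(approaches):
        pipeline = pp.make_approach(approach) if isinstance(approach, str) else approach
        name = approach if isinstance(approach, str) else f"pipeline{ai}"
        processed = pp.apply_pipeline(subset, pipeline)
        y = labels_from_meta(processed.meta, label)
        if np.unique(y).size < 2:
            raise ValueError(f"subset yields a single class for label '{label}'")
        for mi, spec in enumerate(specs):
            cell_cfg = NestedCVConfig(
                outer_folds=cfg.outer_folds, inner_folds=cfg.inner_folds,
                repetitions=cfg.repetitions, seed=_seed_for(cfg.seed, ai, mi),
                inner_grid=cfg.inner_grid,
                compute_inner_validation=cfg.compute_inner_validation,
            )
            res = run_evaluation(processed.absorbance, y, spec, cell_cfg)
            rows.append(
                {
                    "approach": name,
                    "model": spec.model_id,
                    "mean_pct": res.mean_pct,
                    "sd_pct": res.sd_pct,
                }
            )
            matrices[(name, spec.model_id)] = res.accumulated
    return pd.DataFrame(rows), matrices
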