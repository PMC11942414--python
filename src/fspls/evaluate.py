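"""Cross-validation harness and performance metrics.

Samples are split once into stratified folds; the same plan is reused for
the normalisation and the discrimination task so held-out samples are unseen
by both models.  All training statistics -- feature filters, centering
means, the library-size surrogate model -- are computed from training folds
only.  Binary performance is summarised by AUC; multinomial by per-class
one-vs-rest AUC (macro-averaged), sensitivity and specificity, plus the
Wasserstein-1 separation between case and control predicted probabilities;
continuous outcomes by MSE and adjusted R^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .core import Outcome
from .normalize import (
    NormalizationModel,
    faux_normalize,
    filter_top_expressed,
    filter_top_variable,
    fit_normalization,
    library_sizes,
    log_transform,
    ordinary_normalize,
    ratio_normalize,
)
from .selection import FitOptions, FsplsModel, fit, predict

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "make_folds",
    "auc",
    "per_class_metrics",
    "wasserstein_separation",
    "class_weights",
    "adjusted_r2",
    "run_benchmark",
]


@dataclass(frozen=True)
class FoldPlan:
    """A reusable assignment of samples to cross-validation folds."""

    n_folds: int
    assignments: np.ndarray  # per-sample fold label, 0..n_folds-1
    seed: int
    stratified: bool

    def split(self):
        for f in range(self.n_folds):
            test = np.nonzero(self.assignments == f)[0]
            train = np.nonzero(self.assignments != f)[0]
            yield train, test

    def to_tsv(self, sample_ids: Optional[Sequence[str]] = None) -> str:
        ids = (
            list(map(str, sample_ids))
            if sample_ids is not None
            else [f"s{i}" for i in range(self.assignments.size)]
        )
        lines = ["sample_id\tfold"]
        lines += [f"{sid}\t{f}" for sid, f in zip(ids, self.assignments)]
        return "\n".join(lines) + "\n"


def make_folds(
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> FoldPlan:
    """Deterministic (seeded) fold assignment, stratified by default."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    assignments = np.empty(labels.size, dtype=int)
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples, fewer than "
                f"{n_folds} folds"
            )
        splitter = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(labels.size), labels)
    else:
        splitter = KFold(n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(labels.size))
    for f, (_, test) in enumerate(split):
        assignments[test] = f
    return FoldPlan(n_folds, assignments, seed, stratified)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def wasserstein_separation(probs: np.ndarray, is_case: np.ndarray) -> float:
    """Wasserstein-1 distance between case and control predicted-probability
    distributions; the area between their empirical CDFs."""
    probs = np.asarray(probs, dtype=float)
    is_case = np.asarray(is_case).astype(bool)
    if not is_case.any() or is_case.all():
        raise ValueError("both case and control groups must be non-empty")
    return float(stats.wasserstein_distance(probs[is_case], probs[~is_case]))


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-class-proportion weights, w_i = n / (C * n_{class(i)})."""
    labels = np.asarray(labels)
    classes, inverse, counts = np.unique(
        labels, return_inverse=True, return_counts=True
    )
    w = labels.size / (classes.size * counts.astype(float))
    return w[inverse]


def adjusted_r2(y_true: np.ndarray, y_pred: np.ndarray, n_predictors: int = 1) -> float:
    """Adjusted R^2 of predictions against truth (prediction = 1 regressor)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_true.size
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def per_class_metrics(
    prob_matrix: np.ndarray,
    labels: np.ndarray,
    class_names: Optional[Sequence] = None,
) -> pd.DataFrame:
    """One-vs-rest AUC, sensitivity and specificity per class.

    Hard predictions are by argmax (ties to the lowest class index).  A class
    absent from ``labels`` gets NaN metrics rather than silent zeros.
    """
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    labels = np.asarray(labels).astype(int)
    C = P.shape[1]
    names = list(class_names) if class_names is not None else list(range(C))
    hard = np.argmax(P, axis=1)
    rows = []
    for c in range(C):
        is_c = labels == c
        if not is_c.any():
            rows.append((names[c], np.nan, np.nan, np.nan, 0))
            continue
        auc_c = auc(P[:, c], is_c.astype(int)) if (~is_c).any() else np.nan
        sens = float(np.mean(hard[is_c] == c))
        spec = float(np.mean(hard[~is_c] != c)) if (~is_c).any() else np.nan
        rows.append((names[c], auc_c, sens, spec, int(is_c.sum())))
    df = pd.DataFrame(rows, columns=["class", "auc", "sensitivity", "specificity", "n"])
    return df


def _fold_ci(values: np.ndarray) -> tuple[float, float, float]:
    """Mean and 95% t-interval across folds (4 df for 5 folds)."""
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if values.size < 2:
        return m, m, m
    half = float(
        stats.t.ppf(0.975, values.size - 1) * values.std(ddof=1) / np.sqrt(values.size)
    )
    return m, m - half, m + half


@dataclass
class EvaluationReport:
    """Per-fold and pooled cross-validation results."""

    family: str
    mode: str
    n_folds: int
    fold_metrics: pd.DataFrame  # one row per fold
    pooled: dict
    per_class: Optional[pd.DataFrame] = None
    feature_counts: list[int] = field(default_factory=list)
    models: list[FsplsModel] = field(default_factory=list)
    normalization_models: list[Optional[NormalizationModel]] = field(
        default_factory=list
    )

    def summary(self) -> dict:
        out = {
            "family": self.family,
            "mode": self.mode,
            "n_folds": self.n_folds,
            "pooled": self.pooled,
            "feature_counts": self.feature_counts,
        }
        metric_cols = [c for c in self.fold_metrics.columns if c != "fold"]
        for col in metric_cols:
            mean, lo, hi = _fold_ci(self.fold_metrics[col].to_numpy())
            out[f"fold_{col}"] = {"mean": mean, "ci95": [lo, hi]}
        return out

    def to_json(self) -> str:
        doc = self.summary()
        doc["folds"] = self.fold_metrics.to_dict(orient="records")
        if self.per_class is not None:
            doc["per_class"] = self.per_class.to_dict(orient="records")
        return json.dumps(doc, indent=1, default=float)

    def to_tsv(self) -> str:
        """Flat table: one row per fold x metric (plus pooled per-class rows)."""
        rows = []
        for _, r in self.fold_metrics.iterrows():
            for col in self.fold_metrics.columns:
                if col == "fold":
                    continue
                rows.append((int(r["fold"]), "all", col, r[col]))
        if self.per_class is not None:
            for _, r in self.per_class.iterrows():
                for col in ("auc", "sensitivity", "specificity"):
                    rows.append(("pooled", r["class"], col, r[col]))
        df = pd.DataFrame(rows, columns=["fold", "class", "metric", "value"])
        return df.to_csv(sep="\t", index=False)


ExternalSelector = Callable[[np.ndarray, Outcome], "FsplsModel"]
"""Plug-in adapter signature for comparator methods: anything that maps a
(training matrix, outcome) to an object with ``steps`` and ``predict``-able
structure can be benchmarked through :func:`run_benchmark`'s ``fit_fn``."""


def run_benchmark(
    counts: np.ndarray,
    y: Outcome,
    plan: FoldPlan,
    mode: str = "ordinary",
    fit_options: FitOptions = FitOptions(),
    feature_ids: Optional[Sequence[str]] = None,
    k_variable: int = 10000,
    k_expressed: int = 10000,
    trim: float = 0.05,
    norm_max_features: int = 2,
    pseudocount: float = 1.0,
    weighting: str = "none",
    fit_fn: Optional[ExternalSelector] = None,
) -> EvaluationReport:
    """Cross-validated normalisation + discrimination pipeline.

    Per fold: library sizes are taken per sample from the raw counts; the
    discrimination candidate pool is the top ``k_variable`` most variable and
    the normalisation pool the top ``k_expressed`` most (trimmed-mean)
    expressed features of the *training* partition; under ``faux``/``ratio``
    a surrogate library-size model is fitted on training folds and applied,
    sample by sample, to the held-out fold.  ``fit_fn`` swaps in an external
    feature-selection adapter in place of the built-in FS-PLS fit.
    """
    counts = np.asarray(counts, dtype=float)
    if mode not in ("ordinary", "faux", "ratio", "none"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    ids = (
        list(map(str, feature_ids))
        if feature_ids is not None
        else [f"f{j}" for j in range(counts.shape[1])]
    )
    log_counts = log_transform(counts, pseudocount)
    log_lib = library_sizes(counts) if mode != "none" else None
    fitter = fit_fn if fit_fn is not None else fit

    fold_rows = []
    pooled_scores, pooled_labels = [], []
    feature_counts, models, norm_models = [], [], []
    for fold, (train, test) in enumerate(plan.split()):
        disc_pool = filter_top_variable(log_counts[train], k_variable)
        norm_model = None
        if mode == "ordinary":
            tr = ordinary_normalize(log_counts[train], log_lib[train], ids)
            te = ordinary_normalize(log_counts[test], log_lib[test], ids)
            Xtr, Xte = tr.data[:, disc_pool], te.data[:, disc_pool]
            fit_ids = [ids[j] for j in disc_pool]
        elif mode == "none":
            Xtr, Xte = log_counts[train][:, disc_pool], log_counts[test][:, disc_pool]
            fit_ids = [ids[j] for j in disc_pool]
        else:
            norm_pool = filter_top_expressed(log_counts[train], k_expressed, trim)
            norm_model = fit_normalization(
                log_counts[train][:, norm_pool],
                log_lib[train],
                feature_ids=[ids[j] for j in norm_pool],
                max_features=norm_max_features,
                pseudocount=pseudocount,
            )
            normalizer = faux_normalize if mode == "faux" else ratio_normalize
            tr = normalizer(log_counts[train], norm_model, ids)
            te = normalizer(log_counts[test], norm_model, ids)
            if mode == "faux":
                Xtr, Xte = tr.data[:, disc_pool], te.data[:, disc_pool]
                fit_ids = [ids[j] for j in disc_pool]
            else:
                # ratio columns derived from the discrimination pool
                keep = [
                    j
                    for j, rid in enumerate(tr.feature_ids)
                    if rid.split("/")[0] in {ids[i] for i in disc_pool}
                ]
                Xtr, Xte = tr.data[:, keep], te.data[:, keep]
                fit_ids = [tr.feature_ids[j] for j in keep]

        w = class_weights(y.values[train]) if weighting == "inverse_class" else None
        y_tr = Outcome(y.values[train], y.family, weights=w)
        model = fitter(Xtr, y_tr, fit_options, feature_ids=fit_ids)
        pred = predict(model, Xte, feature_ids=fit_ids)
        models.append(model)
        norm_models.append(norm_model)
        feature_counts.append(len(model.steps))

        y_te = y.values[test]
        row = {"fold": fold, "n_features": len(model.steps)}
        if y.family == "binomial":
            row["auc"] = auc(pred, y_te)
        elif y.family == "multinomial":
            aucs = [
                auc(pred[:, c], (y_te == c).astype(int))
                for c in range(y.n_classes)
                if 0 < np.sum(y_te == c) < y_te.size
            ]
            row["macro_auc"] = float(np.mean(aucs))
        else:
            row["mse"] = float(np.mean((pred - y_te) ** 2))
            row["adjusted_r2"] = adjusted_r2(y_te, pred)
        fold_rows.append(row)
        pooled_scores.append(pred)
        pooled_labels.append(y_te)

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    pooled: dict = {}
    per_class = None
    if y.family == "binomial":
        pooled["auc"] = auc(scores, labels)
        pooled["wasserstein"] = wasserstein_separation(scores, labels > 0.5)
    elif y.family == "multinomial":
        per_class = per_class_metrics(scores, labels)
        pooled["macro_auc"] = float(per_class["auc"].mean())
        pooled["wasserstein_per_class"] = {
            int(c): wasserstein_separation(scores[:, c], labels == c)
            for c in range(y.n_classes)
        }
    else:
        pooled["mse"] = float(np.mean((scores - labels) ** 2))
        pooled["adjusted_r2"] = adjusted_r2(labels, scores)

    return EvaluationReport(
        family=y.family,
        mode=mode,
        n_folds=plan.n_folds,
        fold_metrics=pd.DataFrame(fold_rows),
        pooled=pooled,
        per_class=per_class,
        feature_counts=feature_counts,
        models=models,
        normalization_models=norm_models,
    )
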