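"""Library-size surrogate discovery and library-size-free normalisation.

A sequencing sample's library size (total counts) is the usual normalising
quantity, but it requires measuring the whole assay.  Instead, a sparse
gaussian FS-PLS model is trained to predict the log library size from a
handful of stably expressed ("housekeeping-like") features.  Two downstream
normalisations then need only those surrogate features:

faux
    subtract the *predicted* log library size from every log count of the
    sample (the log-scale analogue of dividing counts by the total);
ratio
    recast every feature as its log-ratio against each normalising feature,
    yielding an n x (p*q) matrix that is invariant to any per-sample scaling.

Both act on one sample in isolation, which is what makes a signature
deployable without the full assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import Outcome
from .selection import FitOptions, FsplsModel, fit, predict, select_model_size

__all__ = [
    "NormalizationModel",
    "NormalizedMatrix",
    "log_transform",
    "library_sizes",
    "fit_normalization",
    "predict_log_library",
    "faux_normalize",
    "ratio_normalize",
    "ordinary_normalize",
    "filter_top_variable",
    "filter_top_expressed",
    "intersect_features",
]

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class NormalizationModel:
    """A gaussian FS-PLS model of log library size plus its bookkeeping."""

    inner: FsplsModel
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def normalizing_feature_ids(self) -> list[str]:
        return self.inner.selected_ids

    @property
    def n_normalizing(self) -> int:
        return len(self.inner.steps)


@dataclass
class NormalizedMatrix:
    """A normalised matrix tagged with how it was produced."""

    data: np.ndarray
    feature_ids: list[str]
    mode: str  # ordinary | faux | ratio
    provenance: Optional[NormalizationModel] = None


def log_transform(
    counts: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Natural log of (count + pseudocount)."""
    counts = np.asarray(counts, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return np.log(counts + pseudocount)


def library_sizes(
    counts: np.ndarray, sample_ids: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Natural log of per-sample total counts, on the unfiltered matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a samples x features count matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    zero = np.nonzero(totals <= 0)[0]
    if zero.size:
        names = (
            [str(sample_ids[i]) for i in zero[:5]]
            if sample_ids is not None
            else [f"sample {i}" for i in zero[:5]]
        )
        raise ValueError(f"zero library size for: {', '.join(names)}")
    return np.log(totals)


def fit_normalization(
    log_counts: np.ndarray,
    log_lib: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
    max_features: int = 2,
    pvalue_threshold: float = 0.05,
    ridge_lambda: float = 0.01,
    rule: str = "one_se",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NormalizationModel:
    """Sparse gaussian FS-PLS fit of log library size on log counts.

    The candidate pool is expected to be pre-filtered (see
    :func:`filter_top_expressed`).  The selection is capped at
    ``max_features`` (two by default) and the shipped model size is then
    chosen by the one-standard-error rule on per-size training MSE.
    """
    log_counts = np.asarray(log_counts, dtype=float)
    y = Outcome(np.asarray(log_lib, dtype=float), "gaussian")
    opts = FitOptions(
        pvalue_threshold=pvalue_threshold,
        max_features=max_features,
        ridge_lambda=ridge_lambda,
    )
    model = fit(log_counts, y, opts, feature_ids=feature_ids)
    if not model.steps:
        raise ValueError(
            "no feature predicts library size at the stated threshold"
        )
    if len(model.steps) > 1 and rule is not None:
        losses, ses = [], []
        for k in range(1, len(model.steps) + 1):
            pred = predict(model, log_counts, through_step=k)
            sq = (pred - y.values) ** 2
            losses.append(float(sq.mean()))
            ses.append(float(sq.std(ddof=1) / np.sqrt(sq.size)))
        k_sel = select_model_size(losses, rule=rule, se=ses)
        model = model.truncate(k_sel)
    return NormalizationModel(inner=model, pseudocount=pseudocount)


def predict_log_library(
    model: NormalizationModel,
    log_counts: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Predicted log library size per sample (single-sample capable)."""
    return predict(model.inner, log_counts, feature_ids=feature_ids)


def faux_normalize(
    log_counts: np.ndarray,
    model: NormalizationModel,
    feature_ids: Optional[Sequence[str]] = None,
) -> NormalizedMatrix:
    """Subtract each sample's *predicted* log library size from its log counts."""
    log_counts = np.atleast_2d(np.asarray(log_counts, dtype=float))
    ids = (
        list(map(str, feature_ids))
        if feature_ids is not None
        else list(model.inner.feature_ids)
    )
    pred = predict_log_library(model, log_counts, feature_ids=ids)
    return NormalizedMatrix(
        data=log_counts - pred[:, None],
        feature_ids=ids,
        mode="faux",
        provenance=model,
    )


def ratio_normalize(
    log_counts: np.ndarray,
    model: NormalizationModel,
    feature_ids: Optional[Sequence[str]] = None,
) -> NormalizedMatrix:
    """Log-ratio of every feature against each of the q normalising features.

    Output has p*q columns with composite ids "feature/normfeature"; with the
    default cap of two normalising features this is the n x 2p construction.
    Self-ratio columns are retained as constant zero; downstream selection
    ignores zero-variance columns anyway.
    """
    log_counts = np.atleast_2d(np.asarray(log_counts, dtype=float))
    ids = (
        list(map(str, feature_ids))
        if feature_ids is not None
        else list(model.inner.feature_ids)
    )
    colmap = {fid: j for j, fid in enumerate(ids)}
    norm_ids = model.normalizing_feature_ids
    missing = [g for g in norm_ids if g not in colmap]
    if missing:
        raise ValueError(f"missing normalizing feature(s): {', '.join(missing)}")
    blocks, out_ids = [], []
    for g in norm_ids:
        blocks.append(log_counts - log_counts[:, [colmap[g]]])
        out_ids.extend(f"{fid}/{g}" for fid in ids)
    return NormalizedMatrix(
        data=np.concatenate(blocks, axis=1),
        feature_ids=out_ids,
        mode="ratio",
        provenance=model,
    )


def ordinary_normalize(
    log_counts: np.ndarray,
    log_lib: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
) -> NormalizedMatrix:
    """Baseline: subtract the *true* log library size (needs the full assay)."""
    log_counts = np.atleast_2d(np.asarray(log_counts, dtype=float))
    ids = (
        list(map(str, feature_ids))
        if feature_ids is not None
        else [f"f{j}" for j in range(log_counts.shape[1])]
    )
    return NormalizedMatrix(
        data=log_counts - np.asarray(log_lib, dtype=float)[:, None],
        feature_ids=ids,
        mode="ordinary",
        provenance=None,
    )


def filter_top_variable(X: np.ndarray, k: int = 10000) -> np.ndarray:
    """Indices of the min(k, p) most variable features, by decreasing
    variance (ties to the lower index)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    variances = X.var(axis=0)
    order = np.argsort(-variances, kind="stable")
    return order[: min(k, X.shape[1])]


def filter_top_expressed(
    X: np.ndarray, k: int = 10000, trim: float = 0.05
) -> np.ndarray:
    """Indices of the min(k, p) features with largest trimmed-mean value.

    The mean is taken after discarding the floor(trim * m) lowest and highest
    samples of each feature.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    X = np.asarray(X, dtype=float)
    tmeans = stats.trim_mean(X, trim, axis=0)
    order = np.argsort(-tmeans, kind="stable")
    return order[: min(k, X.shape[1])]


def intersect_features(*sets: Sequence[str]) -> list[str]:
    """Ids present in every collection, in the first collection's order."""
    if len(sets) < 2:
        raise ValueError("need at least two feature-id collections")
    rest = [set(map(str, s)) for s in sets[1:]]
    common = [fid for fid in map(str, sets[0]) if all(fid in s for s in rest)]
    if not common:
        raise ValueError("feature sets have an empty intersection")
    return common
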