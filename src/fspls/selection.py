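"""Forward selection with SVD-projection deflation (FS-PLS).

At each iteration the sample x feature matrix is deflated by projecting out
the subspace spanned by the columns selected so far (an orthonormal basis of
that span is obtained by thin SVD), a univariate GLM is fitted for every
remaining column of the deflated matrix with the accumulated linear predictor
held fixed as an offset, the column with the largest log-likelihood is
selected, its coefficient is re-fitted with L2 shrinkage, and a chi-squared
likelihood-ratio test decides whether to keep going.  Coefficients live in
the deflated space and are fixed once estimated; prediction replays the saved
orthogonalisation for each step, which is what lets a fitted model score a
single unseen sample with no batch statistics and no features beyond the
selected ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import core
from .core import Outcome, UnivariateFit

__all__ = [
    "FeatureMatrix",
    "FitOptions",
    "SelectionStep",
    "FsplsModel",
    "center",
    "deflate",
    "select_next",
    "fit",
    "predict",
    "select_model_size",
]

#: Singular directions below this fraction of the largest singular value are
#: dropped from the orthonormal basis (guards collinear selections).
SV_RTOL = 1e-10

#: Deflated columns with variance below this are out of candidacy: they carry
#: no information orthogonal to the selected set (this covers the selected
#: columns themselves, which deflation reduces to zero variance).
VAR_TOL = 1e-12

MODEL_FORMAT_VERSION = 1


@dataclass
class FeatureMatrix:
    """A samples x features matrix with per-feature centering bookkeeping."""

    data: np.ndarray
    feature_ids: list[str]
    feature_means: np.ndarray
    centered: bool = True

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the selection loop.

    pvalue_threshold
        Stop once the step likelihood-ratio p-value reaches this level.
    max_features
        Hard cap on the number of selected features (None = unlimited).
    ridge_lambda
        L2 shrinkage strength applied at each coefficient refit.
    force_to_max
        Keep selecting up to ``max_features`` even past the p-value
        threshold (used when class imbalance degrades the training loss).
    """

    pvalue_threshold: float = 0.05
    max_features: Optional[int] = None
    ridge_lambda: float = 0.01
    force_to_max: bool = False

    def __post_init__(self):
        if not (0.0 < self.pvalue_threshold <= 1.0):
            raise ValueError("pvalue_threshold must be in (0, 1]")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be a positive integer")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")
        if self.force_to_max and self.max_features is None:
            raise ValueError("force_to_max requires max_features")


@dataclass
class SelectionStep:
    """One iteration's frozen record.

    ``beta``/``intercept_update`` are deflated-space coefficients (scalar, or
    length C-1 for multinomial).  ``basis_vector`` is the unit-norm direction
    added to the orthonormal basis at this step; ``loadings`` maps each
    feature onto that direction (u^T X), which is exactly what is needed to
    deflate an unseen sample.  The loading of the step's own feature equals
    the norm of its deflated column.
    """

    feature_index: int
    feature_id: str
    beta: np.ndarray | float
    intercept_update: np.ndarray | float
    loglik: float
    pvalue: float
    basis_vector: np.ndarray
    loadings: np.ndarray
    converged: bool = True


@dataclass
class FsplsModel:
    family: str
    feature_ids: list[str]
    feature_means: np.ndarray
    null_intercept: np.ndarray | float
    null_loglik: float
    steps: list[SelectionStep]
    stop_reason: str
    options: FitOptions
    n_classes: int = 2

    @property
    def selected_ids(self) -> list[str]:
        return [s.feature_id for s in self.steps]

    @property
    def selected_indices(self) -> list[int]:
        return [s.feature_index for s in self.steps]

    def truncate(self, k: int) -> "FsplsModel":
        """Model restricted to its first ``k`` selection steps."""
        if not (0 <= k <= len(self.steps)):
            raise ValueError(f"cannot truncate to {k} of {len(self.steps)} steps")
        return FsplsModel(
            family=self.family,
            feature_ids=self.feature_ids,
            feature_means=self.feature_means,
            null_intercept=self.null_intercept,
            null_loglik=self.null_loglik,
            steps=self.steps[:k],
            stop_reason="truncated" if k < len(self.steps) else self.stop_reason,
            options=self.options,
            n_classes=self.n_classes,
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, prune: bool = True) -> str:
        """Serialize; ``prune`` keeps only loadings/means of selected features,
        the minimal set a prediction ever touches."""
        sel = self.selected_indices
        keep = sel if prune else list(range(len(self.feature_ids)))
        doc = {
            "format": "fspls-model",
            "version": MODEL_FORMAT_VERSION,
            "family": self.family,
            "n_classes": self.n_classes,
            "options": {
                "pvalue_threshold": self.options.pvalue_threshold,
                "max_features": self.options.max_features,
                "ridge_lambda": self.options.ridge_lambda,
                "force_to_max": self.options.force_to_max,
            },
            "stop_reason": self.stop_reason,
            "null_intercept": _tolist(self.null_intercept),
            "null_loglik": self.null_loglik,
            "feature_means": {
                self.feature_ids[j]: float(self.feature_means[j]) for j in keep
            },
            "steps": [
                {
                    "feature_id": s.feature_id,
                    "beta": _tolist(s.beta),
                    "intercept_update": _tolist(s.intercept_update),
                    "loglik": s.loglik,
                    "pvalue": s.pvalue,
                    "converged": s.converged,
                    "basis_vector": np.asarray(s.basis_vector).tolist(),
                    "loadings": {
                        self.feature_ids[j]: float(s.loadings[j]) for j in keep
                    },
                }
                for s in self.steps
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FsplsModel":
        doc = json.loads(text)
        if doc.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {doc.get('version')!r}"
            )
        ids = list(doc["feature_means"].keys())
        means = np.array([doc["feature_means"][i] for i in ids])
        index = {fid: j for j, fid in enumerate(ids)}
        multi = doc["family"] == "multinomial"
        steps = []
        for s in doc["steps"]:
            loadings = np.zeros(len(ids))
            for fid, val in s["loadings"].items():
                loadings[index[fid]] = val
            steps.append(
                SelectionStep(
                    feature_index=index[s["feature_id"]],
                    feature_id=s["feature_id"],
                    beta=_fromlist(s["beta"], multi),
                    intercept_update=_fromlist(s["intercept_update"], multi),
                    loglik=s["loglik"],
                    pvalue=s["pvalue"],
                    basis_vector=np.asarray(s["basis_vector"]),
                    loadings=loadings,
                    converged=s.get("converged", True),
                )
            )
        opts = FitOptions(**doc["options"])
        return cls(
            family=doc["family"],
            feature_ids=ids,
            feature_means=means,
            null_intercept=_fromlist(doc["null_intercept"], multi),
            null_loglik=doc["null_loglik"],
            steps=steps,
            stop_reason=doc["stop_reason"],
            options=opts,
            n_classes=doc.get("n_classes", 2),
        )


def _tolist(v):
    return np.asarray(v).tolist() if isinstance(v, np.ndarray) else float(v)


def _fromlist(v, multi: bool):
    return np.asarray(v, dtype=float) if multi else float(v)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def center(
    X: np.ndarray, feature_ids: Optional[Sequence[str]] = None
) -> FeatureMatrix:
    """Column-center ``X``, recording the means mu_1..mu_p."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-d samples x features matrix")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    feature_ids = list(map(str, feature_ids))
    if len(feature_ids) != X.shape[1]:
        raise ValueError("feature_ids length must match the number of columns")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("feature_ids must be unique")
    bad = ~np.all(np.isfinite(X), axis=0)
    if bad.any():
        names = [feature_ids[j] for j in np.nonzero(bad)[0][:5]]
        raise ValueError(f"non-finite values in feature(s): {', '.join(names)}")
    means = X.mean(axis=0)
    return FeatureMatrix(X - means, feature_ids, means, centered=True)


def _as_centered(X, feature_ids=None) -> FeatureMatrix:
    if isinstance(X, FeatureMatrix):
        if not X.centered:
            return center(X.data, X.feature_ids)
        return X
    return center(X, feature_ids)


def orthonormal_basis(selected: np.ndarray) -> np.ndarray:
    """Orthonormal basis U of the column space of ``selected`` via thin SVD,
    dropping directions with singular value < SV_RTOL x the largest."""
    if selected.size == 0:
        return np.zeros((selected.shape[0], 0))
    U, s, _ = np.linalg.svd(selected, full_matrices=False)
    keep = s > SV_RTOL * s[0] if s.size else np.zeros(0, dtype=bool)
    return U[:, keep]


def deflate(X: np.ndarray | FeatureMatrix, selected: np.ndarray) -> np.ndarray:
    """R^k = X - U U^T X, with U an orthonormal basis of span(selected)."""
    data = X.data if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    selected = np.asarray(selected, dtype=float)
    if selected.ndim == 1:
        selected = selected[:, None]
    if selected.shape[1] == 0:
        return data.copy()
    if selected.shape[0] != data.shape[0]:
        raise ValueError("selected columns must have the same number of samples")
    U = orthonormal_basis(selected)
    return data - U @ (U.T @ data)


def select_next(
    Rk: np.ndarray,
    y: Outcome,
    excluded: Sequence[int] = (),
    offset: Optional[np.ndarray] = None,
) -> tuple[int, UnivariateFit]:
    """Index and fit of the candidate column with maximal log-likelihood.

    Columns in ``excluded`` and columns whose variance fell below ``VAR_TOL``
    after deflation are out of candidacy.  Ties break to the lowest index.
    """
    Rk = np.asarray(Rk, dtype=float)
    variances = Rk.var(axis=0)
    candidate = variances > VAR_TOL
    candidate[list(excluded)] = False
    if not candidate.any():
        raise core.DegenerateOutcomeError(
            "no candidate columns with variance above tolerance"
        )
    idx = np.nonzero(candidate)[0]
    icpt, slope, ll, conv = core.fit_univariate_many(Rk[:, idx], y, offset=offset)
    best = int(idx[np.argmax(ll)])
    pos = int(np.nonzero(idx == best)[0][0])
    fit_ = UnivariateFit(
        slope[pos] if np.ndim(slope[pos]) else float(slope[pos]),
        icpt[pos] if np.ndim(icpt[pos]) else float(icpt[pos]),
        float(ll[pos]),
        bool(conv[pos]),
    )
    return best, fit_


def fit(
    X: np.ndarray | FeatureMatrix,
    y: Outcome,
    opts: FitOptions = FitOptions(),
    feature_ids: Optional[Sequence[str]] = None,
) -> FsplsModel:
    """Run the FS-PLS loop: center, deflate, select, shrink-refit, test, stop.

    The linear predictor accumulates fixed per-step contributions; earlier
    steps' coefficients are never revisited.  Each step's LRT compares the new
    feature's fit (with the accumulated predictor as offset) against the
    offset-only model, on 1 degree of freedom (C-1 for multinomial).
    """
    fm = _as_centered(X, feature_ids)
    if fm.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if len(y) != fm.n_samples:
        raise ValueError("outcome length must match the number of samples")

    alpha0 = core.null_intercept(y)
    ll_null = core.null_loglik(y)
    multi = y.family == "multinomial"
    df = (y.n_classes - 1) if multi else 1
    if multi:
        eta = np.tile(np.asarray(alpha0), (fm.n_samples, 1))
    else:
        eta = np.full(fm.n_samples, float(alpha0))

    steps: list[SelectionStep] = []
    selected: list[int] = []
    stop_reason = "pvalue_threshold"
    Xc = fm.data
    while True:
        if opts.max_features is not None and len(steps) >= opts.max_features:
            stop_reason = "max_features"
            break
        Rk = deflate(Xc, Xc[:, selected]) if selected else Xc
        try:
            j, ml_fit = select_next(Rk, y, excluded=selected, offset=eta)
        except core.DegenerateOutcomeError:
            stop_reason = "loglik_degenerate"
            break
        ll_offset_only = core.model_loglik(y, eta)
        pvalue = core.lrt_pvalue(ml_fit.loglik, ll_offset_only, df)
        if pvalue >= opts.pvalue_threshold and not opts.force_to_max:
            stop_reason = "pvalue_threshold"
            break
        d = Rk[:, j]
        refit = core.ridge_refit(d, y, opts.ridge_lambda, offset=eta)
        norm = float(np.linalg.norm(d))
        u = d / norm
        loadings = u @ Xc
        if multi:
            eta = eta + np.asarray(refit.intercept)[None, :] + np.outer(d, refit.coef)
        else:
            eta = eta + refit.intercept + refit.coef * d
        steps.append(
            SelectionStep(
                feature_index=j,
                feature_id=fm.feature_ids[j],
                beta=refit.coef,
                intercept_update=refit.intercept,
                loglik=core.model_loglik(y, eta),
                pvalue=pvalue,
                basis_vector=u,
                loadings=loadings,
                converged=refit.converged,
            )
        )
        selected.append(j)

    return FsplsModel(
        family=y.family,
        feature_ids=fm.feature_ids,
        feature_means=fm.feature_means,
        null_intercept=alpha0,
        null_loglik=ll_null,
        steps=steps,
        stop_reason=stop_reason,
        options=opts,
        n_classes=y.n_classes,
    )


def linear_predictor(
    model: FsplsModel,
    Xnew: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
    through_step: Optional[int] = None,
) -> np.ndarray:
    """Replay the saved orthogonalisations on new samples.

    ``Xnew`` is (n, q) over any feature universe that covers the model's
    selected features; ``feature_ids`` names its columns (defaults to the
    model's training universe in order).  Only selected-feature columns are
    read, so a sample can be scored from the selected measurements alone, one
    sample at a time.
    """
    steps = model.steps if through_step is None else model.steps[:through_step]
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if feature_ids is None:
        if Xnew.shape[1] != len(model.feature_ids):
            raise ValueError(
                "feature_ids required when Xnew does not match the training universe"
            )
        feature_ids = model.feature_ids
    colmap = {fid: j for j, fid in enumerate(map(str, feature_ids))}
    needed = [s.feature_id for s in steps]
    missing = [fid for fid in needed if fid not in colmap]
    if missing:
        raise ValueError(f"missing required feature(s): {', '.join(missing)}")

    n = Xnew.shape[0]
    multi = model.family == "multinomial"
    if multi:
        eta = np.tile(np.asarray(model.null_intercept), (n, 1))
    else:
        eta = np.full(n, float(model.null_intercept))

    model_index = {fid: j for j, fid in enumerate(model.feature_ids)}
    # centered selected-feature values, deflated progressively
    Z = np.empty((n, len(steps)))
    for k, s in enumerate(steps):
        Z[:, k] = Xnew[:, colmap[s.feature_id]] - model.feature_means[
            model_index[s.feature_id]
        ]
    for k, s in enumerate(steps):
        z = Z[:, k].copy()
        if multi:
            eta = eta + np.asarray(s.intercept_update)[None, :] + np.outer(
                z, np.asarray(s.beta)
            )
        else:
            eta = eta + s.intercept_update + s.beta * z
        own = s.loadings[model_index[s.feature_id]]
        t = z / own
        for k2 in range(k + 1, len(steps)):
            Z[:, k2] -= t * s.loadings[model_index[steps[k2].feature_id]]
    return eta


def predict(
    model: FsplsModel,
    Xnew: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
    through_step: Optional[int] = None,
) -> np.ndarray:
    """Per-sample predictions on the response scale.

    gaussian -> fitted value; binomial -> probability of class 1;
    multinomial -> (n, C) rows on the probability simplex.
    """
    eta = linear_predictor(model, Xnew, feature_ids, through_step)
    if model.family == "gaussian":
        return eta
    if model.family == "binomial":
        from scipy.special import expit

        return expit(eta)
    from scipy.special import softmax

    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    return softmax(full, axis=1)


def select_model_size(
    losses: Sequence[float],
    rule: str = "min",
    se: Optional[Sequence[float]] = None,
) -> int:
    """Model size (number of steps, 1-based) by the 'min' or '1se' rule.

    ``losses[k-1]`` is the loss of the k-step model.  'min' returns the
    smallest argmin; 'one_se' returns the smallest k whose loss is within one
    standard error of the minimum (the standard error of the minimizing
    entry, as in glmnet's lambda.1se).
    """
    losses = np.asarray(losses, dtype=float)
    if losses.size == 0:
        raise ValueError("empty loss vector")
    k_min = int(np.argmin(losses))
    if rule == "min":
        return k_min + 1
    if rule != "one_se":
        raise ValueError(f"unknown rule {rule!r}")
    if se is None:
        raise ValueError("one_se rule requires standard errors")
    se = np.asarray(se, dtype=float)
    if se.shape != losses.shape:
        raise ValueError("se must have the same length as losses")
    threshold = losses[k_min] + se[k_min]
    return int(np.nonzero(losses <= threshold)[0][0]) + 1
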