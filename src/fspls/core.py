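"""Univariate generalized-linear fitting primitives.

Everything in the selection algorithm reduces to fitting a single feature
against an outcome -- possibly with an accumulated linear predictor supplied
as a fixed offset, and possibly with an L2 (ridge) penalty on the slope.
Three outcome families are supported: gaussian (identity link, profile
variance), binomial (logit link) and multinomial (softmax with class 0 as
reference, fitted on the exact likelihood).

Log-likelihoods are always weighted sums ``sum_i w_i * log p(y_i)``; absent
weights default to 1.  The gaussian likelihood uses the profile (maximum
likelihood) error variance so that likelihood-ratio statistics are
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Outcome",
    "UnivariateFit",
    "DegenerateOutcomeError",
    "fit_univariate",
    "null_loglik",
    "null_intercept",
    "ridge_refit",
    "lrt_pvalue",
]

#: Families understood by this module.
FAMILIES = ("gaussian", "binomial", "multinomial")

#: Cap on slope magnitude, on the standardized (unit-variance predictor)
#: scale.  Hit only under (quasi-)separation; such fits are flagged
#: ``converged=False`` instead of diverging.
COEF_CAP = 30.0

#: Relative log-likelihood convergence tolerance and iteration cap for the
#: iterative (binomial / multinomial) fits.
LOGLIK_RTOL = 1e-8
MAX_ITER = 100

#: Floor on the gaussian profile variance, guarding exact-fit degeneracy.
VAR_FLOOR = 1e-12

_PROB_EPS = 1e-12


class DegenerateOutcomeError(ValueError):
    """Raised when an outcome admits no non-trivial model (e.g. one class)."""


@dataclass(frozen=True)
class Outcome:
    """An outcome vector tagged with its family and optional sample weights.

    Parameters
    ----------
    values
        Length-m vector: reals (gaussian), {0,1} (binomial) or integer class
        labels 0..C-1 (multinomial, C >= 3).
    family
        One of ``gaussian``, ``binomial``, ``multinomial``.
    weights
        Optional non-negative per-sample weights with at least one strictly
        positive entry.
    """

    values: np.ndarray
    family: str
    weights: Optional[np.ndarray] = None
    n_classes: int = field(init=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if values.ndim != 1 or values.size == 0:
            raise ValueError("outcome values must be a non-empty 1-d vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("outcome contains non-finite values")
        if self.family == "binomial":
            if not np.all(np.isin(values, (0.0, 1.0))):
                raise ValueError("binomial outcome values must be in {0, 1}")
            n_classes = 2
        elif self.family == "multinomial":
            labels = np.unique(values)
            if not np.all(labels == np.arange(labels.size)):
                raise ValueError(
                    "multinomial labels must be 0..C-1 with every class present"
                )
            if labels.size < 3:
                raise ValueError(
                    "multinomial outcome needs C >= 3 classes; use binomial"
                )
            n_classes = int(labels.size)
        else:
            n_classes = 1
        object.__setattr__(self, "n_classes", n_classes)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != values.shape:
                raise ValueError("weights length must match outcome length")
            if np.any(w < 0) or not np.all(np.isfinite(w)):
                raise ValueError("weights must be finite and non-negative")
            if not np.any(w > 0):
                raise ValueError("weights must include a strictly positive entry")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.values.size

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones_like(self.values)
        return self.weights


@dataclass(frozen=True)
class UnivariateFit:
    """Result of a single-feature fit.

    ``coef`` / ``intercept`` are scalars for gaussian and binomial, and
    length-(C-1) arrays for multinomial (class 0 is the reference).
    ``loglik`` is the attained log-likelihood *including* any offset supplied
    to the fit, i.e. the cumulative-model log-likelihood.
    """

    coef: np.ndarray | float
    intercept: np.ndarray | float
    loglik: float
    converged: bool = True


# ---------------------------------------------------------------------------
# family log-likelihoods
# ---------------------------------------------------------------------------

def _gaussian_loglik(y: np.ndarray, w: np.ndarray, mu: np.ndarray) -> float:
    W = w.sum()
    rss = float(np.sum(w * (y - mu) ** 2))
    sigma2 = max(rss / W, VAR_FLOOR)
    return -0.5 * W * (np.log(2.0 * np.pi * sigma2) + rss / (W * sigma2))


def _binomial_loglik(y: np.ndarray, w: np.ndarray, eta: np.ndarray) -> float:
    # log-likelihood written via log1p(exp) for stability
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _multinomial_loglik(y_onehot: np.ndarray, w: np.ndarray, eta: np.ndarray) -> float:
    """eta: (m, C-1) non-reference logits; reference class logit is 0."""
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    logz = special.logsumexp(full, axis=1)
    return float(np.sum(w * (np.sum(y_onehot[:, 1:] * eta, axis=1) - logz)))


def model_loglik(y: Outcome, eta: np.ndarray) -> float:
    """Log-likelihood of outcome ``y`` at linear predictor ``eta``.

    ``eta`` has shape (m,) for gaussian/binomial and (m, C-1) for multinomial.
    """
    w = y.effective_weights()
    if y.family == "gaussian":
        return _gaussian_loglik(y.values, w, np.asarray(eta))
    if y.family == "binomial":
        return _binomial_loglik(y.values, w, np.asarray(eta))
    return _multinomial_loglik(_onehot(y), w, np.atleast_2d(eta))


def _onehot(y: Outcome) -> np.ndarray:
    idx = y.values.astype(int)
    out = np.zeros((idx.size, y.n_classes))
    out[np.arange(idx.size), idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def null_intercept(y: Outcome) -> np.ndarray | float:
    """Maximum-likelihood intercept(s) of the intercept-only model."""
    w = y.effective_weights()
    W = w.sum()
    if y.family == "gaussian":
        return float(np.sum(w * y.values) / W)
    if y.family == "binomial":
        p = float(np.sum(w * y.values) / W)
        if p <= 0.0 or p >= 1.0:
            raise DegenerateOutcomeError("binomial outcome has a single class")
        return float(special.logit(p))
    counts = w @ _onehot(y)
    if np.any(counts <= 0):
        raise DegenerateOutcomeError("multinomial outcome has an empty class")
    props = counts / W
    return np.log(props[1:] / props[0])


def null_loglik(y: Outcome) -> float:
    """Log-likelihood of the intercept-only model for ``y``'s family."""
    w = y.effective_weights()
    W = w.sum()
    if y.family == "gaussian":
        mu = np.sum(w * y.values) / W
        if np.sum(w * (y.values - mu) ** 2) / W < VAR_FLOOR:
            raise DegenerateOutcomeError("gaussian outcome is (near-)constant")
        return _gaussian_loglik(y.values, w, np.full_like(y.values, mu))
    if y.family == "binomial":
        p = float(np.sum(w * y.values) / W)
        if p <= 0.0 or p >= 1.0:
            raise DegenerateOutcomeError("binomial outcome has a single class")
        return float(W * (p * np.log(p) + (1 - p) * np.log(1 - p)))
    counts = w @ _onehot(y)
    if np.any(counts <= 0):
        raise DegenerateOutcomeError("multinomial outcome has an empty class")
    props = counts / W
    return float(np.sum(counts * np.log(props)))


# ---------------------------------------------------------------------------
# gaussian fits (closed form / 1-d concentrated ridge)
# ---------------------------------------------------------------------------

def _gaussian_fit_many(
    X: np.ndarray, y: Outcome, offset: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least-squares fit of (y - offset) on every column of X.

    Returns per-column arrays (intercept, slope, loglik, converged).  The
    ridge case (lam > 0) penalizes the standardized slope and is solved by a
    1-d root find on the concentrated penalized score.
    """
    w = y.effective_weights()
    W = w.sum()
    r = y.values - offset
    rbar = np.sum(w * r) / W
    rc = r - rbar
    xbar = (w @ X) / W
    Xc = X - xbar
    A = float(np.sum(w * rc**2))
    B = w @ (Xc * rc[:, None])
    Cq = w @ (Xc**2)
    safe = Cq > 0
    slope = np.zeros(X.shape[1])
    np.divide(B, Cq, out=slope, where=safe)
    converged = np.ones(X.shape[1], dtype=bool)
    if lam > 0.0:
        s2 = Cq / W  # weighted variance of each column
        for j in np.nonzero(safe & (np.abs(B) > 0))[0]:
            slope[j] = _gaussian_ridge_slope(
                A, float(B[j]), float(Cq[j]), W, lam * float(s2[j])
            )
    rss = np.maximum(A - 2.0 * slope * B + slope**2 * Cq, 0.0)
    sigma2 = np.maximum(rss / W, VAR_FLOOR)
    ll = -0.5 * W * (np.log(2.0 * np.pi * sigma2) + rss / (W * sigma2))
    intercept = rbar - slope * xbar
    return intercept, slope, ll, converged


def _gaussian_ridge_slope(A: float, B: float, C: float, W: float, k: float) -> float:
    """Maximize -(W/2) log(RSS(b)/W) - k b^2 with RSS(b) = A - 2Bb + Cb^2.

    ``k`` already folds in the standardization (k = lam * var(x)).  The
    stationarity condition W (B - C b) / RSS(b) = 2 k b has a unique root
    between 0 and the unpenalized slope B/C.
    """
    b_ols = B / C

    def score(b: float) -> float:
        rss = max(A - 2.0 * B * b + C * b * b, VAR_FLOOR)
        return W * (B - C * b) / rss - 2.0 * k * b

    lo, hi = (0.0, b_ols) if b_ols > 0 else (b_ols, 0.0)
    if score(lo) * score(hi) > 0:  # penalty negligible at float precision
        return b_ols
    return float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12))


# ---------------------------------------------------------------------------
# binomial fits (vectorized Newton across columns)
# ---------------------------------------------------------------------------

def _binomial_fit_many(
    X: np.ndarray, y: Outcome, offset: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic fit eta = offset + a + b x, Newton on (a, b).

    All columns are updated simultaneously; the 2x2 Newton systems are solved
    in closed form.  Slopes are capped at ``COEF_CAP`` on the standardized
    scale; columns at the cap are flagged not-converged (separation).
    """
    w = y.effective_weights()
    yv = y.values
    m, p = X.shape
    sd = np.sqrt(np.maximum((w @ (X - (w @ X) / w.sum()) ** 2) / w.sum(), 0.0))
    cap = np.where(sd > 0, COEF_CAP / np.maximum(sd, 1e-300), np.inf)
    ridge = 2.0 * lam * sd**2

    a = np.zeros(p)
    b = np.zeros(p)
    eta = offset[:, None] + a + b * X
    ll = _binom_ll_cols(yv, w, eta) - lam * (b * sd) ** 2
    active = np.ones(p, dtype=bool)
    for _ in range(MAX_ITER):
        mu = special.expit(eta)
        Wv = w[:, None] * mu * (1.0 - mu)
        R = w[:, None] * (yv[:, None] - mu)
        g1 = R.sum(axis=0)
        g2 = (R * X).sum(axis=0) - ridge * b
        h11 = Wv.sum(axis=0)
        h12 = (Wv * X).sum(axis=0)
        h22 = (Wv * X * X).sum(axis=0) + ridge
        det = h11 * h22 - h12 * h12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        # zero-variance columns: slope unidentifiable, fit intercept only
        novar = sd == 0
        if novar.any():
            da[novar] = g1[novar] / np.maximum(h11[novar], 1e-300)
            db[novar] = 0.0
        np.clip(da, -10.0, 10.0, out=da)
        np.clip(db, -cap / 3.0, cap / 3.0, out=db)
        a = np.where(active, a + da, a)
        b = np.where(active, np.clip(b + db, -cap, cap), b)
        eta = offset[:, None] + a + b * X
        ll_new = _binom_ll_cols(yv, w, eta) - lam * (b * sd) ** 2
        moved = np.abs(ll_new - ll) > LOGLIK_RTOL * (np.abs(ll) + 1.0)
        active = active & moved
        ll = ll_new
        if not active.any():
            break
    at_cap = np.abs(b) >= cap * (1.0 - 1e-9)
    converged = ~active & ~at_cap
    loglik = _binom_ll_cols(yv, w, offset[:, None] + a + b * X)
    return a, b, loglik, converged


def _binom_ll_cols(y: np.ndarray, w: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return np.sum(w[:, None] * (y[:, None] * eta - np.logaddexp(0.0, eta)), axis=0)


# ---------------------------------------------------------------------------
# multinomial fit (damped Newton, exact likelihood, one column at a time)
# ---------------------------------------------------------------------------

def _multinomial_fit_one(
    x: np.ndarray, y: Outcome, offset: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Fit eta_c = offset_c + a_c + b_c x for classes c = 1..C-1.

    Newton iterations on the exact multinomial likelihood with step halving;
    slopes capped at COEF_CAP / sd(x) per class.
    """
    w = y.effective_weights()
    W = w.sum()
    Y = _onehot(y)
    K = y.n_classes - 1
    sd = float(np.sqrt(max(np.sum(w * (x - np.sum(w * x) / W) ** 2) / W, 0.0)))
    cap = COEF_CAP / sd if sd > 0 else np.inf
    ridge = 2.0 * lam * sd * sd

    a = np.zeros(K)
    b = np.zeros(K)

    def eta_of(a, b):
        return offset + a[None, :] + np.outer(x, b)

    def penll(a, b):
        return _multinomial_loglik(Y, w, eta_of(a, b)) - lam * (sd * b) @ (sd * b)

    ll = penll(a, b)
    converged = False
    for _ in range(MAX_ITER):
        eta = eta_of(a, b)
        full = np.concatenate([np.zeros((x.size, 1)), eta], axis=1)
        P = special.softmax(full, axis=1)[:, 1:]  # (m, K)
        resid = w[:, None] * (Y[:, 1:] - P)
        g = np.empty(2 * K)
        g[0::2] = resid.sum(axis=0)
        g[1::2] = resid.T @ x - ridge * b
        # Hessian of the negative loglik: blocks over class pairs (c, d)
        H = np.zeros((2 * K, 2 * K))
        for c in range(K):
            for d in range(K):
                wcd = w * (P[:, c] * ((1.0 if c == d else 0.0) - P[:, d]))
                s0 = wcd.sum()
                s1 = wcd @ x
                s2 = wcd @ (x * x)
                H[2 * c, 2 * d] += s0
                H[2 * c, 2 * d + 1] += s1
                H[2 * c + 1, 2 * d] += s1
                H[2 * c + 1, 2 * d + 1] += s2
        H[1::2, 1::2] += np.eye(K) * ridge
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(2 * K), g)
        except np.linalg.LinAlgError:
            break
        if sd == 0:  # slope unidentifiable for a constant column
            step[1::2] = 0.0
        t = 1.0
        for _ in range(30):
            a_new = a + t * step[0::2]
            b_new = np.clip(b + t * step[1::2], -cap, cap)
            ll_new = penll(a_new, b_new)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        a, b = a_new, b_new
        if abs(ll_new - ll) <= LOGLIK_RTOL * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    at_cap = np.any(np.abs(b) >= cap * (1.0 - 1e-9))
    loglik = _multinomial_loglik(Y, w, eta_of(a, b))
    return a, b, loglik, converged and not at_cap


# ---------------------------------------------------------------------------
# public fitting surface
# ---------------------------------------------------------------------------

def _check_x(x: np.ndarray, y: Outcome) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != len(y):
        raise ValueError("feature vector length must match the outcome")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains non-finite values")
    return x


def _default_offset(y: Outcome) -> np.ndarray:
    if y.family == "multinomial":
        return np.zeros((len(y), y.n_classes - 1))
    return np.zeros(len(y))


def fit_univariate(
    x: np.ndarray, y: Outcome, offset: Optional[np.ndarray] = None
) -> UnivariateFit:
    """Maximum-likelihood intercept + slope of ``y`` regressed on ``x``.

    ``offset`` (optional) is a fixed component of the linear predictor; the
    returned log-likelihood includes it, so with an offset this is the
    cumulative-model log-likelihood.  A zero-variance ``x`` yields slope 0
    (the null / offset-only model).
    """
    return ridge_refit(x, y, 0.0, offset=offset)


def ridge_refit(
    x: np.ndarray, y: Outcome, lam: float, offset: Optional[np.ndarray] = None
) -> UnivariateFit:
    """Fit with L2 penalty ``lam * beta_std**2`` on the standardized slope.

    The feature is standardized to unit variance inside the penalty only; the
    returned coefficient is on the original scale.  ``lam = 0`` reproduces
    :func:`fit_univariate`.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    x = _check_x(x, y)
    if offset is None:
        offset = _default_offset(y)
    else:
        offset = np.asarray(offset, dtype=float)
    if y.family == "gaussian":
        icpt, slope, ll, conv = _gaussian_fit_many(x[:, None], y, offset, lam)
        return UnivariateFit(float(slope[0]), float(icpt[0]), float(ll[0]), bool(conv[0]))
    if y.family == "binomial":
        icpt, slope, ll, conv = _binomial_fit_many(x[:, None], y, offset, lam)
        return UnivariateFit(float(slope[0]), float(icpt[0]), float(ll[0]), bool(conv[0]))
    a, b, ll, conv = _multinomial_fit_one(x, y, np.atleast_2d(offset), lam)
    return UnivariateFit(b, a, float(ll), bool(conv))


def fit_univariate_many(
    X: np.ndarray, y: Outcome, offset: Optional[np.ndarray] = None, lam: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit every column of ``X`` univariately; returns (icpt, slope, ll, conv).

    Gaussian and binomial are fully vectorized; multinomial loops columns.
    For multinomial the intercept/slope arrays have shape (p, C-1).
    """
    X = np.asarray(X, dtype=float)
    if offset is None:
        offset = _default_offset(y)
    if y.family == "gaussian":
        return _gaussian_fit_many(X, y, offset, lam)
    if y.family == "binomial":
        return _binomial_fit_many(X, y, offset, lam)
    p = X.shape[1]
    K = y.n_classes - 1
    icpt = np.zeros((p, K))
    slope = np.zeros((p, K))
    ll = np.zeros(p)
    conv = np.zeros(p, dtype=bool)
    off2 = np.atleast_2d(offset)
    for j in range(p):
        icpt[j], slope[j], ll[j], conv[j] = _multinomial_fit_one(X[:, j], y, off2, lam)
    return icpt, slope, ll, conv


def lrt_pvalue(loglik_model: float, loglik_null: float, df: int) -> float:
    """Upper-tail chi-squared p-value of 2*(ll_model - ll_null) at ``df``."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    stat = 2.0 * (loglik_model - loglik_null)
    if stat < -1e-6 * (abs(loglik_null) + 1.0):
        raise ValueError(
            f"model log-likelihood {loglik_model} below null {loglik_null}"
        )
    return float(stats.chi2.sf(max(stat, 0.0), df))
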