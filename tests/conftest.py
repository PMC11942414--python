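"""Shared fixtures and independent oracles.

The oracles here re-derive log-likelihoods from first principles and optimize
them with generic scipy routines; they share no code path with the package's
own Newton/closed-form fitters, which is what makes the comparisons tests.
"""

import numpy as np
import pytest
from scipy import optimize, special


def gaussian_profile_loglik(y, mu, w=None):
    """Gaussian log-likelihood at the profile (MLE) variance."""
    w = np.ones_like(y) if w is None else w
    W = w.sum()
    rss = np.sum(w * (y - mu) ** 2)
    s2 = rss / W
    return -0.5 * W * (np.log(2 * np.pi * s2) + 1.0)


def binomial_loglik(y, eta, w=None):
    w = np.ones_like(y) if w is None else w
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def multinomial_loglik(labels, eta, w=None):
    """eta: (m, C-1) non-reference logits."""
    labels = labels.astype(int)
    w = np.ones(labels.size) if w is None else w
    full = np.column_stack([np.zeros(labels.size), eta])
    logp = full - special.logsumexp(full, axis=1, keepdims=True)
    return float(np.sum(w * logp[np.arange(labels.size), labels]))


def oracle_univariate(x, y, family, w=None, lam=0.0, offset=None):
    """Generic-optimizer fit of intercept+slope; penalty lam*(b*sd(x))^2.

    Returns (intercept, slope, loglik) maximizing the (penalized) likelihood.
    For multinomial, intercept/slope are length C-1 arrays.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = x.size
    wv = np.ones(m) if w is None else np.asarray(w, float)
    sd = np.sqrt(np.sum(wv * (x - np.sum(wv * x) / wv.sum()) ** 2) / wv.sum())

    if family == "gaussian":
        off = np.zeros(m) if offset is None else offset

        def neg(theta):
            a, b = theta
            return -(gaussian_profile_loglik(y, off + a + b * x, wv) - lam * (b * sd) ** 2)

        res = optimize.minimize(neg, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        a, b = res.x
        return a, b, gaussian_profile_loglik(y, off + a + b * x, wv)
    if family == "binomial":
        off = np.zeros(m) if offset is None else offset

        def neg(theta):
            a, b = theta
            return -(binomial_loglik(y, off + a + b * x, wv) - lam * (b * sd) ** 2)

        res = optimize.minimize(neg, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        a, b = res.x
        return a, b, binomial_loglik(y, off + a + b * x, wv)
    # multinomial, reference class 0
    C = int(y.max()) + 1
    K = C - 1
    off = np.zeros((m, K)) if offset is None else offset

    def neg(theta):
        a, b = theta[:K], theta[K:]
        eta = off + a[None, :] + np.outer(x, b)
        return -(multinomial_loglik(y, eta, wv) - lam * np.sum((b * sd) ** 2))

    res = optimize.minimize(neg, np.zeros(2 * K), method="Nelder-Mead",
                            options={"xatol": 1e-11, "fatol": 1e-13, "maxiter": 50000})
    a, b = res.x[:K], res.x[K:]
    eta = off + a[None, :] + np.outer(x, b)
    return a, b, multinomial_loglik(y, eta, wv)


def gram_schmidt_deflate(X, selected):
    """Sequential Gram-Schmidt deflation oracle: remove each selected column's
    direction from X one at a time."""
    R = X.astype(float).copy()
    S = selected.astype(float).copy()
    for k in range(S.shape[1]):
        v = S[:, k].copy()
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            continue
        v /= nv
        R -= np.outer(v, v @ R)
        S -= np.outer(v, v @ S)
    return R


def forward_ols_path(X, y, k):
    """Greedy forward selection oracle: at each step add the feature that
    minimizes the RSS of OLS (with intercept) on the selected set."""
    m, p = X.shape
    selected = []
    for _ in range(k):
        best, best_rss = None, np.inf
        for j in range(p):
            if j in selected:
                continue
            D = np.column_stack([np.ones(m)] + [X[:, i] for i in selected + [j]])
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            rss = float(np.sum((y - D @ beta) ** 2))
            if rss < best_rss - 1e-12:
                best, best_rss = j, rss
        selected.append(best)
    return selected


@pytest.fixture(scope="session")
def golden():
    from fspls import golden_fixtures

    return golden_fixtures()
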