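"""Synthetic omics-like data with known ground truth.

The generator emulates the statistical regime the selection and
normalisation machinery assumes: negative-binomially over-dispersed counts
whose means factor into a per-sample library-size factor, a per-feature
baseline abundance, and a class-dependent effect; a small set of truly
outcome-associated features; optional blocks of mutually correlated nuisance
features (driven by a shared latent log-normal factor); and "housekeeping"
features that scale strictly with library size apart from a small log-scale
noise, making them ideal normalisation surrogates.  A gaussian variant of
the same machinery serves microarray-like tests.  Everything is driven by a
single seeded generator; same spec, same seed, same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["SimulationSpec", "SimulationTruth", "simulate", "simulate_gaussian",
           "golden_fixtures"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated count dataset.

    Defaults are a two-class RNA-seq-like problem: m=200 samples, p=500
    features, 4 planted markers at log-fold-change 1.0, 2 housekeeping
    features (log-noise sd 0.02), log-normal size factors with sd 0.5, and
    NB dispersion 0.3.
    """

    m: int = 200
    p: int = 500
    family: str = "binomial"  # binomial | multinomial | gaussian outcome
    n_signal: int = 4
    effect_size: float = 1.0  # log-fold-change of planted markers
    n_housekeeping: int = 2
    housekeeping_noise_sd: float = 0.02
    #: abundance multiplier for housekeeping features; library-size
    #: surrogates sit at the top of the expression distribution, well above
    #: the typical feature
    housekeeping_scale: float = 30.0
    size_factor_sd: float = 0.5
    correlation_blocks: tuple[tuple[int, float], ...] = ()
    block_strength: float = 2.0  # log-scale sd of the block latent factor
    nb_dispersion: float = 0.3
    #: (size, rho): extra nuisance features correlated with signal feature 0
    #: at latent level rho AND carrying its class effect -- redundant "twins"
    #: that a marginal ranking loves and deflation should suppress.
    twin_block: Optional[tuple[int, float]] = None
    class_proportions: Optional[tuple[float, ...]] = None
    base_log_mean: float = 4.0
    base_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_signal + self.n_housekeeping > self.p:
            raise ValueError("n_signal + n_housekeeping exceeds p")
        if self.class_proportions is not None:
            props = np.asarray(self.class_proportions, dtype=float)
            if not np.isclose(props.sum(), 1.0):
                raise ValueError("class_proportions must sum to 1")
        n_extra = sum(b for b, _ in self.correlation_blocks)
        if self.twin_block is not None:
            if self.n_signal < 1:
                raise ValueError("twin_block requires at least one signal feature")
            n_extra += self.twin_block[0]
        if n_extra > self.p - self.n_signal - self.n_housekeeping:
            raise ValueError("correlation blocks do not fit among nuisance features")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    signal_indices: np.ndarray
    housekeeping_indices: np.ndarray
    twin_indices: np.ndarray
    block_indices: list[np.ndarray]
    size_factors: np.ndarray
    effects: np.ndarray  # (C, p) log-fold-change per class and feature
    labels: np.ndarray


def _class_labels(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "multinomial":
        C = len(spec.class_proportions) if spec.class_proportions else 3
    elif spec.family == "binomial":
        C = 2
    else:
        return np.zeros(spec.m, dtype=int)
    props = (
        np.asarray(spec.class_proportions, dtype=float)
        if spec.class_proportions
        else np.full(C, 1.0 / C)
    )
    # deterministic near-exact proportions, shuffled, so every class is present
    counts = np.floor(props * spec.m).astype(int)
    while counts.sum() < spec.m:
        counts[np.argmax(props * spec.m - counts)] += 1
    labels = np.repeat(np.arange(C), counts)
    rng.shuffle(labels)
    return labels


def simulate(
    spec: SimulationSpec,
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Draw (counts, outcome labels, truth record) for ``spec``.

    Counts are NB with mean s_i * base_g * exp(effect(class_i, g) + latent
    block term); housekeeping features instead follow s_i * base_g up to
    log-normal noise of sd ``housekeeping_noise_sd`` (no NB over-dispersion),
    so their abundance tracks the library size almost exactly.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _class_labels(spec, rng)
    C = max(int(labels.max()) + 1, 1)

    size_factors = np.exp(rng.normal(0.0, spec.size_factor_sd, spec.m))
    base = np.exp(rng.normal(spec.base_log_mean, spec.base_log_sd, spec.p))

    perm = rng.permutation(spec.p)
    signal_idx = perm[: spec.n_signal]
    hk_idx = perm[spec.n_signal : spec.n_signal + spec.n_housekeeping]
    nuisance = perm[spec.n_signal + spec.n_housekeeping :]

    effects = np.zeros((C, spec.p))
    if spec.family in ("binomial", "multinomial"):
        for r, g in enumerate(signal_idx):
            c = 1 + r % (C - 1) if C > 1 else 0
            sign = 1.0 if (r // max(C - 1, 1)) % 2 == 0 else -1.0
            effects[c, g] = sign * spec.effect_size

    log_mu = (
        np.log(size_factors)[:, None]
        + np.log(base)[None, :]
        + effects[labels, :]
    )

    block_indices: list[np.ndarray] = []
    pos = 0
    twin_idx = np.array([], dtype=int)
    if spec.twin_block is not None:
        size, rho = spec.twin_block
        anchor = signal_idx[0]
        twin_idx = nuisance[pos : pos + size]
        pos += size
        shared = rng.normal(0.0, 1.0, spec.m)
        log_mu[:, anchor] += spec.block_strength * np.sqrt(rho) * shared
        for j in twin_idx:
            own = rng.normal(0.0, 1.0, spec.m)
            log_mu[:, j] += effects[labels, anchor] + spec.block_strength * (
                np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            )
    for size, rho in spec.correlation_blocks:
        idx = nuisance[pos : pos + size]
        pos += size
        block_indices.append(idx)
        shared = rng.normal(0.0, 1.0, spec.m)
        own = rng.normal(0.0, 1.0, (spec.m, size))
        z = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * own
        log_mu[:, idx] += spec.block_strength * z

    mu = np.exp(log_mu)
    counts = np.empty((spec.m, spec.p))
    r = 1.0 / spec.nb_dispersion  # NB shape: var = mu + dispersion * mu^2
    nb_cols = np.ones(spec.p, dtype=bool)
    nb_cols[hk_idx] = False
    counts[:, nb_cols] = rng.negative_binomial(
        r, r / (r + mu[:, nb_cols]), size=(spec.m, int(nb_cols.sum()))
    )
    # housekeeping features scale strictly with the realized library size:
    # a fixed (large) share of each sample's background total, up to small
    # log-scale noise -- the over-dispersion of abundant features makes the
    # realized total noisier than the latent size factor, and a usable
    # surrogate must track the former
    if spec.n_housekeeping:
        background = counts[:, nb_cols].sum(axis=1)
        share = spec.housekeeping_scale * base[hk_idx] / base.sum()
        counts[:, hk_idx] = np.round(
            background[:, None]
            * share[None, :]
            * np.exp(
                rng.normal(
                    0.0, spec.housekeeping_noise_sd, (spec.m, spec.n_housekeeping)
                )
            )
        )

    truth = SimulationTruth(
        signal_indices=np.sort(signal_idx),
        housekeeping_indices=np.sort(hk_idx),
        twin_indices=np.sort(twin_idx),
        block_indices=block_indices,
        size_factors=size_factors,
        effects=effects,
        labels=labels,
    )
    if spec.family == "gaussian":
        coefs = np.zeros(spec.p)
        coefs[signal_idx] = spec.effect_size
        log_x = np.log1p(counts)
        y = (log_x - log_x.mean(axis=0)) @ coefs + rng.normal(0, 1.0, spec.m)
        return counts, y, truth
    return counts, labels.astype(float), truth


def simulate_gaussian(
    m: int,
    p: int,
    signal: dict[int, float],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Microarray-like design: standard-normal X, y = X beta + noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (m, p))
    beta = np.zeros(p)
    for j, b in signal.items():
        beta[j] = b
    y = X @ beta + rng.normal(0.0, noise_sd, m)
    return X, y


def golden_fixtures() -> dict:
    """Three small fixed datasets with hand-checkable answers.

    a: 12 x 6 gaussian problem whose selection path is checkable against a
       forward-OLS oracle (ridge off);
    b: 40 x 20 binomial problem with 2 markers that separate the classes;
    c: 30 x 15 count matrix with 2 exact housekeeping genes tracking
       strongly varying library sizes.
    """
    rng = np.random.default_rng(20240101)
    Xa = rng.normal(0.0, 1.0, (12, 6))
    ya = 2.0 * Xa[:, 1] - 1.5 * Xa[:, 4] + 0.05 * rng.normal(0.0, 1.0, 12)

    # two markers that only jointly separate the classes: both ride a shared
    # nuisance direction z, the class signal lives in their difference
    Xb = rng.normal(0.0, 1.0, (40, 20))
    yb = np.array([0.0] * 20 + [1.0] * 20)
    z = rng.normal(0.0, 1.0, 40)
    delta = np.where(yb == 1, 1.0, -1.0)
    Xb[:, 3] = z + 0.8 * delta + rng.normal(0.0, 0.2, 40)
    Xb[:, 11] = z - 0.8 * delta + rng.normal(0.0, 0.2, 40)
    order = rng.permutation(40)
    Xb, yb = Xb[order], yb[order]

    # housekeeping genes 2 and 9 track the size factors up to small
    # independent log-noise; the rest are noisier low-count Poisson draws,
    # so the model needs both trackers to average their noise down
    s = np.exp(rng.normal(0.0, 0.6, 30))
    base = np.exp(rng.normal(1.5, 0.8, 15))
    mu = s[:, None] * base[None, :]
    Xc = rng.poisson(mu).astype(float)
    for j in (2, 9):
        Xc[:, j] = np.round(
            s * base[j] * 30.0 * np.exp(rng.normal(0.0, 0.08, 30))
        )

    return {
        "a": {"X": Xa, "y": ya, "signal": [1, 4]},
        "b": {"X": Xb, "y": yb, "signal": [3, 11]},
        "c": {"counts": Xc, "housekeeping": [2, 9], "size_factors": s},
    }
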