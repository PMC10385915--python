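"""Latent class analysis of categorical functional indicators.

A finite mixture model with K classes: conditional on class membership the
29 indicators are independent categoricals (local independence).  Fitted by
EM from multiple random starts; model choice uses AIC, BIC, sample-size
adjusted BIC, relative entropy, and a parametric bootstrap likelihood ratio
test (BLRT) of K-1 vs K classes.

All indicators are treated as categorical with per-indicator level counts
taken from the data; continuous measures must be discretized upstream.
Label switching is resolved by a profile-based canonical ordering (mean
impairment probability), never by likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

_EM_MONOTONE_TOL = 1e-8


@dataclass
class LCAParams:
    """Mixture weights ``pi`` (K,) and response profiles ``rho``.

    ``rho[j]`` is a (K, C_j) array: the categorical response distribution of
    indicator j in each class.
    """

    K: int
    pi: np.ndarray
    rho: list

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = [np.asarray(r, dtype=float) for r in self.rho]
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        for j, r in enumerate(self.rho):
            if r.shape[0] != self.K:
                raise ValueError(f"rho[{j}] has {r.shape[0]} rows, expected K={self.K}")
            if np.max(np.abs(r.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"rho[{j}] rows must sum to 1")

    @property
    def n_indicators(self) -> int:
        return len(self.rho)

    @property
    def n_params(self) -> int:
        """(K-1) mixture weights + K * sum_j (C_j - 1) response parameters."""
        return (self.K - 1) + self.K * sum(r.shape[1] - 1 for r in self.rho)

    def sample(self, n: int, rng) -> np.ndarray:
        """Draw n observations from the mixture (parametric bootstrap)."""
        classes = rng.choice(self.K, size=n, p=self.pi)
        out = np.empty((n, self.n_indicators), dtype=int)
        for j, r in enumerate(self.rho):
            cdf = r.cumsum(axis=1)[classes]
            u = rng.random(n)
            out[:, j] = (u[:, None] > cdf[:, :-1]).sum(axis=1)
        return out


@dataclass
class LCAFit:
    params: LCAParams
    loglik: float
    n_obs: int
    posteriors: np.ndarray
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return self.params.n_params

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    @property
    def ssa_bic(self) -> float:
        # sample-size adjusted BIC uses n* = (n + 2) / 24
        return -2.0 * self.loglik + self.n_params * np.log((self.n_obs + 2.0) / 24.0)

    @property
    def entropy(self) -> float:
        return relative_entropy(self.posteriors, self.params.K)


def _log_component_densities(data, params):
    """(n, K) log p(x_i | class k) under local independence."""
    n = data.shape[0]
    ll = np.zeros((n, params.K))
    with np.errstate(divide="ignore"):
        for j, r in enumerate(params.rho):
            ll += np.log(r.T[data[:, j]])  # (n, K)
    return ll


def loglik(data: np.ndarray, params: LCAParams) -> float:
    """Observed-data log-likelihood of the mixture."""
    comp = _log_component_densities(data, params)
    with np.errstate(divide="ignore"):
        comp = comp + np.log(params.pi)
    m = comp.max(axis=1)
    return float((m + np.log(np.exp(comp - m[:, None]).sum(axis=1))).sum())


def _posteriors(data, params):
    comp = _log_component_densities(data, params)
    with np.errstate(divide="ignore"):
        comp = comp + np.log(params.pi)
    m = comp.max(axis=1, keepdims=True)
    w = np.exp(comp - m)
    ll = float((m[:, 0] + np.log(w.sum(axis=1))).sum())
    return w / w.sum(axis=1, keepdims=True), ll

def _n_levels(data):
    return [int(data[:, j].max()) + 1 for j in range(data.shape[1])]


def _random_params(K, levels, rng):
    pi = rng.dirichlet(np.full(K, 5.0))
    rho = [rng.dirichlet(np.ones(C), size=K) for C in levels]
    return LCAParams(K, pi, rho)


def fit_lca(
    data: np.ndarray,
    K: int,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
) -> LCAFit:
    """EM fit of a K-class model; the best of ``n_starts`` restarts is kept.

    ``data`` is an (n, J) integer matrix of 0-based categorical codes with
    no missing cells.  Convergence is declared when the absolute change in
    log-likelihood drops below ``tol``.
    """
    data = np.asarray(data, dtype=int)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a non-empty (n, J) matrix")
    if K < 1:
        raise ValueError("K must be >= 1")
    n, J = data.shape
    levels = _n_levels(data)

    n_patterns = len(np.unique(data, axis=0))
    if K > n_patterns:
        warnings.warn(
            f"K={K} exceeds the {n_patterns} distinct response patterns; "
            "fit attempted but the model is not identified",
            stacklevel=2,
        )

    if K == 1:
        # closed form: marginal sample frequencies
        rho = [np.bincount(data[:, j], minlength=levels[j])[None, :] / n for j in range(J)]
        params = LCAParams(1, np.array([1.0]), rho)
        ll = loglik(data, params)
        return LCAFit(params, ll, n, np.ones((n, 1)), 0, True, np.array([ll]))

    rng = np.random.default_rng(seed)
    # collapse to unique response patterns for speed
    patterns, inverse, counts = np.unique(
        data, axis=0, return_inverse=True, return_counts=True
    )
    w = counts.astype(float)

    best = None
    for _ in range(max(1, n_starts)):
        params = _random_params(K, levels, rng)
        path = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            comp = _log_component_densities(patterns, params)
            with np.errstate(divide="ignore"):
                comp = comp + np.log(params.pi)
            m = comp.max(axis=1, keepdims=True)
            e = np.exp(comp - m)
            denom = e.sum(axis=1)
            post = e / denom[:, None]
            ll = float((w * (m[:, 0] + np.log(denom))).sum())
            if ll < prev - _EM_MONOTONE_TOL:
                raise RuntimeError("EM log-likelihood decreased")
            path.append(ll)
            if abs(ll - prev) < tol:
                converged = True
                break
            prev = ll
            # M-step with pattern weights
            wpost = post * w[:, None]
            Nk = wpost.sum(axis=0)
            pi = Nk / Nk.sum()
            rho = []
            for j in range(J):
                r = np.zeros((K, levels[j]))
                for c in range(levels[j]):
                    mask = patterns[:, j] == c
                    r[:, c] = wpost[mask].sum(axis=0)
                r /= r.sum(axis=1, keepdims=True)
                rho.append(r)
            params = LCAParams(K, pi / pi.sum(), rho)
        if best is None or path[-1] > best[1]:
            best = (params, path[-1], np.array(path), it + 1, converged)

    params, ll, path, n_iter, converged = best
    post_pat, _ = _posteriors(patterns, params)
    return LCAFit(params, ll, n, post_pat[inverse], n_iter, converged, path)


def relative_entropy(posteriors: np.ndarray, K: int) -> float:
    """Relative entropy of the classification: 1 - E[H(post)] / ln K.

    1 means perfect separation (one-hot posteriors), 0 maximal uncertainty.
    For K=1 the quantity is undefined; 1 is returned by convention.
    """
    if K == 1:
        log.info("relative_entropy undefined for K=1; returning 1 by convention")
        return 1.0
    p = np.asarray(posteriors, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log(p), 0.0).sum()
    n = p.shape[0]
    return float(1.0 - h / (n * np.log(K)))


def bootstrap_lrt(
    data: np.ndarray,
    K_null: int,
    K_alt: int | None = None,
    B: int = 99,
    seed: int | None = None,
    reduced_em_opts: dict | None = None,
) -> tuple:
    """Parametric bootstrap LRT of K_null vs K_null + 1 classes.

    Returns ``(statistic, p_value, n_dropped)``; the p-value uses the
    add-one rule (1 + #{bootstrap stats >= observed}) / (B + 1).  Bootstrap
    replicates that fail to converge are dropped with a warning.
    """
    if K_alt is None:
        K_alt = K_null + 1
    if K_alt != K_null + 1:
        raise ValueError("BLRT compares K_null with K_null + 1 classes")
    if B < 1:
        raise ValueError("B must be >= 1")
    # bootstrap refits use a looser tolerance: under the null the K+1 model's
    # likelihood surface is flat and strict EM convergence is slow; a slightly
    # early stop only shrinks the bootstrap statistic (conservative)
    opts = dict(n_starts=3, max_iter=500, tol=1e-3)
    opts.update(reduced_em_opts or {})

    rng = np.random.default_rng(seed)
    null_fit = fit_lca(data, K_null, seed=int(rng.integers(2**31)), **opts)
    alt_fit = fit_lca(data, K_alt, seed=int(rng.integers(2**31)), **opts)
    observed = 2.0 * (alt_fit.loglik - null_fit.loglik)

    stats = []
    dropped = 0
    for _ in range(B):
        boot = null_fit.params.sample(data.shape[0], rng)
        try:
            f0 = fit_lca(boot, K_null, seed=int(rng.integers(2**31)), **opts)
            f1 = fit_lca(boot, K_alt, seed=int(rng.integers(2**31)), **opts)
        except RuntimeError:
            dropped += 1
            continue
        if not (f0.converged and f1.converged):
            dropped += 1
            warnings.warn("bootstrap replicate did not converge; dropped", stacklevel=2)
            continue
        stats.append(2.0 * (f1.loglik - f0.loglik))
    stats = np.array(stats)
    p = (1.0 + np.sum(stats >= observed)) / (len(stats) + 1.0)
    return observed, float(p), dropped


def class_impairment_profile(params: LCAParams) -> np.ndarray:
    """Mean impairment probability per class: average over indicators of the
    probability of a non-baseline (code > 0) response."""
    prof = np.zeros(params.K)
    for r in params.rho:
        prof += 1.0 - r[:, 0]
    return prof / params.n_indicators


def assign_and_name_states(
    fit: LCAFit, severity_order: Sequence[int] = (4, 5, 2, 3, 1)
) -> tuple:
    """Map fitted classes to canonical state ids and assign observations.

    Classes are ranked by mean impairment probability (ascending) and mapped
    onto ``severity_order`` (state ids from mild to severe; the default is
    the 4 < 5 < 2 < 3 < 1 severity ladder).  Assignment is modal-posterior.
    Ties in the profile ranking are broken deterministically by class index
    and logged.  Returns ``(state_per_observation, mapping)`` where mapping
    is {class_index: state_id}.
    """
    K = fit.params.K
    if K == 1:
        return np.ones(fit.posteriors.shape[0], dtype=int), {0: 1}
    if K != len(severity_order):
        raise ValueError(
            f"severity_order names {len(severity_order)} states but K={K}"
        )
    prof = class_impairment_profile(fit.params)
    if len(np.unique(prof)) < K:
        log.warning("tied class profiles; tie broken by class index")
    order = np.argsort(prof, kind="stable")  # mild first, ties by class index
    mapping = {int(cls): int(state) for cls, state in zip(order, severity_order)}
    modal = fit.posteriors.argmax(axis=1)
    states = np.array([mapping[int(c)] for c in modal], dtype=int)
    return states, mapping
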