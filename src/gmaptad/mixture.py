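"""Two-component Gaussian mixture binarization of a contact matrix.

Contacts are modeled as a mixture of an intra-domain component
``Y1 ~ N(mu1, sigma1^2)`` (high frequency) and an inter-domain component
``Y2 ~ N(mu2, sigma2^2)`` with mixing weight ``alpha`` on the intra-domain
component.  The matrix is binarized through the posterior probability of
the intra-domain component: ``h_ij = 1`` iff the posterior exceeds 0.5
(strict inequality).

Normalized Hi-C counts are right-skewed, so by default the mixture is fit
on ``log2(1 + H_ij)``; ``log_transform=False`` fits raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .hic_io import ContactMatrix

__all__ = ["GMMParams", "StateMatrix", "fit_gmm", "state_matrix",
           "eligible_values", "DEFAULT_MAX_DIST_BP"]

#: Background distance cap D: bin pairs further apart never influence calls.
DEFAULT_MAX_DIST_BP = 2_000_000

_MIN_VALUES = 20
_VAR_FLOOR_FRAC = 1e-6


@dataclass
class GMMParams:
    """Fitted mixture parameters, ordered so mu1 >= mu2 (intra-domain high)."""

    mu1: float
    mu2: float
    sigma1_sq: float
    sigma2_sq: float
    alpha: float
    loglik: float
    n_iter: int
    log_transform: bool = True
    loglik_trace: tuple[float, ...] = ()


@dataclass
class StateMatrix:
    """Binary intra-domain state matrix h with its posterior matrix."""

    h: np.ndarray
    posterior: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.h.shape[0]


def max_dist_bins(resolution_bp: int, max_dist_bp: int = DEFAULT_MAX_DIST_BP) -> int:
    """Background cap D in bins (at least 1)."""
    return max(1, int(max_dist_bp // resolution_bp))


def eligible_values(
    cm: ContactMatrix,
    max_dist_bins: int,
    log_transform: bool = True,
) -> np.ndarray:
    """Upper-triangle entries with 1 <= j - i <= max_dist_bins.

    The diagonal is excluded; zeros are kept (they carry inter-domain
    signal).  Values are log2(1+x)-transformed when ``log_transform``.
    """
    n = cm.n_bins
    i, j = np.triu_indices(n, k=1)
    keep = (j - i) <= max_dist_bins
    vals = cm.values[i[keep], j[keep]]
    if log_transform:
        vals = np.log2(1.0 + vals)
    return vals


def fit_gmm(
    values: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    n_restarts: int = 0,
    log_transform: bool = True,
) -> GMMParams:
    """Fit the two-component mixture by EM.

    Initialization is deterministic: the sample is split at its median and
    component 1 (intra-domain) is initialized from the upper half.  Random
    restarts (seeded) are available but off by default.  Convergence is a
    relative log-likelihood change below ``tol``.

    Raises ``ValueError`` on fewer than 20 finite values or a degenerate
    (constant) sample.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < _MIN_VALUES:
        raise ValueError(f"need at least {_MIN_VALUES} finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values identical")

    var_floor = _VAR_FLOOR_FRAC * float(np.var(x))
    var_floor = max(var_floor, 1e-300)

    med = float(np.median(x))
    hi, lo = x[x > med], x[x <= med]
    if hi.size == 0:  # median equals max; split strictly below
        hi, lo = x[x >= med], x[x < med]
    inits = [(
        float(np.mean(hi)), float(np.mean(lo)),
        max(float(np.var(hi)), var_floor), max(float(np.var(lo)), var_floor),
        hi.size / x.size,
    )]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            m1, m2 = rng.choice(x, 2, replace=False)
            v = max(float(np.var(x)), var_floor)
            inits.append((max(m1, m2), min(m1, m2), v, v, 0.5))

    best: GMMParams | None = None
    for mu1, mu2, s1, s2, alpha in inits:
        params = _em(x, mu1, mu2, s1, s2, alpha, tol, max_iter, var_floor,
                     log_transform)
        if best is None or params.loglik > best.loglik:
            best = params
    assert best is not None
    return best


def _em(x, mu1, mu2, s1, s2, alpha, tol, max_iter, var_floor, log_transform):
    n = x.size
    trace: list[float] = []
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step in log space for stability
        log_p1 = np.log(alpha) + norm.logpdf(x, mu1, np.sqrt(s1))
        log_p2 = np.log1p(-alpha) + norm.logpdf(x, mu2, np.sqrt(s2))
        m = np.maximum(log_p1, log_p2)
        log_tot = m + np.log(np.exp(log_p1 - m) + np.exp(log_p2 - m))
        ll = float(log_tot.sum())
        trace.append(ll)
        r1 = np.exp(log_p1 - log_tot)
        # M step
        w1 = float(r1.sum())
        w2 = n - w1
        if w1 <= 0 or w2 <= 0:  # one component vanished
            break
        mu1 = float((r1 * x).sum() / w1)
        mu2 = float(((1 - r1) * x).sum() / w2)
        s1 = max(float((r1 * (x - mu1) ** 2).sum() / w1), var_floor)
        s2 = max(float(((1 - r1) * (x - mu2) ** 2).sum() / w2), var_floor)
        alpha = min(max(w1 / n, 1e-12), 1 - 1e-12)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
    if mu1 < mu2:  # relabel: component 1 is the high-frequency one
        mu1, mu2, s1, s2, alpha = mu2, mu1, s2, s1, 1 - alpha
    return GMMParams(mu1, mu2, s1, s2, alpha, trace[-1], n_iter,
                     log_transform=log_transform, loglik_trace=tuple(trace))


def state_matrix(
    cm: ContactMatrix,
    params: GMMParams,
    threshold: float = 0.5,
    max_dist_bins: int | None = None,
) -> StateMatrix:
    """Binarize a contact matrix through the fitted mixture posterior.

    posterior_ij = alpha*phi(H_ij; mu1, s1) /
                   [alpha*phi(H_ij; mu1, s1) + (1-alpha)*phi(H_ij; mu2, s2)]

    evaluated on the same transform the mixture was fit on.  ``h_ij = 1``
    iff posterior > threshold (strict).  When the fitted variances differ,
    the wide intra-domain component can also claim the far *low* tail
    (near-zero contacts); since the intra-domain component is by
    definition the high-frequency one, the posterior is clamped to 0
    below the inter-domain mean, making the state rule monotone in the
    contact value.  The diagonal and pairs beyond ``max_dist_bins`` get
    h = 0, posterior = 0; h is symmetrized from the upper triangle.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    n = cm.n_bins
    v = cm.values
    if params.log_transform:
        v = np.log2(1.0 + v)
    log_p1 = np.log(params.alpha) + norm.logpdf(v, params.mu1, np.sqrt(params.sigma1_sq))
    log_p2 = np.log1p(-params.alpha) + norm.logpdf(v, params.mu2, np.sqrt(params.sigma2_sq))
    m = np.maximum(log_p1, log_p2)
    post = np.exp(log_p1 - m) / (np.exp(log_p1 - m) + np.exp(log_p2 - m))
    post[v < params.mu2] = 0.0  # monotone guard on the low tail

    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mask = dist == 0
    if max_dist_bins is not None:
        mask |= dist > max_dist_bins
    post[mask] = 0.0
    h = (post > threshold).astype(np.int8)
    # symmetrize from the upper triangle
    h = np.triu(h, k=1)
    h = h + h.T
    post = np.triu(post, k=1)
    post = post + post.T
    return StateMatrix(h=h, posterior=post)
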