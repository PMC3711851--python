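"""One-dimensional Gaussian-mixture fitting by EM with BIC model selection.

This is the shared primitive behind noise thresholding of log2 expression
signals and differential calling on signal-log-ratio (SLR) distributions.
Components are always reported sorted by ascending mean. The per-iteration
log-likelihood trace is kept on the fit object so EM monotonicity can be
audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = ["Mixture1D", "FitError", "InputError", "fit_gmm_1d", "select_gmm_1d"]

# sd floor keeps components from collapsing onto single points
SD_FLOOR = 1e-3
EM_TOL = 1e-8
EM_MAX_ITER = 500
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class InputError(ValueError):
    """Raised when the data handed to a fit is unusable."""


class FitError(RuntimeError):
    """Raised when EM cannot produce a non-degenerate fit."""


@dataclass
class Mixture1D:
    """A fitted 1-D Gaussian mixture, components sorted by ascending mean.

    Attributes
    ----------
    weights, means, sds : ndarray of shape (K,)
        Mixture parameters; weights sum to one, sds are floored at
        ``SD_FLOOR``.
    loglik : float
        Final log-likelihood of the training data.
    bic : float
        ``-2*loglik + n_params*log(n)`` with ``n_params = 3K - 1``.
    loglik_trace : ndarray
        Log-likelihood at the start of every EM iteration of the winning
        restart (non-decreasing by EM theory).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n_obs: int
    loglik_trace: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.means)

    def component_log_density(self, x) -> np.ndarray:
        """log(w_j * phi_j(x)) for each component, shape (len(x), K)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.log(self.weights) + norm.logpdf(x[:, None], self.means, self.sds)

    def posteriors(self, x) -> np.ndarray:
        """Posterior component membership probabilities, shape (len(x), K)."""
        lp = self.component_log_density(x)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def pdf(self, x) -> np.ndarray:
        return np.exp(logsumexp(self.component_log_density(x), axis=1))


def _em_once(x: np.ndarray, k: int, rng: np.random.Generator) -> Mixture1D:
    n = x.size
    # quantile-anchored means with jitter; spread-matched sds
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs) + rng.normal(0.0, x.std() / (2 * k) + 1e-12, size=k)
    sds = np.full(k, max(x.std() / k, 10 * SD_FLOOR))
    weights = np.full(k, 1.0 / k)

    trace = []
    prev = -np.inf
    xc = x[:, None]
    for _ in range(EM_MAX_ITER):
        z = (xc - means) / sds
        log_wphi = np.log(weights) - 0.5 * z * z - np.log(sds) - _LOG_SQRT_2PI
        log_tot = logsumexp(log_wphi, axis=1)
        ll = float(log_tot.sum())
        trace.append(ll)
        resp = np.exp(log_wphi - log_tot[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):
            raise FitError(f"component collapsed to zero weight at K={k}")
        weights = nk / n
        means = resp.T @ x / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, SD_FLOOR**2))
        if ll - prev <= EM_TOL * abs(ll):
            break
        prev = ll

    order = np.argsort(means)
    n_params = 3 * k - 1
    return Mixture1D(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik=ll,
        bic=-2.0 * ll + n_params * np.log(n),
        n_obs=n,
        loglik_trace=np.asarray(trace),
    )


def fit_gmm_1d(values, k: int, seed: int, n_init: int = 5) -> Mixture1D:
    """Fit a K-component 1-D Gaussian mixture by EM with seeded restarts.

    The best of ``n_init`` restarts (by final log-likelihood) is returned.

    Raises
    ------
    InputError
        Fewer than 50 finite values, or zero-variance (constant) input.
    FitError
        Every restart collapsed.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise InputError(f"need at least 50 finite values, got {x.size}")
    if k < 1:
        raise InputError(f"component count must be >= 1, got {k}")
    if np.ptp(x) == 0.0:
        raise FitError("constant input: zero-variance degenerate fit")

    rng = np.random.default_rng(seed)
    best: Mixture1D | None = None
    errors: list[str] = []
    for _ in range(n_init):
        try:
            fit = _em_once(x, k, rng)
        except FitError as exc:  # collapsed restart; try the next one
            errors.append(str(exc))
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise FitError(f"EM failed in all {n_init} restarts at K={k}: {errors[-1]}")
    return best


def select_gmm_1d(values, k_range: tuple[int, int], seed: int, n_init: int = 5) -> Mixture1D:
    """Fit mixtures for every K in ``k_range`` (inclusive) and keep the
    minimum-BIC model.

    Raises ``FitError`` only if EM fails at every K.
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if not 1 <= k_min <= k_max:
        raise InputError(f"invalid k_range {k_range}")
    best: Mixture1D | None = None
    failures: list[str] = []
    for k in range(k_min, k_max + 1):
        try:
            fit = fit_gmm_1d(values, k, seed=seed + k, n_init=n_init)
        except FitError as exc:
            failures.append(f"K={k}: {exc}")
            continue
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise FitError("EM failed at every K: " + "; ".join(failures))
    return best
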