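"""Univariate Gaussian mixture fitting by EM and bimodality descriptors.

The O/E CpG distribution of a species with gene-body methylation is modeled
as a mixture of two normal components — depleted (methylated) and
non-depleted (unmethylated) genes. We fit both a one- and a two-component
model; the decisive statistic is the distance ``d`` between the two
component means. AIC (``2k - 2 ln L`` with ``k = 3c - 1`` free parameters:
c means, c variances, c-1 weights) is reported for both fits but is not used
for calling: with tens of thousands of transcripts it favors two components
even on shuffled, structure-free data.

EM is run from ``n_init`` starts (one deterministic sorted-block split plus
seeded random restarts) and the best final log-likelihood is kept. The
log-likelihood trace of the winning run is recorded; it is non-decreasing up
to floating-point tolerance, a property the test suite asserts on every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .cpg import DistributionSummary

#: lower bound on component variances, guards against singular components
VARIANCE_FLOOR = 1e-8

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureFit:
    """A fitted c-component 1-D Gaussian mixture, components sorted by mean."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    aic: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    n_obs: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances < VARIANCE_FLOOR - 1e-15):
            raise ValueError("component variance below floor")


@dataclass
class BimodalitySummary:
    """Descriptors of the two-component fit used for the methylation call."""

    mean_low: float
    mean_high: float
    distance_d: float
    pct_low: float
    aic_1comp: float
    aic_2comp: float
    summary: DistributionSummary
    pct_low_hard: float | None = None

    def __post_init__(self) -> None:
        if self.mean_low > self.mean_high + 1e-12:
            raise ValueError("mean_low must not exceed mean_high")
        if self.distance_d < -1e-12:
            raise ValueError("distance d must be non-negative")


def _log_gauss(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """log N(x | mean, var) for x shape (n,1) against component vectors."""
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _em_run(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """One EM run from the given start; returns params, trace, converged."""
    n = x.size
    xcol = x[:, None]
    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        log_comp = np.log(weights) + _log_gauss(xcol, means, variances)
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * xcol).sum(axis=0) / nk
        variances = (resp * (xcol - means) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, VARIANCE_FLOOR)
    return weights, means, variances, trace, converged


def _block_init(x_sorted: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic start: split the sorted data into c contiguous blocks."""
    blocks = np.array_split(x_sorted, c)
    means = np.array([b.mean() for b in blocks])
    variances = np.maximum(np.array([b.var() for b in blocks]), VARIANCE_FLOOR)
    weights = np.array([b.size for b in blocks], dtype=float)
    weights /= weights.sum()
    return weights, means, variances


def fit_gmm(
    values: Sequence[float] | np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 10,
) -> MixtureFit:
    """Fit a c-component univariate Gaussian mixture by best-of-``n_init`` EM.

    Parameters
    ----------
    values
        Finite O/E values; at least ``10 * n_components`` of them.
    n_components
        1 or 2.
    seed
        Seeds the random restarts; the fit is deterministic given
        ``(values, n_components, seed)``.
    tol
        Absolute log-likelihood improvement below which a run stops.
    n_init
        One sorted-block start plus ``n_init - 1`` random restarts.

    Returns
    -------
    MixtureFit with components in ascending-mean order. On zero-variance
    input the fit is flagged ``degenerate``: every component sits at the
    common value with the floor variance.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} values for {n_components} components, got {x.size}"
        )

    k_params = 3 * n_components - 1

    if np.ptp(x) == 0.0:
        # all values identical: EM is ill-posed, report the degenerate fit
        means = np.full(n_components, x[0])
        variances = np.full(n_components, VARIANCE_FLOOR)
        weights = np.full(n_components, 1.0 / n_components)
        ll = float(np.sum(_log_gauss(x[:, None], means, variances)[:, 0]))
        return MixtureFit(
            n_components=n_components,
            weights=weights,
            means=means,
            variances=variances,
            log_likelihood=ll,
            aic=2.0 * k_params - 2.0 * ll,
            n_iter=0,
            converged=True,
            loglik_trace=np.array([ll]),
            n_obs=x.size,
            degenerate=True,
        )

    rng = np.random.default_rng(seed)
    x_sorted = np.sort(x)
    global_var = max(float(x.var()), VARIANCE_FLOOR)

    starts = [_block_init(x_sorted, n_components)]
    for _ in range(max(0, n_init - 1)):
        means0 = rng.choice(x, size=n_components, replace=False)
        weights0 = np.full(n_components, 1.0 / n_components)
        variances0 = np.full(n_components, global_var)
        starts.append((weights0, means0.astype(float), variances0))

    best = None
    for weights0, means0, variances0 in starts:
        w, m, v, trace, conv = _em_run(x, weights0.copy(), means0.copy(), variances0.copy(), tol, max_iter)
        if best is None or trace[-1] > best[3][-1]:
            best = (w, m, v, trace, conv)

    w, m, v, trace, conv = best
    order = np.argsort(m)
    w, m, v = w[order], m[order], v[order]
    ll = trace[-1]
    return MixtureFit(
        n_components=n_components,
        weights=w,
        means=m,
        variances=v,
        log_likelihood=ll,
        aic=2.0 * k_params - 2.0 * ll,
        n_iter=len(trace),
        converged=conv,
        loglik_trace=np.array(trace),
        n_obs=x.size,
    )


def hard_assignment_fraction_low(fit: MixtureFit, values: np.ndarray) -> float:
    """Fraction of points whose posterior favors the low-mean component."""
    x = np.asarray(values, dtype=float).ravel()[:, None]
    log_comp = np.log(fit.weights) + _log_gauss(x, fit.means, fit.variances)
    return float(np.mean(np.argmax(log_comp, axis=1) == 0))


def summarize_bimodality(
    fit1: MixtureFit,
    fit2: MixtureFit,
    summary: DistributionSummary,
    values: np.ndarray | None = None,
) -> BimodalitySummary:
    """Combine the 1- and 2-component fits into the calling descriptors.

    ``pct_low`` is the fitted mixture weight of the low-mean component (the
    expected fraction of transcripts in it). When ``values`` is given, the
    hard-assignment fraction is also reported for comparison.
    """
    if fit1.n_components != 1 or fit2.n_components != 2:
        raise ValueError("expected a 1-component and a 2-component fit")
    if fit1.n_obs != fit2.n_obs:
        raise ValueError("fits were made on different data (n_obs mismatch)")
    mean_low, mean_high = float(fit2.means[0]), float(fit2.means[1])
    pct_low_hard = None
    if values is not None:
        pct_low_hard = hard_assignment_fraction_low(fit2, values)
    return BimodalitySummary(
        mean_low=mean_low,
        mean_high=mean_high,
        distance_d=mean_high - mean_low,
        pct_low=float(fit2.weights[0]),
        aic_1comp=fit1.aic,
        aic_2comp=fit2.aic,
        summary=summary,
        pct_low_hard=pct_low_hard,
    )
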