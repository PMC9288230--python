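"""The q-exponential distribution and its superstatistical origin.

The q-exponential generalises the exponential law and is the stationary
marginal of a superstatistical process: locally exponential fluctuations
whose rate ``lam`` itself varies slowly.  Its normalised density is

    f_{q,lam}(x) = (2 - q) * lam * [1 - lam*(1 - q)*x]**(1/(1 - q))

on ``1 - lam*(1 - q)*x >= 0, x > 0``.  For ``q -> 1`` it reduces to the
ordinary exponential ``lam * exp(-lam*x)``.  For ``q > 1`` the density has a
power-law tail with exponent ``-1/(q - 1)``; for ``q < 1`` it lives on the
finite support ``[0, 1/(lam*(1 - q))]``.  Normalisability requires
``0 < q < 2`` and ``lam > 0``.

This module provides the density, distribution function, quantiles,
inverse-transform sampling, moments, the log-likelihood, a maximum-likelihood
estimator of ``(q, lam)``, and the superstatistical entropic index
``q = <lam^2>/<lam>^2`` computed from samples of the fluctuating rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DataError, ParameterError

__all__ = [
    "QExpParams",
    "qexp_pdf",
    "qexp_cdf",
    "qexp_quantile",
    "qexp_sample",
    "qexp_loglik",
    "qexp_mle",
    "qexp_mean",
    "superstat_q",
]

# estimator knobs; the defaults are the package-wide convention
MLE_LOGLIK_TOL = 1e-8
MLE_MAX_ITER = 500
MLE_MULTISTART_OFFSET = 0.2
_Q_LO, _Q_HI = 1e-3, 2.0 - 1e-3
_PENALTY = 1e18


@dataclass(frozen=True)
class QExpParams:
    """Parameters of a q-exponential distribution.

    Attributes
    ----------
    q : float
        Entropic index, ``0 < q < 2``.  ``q > 1`` gives a power-law tail with
        exponent ``-1/(q - 1)``; ``q < 1`` gives a finite support; ``q = 1``
        is the exponential distribution.
    lam : float
        Width (inverse-scale) parameter in 1/(µg/m³), ``lam > 0``.  Larger
        ``lam`` means faster decay, i.e. cleaner air.
    """

    q: float
    lam: float

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 2.0):
            raise ParameterError(f"entropic index q must lie in (0, 2); got {self.q}")
        if not self.lam > 0.0:
            raise ParameterError(f"width parameter lam must be positive; got {self.lam}")

    @property
    def support_upper(self) -> float:
        """Upper end of the support: ``1/(lam*(1-q))`` for q < 1, else inf."""
        if self.q < 1.0:
            return 1.0 / (self.lam * (1.0 - self.q))
        return np.inf

    @property
    def tail_exponent(self) -> float:
        """Asymptotic power-law exponent ``-1/(q-1)`` (only meaningful for q > 1)."""
        if self.q <= 1.0:
            raise ParameterError("tail exponent is defined for q > 1 only")
        return -1.0 / (self.q - 1.0)


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("concentrations must be finite")
    return arr


def qexp_pdf(params: QExpParams, x) -> np.ndarray | float:
    """Density of the q-exponential at concentration ``x``.

    Zero outside the support (``x <= 0`` or, for q < 1, beyond the cutoff
    ``1/(lam*(1-q))``).  Scalar in, scalar out.
    """
    arr = _as_float_array(x)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    q, lam = params.q, params.lam
    out = np.zeros_like(arr)
    pos = arr > 0
    if q == 1.0:
        out[pos] = lam * np.exp(-lam * arr[pos])
    else:
        base = 1.0 - lam * (1.0 - q) * arr
        ok = pos & (base >= 0.0)
        out[ok] = (2.0 - q) * lam * np.power(base[ok], 1.0 / (1.0 - q))
    return float(out[0]) if scalar else out


def qexp_cdf(params: QExpParams, x) -> np.ndarray | float:
    """Distribution function ``F(x) = 1 - [1 - lam*(1-q)*x]**((2-q)/(1-q))``.

    Clamped to [0, 1]; exponential form at q = 1.
    """
    arr = _as_float_array(x)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    q, lam = params.q, params.lam
    out = np.zeros_like(arr)
    pos = arr > 0
    if q == 1.0:
        out[pos] = -np.expm1(-lam * arr[pos])
    else:
        base = 1.0 - lam * (1.0 - q) * arr
        inside = pos & (base > 0.0)
        out[inside] = 1.0 - np.power(base[inside], (2.0 - q) / (1.0 - q))
        out[pos & (base <= 0.0)] = 1.0  # beyond the finite support (q < 1)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def qexp_quantile(params: QExpParams, p) -> np.ndarray | float:
    """Exact inverse of :func:`qexp_cdf` for probabilities ``0 <= p < 1``."""
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0.0) or np.any(arr >= 1.0):
        raise DataError("probabilities must lie in [0, 1)")
    q, lam = params.q, params.lam
    if q == 1.0:
        out = -np.log1p(-arr) / lam
    else:
        out = (1.0 - np.power(1.0 - arr, (1.0 - q) / (2.0 - q))) / (lam * (1.0 - q))
    return float(out[0]) if scalar else out


def qexp_sample(params: QExpParams, n: int, seed: int | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` i.i.d. values by inverse-transform sampling.

    Reproducible for a fixed ``seed``; alternatively pass an existing
    :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise DataError("sample size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return qexp_quantile(params, rng.random(n))


def _logpdf(q: float, lam: float, x: np.ndarray) -> np.ndarray:
    """Pointwise log-density; -inf outside the support."""
    out = np.full_like(x, -np.inf)
    pos = x > 0
    if q == 1.0:
        out[pos] = np.log(lam) - lam * x[pos]
        return out
    base = 1.0 - lam * (1.0 - q) * x
    ok = pos & (base > 0.0)
    out[ok] = np.log((2.0 - q) * lam) + np.log(base[ok]) / (1.0 - q)
    return out


def qexp_loglik(params: QExpParams, data) -> float:
    """Total log-likelihood ``sum(log f(x_i))``; ``-inf`` if any point has
    zero density (outside the support)."""
    arr = _as_float_array(data)
    if arr.size == 0:
        raise DataError("log-likelihood of empty data is undefined")
    return float(np.sum(_logpdf(params.q, params.lam, np.atleast_1d(arr))))


def _moment_start(data: np.ndarray) -> tuple[float, float]:
    """Method-of-moments initialisation.

    The q-exponential satisfies CV^2 = var/mean^2 = (2-q)/(4-3q), which
    inverts to q = (2 - 4c)/(1 - 3c) with c = CV^2.  The start is clipped to
    [0.7, 1.8] and lam follows from mean = 1/(lam*(3-2q)).
    """
    m = float(np.mean(data))
    c = float(np.var(data)) / m**2
    denom = 1.0 - 3.0 * c
    q0 = (2.0 - 4.0 * c) / denom if abs(denom) > 1e-12 else 1.8
    if not np.isfinite(q0):
        q0 = 1.0
    q0 = float(np.clip(q0, 0.7, 1.8))
    lam0 = 1.0 / ((3.0 - 2.0 * q0) * m)
    return q0, lam0


def qexp_mle(data, *, tol: float = MLE_LOGLIK_TOL,
             maxiter: int = MLE_MAX_ITER) -> tuple[QExpParams, float]:
    """Joint maximum-likelihood estimate of ``(q, lam)``.

    Numerical maximisation of the log-likelihood over ``0 < q < 2``,
    ``lam > 0`` (Nelder-Mead in ``(q, log lam)``), started from a
    method-of-moments guess plus offsets ``q0 +/- 0.2`` so both the finite
    support (q < 1) and the power-law (q > 1) regimes are explored.  For
    q < 1 a candidate whose support excludes any data point is rejected
    outright (its likelihood is exactly zero).

    Parameters
    ----------
    data : array-like
        At least 50 strictly positive, not-all-identical concentrations.

    Returns
    -------
    (QExpParams, float)
        The estimate and the attained log-likelihood.

    Raises
    ------
    DataError
        Fewer than 50 points, non-positive values, or degenerate data.
    ConvergenceError
        The optimiser failed to converge from every start.
    """
    arr = np.atleast_1d(_as_float_array(data))
    if arr.size < 50:
        raise DataError(f"MLE needs at least 50 data points; got {arr.size}")
    if np.any(arr <= 0.0):
        raise DataError("MLE requires strictly positive concentrations")
    if np.ptp(arr) == 0.0:
        raise DataError("MLE on all-identical data is degenerate")

    xmax = float(np.max(arr))

    def negloglik(theta: np.ndarray) -> float:
        q, loglam = theta
        if not (_Q_LO < q < _Q_HI) or not np.isfinite(loglam):
            return _PENALTY
        lam = float(np.exp(loglam))
        if q < 1.0 and 1.0 - lam * (1.0 - q) * xmax <= 0.0:
            return _PENALTY  # a data point outside the candidate support
        ll = np.sum(_logpdf(q, lam, arr))
        return -float(ll) if np.isfinite(ll) else _PENALTY

    q0, lam0 = _moment_start(arr)
    starts = []
    for qs in (q0, q0 - MLE_MULTISTART_OFFSET, q0 + MLE_MULTISTART_OFFSET):
        qs = float(np.clip(qs, 0.05, 1.95))
        ls = lam0
        if qs < 1.0:
            # keep the start inside the feasible region for this q
            ls = min(ls, 0.99 / ((1.0 - qs) * xmax))
        starts.append((qs, np.log(ls)))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            negloglik, np.asarray(x0), method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-10, "maxiter": maxiter,
                     "maxfev": 4 * maxiter},
        )
        if res.fun >= _PENALTY:
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any_converged:
        raise ConvergenceError("q-exponential MLE did not converge from any start")
    qhat = float(best.x[0])
    lamhat = float(np.exp(best.x[1]))
    return QExpParams(qhat, lamhat), -float(best.fun)


def qexp_mean(params: QExpParams) -> float:
    """Mean ``1/(lam*(3-2q))``; finite only for q < 1.5."""
    if params.q >= 1.5:
        raise ParameterError(f"mean diverges for q >= 1.5; got q={params.q}")
    return 1.0 / (params.lam * (3.0 - 2.0 * params.q))


def superstat_q(lambda_samples) -> float:
    """Superstatistical entropic index ``q = <lam^2>/<lam>^2``.

    Computed from samples of the fluctuating rate of the local exponential
    dynamics.  Always >= 1 (Cauchy-Schwarz); equal to 1 iff the rate is
    constant.  Note this is a distinct convention from the exponent of the
    mixture marginal: for a Gamma(a, theta) rate it gives ``1 + 1/a``, while
    the marginal density is a q-exponential with ``q = (a+2)/(a+1)``.
    """
    arr = np.atleast_1d(np.asarray(lambda_samples, dtype=float))
    if arr.size == 0:
        raise DataError("need at least one lambda sample")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0):
        raise DataError("lambda samples must be finite and strictly positive")
    return float(np.mean(arr**2) / np.mean(arr) ** 2)
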