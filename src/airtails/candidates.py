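"""Candidate distribution families and log-likelihood model selection.

Air-pollutant concentration tails have traditionally been fitted with
log-normal, Weibull and gamma distributions, all of which decay roughly
exponentially.  This module fits those families, the plain exponential and
the q-exponential by maximum likelihood on the same (tail-shifted) data and
ranks them by attained log-likelihood; the family with the highest
log-likelihood wins.  All families are anchored at the origin of the shifted
tail variable (location fixed at 0) so their likelihoods are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError
from .qexp import qexp_mle

__all__ = ["FAMILIES", "CandidateFit", "ModelComparison", "fit_family", "compare_models"]

FAMILIES = ("exponential", "gamma", "weibull", "lognormal", "qexponential")

# free parameters per family, used to break log-likelihood ties in favour of
# the more parsimonious model
N_PARAMS = {
    "exponential": 1,
    "gamma": 2,
    "weibull": 2,
    "lognormal": 2,
    "qexponential": 2,
}


@dataclass(frozen=True)
class CandidateFit:
    """MLE result for one family on one data set."""

    family: str
    params: dict[str, float]
    loglik: float
    n: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DataError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n < 1:
            raise DataError("sample size must be >= 1")
        if not (np.isfinite(self.loglik) or self.loglik == -np.inf):
            raise DataError("log-likelihood must be finite or -inf")


@dataclass(frozen=True)
class ModelComparison:
    """Families ranked by log-likelihood, best first."""

    ranked: tuple[CandidateFit, ...]
    best_family: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "best_family", self.ranked[0].family)


def _validate(data) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(data, dtype=float))
    if arr.size < 50:
        raise DataError(f"need at least 50 data points; got {arr.size}")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0):
        raise DataError("data must be finite and strictly positive")
    return arr


def fit_family(data, family: str) -> CandidateFit:
    """Maximum-likelihood fit of one named family with location fixed at 0.

    The exponential MLE is closed form (``lam = 1/mean``); gamma and Weibull
    use scipy's constrained fits; the log-normal MLE is the moment fit on
    ``log(data)``; the q-exponential uses :func:`airtails.qexp.qexp_mle`.
    """
    arr = _validate(data)
    n = int(arr.size)
    if family == "exponential":
        lam = 1.0 / float(np.mean(arr))
        ll = n * np.log(lam) - lam * float(np.sum(arr))
        return CandidateFit("exponential", {"lam": lam}, float(ll), n)
    if family == "gamma":
        if np.ptp(arr) == 0.0:
            raise DataError("gamma fit on constant data is degenerate")
        shape, _, scale = stats.gamma.fit(arr, floc=0.0)
        ll = float(np.sum(stats.gamma.logpdf(arr, shape, loc=0.0, scale=scale)))
        return CandidateFit("gamma", {"shape": shape, "scale": scale}, ll, n)
    if family == "weibull":
        if np.ptp(arr) == 0.0:
            raise DataError("weibull fit on constant data is degenerate")
        shape, _, scale = stats.weibull_min.fit(arr, floc=0.0)
        ll = float(np.sum(stats.weibull_min.logpdf(arr, shape, loc=0.0, scale=scale)))
        return CandidateFit("weibull", {"shape": shape, "scale": scale}, ll, n)
    if family == "lognormal":
        logs = np.log(arr)
        mu = float(np.mean(logs))
        sigma = float(np.std(logs))
        if sigma == 0.0:
            raise DataError("lognormal fit on constant data is degenerate")
        ll = float(np.sum(stats.lognorm.logpdf(arr, sigma, loc=0.0, scale=np.exp(mu))))
        return CandidateFit("lognormal", {"mu": mu, "sigma": sigma}, ll, n)
    if family == "qexponential":
        params, ll = qexp_mle(arr)
        return CandidateFit("qexponential", {"q": params.q, "lam": params.lam}, ll, n)
    raise DataError(f"unknown family {family!r}; expected one of {FAMILIES}")


def fit_all_families(data) -> dict[str, CandidateFit]:
    """Convenience: fit every family in :data:`FAMILIES` on the same data."""
    return {fam: fit_family(data, fam) for fam in FAMILIES}


def compare_models(fits) -> ModelComparison:
    """Rank fits by log-likelihood, highest first.

    All fits must come from the same data (equal ``n``).  Exact ties are
    broken toward the family with fewer free parameters, then
    alphabetically, which makes the ranking invariant to input order.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise DataError("model comparison needs at least two fits")
    sizes = {f.n for f in fits}
    if len(sizes) > 1:
        raise DataError(f"fits have mixed sample sizes {sorted(sizes)}; "
                        "they must come from the same data")
    ranked = tuple(sorted(fits, key=lambda f: (-f.loglik, N_PARAMS[f.family], f.family)))
    return ModelComparison(ranked)
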