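"""Truncated univariate marginal distributions for PBPK model parameters.

Every sampled model parameter is described by a :class:`MarginalSpec`: a
distribution family (normal, lognormal or Weibull), its two shape parameters,
and hard truncation bounds in parameter units.  Constants use the ``fixed``
family.  Conventions:

* ``normal(p1, p2)`` — mean ``p1`` and **variance** ``p2`` (the drug tables
  quote, e.g., ``Norm(0.008, 6.4e-7)`` for a 10% CV around 0.008, which only
  works if the second parameter is a variance).
* ``lognormal(p1, p2)`` — mean ``p1`` and **variance** ``p2`` of the natural
  log of the values, so the median is ``exp(p1)``.
* ``weibull(p1, p2)`` — shape ``p1`` and scale ``p2``.

Truncation is applied by CDF renormalisation (inverse-CDF mapping), never by
rejection, so low-discrepancy designs pushed through :meth:`MarginalSpec.quantile`
stay uniform in the unit cube.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MarginalSpec",
    "SpecError",
    "DegenerateSupportError",
    "DomainError",
    "FitError",
    "fit_best",
]

FAMILIES = ("normal", "lognormal", "weibull", "fixed")

#: minimum truncated-interval probability mass before the support is
#: considered degenerate
_MASS_TOL = 1e-12


class SpecError(ValueError):
    """Invalid distribution specification."""


class DegenerateSupportError(SpecError):
    """Truncation interval carries (numerically) no probability mass."""


class DomainError(ValueError):
    """Evaluation point outside the truncated support."""


class FitError(RuntimeError):
    """No candidate family could be fitted to the data."""


@dataclasses.dataclass(frozen=True)
class MarginalSpec:
    """One model parameter's marginal distribution with truncation bounds.

    Parameters
    ----------
    name : str
        Parameter label (e.g. ``"BW"``, ``"CLint_CYP3A4"``).
    family : {"normal", "lognormal", "weibull", "fixed"}
    p1, p2 : float, optional
        Shape parameters; see module docstring for the per-family meaning.
        Unused for ``fixed``.
    lower, upper : float
        Truncation bounds in parameter units.
    value : float, optional
        The constant (``fixed`` family only).
    unit : str
        Unit string, informational only.
    """

    name: str
    family: str
    p1: float | None = None
    p2: float | None = None
    lower: float = -math.inf
    upper: float = math.inf
    value: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"{self.name}: unknown family {self.family!r}")
        if self.family == "fixed":
            if self.value is None:
                raise SpecError(f"{self.name}: fixed family requires a value")
            if not (self.lower <= self.value <= self.upper):
                raise SpecError(
                    f"{self.name}: fixed value {self.value} outside "
                    f"[{self.lower}, {self.upper}]"
                )
            return
        if self.p1 is None or self.p2 is None:
            raise SpecError(f"{self.name}: {self.family} requires p1 and p2")
        if not (self.lower < self.upper):
            raise SpecError(f"{self.name}: lower must be < upper")
        if self.family in ("normal", "lognormal") and not self.p2 > 0:
            raise SpecError(f"{self.name}: variance p2 must be > 0")
        if self.family == "weibull" and not (self.p1 > 0 and self.p2 > 0):
            raise SpecError(f"{self.name}: weibull shape and scale must be > 0")
        lo, hi = self._untruncated().cdf([self.lower, self.upper])
        if hi - lo < _MASS_TOL:
            raise DegenerateSupportError(
                f"{self.name}: truncation interval [{self.lower}, {self.upper}] "
                f"carries probability mass {hi - lo:.3e}"
            )

    # -- distribution plumbing -------------------------------------------

    def _untruncated(self):
        """The untruncated scipy frozen distribution."""
        if self.family == "normal":
            return stats.norm(loc=self.p1, scale=math.sqrt(self.p2))
        if self.family == "lognormal":
            return stats.lognorm(s=math.sqrt(self.p2), scale=math.exp(self.p1))
        if self.family == "weibull":
            return stats.weibull_min(c=self.p1, scale=self.p2)
        raise SpecError(f"{self.name}: fixed family has no distribution")

    def _mass(self):
        dist = self._untruncated()
        lo, hi = dist.cdf([self.lower, self.upper])
        return dist, lo, hi

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    # -- public surface ---------------------------------------------------

    def quantile(self, u):
        """Truncated inverse CDF: maps ``u`` in [0, 1] into [lower, upper]."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise DomainError(f"{self.name}: u outside [0, 1]")
        if self.is_fixed:
            return np.broadcast_to(np.float64(self.value), u.shape).copy()[()]
        dist, lo, hi = self._mass()
        x = dist.ppf(lo + u * (hi - lo))
        return np.clip(x, self.lower, self.upper)[()]

    def cdf(self, x):
        """Truncated CDF; inverse of :meth:`quantile` on [lower, upper]."""
        x = np.asarray(x, dtype=float)
        if self.is_fixed:
            return (x >= self.value).astype(float)[()]
        if np.any((x < self.lower - 1e-12) | (x > self.upper + 1e-12)):
            raise DomainError(f"{self.name}: x outside [{self.lower}, {self.upper}]")
        dist, lo, hi = self._mass()
        u = (dist.cdf(x) - lo) / (hi - lo)
        return np.clip(u, 0.0, 1.0)[()]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` independent values via the truncated inverse CDF."""
        if self.is_fixed:
            return np.full(n, float(self.value))
        return np.atleast_1d(self.quantile(rng.uniform(size=n)))


# ---------------------------------------------------------------------------
# maximum-likelihood family selection
# ---------------------------------------------------------------------------

def _fit_normal(x: np.ndarray) -> tuple[float, float, float]:
    mu = float(np.mean(x))
    var = float(np.var(x))  # MLE (ddof=0)
    logl = float(np.sum(stats.norm.logpdf(x, loc=mu, scale=math.sqrt(var))))
    return mu, var, logl


def _fit_lognormal(x: np.ndarray) -> tuple[float, float, float]:
    lx = np.log(x)
    mu = float(np.mean(lx))
    var = float(np.var(lx))
    if var <= 0:
        raise FitError("zero variance on the log scale")
    logl = float(
        np.sum(stats.lognorm.logpdf(x, s=math.sqrt(var), scale=math.exp(mu)))
    )
    return mu, var, logl


def _fit_weibull(x: np.ndarray) -> tuple[float, float, float]:
    shape, _, scale = stats.weibull_min.fit(x, floc=0)
    logl = float(np.sum(stats.weibull_min.logpdf(x, c=shape, scale=scale)))
    return float(shape), float(scale), logl


def fit_best(data: Sequence[float], name: str = "fitted") -> MarginalSpec:
    """Select the best marginal family for ``data`` by lowest AIC.

    Normal, lognormal and Weibull maximum-likelihood fits are compared with
    ``AIC = 2k - 2 logL`` (``k = 2`` for all three families; at the population
    sizes in play a small-sample correction is indistinguishable).  The
    lognormal and Weibull candidates require strictly positive data and are
    silently excluded otherwise.  Ties break in the order
    normal < lognormal < weibull.  The returned spec is truncated to the
    observed data range.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size < 30:
        raise FitError("need a 1-d sample of at least 30 observations")
    if not np.all(np.isfinite(x)):
        raise FitError("non-finite observations")
    if np.var(x) == 0:
        raise FitError("constant data: zero variance")

    candidates: list[tuple[float, int, MarginalSpec]] = []
    lo, hi = float(np.min(x)), float(np.max(x))

    mu, var, logl = _fit_normal(x)
    candidates.append(
        (4 - 2 * logl, 0, MarginalSpec(name, "normal", mu, var, lo, hi))
    )
    if np.all(x > 0):
        try:
            lmu, lvar, logl = _fit_lognormal(x)
            candidates.append(
                (4 - 2 * logl, 1, MarginalSpec(name, "lognormal", lmu, lvar, lo, hi))
            )
        except (FitError, SpecError):
            pass
        try:
            shape, scale, logl = _fit_weibull(x)
            candidates.append(
                (4 - 2 * logl, 2, MarginalSpec(name, "weibull", shape, scale, lo, hi))
            )
        except (RuntimeError, ValueError):
            pass

    finite = [c for c in candidates if math.isfinite(c[0])]
    if not finite:
        raise FitError("no candidate family converged")
    finite.sort(key=lambda c: (c[0], c[1]))
    return finite[0][2]
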