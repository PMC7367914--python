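"""Benchmark functions with closed-form sensitivity indices.

These are the standard GSA validation problems: the engines' estimates are
checked against exact variance decompositions, so the oracles here must stay
independent of the estimator code paths.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "UniformMarginal",
    "ishigami",
    "ishigami_indices",
    "ishigami_marginals",
    "g_function",
    "g_function_indices",
    "g_function_marginals",
    "linear_gaussian_ext_indices",
    "wide_normal_marginal",
]


@dataclasses.dataclass(frozen=True)
class UniformMarginal:
    """Uniform(lower, upper) marginal for benchmark inputs.

    Duck-types the quantile/cdf surface the GSA engines need; the drug
    fixtures themselves only ever use the normal/lognormal/Weibull families.
    """

    name: str
    lower: float
    upper: float
    family: str = "uniform"

    def quantile(self, u):
        return self.lower + np.asarray(u, dtype=float) * (self.upper - self.lower)

    def cdf(self, x):
        return (np.asarray(x, dtype=float) - self.lower) / (self.upper - self.lower)


def wide_normal_marginal(name: str, bound: float = 10.0):
    """Standard-normal marginal with effectively untruncated bounds."""
    from .marginals import MarginalSpec

    return MarginalSpec(name, "normal", 0.0, 1.0, -bound, bound)


# ---------------------------------------------------------------------------
# Ishigami-Homma
# ---------------------------------------------------------------------------

def ishigami(X: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """``sin x1 + a sin^2 x2 + b x3^4 sin x1`` on [-pi, pi]^3."""
    X = np.atleast_2d(X)
    return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
            + b * X[:, 2] ** 4 * np.sin(X[:, 0]))


def ishigami_indices(a: float = 7.0, b: float = 0.1) -> dict[str, float]:
    """Exact variance decomposition of the Ishigami function."""
    p4 = math.pi ** 4
    p8 = math.pi ** 8
    V1 = 0.5 * (1 + b * p4 / 5) ** 2
    V2 = a**2 / 8
    V13 = b**2 * p8 * (1 / 18 - 1 / 50)
    V = V1 + V2 + V13
    return {
        "S1": V1 / V, "S2": V2 / V, "S3": 0.0,
        "ST1": (V1 + V13) / V, "ST2": V2 / V, "ST3": V13 / V,
        "V": V,
    }


def ishigami_marginals() -> list[UniformMarginal]:
    return [UniformMarginal(f"x{i+1}", -math.pi, math.pi) for i in range(3)]


# ---------------------------------------------------------------------------
# Sobol g-function
# ---------------------------------------------------------------------------

def g_function(X: np.ndarray, a=(0.0, 1.0, 4.5, 9.0)) -> np.ndarray:
    """``prod (|4 x_i - 2| + a_i)/(1 + a_i)`` on the unit cube."""
    X = np.atleast_2d(X)
    a = np.asarray(a, dtype=float)
    return np.prod((np.abs(4 * X - 2) + a) / (1 + a), axis=1)


def g_function_indices(a=(0.0, 1.0, 4.5, 9.0)) -> dict[str, np.ndarray]:
    """Exact first-order and total indices of the g-function."""
    a = np.asarray(a, dtype=float)
    Vi = (1.0 / 3.0) / (1 + a) ** 2
    V = np.prod(1 + Vi) - 1
    ST = Vi * np.array([np.prod(1 + np.delete(Vi, i)) for i in range(len(a))])
    return {"S": Vi / V, "ST": ST / V, "V": V}


def g_function_marginals(k: int = 4) -> list[UniformMarginal]:
    return [UniformMarginal(f"x{i+1}", 0.0, 1.0) for i in range(k)]


# ---------------------------------------------------------------------------
# linear function of correlated Gaussians (extended-Sobol oracle)
# ---------------------------------------------------------------------------

def linear_gaussian_ext_indices(coeffs: np.ndarray, sigma: np.ndarray
                                ) -> dict[str, np.ndarray]:
    """Closed-form extended indices of ``f = a^T x``, ``x ~ N(0, Sigma)``.

    ``S_i_ext = (sum_j a_j Sigma_ij)^2 / (a^T Sigma a * Sigma_ii)`` and
    ``S_Ti_ext = a_i^2 Var(x_i | x_~i) / a^T Sigma a`` with the conditional
    variance from the Schur complement.
    """
    a = np.asarray(coeffs, dtype=float)
    s = np.asarray(sigma, dtype=float)
    k = len(a)
    V = float(a @ s @ a)
    Si = (s @ a) ** 2 / (V * np.diag(s))
    STi = np.empty(k)
    for i in range(k):
        rest = np.delete(np.arange(k), i)
        s11 = s[np.ix_(rest, rest)]
        s12 = s[rest, i]
        cond_var = s[i, i] - s12 @ np.linalg.solve(s11, s12)
        STi[i] = a[i] ** 2 * cond_var / V
    return {"S_ext": Si, "ST_ext": STi, "V": V}
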