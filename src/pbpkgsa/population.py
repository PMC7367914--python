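"""Correlated virtual populations via a Gaussian copula.

The dependence model is a Gaussian copula: a target correlation matrix is
imposed on latent standard-normal scores, which are mapped through the
standard-normal CDF to uniforms and then through each parameter's truncated
quantile.  The target matrix is therefore the correlation of the *latent*
scores; for the mildly skewed marginals used here the induced Pearson
correlation of the transformed values differs by well under the Monte-Carlo
noise of any analysis downstream.  The same latent-space dependence model is
shared with the extended-Sobol engine so population generation and GSA
condition on one and the same structure.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .marginals import MarginalSpec

__all__ = [
    "CorrelationSpec",
    "CorrelationRepairError",
    "nearest_psd",
    "sample_copula",
    "estimate_correlation",
    "adjust_correlation",
]

_PSD_TOL = 1e-8
#: maximum entrywise change the nearest-PSD repair may apply before the
#: matrix is rejected as irreparably inconsistent
_REPAIR_TOL = 0.05


class CorrelationRepairError(ValueError):
    """PSD repair would change the matrix by more than the allowed amount."""


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at zero and the diagonal renormalised back to 1.
    """
    m = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-300, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


@dataclasses.dataclass(frozen=True)
class CorrelationSpec:
    """Labelled symmetric PSD correlation matrix for the varying parameters."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "matrix", m)
        k = len(self.labels)
        if m.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("diagonal must be 1")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValueError("entries must lie in [-1, 1]")

    @classmethod
    def identity(cls, labels) -> "CorrelationSpec":
        labels = tuple(labels)
        return cls(labels, np.eye(len(labels)))

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())

    def is_psd(self, tol: float = _PSD_TOL) -> bool:
        return self.min_eigenvalue >= -tol

    def entry(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def with_entry(self, a: str, b: str, value: float) -> "CorrelationSpec":
        i, j = self.labels.index(a), self.labels.index(b)
        m = self.matrix.copy()
        m[i, j] = m[j, i] = value
        return CorrelationSpec(self.labels, m, dict(self.meta))

    def repaired(self) -> "CorrelationSpec":
        """Return a PSD version, repairing by eigenvalue clipping if needed.

        Raises
        ------
        CorrelationRepairError
            If repair would move any entry by more than 0.05.
        """
        if self.is_psd():
            return self
        fixed = nearest_psd(self.matrix)
        delta = np.abs(fixed - self.matrix).max()
        if delta > _REPAIR_TOL:
            raise CorrelationRepairError(
                f"nearest-PSD repair changes an entry by {delta:.3f} > {_REPAIR_TOL}"
            )
        warnings.warn(
            f"correlation matrix repaired to nearest PSD (max change {delta:.2e})",
            stacklevel=2,
        )
        meta = dict(self.meta)
        meta["psd_repaired"] = True
        meta["psd_repair_max_change"] = float(delta)
        return CorrelationSpec(self.labels, fixed, meta)


def _latent_cholesky(matrix: np.ndarray) -> np.ndarray:
    """Cholesky factor with a graded jitter fallback for semi-definite input."""
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(matrix + jitter * np.eye(len(matrix)))
        except np.linalg.LinAlgError:
            continue
    # last resort: eigenvalue square root
    w, v = np.linalg.eigh(matrix)
    return v * np.sqrt(np.clip(w, 0.0, None))


def sample_copula(
    marginals: list[MarginalSpec],
    corr: CorrelationSpec | None,
    n: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a virtual population of ``n`` subjects.

    Latent standard-normal scores with correlation ``corr`` are transformed
    coordinatewise through the standard-normal CDF and each marginal's
    truncated quantile.  Marginals absent from ``corr`` are sampled
    independently; ``fixed``-family marginals become constant columns.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [m.name for m in marginals]
    if corr is not None:
        missing = set(corr.labels) - set(names)
        if missing:
            raise ValueError(f"correlation labels not among marginals: {missing}")
        corr = corr.repaired()

    columns: dict[str, np.ndarray] = {}
    if corr is not None and len(corr.labels) > 0:
        chol = _latent_cholesky(corr.matrix)
        z = rng.standard_normal((n, len(corr.labels))) @ chol.T
        u = stats.norm.cdf(z)
        by_label = {lab: u[:, j] for j, lab in enumerate(corr.labels)}
    else:
        by_label = {}

    for m in marginals:
        if m.is_fixed:
            columns[m.name] = np.full(n, float(m.value))
        elif m.name in by_label:
            columns[m.name] = np.atleast_1d(m.quantile(by_label[m.name]))
        else:
            columns[m.name] = m.sample(n, rng)

    df = pd.DataFrame(columns, columns=names)
    df.attrs["n_subjects"] = n
    return df


def estimate_correlation(
    pop: pd.DataFrame,
) -> tuple[CorrelationSpec, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values for r = 0.

    Constant columns get zero correlation with p = 1 (and a warning).
    p-values use the exact t transform ``t = r sqrt((n-2)/(1-r^2))``.
    """
    n = len(pop)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    labels = tuple(pop.columns)
    x = pop.to_numpy(dtype=float)
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant columns set to zero correlation: "
            f"{[labels[i] for i in np.flatnonzero(constant)]}",
            stacklevel=2,
        )
    xs = np.where(constant, np.nan, 1.0) * x
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(xs, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)

    rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p[np.abs(r) >= 1.0 - 1e-12] = 0.0
    for i in np.flatnonzero(constant):
        p[i, :] = p[:, i] = 1.0
    np.fill_diagonal(p, 0.0)

    spec = CorrelationSpec(labels, r, {"estimated_n": n})
    return spec, pd.DataFrame(p, index=labels, columns=labels)


def adjust_correlation(
    corr: CorrelationSpec,
    p_values: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    r_min: float = 0.1,
) -> CorrelationSpec:
    """Zero non-significant (p > alpha) and weak (|r| < r_min) entries.

    The screened matrix is re-projected to the nearest PSD correlation matrix
    if screening broke positive semi-definiteness.  Idempotent whenever the
    screened matrix is itself PSD (the usual case).
    """
    p = np.asarray(p_values, dtype=float)
    if p.shape != corr.matrix.shape:
        raise ValueError("p-value table shape does not match correlation matrix")
    m = corr.matrix.copy()
    off = ~np.eye(len(m), dtype=bool)
    kill = off & ((p > alpha) | (np.abs(m) < r_min))
    m[kill] = 0.0
    if np.linalg.eigvalsh(m).min() < -_PSD_TOL:
        m = nearest_psd(m)
    meta = dict(corr.meta)
    meta["adjusted"] = {"alpha": alpha, "r_min": r_min, "zeroed": int(kill.sum() // 2)}
    return CorrelationSpec(corr.labels, m, meta)
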