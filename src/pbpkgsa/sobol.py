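"""Variance-based Sobol indices for independent inputs.

Sampling uses a scrambled Sobol' low-discrepancy sequence in 2k dimensions
split into the two base matrices A and B, pushed through each parameter's
truncated inverse CDF (variance-based analysis samples the *distributions*,
unlike Morris screening which uses ranges only).  Estimators are the
Saltelli (2010) form for the first-order index

    S_i = (1/N) sum fB (fAB_i - fA) / V

and the Jansen form for the total index

    S_Ti = (1/2N) sum (fA - fAB_i)^2 / V,

with the interaction index reported as ``S_Ti - S_i``.  Raw (unclipped)
values are reported so that negative estimates within Monte-Carlo noise stay
visible; repetition dispersion comes from re-running with spawned seeds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "SobolDesign",
    "VarianceIndices",
    "build_design",
    "estimate_indices",
    "repeat_analysis",
    "SobolAnalysis",
]


class DegenerateOutputError(RuntimeError):
    """Model output variance is (numerically) zero."""


@dataclasses.dataclass(frozen=True)
class SobolDesign:
    """Saltelli design: base matrices A, B and the column-swapped AB_i."""

    A: np.ndarray          # (N, k) parameter values
    B: np.ndarray          # (N, k)
    N: int
    labels: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.A.shape[1]

    @property
    def n_evaluations(self) -> int:
        return self.N * (self.k + 2)

    def AB(self, i: int) -> np.ndarray:
        out = self.A.copy()
        out[:, i] = self.B[:, i]
        return out


def build_design(marginals, N: int, seed: int = 0) -> SobolDesign:
    """Quasi-random design through the truncated marginal quantiles.

    Fixed-family marginals cannot be part of a variance-based design (their
    variance is zero); passing only fixed marginals raises.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    varying = [m for m in marginals if getattr(m, "family", None) != "fixed"]
    if not varying:
        raise ValueError("design is degenerate: all marginals are fixed")
    k = len(varying)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # N need not be 2^m
        u = qmc.Sobol(d=2 * k, scramble=True, seed=seed).random(N)
    # keep quantile arguments strictly inside (0, 1)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    A = np.column_stack([m.quantile(u[:, j]) for j, m in enumerate(varying)])
    B = np.column_stack([m.quantile(u[:, k + j]) for j, m in enumerate(varying)])
    return SobolDesign(A, B, N, tuple(m.name for m in varying))


def estimate_indices(fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """First-order and total indices from aligned evaluation vectors.

    ``fA``/``fB`` are ``(N, m)`` and ``fAB`` is ``(k, N, m)`` for m
    endpoints.  Rows containing non-finite values anywhere are dropped
    jointly so the estimators stay aligned.
    """
    fA = np.atleast_2d(np.asarray(fA, dtype=float).T).T
    fB = np.atleast_2d(np.asarray(fB, dtype=float).T).T
    if fAB.ndim == 2:
        fAB = fAB[:, :, None]
    good = (np.isfinite(fA).all(axis=1) & np.isfinite(fB).all(axis=1)
            & np.isfinite(fAB).all(axis=(0, 2)))
    fA, fB, fAB = fA[good], fB[good], fAB[:, good]
    if fA.shape[0] < 2:
        raise DegenerateOutputError("fewer than 2 usable design rows")

    pooled = np.concatenate([fA, fB], axis=0)
    V = pooled.var(axis=0)
    if np.any(V <= 1e-300):
        raise DegenerateOutputError("model output variance is zero")
    Si = np.mean(fB[None] * (fAB - fA[None]), axis=1) / V      # (k, m)
    STi = 0.5 * np.mean((fA[None] - fAB) ** 2, axis=1) / V     # (k, m)
    return Si, STi


@dataclasses.dataclass
class VarianceIndices:
    """First-order/total/interaction indices with repetition dispersion."""

    labels: tuple[str, ...]
    endpoint_names: tuple[str, ...]
    Si: np.ndarray        # (k, m) mean over repetitions
    STi: np.ndarray       # (k, m)
    Si_sd: np.ndarray
    STi_sd: np.ndarray
    n_reps: int
    N: int
    n_evaluations: int = 0
    first_order_attr: str = "S_i"
    total_attr: str = "S_Ti"

    @property
    def interaction(self) -> np.ndarray:
        return self.STi - self.Si

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, ep in enumerate(self.endpoint_names):
            order = np.argsort(-self.STi[:, e])
            rank = np.empty_like(order)
            rank[order] = np.arange(1, len(order) + 1)
            for i, lab in enumerate(self.labels):
                row = {
                    "endpoint": ep, "parameter": lab,
                    self.first_order_attr: self.Si[i, e],
                    self.total_attr: self.STi[i, e],
                    "interaction": self.interaction[i, e],
                    f"{self.first_order_attr}_sd": self.Si_sd[i, e],
                    f"{self.total_attr}_sd": self.STi_sd[i, e],
                    "rank": int(rank[i]),
                }
                if self.first_order_attr.endswith("_ext"):
                    # under correlation the first-order index may exceed the
                    # total index (it absorbs correlated contributions)
                    row["exceeds_total"] = bool(self.Si[i, e] > self.STi[i, e])
                rows.append(row)
        return pd.DataFrame(rows)

    def ranking(self, endpoint: str, by: str = "total") -> list[str]:
        e = self.endpoint_names.index(endpoint)
        key = self.STi[:, e] if by == "total" else self.Si[:, e]
        return [self.labels[i] for i in np.argsort(-key)]

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Variance-based indices ({self.first_order_attr}/{self.total_attr}): "
            f"N = {self.N}, {self.n_reps} repetition(s), "
            f"{self.n_evaluations} model evaluations",
        ]
        for ep in self.endpoint_names:
            sub = df[df.endpoint == ep].sort_values("rank")
            lines.append(f"\n[{ep}]")
            lines.append(sub.head(8).to_string(
                index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _run_once(model, marginals, N, seed, endpoint_probe):
    design = build_design(marginals, N, seed)
    fA = model(design.A)
    fB = model(design.B)
    fAB = np.stack([model(design.AB(i)) for i in range(design.k)])
    if fA.ndim == 1:
        fA, fB, fAB = fA[:, None], fB[:, None], fAB[:, :, None]
    Si, STi = estimate_indices(fA, fB, fAB)
    return design, Si, STi


def repeat_analysis(model, marginals, N: int, n_reps: int = 10,
                    seed: int = 0, endpoint_names=None) -> VarianceIndices:
    """Indices averaged over ``n_reps`` independent repetitions.

    Each repetition uses a seed spawned from ``seed``; per-index dispersion
    across repetitions is reported as a Monte-Carlo standard deviation.
    Repetitions that fail (degenerate output) are skipped as long as at
    least two survive.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2 for a dispersion estimate")
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    all_Si, all_STi, failures = [], [], []
    design = None
    for s in seeds:
        try:
            design, Si, STi = _run_once(model, marginals, N, int(s) % 2**31, None)
            all_Si.append(Si)
            all_STi.append(STi)
        except DegenerateOutputError as err:  # pragma: no cover - rare
            failures.append(str(err))
    if len(all_Si) < 2:
        raise DegenerateOutputError(
            f"fewer than 2 successful repetitions ({failures})")
    Si = np.stack(all_Si)
    STi = np.stack(all_STi)
    labels = design.labels
    m = Si.shape[2]
    endpoint_names = tuple(endpoint_names) if endpoint_names else tuple(
        getattr(model, "endpoint_names", ()) or (f"y{j+1}" for j in range(m)))
    return VarianceIndices(
        labels, endpoint_names, Si.mean(axis=0), STi.mean(axis=0),
        Si.std(axis=0, ddof=1), STi.std(axis=0, ddof=1),
        len(all_Si), N, n_evaluations=len(all_Si) * N * (len(labels) + 2),
    )


class SobolAnalysis:
    """Sobol analysis of a model through its marginal distributions.

    ``model`` maps an ``(n, k)`` value array to outputs and (optionally)
    exposes ``marginals``/``endpoint_names``.  ``run(seed)`` returns a
    :class:`VarianceIndices` result; with ``n_reps == 1`` the dispersion
    columns are zero.
    """

    def __init__(self, model, N: int = 8000, n_reps: int = 1, marginals=None):
        self.model = model
        self.N = N
        self.n_reps = n_reps
        self.marginals = marginals if marginals is not None else model.marginals

    def run(self, seed: int = 0) -> VarianceIndices:
        if self.n_reps > 1:
            return repeat_analysis(self.model, self.marginals, self.N,
                                   self.n_reps, seed)
        design, Si, STi = _run_once(self.model, self.marginals, self.N, seed, None)
        m = Si.shape[1]
        endpoint_names = tuple(
            getattr(self.model, "endpoint_names", ()) or
            (f"y{j+1}" for j in range(m)))
        return VarianceIndices(
            design.labels, endpoint_names, Si, STi,
            np.zeros_like(Si), np.zeros_like(STi), 1, self.N,
            n_evaluations=design.n_evaluations,
        )
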