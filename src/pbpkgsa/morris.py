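"""Morris elementary-effects screening.

The design places ``r`` random trajectories on an ``l``-level grid of the
unit cube with jump ``delta = l/(2(l-1))``: each trajectory starts at a
random admissible grid point and perturbs the coordinates one at a time in a
random order and random direction.  Model inputs are obtained by mapping
unit-cube coordinates *linearly* onto each parameter's [min, max] range —
screening works on ranges only, the marginal distributions play no role
here.

For each parameter the elementary effects ``EE = (f(x + d e_i) - f(x))/d``
(unit-cube scale, so effects are comparable across parameters) are
summarised by the signed mean ``mu``, the mean absolute value ``mu*``, the
standard deviation ``sigma``, and the ranking metric
``GI = sqrt(mu*^2 + sigma^2)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "build_trajectories",
    "elementary_effects",
    "global_index",
    "MorrisAnalysis",
]


@dataclasses.dataclass(frozen=True)
class MorrisDesign:
    """Unit-cube Morris trajectories; rows are grouped per trajectory."""

    k: int
    l: int
    r: int
    delta: float
    points: np.ndarray  # (r*(k+1), k)

    @property
    def n_rows(self) -> int:
        return self.r * (self.k + 1)

    def map_to(self, ranges: np.ndarray) -> np.ndarray:
        """Linear map of the unit-cube design onto parameter [min, max]."""
        ranges = np.asarray(ranges, dtype=float)
        return ranges[:, 0] + self.points * (ranges[:, 1] - ranges[:, 0])


def global_index(mu_star, sigma):
    """Ranking metric ``sqrt(mu*^2 + sigma^2)``."""
    return np.hypot(mu_star, sigma)


def build_trajectories(k: int, l: int, r: int, seed: int | np.random.Generator = 0
                       ) -> MorrisDesign:
    """Randomised-orientation Morris design with ``r`` trajectories.

    ``l`` must be even (the jump spans ``l/2`` grid levels so that
    ``delta = l/(2(l-1))``); base points, coordinate order and jump signs
    are drawn from ``seed``.
    """
    if l < 2 or l % 2 != 0:
        raise ValueError("number of levels l must be even and >= 2")
    if r < 1 or k < 1:
        raise ValueError("need r >= 1 trajectories and k >= 1 parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jump = l // 2                      # grid levels per elementary jump
    delta = jump / (l - 1)             # == l / (2 (l - 1))

    levels = np.empty((r * (k + 1), k), dtype=np.int64)
    for t in range(r):
        signs = rng.integers(0, 2, size=k) * 2 - 1
        base = np.empty(k, dtype=np.int64)
        for j in range(k):
            # admissible base levels keep base + sign*jump on the grid
            base[j] = rng.integers(0, l - jump) if signs[j] > 0 \
                else rng.integers(jump, l)
        order = rng.permutation(k)
        row = base.copy()
        block = levels[t * (k + 1):(t + 1) * (k + 1)]
        block[0] = row
        for step, j in enumerate(order, start=1):
            row = row.copy()
            row[j] += signs[j] * jump
            block[step] = row
    return MorrisDesign(k, l, r, delta, levels / (l - 1))


@dataclasses.dataclass
class MorrisResult:
    """Per-parameter screening summaries, one column set per endpoint."""

    labels: tuple[str, ...]
    endpoint_names: tuple[str, ...]
    mu: np.ndarray        # (k, m) signed mean elementary effect
    mu_star: np.ndarray   # (k, m) mean absolute elementary effect
    sigma: np.ndarray     # (k, m) sd of elementary effects
    n_trajectories: int
    n_dropped: int

    @property
    def gi(self) -> np.ndarray:
        return global_index(self.mu_star, self.sigma)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, ep in enumerate(self.endpoint_names):
            order = np.argsort(-self.gi[:, e])
            rank = np.empty_like(order)
            rank[order] = np.arange(1, len(order) + 1)
            for i, lab in enumerate(self.labels):
                rows.append({
                    "endpoint": ep, "parameter": lab, "mu": self.mu[i, e],
                    "mu_star": self.mu_star[i, e], "sigma": self.sigma[i, e],
                    "gi": self.gi[i, e], "rank": int(rank[i]),
                })
        return pd.DataFrame(rows)

    def ranking(self, endpoint: str) -> list[str]:
        e = self.endpoint_names.index(endpoint)
        return [self.labels[i] for i in np.argsort(-self.gi[:, e])]

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Morris screening: {len(self.labels)} parameters, "
            f"{self.n_trajectories} trajectories used "
            f"({self.n_dropped} dropped)",
        ]
        for ep in self.endpoint_names:
            sub = df[df.endpoint == ep].sort_values("rank")
            lines.append(f"\n[{ep}] top parameters by GI = sqrt(mu*^2 + sigma^2)")
            lines.append(sub.head(8).to_string(
                index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def elementary_effects(design: MorrisDesign, outputs: np.ndarray,
                       labels=None, endpoint_names=None) -> MorrisResult:
    """Summarise elementary effects from model outputs on the design rows.

    ``outputs`` has one row per design point and one column per endpoint.
    Trajectories containing any non-finite output are dropped and counted.
    """
    y = np.asarray(outputs, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != design.n_rows:
        raise ValueError("outputs not aligned with design rows")
    m = y.shape[1]
    k, r = design.k, design.r
    labels = tuple(labels) if labels is not None else tuple(
        f"x{i+1}" for i in range(k))
    endpoint_names = tuple(endpoint_names) if endpoint_names is not None else tuple(
        f"y{j+1}" for j in range(m))

    pts = design.points.reshape(r, k + 1, k)
    yy = y.reshape(r, k + 1, m)
    good = np.isfinite(yy).all(axis=(1, 2))
    n_used = int(good.sum())
    if n_used == 0:
        raise ValueError("all trajectories contained non-finite outputs")

    dpts = np.diff(pts[good], axis=1)          # (g, k, k)
    dy = np.diff(yy[good], axis=1)             # (g, k, m)
    which = np.argmax(np.abs(dpts), axis=2)    # changed coordinate per step
    signed = np.take_along_axis(dpts, which[:, :, None], axis=2)[:, :, 0]

    # each trajectory perturbs every coordinate exactly once, so this fills
    # the whole (trajectory, parameter) grid
    ee = np.empty((n_used, k, m))
    ee[np.arange(n_used)[:, None], which, :] = dy / signed[:, :, None]

    mu = ee.mean(axis=0)
    mu_star = np.abs(ee).mean(axis=0)
    sigma = ee.std(axis=0, ddof=1) if n_used > 1 else np.zeros((k, m))
    return MorrisResult(labels, endpoint_names, mu, mu_star, sigma,
                        n_used, r - n_used)


class MorrisAnalysis:
    """Morris screening of a model over its parameter ranges.

    Parameters
    ----------
    model : callable
        Maps an ``(n, k)`` value array to an ``(n, m)`` output array; if it
        exposes ``labels``/``ranges``/``endpoint_names`` they are picked up.
    l, r : int
        Grid levels and number of trajectories.
    ranges : (k, 2) array, optional
        Parameter [min, max]; defaults to ``model.ranges``.
    """

    def __init__(self, model, l: int = 10, r: int = 1500, ranges=None):
        self.model = model
        self.l, self.r = l, r
        self.ranges = np.asarray(
            ranges if ranges is not None else model.ranges, dtype=float)
        self.labels = tuple(getattr(model, "labels",
                                    [f"x{i+1}" for i in range(len(self.ranges))]))
        self.endpoint_names = tuple(getattr(model, "endpoint_names", ()))

    def run(self, seed: int = 0) -> MorrisResult:
        design = build_trajectories(len(self.ranges), self.l, self.r, seed)
        y = self.model(design.map_to(self.ranges))
        return elementary_effects(design, y, self.labels,
                                  self.endpoint_names or None)
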