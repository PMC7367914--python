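"""Per-drug GSA orchestration, influence classification and validation.

Ties the pieces together: build a drug's :class:`~pbpkgsa.mpbpk.PBPKModel`
(fixture + scenario), run the requested engine, classify parameters as
negligible / influential (> 1% of output variance) / key (> 10%), and emit
ranked tables plus a reproducibility manifest.  Also hosts the benchmark
validation suite that checks all three engines against analytic oracles.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .ext_sobol import ExtendedSobolAnalysis
from .morris import MorrisAnalysis, MorrisResult
from .mpbpk import PBPKModel
from .sobol import SobolAnalysis, VarianceIndices
from . import testfunctions as tf

__all__ = [
    "AnalysisConfig",
    "classify",
    "classify_pair",
    "run_drug",
    "DrugAnalysisResult",
    "FunctionModel",
    "validate_testsuite",
    "ValidationReport",
]

METHODS = ("morris", "sobol", "ext_sobol")

#: variance-share thresholds (strict inequalities)
INFLUENTIAL_THRESHOLD = 0.01
KEY_THRESHOLD = 0.1

#: abort threshold on the infeasible-subject rate for distribution-based
#: sampling (for Morris range grids, dropped trajectories are reported
#: instead; see AnalysisConfig docstring)
MAX_INFEASIBLE_RATE = 0.05


def classify(index_value: float) -> str:
    """Influence class of a single variance-based sensitivity index."""
    v = float(index_value)
    if not np.isfinite(v):
        raise ValueError("index value must be finite")
    if v > KEY_THRESHOLD:
        return "key"
    if v > INFLUENTIAL_THRESHOLD:
        return "influential"
    return "negligible"


def classify_pair(first_order: float, total: float) -> str:
    """A parameter's class is the stronger of its first-order/total class."""
    order = {"negligible": 0, "influential": 1, "key": 2}
    a, b = classify(first_order), classify(total)
    return a if order[a] >= order[b] else b


@dataclasses.dataclass
class AnalysisConfig:
    """One GSA run: drug, engine, sampling settings and scenario.

    Scaled-down defaults (N = 2000, r = 200, single repetition) keep a full
    drug analysis in the minutes range; ``reference_scale()`` switches to the
    heavy reference settings (N = 8000, r = 1500, 10 repetitions).
    """

    drug: str
    method: str = "sobol"
    endpoints: tuple[str, ...] = ("C_max", "T_max", "AUC_24h", "AUC_48h")
    morris_l: int = 10
    morris_r: int = 200
    N: int = 2000
    n_reps: int = 1
    seed: int = 0
    scenario: str = "baseline"
    correlation_overrides: dict | None = None
    population_size: int = 2000

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def reference_scale(self) -> "AnalysisConfig":
        return dataclasses.replace(self, morris_r=1500, N=8000, n_reps=10)


@dataclasses.dataclass
class DrugAnalysisResult:
    """Engine result plus ranked/classified tables and a run manifest."""

    config: AnalysisConfig
    result: MorrisResult | VarianceIndices
    ranked: dict[str, pd.DataFrame]
    manifest: dict

    def ranking(self, endpoint: str) -> list[str]:
        return list(self.ranked[endpoint]["parameter"])

    def influential(self, endpoint: str) -> set[str]:
        t = self.ranked[endpoint]
        if "influence" not in t.columns:
            raise ValueError("influence classes apply to variance-based methods only")
        return set(t.loc[t["influence"] != "negligible", "parameter"])

    def summary(self) -> str:
        return self.result.summary()

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.result.to_frame().to_csv(out / "indices.csv", index=False)
        for ep, table in self.ranked.items():
            table.to_csv(out / f"ranked_{ep}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _ranked_tables(result, endpoints) -> dict[str, pd.DataFrame]:
    tables = {}
    df = result.to_frame()
    variance_based = isinstance(result, VarianceIndices)
    for ep in endpoints:
        sub = df[df.endpoint == ep].sort_values("rank").reset_index(drop=True)
        if variance_based:
            first, total = result.first_order_attr, result.total_attr
            sub["influence"] = [
                classify_pair(a, b) for a, b in zip(sub[first], sub[total])
            ]
        tables[ep] = sub
    return tables


def run_drug(config: AnalysisConfig) -> DrugAnalysisResult:
    """Run one engine on one drug and return ranked, classified tables.

    Raises if the infeasible-subject rate of distribution-based sampling
    exceeds 5%, or if Morris loses more than half its trajectories to
    infeasible design corners.
    """
    model = PBPKModel.from_drug(config.drug, config.scenario,
                                config.correlation_overrides)
    if config.method == "morris":
        res = MorrisAnalysis(model, l=config.morris_l, r=config.morris_r
                             ).run(config.seed)
        if res.n_dropped > 0.5 * config.morris_r:
            raise RuntimeError(
                f"{config.drug}: {res.n_dropped}/{config.morris_r} Morris "
                "trajectories hit infeasible corners (V_sys <= 0)")
    elif config.method == "sobol":
        res = SobolAnalysis(model, N=config.N, n_reps=config.n_reps
                            ).run(config.seed)
    else:
        res = ExtendedSobolAnalysis(model, N=config.N, n_reps=config.n_reps
                                    ).run(config.seed)
    rate = model.n_infeasible / max(model.n_evaluations, 1)
    if config.method != "morris" and rate > MAX_INFEASIBLE_RATE:
        raise RuntimeError(
            f"{config.drug}: infeasible-subject rate {rate:.1%} exceeds "
            f"{MAX_INFEASIBLE_RATE:.0%}; check marginals/correlation fixture")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_model_evaluations": model.n_evaluations,
        "n_infeasible_subjects": model.n_infeasible,
        "infeasible_rate": rate,
    }
    if isinstance(res, MorrisResult):
        manifest["n_trajectories_dropped"] = res.n_dropped
    return DrugAnalysisResult(config, res,
                              _ranked_tables(res, config.endpoints), manifest)


# ---------------------------------------------------------------------------
# engine validation against analytic oracles
# ---------------------------------------------------------------------------

class FunctionModel:
    """Adapter presenting a plain function as a model for the engines."""

    def __init__(self, fn, marginals, endpoint_names=("y",)):
        self.fn = fn
        self.marginals = tuple(marginals)
        self.labels = tuple(m.name for m in self.marginals)
        self.ranges = np.array([[m.lower, m.upper] for m in self.marginals])
        self.endpoint_names = tuple(endpoint_names)
        self.corr = None

    def __call__(self, X):
        return np.asarray(self.fn(np.atleast_2d(X)), dtype=float)


@dataclasses.dataclass
class ValidationReport:
    rows: list[dict]

    @property
    def passed(self) -> bool:
        return all(r["passed"] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> str:
        df = self.to_frame()
        status = "PASS" if self.passed else "FAIL"
        return (f"GSA engine validation: {status} "
                f"({int(df.passed.sum())}/{len(df)} checks)\n"
                + df.to_string(index=False,
                               float_format=lambda v: f"{v:.4f}"))


def validate_testsuite(N: int = 8000, seed: int = 0,
                       morris_r: int = 200) -> ValidationReport:
    """Check all three engines against analytic benchmark solutions.

    Sobol runs the Ishigami-Homma function and the g-function; extended
    Sobol a linear function of correlated Gaussians (rho = 0.5); Morris a
    linear function whose analytic ranking is known.  Tolerance is +/-0.02
    on every index estimate.
    """
    rows = []
    tol = 0.02

    # Sobol: Ishigami
    model = FunctionModel(tf.ishigami, tf.ishigami_marginals())
    res = SobolAnalysis(model, N=N).run(seed)
    oracle = tf.ishigami_indices()
    for label, est, true in [
        ("S1", res.Si[0, 0], oracle["S1"]), ("S2", res.Si[1, 0], oracle["S2"]),
        ("S3", res.Si[2, 0], oracle["S3"]), ("ST3", res.STi[2, 0], oracle["ST3"]),
    ]:
        rows.append({"case": "sobol/ishigami", "quantity": label,
                     "estimate": float(est), "oracle": float(true), "tol": tol,
                     "passed": bool(abs(est - true) <= tol)})

    # Sobol: g-function
    model = FunctionModel(tf.g_function, tf.g_function_marginals())
    res = SobolAnalysis(model, N=N).run(seed + 1)
    oracle = tf.g_function_indices()
    for i in range(4):
        rows.append({"case": "sobol/g-function", "quantity": f"S{i+1}",
                     "estimate": float(res.Si[i, 0]),
                     "oracle": float(oracle["S"][i]), "tol": tol,
                     "passed": bool(abs(res.Si[i, 0] - oracle["S"][i]) <= tol)})

    # extended Sobol: linear correlated Gaussian
    rho = 0.5
    from .population import CorrelationSpec

    margs = [tf.wide_normal_marginal("x1"), tf.wide_normal_marginal("x2")]
    corr = CorrelationSpec(("x1", "x2"), np.array([[1.0, rho], [rho, 1.0]]))
    model = FunctionModel(lambda X: X.sum(axis=1), margs)
    res = ExtendedSobolAnalysis(model, corr=corr, N=N).run(seed + 2)
    oracle = tf.linear_gaussian_ext_indices([1.0, 1.0], corr.matrix)
    for label, est, true in [
        ("S1_ext", res.Si[0, 0], oracle["S_ext"][0]),
        ("ST1_ext", res.STi[0, 0], oracle["ST_ext"][0]),
    ]:
        rows.append({"case": "ext_sobol/linear-gaussian", "quantity": label,
                     "estimate": float(est), "oracle": float(true), "tol": tol,
                     "passed": bool(abs(est - true) <= tol)})

    # Morris: linear function, analytic ranking |coefficient * range width|
    coeffs = np.array([4.0, 2.0, 1.0, 0.5, 0.0])
    margs = [tf.UniformMarginal(f"x{i+1}", 0.0, 1.0) for i in range(5)]
    model = FunctionModel(lambda X: X @ coeffs, margs)
    res = MorrisAnalysis(model, l=10, r=morris_r).run(seed + 3)
    expected_rank = [f"x{i+1}" for i in np.argsort(-coeffs)]
    got_rank = res.ranking("y")
    rows.append({"case": "morris/linear", "quantity": "ranking",
                 "estimate": float(got_rank == expected_rank),
                 "oracle": 1.0, "tol": 0.0,
                 "passed": got_rank == expected_rank})
    for i, c in enumerate(coeffs):
        est = float(res.mu_star[i, 0])
        rows.append({"case": "morris/linear", "quantity": f"mu*_{i+1}",
                     "estimate": est, "oracle": float(c), "tol": 1e-9,
                     "passed": bool(abs(est - c) <= 1e-9)})
    return ValidationReport(rows)


def plot_indices(result, endpoint: str, ax=None):
    """Simple bar chart of a result's indices for one endpoint."""
    import matplotlib.pyplot as plt

    df = result.to_frame()
    sub = df[df.endpoint == endpoint].sort_values("rank")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    if isinstance(result, VarianceIndices):
        first, total = result.first_order_attr, result.total_attr
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub[first], width=0.4, label=first)
        ax.bar(x + 0.2, sub[total], width=0.4, label=total)
        ax.axhline(INFLUENTIAL_THRESHOLD, ls=":", c="grey", lw=0.8)
        ax.axhline(KEY_THRESHOLD, ls="--", c="grey", lw=0.8)
        ax.set_xticks(x)
        ax.legend()
    else:
        x = np.arange(len(sub))
        ax.bar(x, sub["gi"], width=0.6, label="GI")
        ax.set_xticks(x)
        ax.legend()
    ax.set_xticklabels(sub["parameter"], rotation=60, ha="right", fontsize=7)
    ax.set_title(endpoint)
    ax.set_ylabel("sensitivity index")
    return ax
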