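"""Drug fixtures: dose, parameter marginals, enzyme pathways, correlation.

Each supported drug (quinidine, alprazolam, midazolam) ships as a YAML
config mirroring its published parameter table: one record per parameter
(family, shape parameters, truncation bounds, unit) plus the enzyme pathway
roster and model options (adjusting compartment on/off, clearance mode).

The numeric correlation matrix behind the published analysis is not public
(only its qualitative structure is described), so :func:`default_correlation`
builds a configurable fixture: a strong Kp_liver-fu link of 0.9, moderate
body-weight links to liver volume and the two hepatic blood flows, and
moderate inter-enzyme links, all overridable.  The fixture is flagged
non-published in its metadata.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import yaml

from .marginals import MarginalSpec
from .population import CorrelationSpec

__all__ = [
    "SubPathway",
    "EnzymePathway",
    "DrugSpec",
    "DRUGS",
    "SCENARIOS",
    "load_drug",
    "default_correlation",
    "default_fixture",
    "apply_scenario",
]

DRUGS = ("quinidine", "alprazolam", "midazolam")
SCENARIOS = ("baseline", "normalized_flows", "independent_cyps")

#: default fixture correlations (latent-normal scale); overridable
FIXTURE_CORRELATIONS = {
    ("Kp_liver", "fu"): 0.9,
    ("BW", "V_liver"): 0.6,
    ("BW", "Q_HA"): 0.5,
    ("BW", "Q_PV"): 0.4,
}
FIXTURE_ENZYME_CORRELATION = 0.4

#: normalised-flow marginals (flow per kg body weight), used by the
#: normalized_flows scenario
NORMALIZED_FLOW_MARGINALS = {
    "Q_HA": ("Qhat_HA", -1.24, 1.44e-2),
    "Q_PV": ("Qhat_PV", -0.11, 1.77e-2),
}


@dataclasses.dataclass(frozen=True)
class SubPathway:
    """One Michaelis-Menten metabolite-formation route of an enzyme."""

    label: str
    vmax_param: str
    km_param: str


@dataclasses.dataclass(frozen=True)
class EnzymePathway:
    """One enzyme's contribution to hepatic intrinsic clearance.

    Direct mode references a sampled CL_int parameter; Michaelis-Menten mode
    references a sampled abundance plus fixed (Vmax, Km) sub-pathways.
    """

    enzyme: str
    clint_param: str | None = None
    abundance_param: str | None = None
    subpathways: tuple[SubPathway, ...] = ()

    def __post_init__(self) -> None:
        if self.clint_param is None and self.abundance_param is None:
            raise ValueError(f"{self.enzyme}: pathway needs clint or abundance")
        if self.abundance_param is not None and not self.subpathways:
            raise ValueError(f"{self.enzyme}: Michaelis-Menten pathway needs sub-pathways")


@dataclasses.dataclass(frozen=True)
class DrugSpec:
    """A drug's dose, parameter roster, pathways and model options."""

    name: str
    dose_mg: float
    sac_enabled: bool
    clearance_mode: str  # "direct_clint" | "michaelis_menten"
    marginals: tuple[MarginalSpec, ...]
    pathways: tuple[EnzymePathway, ...]
    molecular_weight: float | None = None
    flows_normalized: bool = False

    def __post_init__(self) -> None:
        if self.clearance_mode not in ("direct_clint", "michaelis_menten"):
            raise ValueError(f"unknown clearance mode {self.clearance_mode!r}")
        if self.clearance_mode == "michaelis_menten" and self.molecular_weight is None:
            raise ValueError("Michaelis-Menten mode needs a molecular weight")

    @property
    def varying(self) -> tuple[MarginalSpec, ...]:
        return tuple(m for m in self.marginals if not m.is_fixed)

    @property
    def varying_labels(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.varying)

    @property
    def fixed_values(self) -> dict[str, float]:
        return {m.name: float(m.value) for m in self.marginals if m.is_fixed}

    @property
    def enzyme_params(self) -> tuple[str, ...]:
        out = []
        for p in self.pathways:
            out.append(p.clint_param or p.abundance_param)
        return tuple(out)

    def marginal(self, name: str) -> MarginalSpec:
        for m in self.marginals:
            if m.name == name:
                return m
        raise KeyError(name)

    def replace(self, **kw) -> "DrugSpec":
        return dataclasses.replace(self, **kw)


def load_drug(name: str) -> DrugSpec:
    """Load a drug config shipped with the package."""
    if name not in DRUGS:
        raise ValueError(f"unknown drug {name!r}; choose from {DRUGS}")
    text = resources.files("pbpkgsa.data").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    margs = tuple(MarginalSpec(**rec) for rec in raw["parameters"])
    pathways = []
    for rec in raw["pathways"]:
        subs = tuple(SubPathway(**s) for s in rec.pop("subpathways", []))
        pathways.append(EnzymePathway(subpathways=subs, **rec))
    return DrugSpec(
        name=raw["name"],
        dose_mg=float(raw["dose_mg"]),
        sac_enabled=bool(raw["sac_enabled"]),
        clearance_mode=raw["clearance_mode"],
        marginals=margs,
        pathways=tuple(pathways),
        molecular_weight=raw.get("molecular_weight"),
    )


def default_correlation(
    drug: DrugSpec,
    overrides: dict[tuple[str, str], float] | None = None,
) -> CorrelationSpec:
    """Build the configurable correlation fixture for a drug.

    Entries: Kp_liver-fu 0.9; BW to V_liver/Q_HA/Q_PV 0.6/0.5/0.4; pairwise
    inter-enzyme (CL_int or abundance) 0.4; everything else 0.  ``overrides``
    maps (label, label) pairs to replacement values (0 removes a link).
    """
    labels = drug.varying_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    m = np.eye(len(labels))

    entries = dict(FIXTURE_CORRELATIONS)
    enz = drug.enzyme_params
    for i, a in enumerate(enz):
        for b in enz[i + 1:]:
            entries[(a, b)] = FIXTURE_ENZYME_CORRELATION
    if overrides:
        for (a, b), r in overrides.items():
            entries[(a, b)] = float(r)

    for (a, b), r in entries.items():
        if a in idx and b in idx:
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    spec = CorrelationSpec(labels, m, {"source": "configurable fixture (non-published values)"})
    return spec.repaired() if not spec.is_psd() else spec


def default_fixture(
    name: str,
    correlation_overrides: dict[tuple[str, str], float] | None = None,
) -> tuple[DrugSpec, CorrelationSpec]:
    """Published marginals plus the default correlation fixture for a drug."""
    drug = load_drug(name)
    return drug, default_correlation(drug, correlation_overrides)


def _zero_links(corr: CorrelationSpec, involved: set[str]) -> np.ndarray:
    m = corr.matrix.copy()
    for i, a in enumerate(corr.labels):
        for j, b in enumerate(corr.labels):
            if i != j and (a in involved or b in involved):
                m[i, j] = 0.0
    return m


def apply_scenario(
    drug: DrugSpec, corr: CorrelationSpec, scenario: str
) -> tuple[DrugSpec, CorrelationSpec]:
    """Return (drug, correlation) modified for a reparametrisation scenario.

    ``normalized_flows`` replaces the absolute hepatic flows with flows per
    kg body weight (Qhat = Q/BW, lognormal marginals) and removes their
    correlation links (the reparametrisation exists precisely to strip the
    body-weight effect from the flows); the model multiplies by BW again
    internally.  ``independent_cyps`` zeroes the inter-enzyme correlations
    and keeps everything else.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "baseline":
        return drug, corr

    if scenario == "normalized_flows":
        new_margs = []
        renames = {}
        for m in drug.marginals:
            if m.name in NORMALIZED_FLOW_MARGINALS:
                new_name, p1, p2 = NORMALIZED_FLOW_MARGINALS[m.name]
                renames[m.name] = new_name
                new_margs.append(
                    MarginalSpec(new_name, "lognormal", p1, p2, 1e-6, 10.0, unit="L/h/kg")
                )
            else:
                new_margs.append(m)
        new_drug = drug.replace(marginals=tuple(new_margs), flows_normalized=True)
        labels = tuple(renames.get(lab, lab) for lab in corr.labels)
        m = _zero_links(CorrelationSpec(labels, corr.matrix, dict(corr.meta)),
                        set(renames.values()))
        meta = dict(corr.meta)
        meta["scenario"] = scenario
        return new_drug, CorrelationSpec(labels, m, meta)

    # independent_cyps
    enz = set(drug.enzyme_params)
    m = corr.matrix.copy()
    for i, a in enumerate(corr.labels):
        for j, b in enumerate(corr.labels):
            if i != j and a in enz and b in enz:
                m[i, j] = 0.0
    meta = dict(corr.meta)
    meta["scenario"] = scenario
    return drug, CorrelationSpec(corr.labels, m, meta)
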