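"""Minimal PBPK model: systemic blood, portal vein, liver, optional SAC.

State variables are blood (or tissue) concentrations in mg/L:

* ``C_sys`` — systemic blood; drains into the liver through the hepatic
  artery (flow ``Q_HA``) and the splanchnic bed / portal vein (``Q_PV``),
  cleared renally at ``CL_R`` (plasma clearance, hence the ``/BP``) and
  optionally exchanges with a single adjusting compartment (SAC) at rates
  ``K_in``/``K_out``.
* ``C_pv`` — portal-vein blood; receives the first-order oral input
  ``f_a k_a F_g Dose e^(-k_a t)``.
* ``C_liver`` — liver tissue; venous outflow concentration is
  ``C_liver/(Kp_liver/BP)`` and hepatic elimination is
  ``CL_uintH f_u C_liver/Kp_liver`` (unbound intrinsic clearance acting on
  the unbound tissue concentration).
* ``C_sac`` — the empirical peripheral compartment (midazolam only).

The systemic volume is not sampled directly but derived from the sampled
steady-state volume of distribution:
``V_sys = (V_ss BW - Kp_liver V_liver + V_sac BW) / BP``; subjects for whom
this is non-positive are physiologically infeasible and rejected.

Hepatic intrinsic clearance is either a sum of directly sampled per-enzyme
``CL_int`` values (quinidine, alprazolam — a linear, constant-coefficient
system solved in closed form) or re-evaluated along the trajectory from
enzyme abundances via Michaelis-Menten kinetics (midazolam — integrated
numerically with LSODA).

PK endpoints are computed on the *plasma* concentration ``C_sys/BP``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numba
import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

from . import drugs as _drugs
from .drugs import DrugSpec, EnzymePathway

__all__ = [
    "ENDPOINT_NAMES",
    "InfeasibleSubjectError",
    "Trajectory",
    "PKEndpoints",
    "derive_vsys",
    "fraction_cleared",
    "hepatic_clint",
    "assemble_parameters",
    "simulate",
    "endpoints",
    "evaluate_endpoints",
    "auc_infinity_oracle",
    "PBPKModel",
]

ENDPOINT_NAMES = ("C_max", "T_max", "AUC_24h", "AUC_48h")

#: pmol/min per uM  ->  L/h
_MM_UNIT = 60e-6

#: symbols every assembled parameter vector must carry
_CORE_SYMBOLS = (
    "fa", "ka", "Fg", "BP", "fu", "Kp_liver", "Q_HA", "Q_PV",
    "BW", "V_pv", "V_liver", "V_ss", "CL_R",
)


class InfeasibleSubjectError(ValueError):
    """Sampled vector implies a non-positive systemic volume."""


class SimulationError(RuntimeError):
    """ODE solver failed for a parameter vector."""


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def fraction_cleared(t: float, half_life: float) -> float:
    """Fraction of drug eliminated after time ``t`` under first-order decay.

    ``1 - 2^(-t/t_half)`` — the back-of-envelope used to argue when a
    truncated AUC already approximates AUC_inf (e.g. a 6-8 h half-life
    clears ~87-94% of the dose within 24 h).
    """
    if half_life <= 0 or t < 0:
        raise ValueError("need t >= 0 and half_life > 0")
    return 1.0 - 2.0 ** (-t / half_life)


def derive_vsys(V_ss, Kp_liver, V_liver, V_sac, BW, BP):
    """Systemic volume (L) from the steady-state distribution volume.

    Inverts ``V_ss = (Kp_liver V_liver + V_sys BP - V_sac BW)/BW`` exactly as
    printed (``V_ss`` and ``V_sac`` are per kg).  Non-positive results mark
    the subject infeasible; scalar callers should reject, batch callers mask.
    """
    return (V_ss * BW - Kp_liver * V_liver + V_sac * BW) / BP


def hepatic_clint(
    pathways: tuple[EnzymePathway, ...],
    C_u_liver: float,
    values: Mapping[str, float],
) -> float:
    """Unbound hepatic intrinsic clearance (L/h) summed over enzymes.

    Direct pathways contribute their sampled CL_int directly; Michaelis-
    Menten pathways contribute ``A Vm/(Km + C_u_liver)`` in pmol/min per uM,
    converted to L/h (x 60e-6).  ``C_u_liver`` is the unbound liver
    concentration in uM.
    """
    if C_u_liver < 0:
        raise ValueError("C_u_liver must be >= 0")
    total = 0.0
    for p in pathways:
        if p.clint_param is not None:
            cl = float(values[p.clint_param])
            if cl < 0:
                raise ValueError(f"{p.enzyme}: negative CL_int")
            total += cl
        else:
            a = float(values[p.abundance_param])
            if a < 0:
                raise ValueError(f"{p.enzyme}: negative abundance")
            for s in p.subpathways:
                vm, km = float(values[s.vmax_param]), float(values[s.km_param])
                total += _MM_UNIT * a * vm / (km + C_u_liver)
    return total


def assemble_parameters(drug: DrugSpec, values: Mapping[str, float]) -> dict[str, float]:
    """Merge sampled values with the drug's fixed constants into one vector.

    Handles the normalised-flow reparametrisation (``Q = Qhat * BW``) and
    defaults the SAC constants to zero when the compartment is disabled.
    """
    p = dict(drug.fixed_values)
    p.update({k: float(v) for k, v in values.items()})
    if drug.flows_normalized:
        p["Q_HA"] = p.pop("Qhat_HA") * p["BW"]
        p["Q_PV"] = p.pop("Qhat_PV") * p["BW"]
    if not drug.sac_enabled:
        p.setdefault("K_in", 0.0)
        p.setdefault("K_out", 0.0)
        p.setdefault("V_sac", 0.0)
    missing = [s for s in _CORE_SYMBOLS if s not in p]
    if missing:
        raise KeyError(f"missing model symbols: {missing}")
    p["V_sys"] = derive_vsys(
        p["V_ss"], p["Kp_liver"], p["V_liver"], p["V_sac"], p["BW"], p["BP"]
    )
    return p


# ---------------------------------------------------------------------------
# reference trajectory simulation (scipy solve_ivp)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Trajectory:
    """Dense solution of the model on a regular time grid (h, mg/L)."""

    t: np.ndarray
    C_sys: np.ndarray
    C_sac: np.ndarray
    C_pv: np.ndarray
    C_liver: np.ndarray
    auc_plasma: np.ndarray  # cumulative integral of C_sys/BP

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.t, "C_sys": self.C_sys, "C_sac": self.C_sac,
            "C_pv": self.C_pv, "C_liver": self.C_liver,
            "auc_plasma": self.auc_plasma,
        })


@dataclasses.dataclass(frozen=True)
class PKEndpoints:
    """Plasma-scale endpoints of one simulated subject."""

    C_max: float   # mg/L
    T_max: float   # h
    AUC_24h: float  # mg*h/L
    AUC_48h: float  # mg*h/L

    def as_array(self) -> np.ndarray:
        return np.array([self.C_max, self.T_max, self.AUC_24h, self.AUC_48h])


def _mm_tables(drug: DrugSpec, values: Mapping[str, float]):
    """Per-sub-pathway (abundance, Vmax, Km) arrays for Michaelis-Menten mode."""
    a, vm, km = [], [], []
    for p in drug.pathways:
        for s in p.subpathways:
            a.append(float(values[p.abundance_param]))
            vm.append(float(values[s.vmax_param]))
            km.append(float(values[s.km_param]))
    return np.array(a), np.array(vm), np.array(km)


def simulate(
    drug: DrugSpec,
    values: Mapping[str, float],
    t_end: float = 48.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid: float = 0.01,
) -> Trajectory:
    """Integrate the model for one subject with LSODA (reference path).

    ``values`` maps the drug's varying parameter labels to concrete values.
    Raises :class:`InfeasibleSubjectError` when the derived systemic volume
    is non-positive.
    """
    p = assemble_parameters(drug, values)
    if p["V_sys"] <= 0:
        raise InfeasibleSubjectError(
            f"V_sys = {p['V_sys']:.4g} L <= 0 for subject of {drug.name}"
        )

    Q = p["Q_HA"] + p["Q_PV"]
    E = p["Kp_liver"] / p["BP"]
    vsac_abs = max(p["V_sac"] * p["BW"], 1e-30)
    dose_rate0 = p["fa"] * p["ka"] * p["Fg"] * drug.dose_mg
    mm = drug.clearance_mode == "michaelis_menten"
    if mm:
        a_arr, vm_arr, km_arr = _mm_tables(drug, p)
        mw = float(drug.molecular_weight)

    def rhs(t, y):
        c_sys, c_sac, c_pv, c_liv, _ = y
        if mm:
            cu = p["fu"] * c_liv / p["Kp_liver"] / mw * 1000.0  # mg/L -> uM
            cl_uinth = float(np.sum(_MM_UNIT * a_arr * vm_arr / (km_arr + max(cu, 0.0))))
        else:
            cl_uinth = sum(p[pw.clint_param] for pw in drug.pathways)
        d_sys = (
            Q * c_liv / E - Q * c_sys - p["CL_R"] * c_sys / p["BP"]
            - p["K_in"] * p["V_sys"] * c_sys + p["K_out"] * vsac_abs * c_sac
        ) / p["V_sys"]
        d_sac = (p["K_in"] * p["V_sys"] * c_sys - p["K_out"] * vsac_abs * c_sac) / vsac_abs
        d_pv = (
            p["Q_PV"] * c_sys - p["Q_PV"] * c_pv + dose_rate0 * math.exp(-p["ka"] * t)
        ) / p["V_pv"]
        d_liv = (
            p["Q_PV"] * c_pv + p["Q_HA"] * c_sys - Q * c_liv / E
            - cl_uinth * p["fu"] * c_liv / p["Kp_liver"]
        ) / p["V_liver"]
        return (d_sys, d_sac, d_pv, d_liv, c_sys / p["BP"])

    t_eval = np.arange(0.0, t_end + grid / 2, grid)
    sol = solve_ivp(
        rhs, (0.0, t_end), np.zeros(5), method="LSODA",
        rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationError(f"{drug.name}: {sol.message}")
    y = sol.y
    if np.any(y[[0, 1, 2, 3]] < -1e-9):
        raise SimulationError(f"{drug.name}: negative concentrations beyond tolerance")
    return Trajectory(sol.t, y[0], y[1], y[2], y[3], y[4])


# ---------------------------------------------------------------------------
# endpoint extraction
# ---------------------------------------------------------------------------

def _refine_max(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Peak of a sampled curve with local quadratic refinement."""
    i = int(np.argmax(c))
    if c[i] <= 0:
        return 0.0, 0.0
    if 0 < i < len(c) - 1:
        y0, y1, y2 = c[i - 1], c[i], c[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper local max
            s = 0.5 * (y0 - y2) / denom
            s = float(np.clip(s, -1.0, 1.0))
            dt = t[1] - t[0]
            return float(y1 - 0.25 * (y0 - y2) * s), float(t[i] + s * dt)
    return float(c[i]), float(t[i])


def endpoints(traj: Trajectory, BP: float) -> PKEndpoints:
    """Plasma C_max/T_max and the 0-24 h / 0-48 h partial AUCs."""
    plasma = traj.C_sys / BP
    cmax, tmax = _refine_max(traj.t, plasma)
    auc24 = float(np.interp(24.0, traj.t, traj.auc_plasma))
    auc48 = float(np.interp(48.0, traj.t, traj.auc_plasma))
    if cmax == 0.0:
        return PKEndpoints(0.0, 0.0, 0.0, 0.0)
    return PKEndpoints(cmax, tmax, auc24, auc48)


# ---------------------------------------------------------------------------
# fast batch paths
# ---------------------------------------------------------------------------

def _collect(drug: DrugSpec, values) -> dict[str, np.ndarray]:
    """Columns (n,) for every model symbol, fixed constants broadcast."""
    if isinstance(values, pd.DataFrame):
        cols = {k: values[k].to_numpy(dtype=float) for k in values.columns}
    else:
        cols = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in values.items()}
    n = max(len(v) for v in cols.values())
    p = {k: np.full(n, v) for k, v in drug.fixed_values.items()}
    for k, v in cols.items():
        p[k] = np.broadcast_to(v, (n,)).astype(float)
    if drug.flows_normalized:
        p["Q_HA"] = p.pop("Qhat_HA") * p["BW"]
        p["Q_PV"] = p.pop("Qhat_PV") * p["BW"]
    if not drug.sac_enabled:
        for k in ("K_in", "K_out", "V_sac"):
            p.setdefault(k, np.zeros(n))
    p["V_sys"] = derive_vsys(p["V_ss"], p["Kp_liver"], p["V_liver"],
                             p["V_sac"], p["BW"], p["BP"])
    return p


def _linear_endpoints(drug: DrugSpec, p: dict[str, np.ndarray],
                      mask: np.ndarray) -> np.ndarray:
    """Closed-form endpoints for the constant-clearance (linear) system.

    The three-state system ``x' = A x + b0 exp(-ka t)`` with ``x(0) = 0`` has
    solution ``x(t) = exp(-ka t) v - P exp(L t) P^-1 v`` with
    ``v = -(A + ka I)^-1 b0``; peak search runs on a 0.02 h grid with
    quadratic refinement and the partial AUCs are evaluated exactly.
    """
    n = len(mask)
    out = np.full((n, 4), np.nan)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out

    QHA, QPV = p["Q_HA"][idx], p["Q_PV"][idx]
    Q = QHA + QPV
    BP, Kp, fu = p["BP"][idx], p["Kp_liver"][idx], p["fu"][idx]
    E = Kp / BP
    Vs, Vp, Vl = p["V_sys"][idx], p["V_pv"][idx], p["V_liver"][idx]
    ka = p["ka"][idx].copy()
    clu = np.zeros(idx.size)
    for pw in drug.pathways:
        clu = clu + p[pw.clint_param][idx]

    m = idx.size
    A = np.zeros((m, 3, 3))
    A[:, 0, 0] = -(Q + p["CL_R"][idx] / BP) / Vs
    A[:, 0, 2] = Q / E / Vs
    A[:, 1, 0] = QPV / Vp
    A[:, 1, 1] = -QPV / Vp
    A[:, 2, 0] = QHA / Vl
    A[:, 2, 1] = QPV / Vl
    A[:, 2, 2] = -(Q / E + clu * fu / Kp) / Vl
    b0 = np.zeros((m, 3))
    b0[:, 1] = p["fa"][idx] * ka * p["Fg"][idx] * drug.dose_mg / Vp

    lam, P = np.linalg.eig(A)
    # avoid resonance between the absorption rate and a system eigenvalue
    clash = np.min(np.abs(lam + ka[:, None]), axis=1) < 1e-9
    ka[clash] *= 1.0 + 1e-7

    eye = np.eye(3)

    def _batch_solve(mats, rhs):
        try:
            return np.linalg.solve(mats, rhs[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # a grid-corner subject can yield a (near-)singular matrix;
            # fall back to least squares row by row
            out = np.empty_like(rhs)
            for r in range(len(mats)):
                out[r] = np.linalg.lstsq(mats[r], rhs[r], rcond=None)[0]
            return out

    v = _batch_solve(A + ka[:, None, None] * eye, -b0)
    w = _batch_solve(P, v.astype(complex))
    coef = P[:, 0, :] * w          # (m, 3) complex
    cka = v[:, 0]                  # (m,) real

    tg = np.arange(0.0, 48.0 + 1e-9, 0.02)
    cmax = np.zeros(m)
    tmax = np.zeros(m)
    chunk = 512
    for s in range(0, m, chunk):
        sl = slice(s, min(s + chunk, m))
        et = np.exp(lam[sl, :, None] * tg[None, None, :])      # (c,3,nt)
        c_sys = (cka[sl, None] * np.exp(-ka[sl, None] * tg[None, :])
                 - np.einsum("cj,cjt->ct", coef[sl], et).real)
        plasma = c_sys / BP[sl, None]
        for r, row in enumerate(plasma):
            cmax[s + r], tmax[s + r] = _refine_max(tg, row)

    lam_safe = np.where(np.abs(lam) < 1e-300, -1e-300, lam)

    def _auc(t):
        growth = (np.exp(lam * t) - 1.0) / lam_safe
        return (cka * (1.0 - np.exp(-ka * t)) / ka
                - np.sum(coef * growth, axis=1).real) / BP

    zero = b0[:, 1] == 0.0
    res = np.column_stack([cmax, tmax, _auc(24.0), _auc(48.0)])
    res[zero] = 0.0
    res = np.clip(res, 0.0, None)
    out[idx] = res
    return out


@numba.njit(cache=False)
def _mm_rhs(t, y, c, a_arr, vm_arr, km_arr):
    """Michaelis-Menten model right-hand side (numba-compiled).

    ``c`` packs [Q_HA, Q_PV, V_pv, V_liver, V_sys, Kp, BP, fu, ka,
    dose_rate0, K_in, K_out, Vsac_abs, CL_R, MW].
    """
    QHA, QPV, Vp, Vl, Vs, Kp, BP, fu, ka, dr0, Kin, Kout, Vsac, CLR, MW = c
    c_sys, c_sac, c_pv, c_liv, _ = y
    cu = fu * c_liv / Kp / MW * 1000.0
    if cu < 0.0:
        cu = 0.0
    cl = 0.0
    for j in range(a_arr.shape[0]):
        cl += a_arr[j] * vm_arr[j] / (km_arr[j] + cu)
    cl *= _MM_UNIT
    Q = QHA + QPV
    E = Kp / BP
    out = np.empty(5)
    out[0] = (Q * c_liv / E - Q * c_sys - CLR * c_sys / BP
              - Kin * Vs * c_sys + Kout * Vsac * c_sac) / Vs
    out[1] = (Kin * Vs * c_sys - Kout * Vsac * c_sac) / Vsac
    out[2] = (QPV * c_sys - QPV * c_pv + dr0 * np.exp(-ka * t)) / Vp
    out[3] = (QPV * c_pv + QHA * c_sys - Q * c_liv / E - cl * fu * c_liv / Kp) / Vl
    out[4] = c_sys / BP
    return out


def _mm_endpoints(drug: DrugSpec, p: dict[str, np.ndarray],
                  mask: np.ndarray, rtol: float = 1e-8,
                  atol: float = 1e-10) -> np.ndarray:
    """LSODA batch integration for the Michaelis-Menten (nonlinear) system."""
    n = len(mask)
    out = np.full((n, 4), np.nan)
    tg = np.arange(0.0, 48.0 + 1e-9, 0.02)
    i24 = int(round(24.0 / 0.02))
    mw = float(drug.molecular_weight)

    sub_a, sub_vm, sub_km = [], [], []
    for pw in drug.pathways:
        for s in pw.subpathways:
            sub_a.append(pw.abundance_param)
            sub_vm.append(s.vmax_param)
            sub_km.append(s.km_param)

    y0 = np.zeros(5)
    for i in np.flatnonzero(mask):
        vsac_abs = max(p["V_sac"][i] * p["BW"][i], 1e-30)
        c = np.array([
            p["Q_HA"][i], p["Q_PV"][i], p["V_pv"][i], p["V_liver"][i],
            p["V_sys"][i], p["Kp_liver"][i], p["BP"][i], p["fu"][i],
            p["ka"][i], p["fa"][i] * p["ka"][i] * p["Fg"][i] * drug.dose_mg,
            p["K_in"][i], p["K_out"][i], vsac_abs, p["CL_R"][i], mw,
        ])
        a_arr = np.array([p[nm][i] for nm in sub_a])
        vm_arr = np.array([p[nm][i] for nm in sub_vm])
        km_arr = np.array([p[nm][i] for nm in sub_km])
        y = odeint(_mm_rhs, y0, tg, args=(c, a_arr, vm_arr, km_arr),
                   rtol=rtol, atol=atol, tfirst=True)
        plasma = y[:, 0] / p["BP"][i]
        cm, tm = _refine_max(tg, plasma)
        out[i] = (cm, tm, max(y[i24, 4], 0.0), max(y[-1, 4], 0.0)) if cm > 0 \
            else (0.0, 0.0, 0.0, 0.0)
    return out


def evaluate_endpoints(drug: DrugSpec, values) -> tuple[np.ndarray, int]:
    """Endpoints (n, 4) for a table of subjects; infeasible rows are NaN.

    ``values`` is a DataFrame (or mapping of arrays) of the drug's varying
    parameters.  Returns the endpoint matrix in :data:`ENDPOINT_NAMES` order
    and the count of infeasible (rejected) subjects.
    """
    p = _collect(drug, values)
    feasible = p["V_sys"] > 0
    if drug.clearance_mode == "direct_clint":
        out = _linear_endpoints(drug, p, feasible)
    else:
        out = _mm_endpoints(drug, p, feasible)
    return out, int((~feasible).sum())


def auc_infinity_oracle(drug: DrugSpec, values: Mapping[str, float]) -> float:
    """Stationary linear-system AUC_inf (plasma) for direct-clearance drugs.

    Solves ``A auc = -b0/ka`` where ``A`` is the constant system matrix and
    ``b0/ka`` the time-integral of the oral input; independent of the
    time-stepping used by :func:`simulate`.
    """
    if drug.clearance_mode != "direct_clint":
        raise ValueError("oracle applies to the linear (direct-clearance) mode")
    p = assemble_parameters(drug, values)
    if p["V_sys"] <= 0:
        raise InfeasibleSubjectError("V_sys <= 0")
    Q = p["Q_HA"] + p["Q_PV"]
    E = p["Kp_liver"] / p["BP"]
    clu = sum(p[pw.clint_param] for pw in drug.pathways)
    A = np.array([
        [-(Q + p["CL_R"] / p["BP"]) / p["V_sys"], 0.0, Q / E / p["V_sys"]],
        [p["Q_PV"] / p["V_pv"], -p["Q_PV"] / p["V_pv"], 0.0],
        [p["Q_HA"] / p["V_liver"], p["Q_PV"] / p["V_liver"],
         -(Q / E + clu * p["fu"] / p["Kp_liver"]) / p["V_liver"]],
    ])
    # the oral input integrates to f_a Fg Dose / V_pv (the ka factors cancel)
    b_int = np.array([0.0, p["fa"] * p["Fg"] * drug.dose_mg / p["V_pv"], 0.0])
    auc = np.linalg.solve(A, -b_int)
    return float(auc[0] / p["BP"])


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class PBPKModel:
    """A drug's PBPK endpoint map over its varying parameters.

    The model object bundles the drug fixture (marginals, pathways, dose),
    the correlation fixture, and the scenario reparametrisation; calling it
    with an ``(n, k)`` array of parameter values (columns in ``labels``
    order) returns the ``(n, 4)`` endpoint matrix.  It is the object the GSA
    analysis classes are fitted to.
    """

    def __init__(self, drug: DrugSpec, corr=None):
        self.drug = drug
        self.corr = corr
        self.labels = drug.varying_labels
        self.marginals = drug.varying
        self.endpoint_names = ENDPOINT_NAMES
        self.ranges = np.array([[m.lower, m.upper] for m in self.marginals])
        self.n_evaluations = 0
        self.n_infeasible = 0

    @classmethod
    def from_drug(cls, name: str, scenario: str = "baseline",
                  correlation_overrides=None) -> "PBPKModel":
        drug, corr = _drugs.default_fixture(name, correlation_overrides)
        drug, corr = _drugs.apply_scenario(drug, corr, scenario)
        return cls(drug, corr)

    @property
    def k(self) -> int:
        return len(self.labels)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.k:
            raise ValueError(f"expected {self.k} columns, got {X.shape[1]}")
        table = {lab: X[:, j] for j, lab in enumerate(self.labels)}
        out, n_bad = evaluate_endpoints(self.drug, table)
        self.n_evaluations += len(X)
        self.n_infeasible += n_bad
        return out

    def median_subject(self) -> dict[str, float]:
        return {m.name: float(m.quantile(0.5)) for m in self.marginals}

    def simulate_subject(self, values: Mapping[str, float] | None = None,
                         **kw) -> Trajectory:
        return simulate(self.drug, values or self.median_subject(), **kw)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PBPKModel({self.drug.name!r}, k={self.k}, "
                f"mode={self.drug.clearance_mode})")
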