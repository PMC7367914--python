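# Methods

## The model

`pbpkgsa` simulates single oral doses with a minimal PBPK model of four
blood/tissue compartments: systemic blood (`C_sys`), portal vein (`C_pv`),
liver (`C_liver`) and, for midazolam, an empirical single adjusting
compartment (SAC, `C_sac`). All states are concentrations in mg/L:

    dC_sys/dt   = [ (Q_HA + Q_PV) C_liver/(Kp_liver/BP) − (Q_HA + Q_PV) C_sys
                    − CL_R C_sys/BP − K_in V_sys C_sys + K_out V_sac' C_sac ] / V_sys
    dC_sac/dt   = [ K_in V_sys C_sys − K_out V_sac' C_sac ] / V_sac'
    dC_pv/dt    = [ Q_PV C_sys − Q_PV C_pv + f_a k_a F_g Dose e^(−k_a t) ] / V_pv
    dC_liver/dt = [ Q_PV C_pv + Q_HA C_sys − (Q_HA + Q_PV) C_liver/(Kp_liver/BP)
                    − CL_uintH f_u C_liver/Kp_liver ] / V_liver

with `V_sac' = V_sac · BW` (the SAC volume is specified per kg).  The
systemic volume is derived by inverting the steady-state distribution-volume
relation exactly as specified,

    V_sys = (V_ss · BW − Kp_liver · V_liver + V_sac · BW) / BP,

and a sampled subject with `V_sys ≤ 0` is physiologically infeasible and
rejected (counted and reported in every run manifest).  Unbound hepatic
intrinsic clearance is either a sum of directly sampled per-enzyme values
(quinidine: CYP3A4/2C9/2E1; alprazolam: CYP3A4/3A5) or, for midazolam,
re-evaluated along the trajectory from sampled enzyme abundances via
Michaelis–Menten kinetics,

    CL_int,enz = A_enz · V_m,enz / (K_m,enz + C_u,liver),

in pmol/min per µM, converted to L/h (× 60·10⁻⁶).  The driving unbound
liver concentration is `C_u,liver = f_u C_liver / Kp_liver`, converted from
mg/L to µM with the molecular weight (config field; midazolam default
325.8 g/mol).  The UGT1A4 maximum rate is tabulated per mg microsomal
protein while the abundance is in pmol UGT; the same `A·V_m/(K_m + C_u)`
form is applied and the unit mismatch is a documented caveat of the
parameterisation.  One notational choice: the liver outflow uses
`Q_HA + Q_PV` throughout (the hepatic venous flow equals the total inflow).

PK endpoints (`C_max`, `T_max`, partial `AUC_24h`/`AUC_48h`) are computed on
the **plasma** concentration `C_sys/BP`.  The peak is located on a dense
output grid and refined with a local quadratic fit; the AUC is carried as an
auxiliary ODE state (reference path) or evaluated in closed form (batch
path).

### Numerical strategy

* Reference path — `simulate()`: LSODA (stiff-capable) at rtol 1e-8 /
  atol 1e-10, dense output on a 0.01 h grid over 0–48 h.
* Linear batch path — quinidine and alprazolam have constant clearances, so
  the system is linear time-invariant with forcing `b0 e^(−k_a t)`.  The
  solution `x(t) = e^(−k_a t) v − P e^(Λt) P⁻¹ v`, `v = −(A + k_a I)⁻¹ b0`,
  is evaluated from a batched eigendecomposition; partial AUCs are exact.
  If `k_a` collides with a system eigenvalue it is nudged by 1e-7 relative.
* Michaelis–Menten batch path — LSODA (`scipy.integrate.odeint`) with a
  numba-compiled right-hand side at the same tolerances, output on a 0.02 h
  grid.

Both batch paths are cross-checked against the reference integrator in the
test suite (agreement to ~1e-3 relative or better per endpoint, dominated by
the T_max grid refinement).  A further structural oracle checks that the
long-time integrated AUC matches the stationary linear-system solution
`A·auc = −b0/k_a` to < 0.1% over 100 random quinidine subjects, and that
with all elimination set to zero the total drug amount is conserved to
< 1e-4 relative drift.

## Input distributions and the virtual population

Every parameter has a marginal from one of three families — normal,
lognormal, Weibull — plus hard truncation bounds, as tabulated per drug in
`src/pbpkgsa/data/*.yaml`.  The second distribution parameter is a
**variance** (of the values for normal, of the log values for lognormal);
this is the only reading under which the tabulated `Norm(0.008, 6.4e-7)`
with a stated 10% CV is self-consistent, and it makes every implied central
value physiological (body-weight median e^4.30 ≈ 73.7 kg).  Truncation is
implemented by CDF renormalisation (inverse-CDF mapping), never rejection,
so quasi-random designs remain uniform after transformation.

Dependence is a Gaussian copula: a correlation matrix is imposed on latent
standard-normal scores, which are mapped through Φ and the truncated
quantiles.  The target matrix is therefore the *latent* correlation; for
these mildly skewed marginals the induced Pearson correlation of the values
differs by well under 0.03 (the copula round-trip test recovers the target
entrywise to ±0.04 at n = 5000).  Using the latent scale makes the
conditional sampling in the extended-Sobol engine exact and shares one
dependence model between population generation and GSA.

The numeric correlation matrix behind the published analysis is not public,
so the package ships a configurable fixture flagged non-published in its
metadata: Kp_liver–f_u = 0.9 (the strong partitioning/binding link, kept
just below 1 so both parameters remain individually explorable), body-weight
links to liver volume / hepatic-artery flow / portal flow of 0.6 / 0.5 / 0.4
(moderate-to-strong, with the artery slightly stronger than the portal
vein), pairwise inter-enzyme links of 0.4, everything else zero.  All
entries are overridable per run.  Consequences: drug-specific *numeric*
index values depend on this fixture and are not exactly reproducible;
the qualitative conclusions checked by the acceptance suite depend only on
the printed marginals (Morris/Sobol) or on the fixture's qualitative
structure (scenario direction).

Matrices estimated from data (`estimate_correlation`) carry exact-t
p-values; `adjust_correlation` zeroes non-significant (p > 0.05) and weak
(|r| < 0.1) entries and re-projects to the nearest PSD correlation matrix
(eigenvalue clipping + diagonal renormalisation) only if screening broke
semi-definiteness.  A repair that would move any entry by more than 0.05 is
treated as an error rather than silently applied.

`fit_best` re-fits marginals to generated populations by maximum likelihood
and selects the family by lowest AIC (= 4 − 2 logL for all three
two-parameter families; ties break normal < lognormal < Weibull).
Likelihoods are untruncated and truncation is applied at sampling time; at
n = 2000 the distinction is immaterial and the generating family is
recovered in ≥ 95% of replicates for well-separated generators.

## Sensitivity engines

**Morris screening** uses `r` randomised trajectories on an `l`-level grid
of the unit cube, jump `Δ = l/(2(l−1))`, with coordinates mapped *linearly*
onto each parameter's [min, max] — screening uses ranges only, not the
distributions.  Elementary effects are kept in unit-cube scale so `μ*` is
comparable across parameters; ranking uses `GI = sqrt(μ*² + σ²)` with no
influence thresholds (a screening index says nothing about variance
fractions).  Trajectories that hit infeasible corners (the full printed
ranges do contain combinations with `V_sys ≤ 0`, e.g. maximal
Kp_liver·V_liver against minimal V_ss·BW) are dropped and counted; a run
aborts only if more than half are lost.  Because Morris spans the full
ranges while the variance-based engines sample the concentrated marginals,
parameters whose printed range vastly exceeds their population spread
(f_u, BP, the flows) rank visibly higher under Morris — the screening
ranking should be read with that in mind.

**Sobol** samples the truncated marginals through a scrambled Sobol'
low-discrepancy sequence (2k dimensions split into the A/B base matrices;
N(k+2) model runs).  Estimators: Saltelli-2010 for the first-order index,
Jansen for the total index; interaction = S_Ti − S_i.  Estimates are
reported raw (no clipping at zero) so negative values within Monte-Carlo
noise stay visible.  Repetitions with spawned seeds give per-index
dispersion.  Engine validation: Ishigami–Homma and g-function indices within
±0.02 of their closed forms at N = 8000.

**Extended Sobol** (correlated inputs) conditions in the latent-normal space
of the same Gaussian copula, with marginal transforms applied after
conditioning.  Single-loop double-randomisation estimators: the first-order
index from the covariance of output pairs sharing `x_i` (conditional
complements drawn from the Schur-complement normal), the total index from
half the mean squared difference of output pairs sharing the complement.
Cost is 4N runs per parameter.  Under correlation the first-order index
absorbs correlated contributions and may exceed the total index or 1; with
an identity matrix both reduce to the standard Sobol indices (checked on
Ishigami at N = 8000).  Closed-form validation uses linear functions of
correlated Gaussians (for `f = x₁ + x₂`, ρ = 0.5: S₁_ext = 0.75 >
S_T1_ext = 0.25, the signature inversion).

A fourth estimator, `first_order_by_conditional_quadrature`, evaluates
`Var(E[f | x_i])/Var(f)` on a quantile grid of `x_i` with one common inner
sample of conditional complements re-used across grid points.  The shared
inner noise largely cancels in the variance over the grid, so indices far
below the single-loop noise floor become resolvable; the price is a bias of
the order of the interaction variance, so it is intended for near-additive
responses — specifically for ordering two weak parameters, as in the
normalised-flow scenario below.  It is validated against the linear-Gaussian
closed form and against tiny-coefficient additive cases.

## Classification, ranking and scenarios

Variance-based indices classify a parameter by the larger of its first-order
and total index: > 0.1 key, > 0.01 influential (strict inequalities), else
negligible.  Ranked tables sort by the total index with the first-order
index alongside; Morris tables sort by GI and carry no influence classes.

Scenarios reparametrise the model:

* `normalized_flows` replaces the absolute hepatic flows with flows per kg
  body weight — `Q̂_HA ~ lognormal(−1.24, 1.44e-2)`,
  `Q̂_PV ~ lognormal(−0.11, 1.77e-2)`, bounds (0, 10] L/h/kg — and the model
  multiplies by BW internally.  The fixture links between the flows and BW
  are removed: stripping the body-weight effect from the flows is the point
  of the reparametrisation, and in the default fixture the flows correlate
  with nothing else.
* `independent_cyps` zeroes the inter-enzyme correlation entries and keeps
  all other links.

For an orally dosed low-extraction drug the hepatic flow largely cancels in
the AUC (the well-stirred first-pass factor against the hepatic clearance),
so the normalised flows' first-order indices on AUC_48h are of order 1e-5.
Their *ordering* (portal vein above hepatic artery, driven by the larger
log-variance and larger flow) is therefore checked with the
conditional-quadrature estimator, which resolves it deterministically; a
plain single-loop run at practical N returns noise an order of magnitude
larger than either index.

## Default problem sizes

Scaled-down defaults keep a full drug analysis in the minutes range on one
core: Sobol/ext-Sobol N = 2000, Morris r = 200, single repetition.  The
reference settings (N = 8000, r = 1500, 10 repetitions) sit behind
`AnalysisConfig.reference_scale()` / the CLI `--reference-scale` flag.  The
acceptance checks run the engine-validation problems at N = 8000 and the
drug rankings at N = 2000 with a three-seed majority vote.

## What the synthetic population does and does not emulate

The generator reproduces: the tabulated marginal families, parameters and
truncation ranges; a linear (Gaussian-copula) dependence structure; and
feasibility screening via the derived systemic volume.  It does not model:
demographic covariates (age/sex/renal function — renal clearance variability
enters only through its printed marginal), nonlinear parameter dependences
(the copula is linear on the latent scale), gut–liver enzyme correlation
(gut availability is an independent input), or any between-study variability
in the tabulated values.  Passing tests therefore demonstrate correctness of
the machinery and reproduction of the study's qualitative structure under
*this* dependence fixture — not numeric transferability to a real
population whose correlation matrix differs.

## Known limitations

* Drug-specific index values depend on the non-published correlation
  fixture; only qualitative claims are asserted.
* Morris on full printed ranges mixes screening over ranges with
  distribution-based variance analysis; rankings from the two families of
  methods agree only partially by construction.
* The UGT1A4 abundance/V_m unit mismatch is inherited from the tabulated
  parameterisation.
* Single dose, no transporters, no permeability-limited tissues, no
  pharmacodynamics.
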