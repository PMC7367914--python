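# Alprazolam: oral 0.5 mg, CYP3A4/CYP3A5 directly sampled intrinsic
# clearances, no peripheral adjusting compartment.
name: alprazolam
dose_mg: 0.5
sac_enabled: false
clearance_mode: direct_clint
parameters:
  - {name: fa,            family: weibull,   p1: 8.86,   p2: 0.94,    lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: ka,            family: lognormal, p1: 1.21,   p2: 0.09,    lower: 1.0e-6, upper: 10.0,  unit: "1/h"}
  - {name: Fg,            family: weibull,   p1: 512.33, p2: 1.0,     lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: BP,            family: normal,    p1: 0.84,   p2: 2.05e-4, lower: 0.55,   upper: 100.0, unit: ""}
  - {name: fu,            family: lognormal, p1: -1.25,  p2: 5.4e-3,  lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: Kp_liver,      family: lognormal, p1: -0.146, p2: 4.9e-3,  lower: 1.0e-6, upper: 10.0,  unit: ""}
  - {name: CLint_CYP3A4,  family: lognormal, p1: 2.10,   p2: 0.26,    lower: 1.0e-6, upper: 100.0, unit: "L/h"}
  - {name: CLint_CYP3A5,  family: lognormal, p1: 1.58,   p2: 0.18,    lower: 1.0e-6, upper: 100.0, unit: "L/h"}
  - {name: Q_HA,          family: lognormal, p1: 3.05,   p2: 1.44e-2, lower: 1.0e-6, upper: 50.0,  unit: "L/h"}
  - {name: Q_PV,          family: lognormal, p1: 4.19,   p2: 1.05e-2, lower: 1.0e-6, upper: 150.0, unit: "L/h"}
  - {name: BW,            family: lognormal, p1: 4.30,   p2: 3.8e-2,  lower: 30.0,   upper: 200.0, unit: "kg"}
  - {name: V_pv,          family: normal,    p1: 0.008,  p2: 6.4e-7,  lower: 1.0e-6, upper: 0.15,  unit: "L"}
  - {name: V_liver,       family: lognormal, p1: 0.39,   p2: 2.97e-2, lower: 0.1,    upper: 5.0,   unit: "L"}
  - {name: V_ss,          family: normal,    p1: 0.76,   p2: 1.06e-2, lower: 1.0e-6, upper: 5.0,   unit: "L/kg"}
  - {name: CL_R,          family: normal,    p1: 0.68,   p2: 4.6e-3,  lower: 1.0e-6, upper: 5.0,   unit: "L/h"}
pathways:
  - {enzyme: CYP3A4, clint_param: CLint_CYP3A4}
  - {enzyme: CYP3A5, clint_param: CLint_CYP3A5}
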