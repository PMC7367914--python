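# Quinidine: oral 200 mg, three CYP pathways with directly sampled
# intrinsic clearances, no peripheral adjusting compartment.
name: quinidine
dose_mg: 200.0
sac_enabled: false
clearance_mode: direct_clint
parameters:
  - {name: fa,            family: weibull,   p1: 8.86,  p2: 0.94,    lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: ka,            family: lognormal, p1: 1.05,  p2: 0.09,    lower: 1.0e-6, upper: 10.0,  unit: "1/h"}
  - {name: Fg,            family: weibull,   p1: 46.3,  p2: 0.96,    lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: BP,            family: normal,    p1: 0.89,  p2: 9.64e-5, lower: 0.55,   upper: 100.0, unit: ""}
  - {name: fu,            family: lognormal, p1: -1.61, p2: 7.0e-3,  lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: Kp_liver,      family: normal,    p1: 4.37,  p2: 3.95e-2, lower: 1.0e-6, upper: 10.0,  unit: ""}
  - {name: CLint_CYP2E1,  family: lognormal, p1: 0.47,  p2: 4.23e-1, lower: 1.0e-6, upper: 100.0, unit: "L/h"}
  - {name: CLint_CYP2C9,  family: lognormal, p1: 0.18,  p2: 4.27e-1, lower: 1.0e-6, upper: 100.0, unit: "L/h"}
  - {name: CLint_CYP3A4,  family: lognormal, p1: 4.35,  p2: 2.59e-1, lower: 1.0e-6, upper: 1000.0, unit: "L/h"}
  - {name: Q_HA,          family: lognormal, p1: 3.05,  p2: 1.44e-2, lower: 1.0e-6, upper: 50.0,  unit: "L/h"}
  - {name: Q_PV,          family: lognormal, p1: 4.19,  p2: 1.05e-2, lower: 1.0e-6, upper: 150.0, unit: "L/h"}
  - {name: BW,            family: lognormal, p1: 4.30,  p2: 3.8e-2,  lower: 30.0,   upper: 200.0, unit: "kg"}
  - {name: V_pv,          family: normal,    p1: 0.008, p2: 6.4e-7,  lower: 1.0e-6, upper: 0.15,  unit: "L"}
  - {name: V_liver,       family: lognormal, p1: 0.39,  p2: 2.97e-2, lower: 0.1,    upper: 5.0,   unit: "L"}
  - {name: V_ss,          family: lognormal, p1: 0.63,  p2: 2.83e-2, lower: 1.0e-6, upper: 5.0,   unit: "L/kg"}
  - {name: CL_R,          family: normal,    p1: 1.95,  p2: 3.8e-2,  lower: 1.0e-6, upper: 5.0,   unit: "L/h"}
pathways:
  - {enzyme: CYP2E1, clint_param: CLint_CYP2E1}
  - {enzyme: CYP2C9, clint_param: CLint_CYP2C9}
  - {enzyme: CYP3A4, clint_param: CLint_CYP3A4}
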