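# Midazolam: oral 5 mg, Michaelis-Menten hepatic clearance from sampled
# enzyme abundances with fixed Vmax/Km sub-pathways (1-OH, 4-OH for the
# CYPs), plus a single adjusting compartment (SAC).
#
# molecular_weight is needed only to convert liver concentration to uM for
# the Michaelis-Menten term; 325.8 g/mol is the compound's standard value
# (config default, overridable).
name: midazolam
dose_mg: 5.0
sac_enabled: true
clearance_mode: michaelis_menten
molecular_weight: 325.8
parameters:
  - {name: fa,            family: weibull,   p1: 8.86,  p2: 0.94,    lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: ka,            family: lognormal, p1: 1.05,  p2: 0.09,    lower: 1.0e-6, upper: 10.0,  unit: "1/h"}
  - {name: Fg,            family: normal,    p1: 0.47,  p2: 0.01,    lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: BP,            family: normal,    p1: 0.64,  p2: 1.05e-3, lower: 0.55,   upper: 100.0, unit: ""}
  - {name: fu,            family: lognormal, p1: -3.46, p2: 1.0e-3,  lower: 1.0e-6, upper: 1.0,   unit: ""}
  - {name: Kp_liver,      family: lognormal, p1: -0.21, p2: 9.6e-3,  lower: 1.0e-6, upper: 10.0,  unit: ""}
  - {name: A_CYP3A4,      family: lognormal, p1: 15.84, p2: 0.26,    lower: 1.0e+6,  upper: 1.0e+8, unit: "pmol P450"}
  - {name: A_CYP3A5,      family: lognormal, p1: 15.72, p2: 0.18,    lower: 1.0e+6,  upper: 1.0e+8, unit: "pmol P450"}
  - {name: A_UGT1A4,      family: lognormal, p1: 14.92, p2: 0.18,    lower: 1.0e+5,  upper: 1.0e+8, unit: "pmol UGT"}
  - {name: Q_HA,          family: lognormal, p1: 3.05,  p2: 1.44e-2, lower: 1.0e-6, upper: 50.0,  unit: "L/h"}
  - {name: Q_PV,          family: lognormal, p1: 4.19,  p2: 1.05e-2, lower: 1.0e-6, upper: 150.0, unit: "L/h"}
  - {name: BW,            family: lognormal, p1: 4.30,  p2: 3.8e-2,  lower: 30.0,   upper: 200.0, unit: "kg"}
  - {name: V_pv,          family: normal,    p1: 0.008, p2: 6.4e-7,  lower: 1.0e-6, upper: 0.15,  unit: "L"}
  - {name: V_liver,       family: lognormal, p1: 0.39,  p2: 2.97e-2, lower: 0.1,    upper: 5.0,   unit: "L"}
  - {name: V_ss,          family: normal,    p1: 0.91,  p2: 4.09e-2, lower: 1.0e-6, upper: 5.0,   unit: "L/kg"}
  - {name: CL_R,          family: normal,    p1: 0.085, p2: 4.6e-3,  lower: 1.0e-6, upper: 5.0,   unit: "L/h"}
  # fixed Michaelis-Menten constants and SAC parameters
  - {name: Vm_CYP3A4_1OH, family: fixed, value: 5.23,  lower: 0.0, upper: 1.0e+6, unit: "pmol/min/pmol"}
  - {name: Vm_CYP3A5_1OH, family: fixed, value: 19.7,  lower: 0.0, upper: 1.0e+6, unit: "pmol/min/pmol"}
  - {name: Vm_CYP3A4_4OH, family: fixed, value: 5.2,   lower: 0.0, upper: 1.0e+6, unit: "pmol/min/pmol"}
  - {name: Vm_CYP3A5_4OH, family: fixed, value: 4.03,  lower: 0.0, upper: 1.0e+6, unit: "pmol/min/pmol"}
  - {name: Vm_UGT1A4,     family: fixed, value: 445.0, lower: 0.0, upper: 1.0e+6, unit: "pmol/min/mg protein"}
  - {name: Km_CYP3A4_1OH, family: fixed, value: 2.16,  lower: 0.0, upper: 1.0e+6, unit: "uM"}
  - {name: Km_CYP3A5_1OH, family: fixed, value: 4.16,  lower: 0.0, upper: 1.0e+6, unit: "uM"}
  - {name: Km_CYP3A4_4OH, family: fixed, value: 31.8,  lower: 0.0, upper: 1.0e+6, unit: "uM"}
  - {name: Km_CYP3A5_4OH, family: fixed, value: 34.8,  lower: 0.0, upper: 1.0e+6, unit: "uM"}
  - {name: Km_UGT1A4,     family: fixed, value: 40.3,  lower: 0.0, upper: 1.0e+6, unit: "uM"}
  - {name: K_in,          family: fixed, value: 0.2,   lower: 0.0, upper: 1.0e+3, unit: "1/h"}
  - {name: K_out,         family: fixed, value: 0.25,  lower: 0.0, upper: 1.0e+3, unit: "1/h"}
  - {name: V_sac,         family: fixed, value: 0.23,  lower: 0.0, upper: 1.0e+3, unit: "L/kg"}
pathways:
  - enzyme: CYP3A4
    abundance_param: A_CYP3A4
    subpathways:
      - {label: 1-OH, vmax_param: Vm_CYP3A4_1OH, km_param: Km_CYP3A4_1OH}
      - {label: 4-OH, vmax_param: Vm_CYP3A4_4OH, km_param: Km_CYP3A4_4OH}
  - enzyme: CYP3A5
    abundance_param: A_CYP3A5
    subpathways:
      - {label: 1-OH, vmax_param: Vm_CYP3A5_1OH, km_param: Km_CYP3A5_1OH}
      - {label: 4-OH, vmax_param: Vm_CYP3A5_4OH, km_param: Km_CYP3A5_4OH}
  - enzyme: UGT1A4
    abundance_param: A_UGT1A4
    subpathways:
      - {label: N-glucuronidation, vmax_param: Vm_UGT1A4, km_param: Km_UGT1A4}
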