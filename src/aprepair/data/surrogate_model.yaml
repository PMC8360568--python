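# Surrogate ventricular AP/Ca2+ parameter set (synthetic).
#
# This is NOT a published cell model: it is a compact Hodgkin-Huxley-style
# parameterisation constructed for this package so that the full pipeline
# (density/flux current split, N588K I_Kr gain of function, drug factors,
# biomarker cost, dose optimisation) can run end to end.  It reproduces the
# qualitative ventricular phenotype -- a ~300 ms adult AP, a Ca2+ transient
# of a few hundred nM, SQT1 shortening of the APD with a depressed Ca2+
# transient -- but no quantitative published values.  Any parameter set
# following this schema can be dropped in via build_model().
#
# Units: mV, ms, A/F, uM.  rho is the dimensionless channel-density scaling
# per cell type; g0 is the per-channel conductance at rho = 1.
schema: 1
name: surrogate-ventricular-v1

reversal:
  E_Na: 65.0
  E_K: -88.0
  E_Ca: 62.0
  E_f: -22.0
  E_b: -30.0

initial_state:
  v: -85.0
  cai: 0.1

calcium:
  ca_rest: 0.1        # uM, diastolic target of the uptake term
  tau_decay: 300.0    # ms, lumped SERCA/NCX removal time constant
  release_gain: 0.003 # uM/ms per open-channel conductance unit; lumps trigger influx + SR release

k1_rectification:   # instantaneous open fraction of I_K1
  v_half: -65.0
  slope: 10.0

currents:
  I_Na:  {g0: 11.0,  rho: {adult-human: 1.0, rabbit: 1.0,  hiPSC-CM: 0.45}}
  I_NaL: {g0: 0.002, rho: {adult-human: 1.0, rabbit: 0.8,  hiPSC-CM: 1.0}}
  I_CaL: {g0: 0.027, rho: {adult-human: 1.0, rabbit: 1.1,  hiPSC-CM: 0.9}}
  I_Kr:  {g0: 0.03,  rho: {adult-human: 1.0, rabbit: 1.3,  hiPSC-CM: 0.75}}
  I_Ks:  {g0: 0.04, rho: {adult-human: 1.0, rabbit: 0.6,  hiPSC-CM: 0.5}}
  I_K1:  {g0: 0.45,  rho: {adult-human: 1.0, rabbit: 1.1,  hiPSC-CM: 0.45}}
  I_f:   {g0: 0.006, rho: {adult-human: 1.0, rabbit: 0.8,  hiPSC-CM: 4.0}}
  I_b:   {g0: 0.008, rho: {adult-human: 1.0, rabbit: 1.0,  hiPSC-CM: 1.0}}

gates:
  # fast Na activation
  m:   {v_half: -40.0, slope: 5.5,  tau_base: 0.03, tau_amp: 0.25, tau_vc: -45.0, tau_sigma: 20.0}
  # fast Na inactivation
  h:   {v_half: -71.0, slope: -5.5, tau_base: 0.35, tau_amp: 25.0, tau_vc: -65.0, tau_sigma: 15.0}
  # L-type Ca activation
  d:   {v_half: -11.0, slope: 6.5,  tau_base: 0.7,  tau_amp: 1.6,  tau_vc: -15.0, tau_sigma: 15.0}
  # L-type Ca inactivation (small non-inactivating floor sustains the plateau)
  f:   {v_half: -28.0, slope: -5.5, floor: 0.02, tau_base: 150.0, tau_amp: 0.0, tau_vc: 0.0, tau_sigma: 1.0}
  # I_Kr activation (deactivation is slow; inactivation is instantaneous, see kernel)
  xr1: {v_half: -21.0, slope: 7.0,  tau_base: 150.0, tau_amp: 300.0, tau_vc: -25.0, tau_sigma: 40.0}
  # I_Ks activation
  xs:  {v_half: -2.0,  slope: 12.0, tau_base: 300.0, tau_amp: 500.0, tau_vc: 0.0, tau_sigma: 60.0}
  # funny-current activation (opens on hyperpolarisation)
  y:   {v_half: -87.0, slope: -9.0, tau_base: 700.0, tau_amp: 800.0, tau_vc: -90.0, tau_sigma: 30.0}
  # late Na activation (effectively non-inactivating)
  mL:  {v_half: -42.0, slope: 5.0,  tau_base: 10.0, tau_amp: 0.0, tau_vc: 0.0, tau_sigma: 1.0}
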