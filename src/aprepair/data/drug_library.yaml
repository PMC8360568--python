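# Default drug library: literature dose-response parameters (EC50 in uM,
# Hill coefficient, maximum relative effect E) per ion current.
#
# The I_Kr entries describe the drug acting on the SQT1 (hERG N588K) mutant
# channel; I_CaL, I_Na, I_NaL and I_f entries describe wild-type currents.
# A missing drug/current cell means "no characterised effect" and yields a
# scale factor of 1.  E = -1 is a full block at saturating dose; E > 0 is
# an agonist (current opener).
schema: 1
concentration_unit: uM
drugs:
  quinidine:
    I_Kr: {ec50_uM: 8.14, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_CaL: {ec50_uM: 153.0, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_Na: {ec50_uM: 77.7, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
  ivabradine:
    I_Kr: {ec50_uM: 12.6, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_Na: {ec50_uM: 86.3, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_f: {ec50_uM: 42.0, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
  ajmaline:
    I_Kr: {ec50_uM: 69.5, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_CaL: {ec50_uM: 46.6, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_Na: {ec50_uM: 435.0, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
  mexiletine:
    I_Kr: {ec50_uM: 281.0, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_CaL: {ec50_uM: 963.0, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
    I_Na: {ec50_uM: 201.0, hill: 1.0, emax: -1.0, source: "SQT1 hiPSC-CM AP inversion"}
  BAY K 8644:
    I_CaL: {ec50_uM: 0.05, hill: 1.7, emax: 1.8, source: "L-type Ca agonist literature estimate"}
  veratridine:
    I_NaL: {ec50_uM: 0.426, hill: 2.0, emax: 1.8, source: "late-Na agonist literature estimate"}
  disopyramide:
    I_Kr: {ec50_uM: 15.77, hill: 0.6, emax: -1.0, source: "N588K voltage-clamp dose-response fit"}
    I_CaL: {ec50_uM: 1036.7, hill: 1.0, emax: -0.779, source: "patch-clamp drug screen"}
    I_Na: {ec50_uM: 168.4, hill: 1.09, emax: -0.311, source: "patch-clamp drug screen"}
  propafenone:
    I_Kr: {ec50_uM: 0.95, hill: 0.7, emax: -1.0, source: "N588K voltage-clamp dose-response fit"}
    I_CaL: {ec50_uM: 1.55, hill: 0.9, emax: -1.0, source: "patch-clamp drug screen"}
    I_Na: {ec50_uM: 3.886, hill: 0.9, emax: -1.0, source: "patch-clamp drug screen"}
    I_NaL: {ec50_uM: 4.036, hill: 0.9, emax: -1.0, source: "patch-clamp drug screen"}
  amiodarone:
    I_Kr: {ec50_uM: 0.318, hill: 0.5, emax: -1.0, source: "N588K voltage-clamp dose-response fit"}
    I_CaL: {ec50_uM: 1.28, hill: 0.6, emax: -1.0, source: "patch-clamp drug screen"}
    I_Na: {ec50_uM: 4.58, hill: 0.7, emax: -1.0, source: "patch-clamp drug screen"}
    I_NaL: {ec50_uM: 9.42, hill: 0.4, emax: -1.0, source: "patch-clamp drug screen"}
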