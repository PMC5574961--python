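# Packaged photophysical / binding parameter sets for intercalating dyes.
#
# Units: k_on per-uM per-s, k_off per-s, brightness a.u. per uM,
# quench_conc uM (half-quench extracellular concentration; .inf disables
# self-quenching). Brightness values are arbitrary-unit per-uM emission
# coefficients; only their ratio (the binding enhancement) is meaningful.
sytox_green:
  k_on: 4.2e-4
  k_off: 0.0
  brightness_free: 1.0
  brightness_bound: 1000.0
  quench_conc: 8.0
propidium_iodide:
  k_on: 1.0e-4
  k_off: 0.0
  brightness_free: 1.0
  brightness_bound: 30.0
  quench_conc: .inf
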