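# Layered cortical microcircuit (V1-like, 8 populations), full scale.
# Base parameter set of the companion spiking model; indegrees are the
# expected per-neuron connection counts derived from the published pairwise
# connection probabilities and population sizes.  All values unmodified --
# the stabilising modifications are applied by the loader.
name: microcircuit
labels: [2/3E, 2/3I, 4E, 4I, 5E, 5I, 6E, 6I]
sizes: [20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948]
neuron:
  tau_m_ms: 10.0      # membrane time constant
  tau_s_ms: 0.5       # synaptic (PSC decay) time constant
  tau_ref_ms: 2.0     # absolute refractory period
  V_th_mV: 15.0       # spike threshold relative to resting potential
  V_reset_mV: 0.0     # reset potential relative to resting potential
  C_m_pF: 250.0       # membrane capacitance
synapse:
  psc_amp_pA: 87.8    # excitatory PSC amplitude at the synapse
  g: 4.0              # inhibition/excitation weight ratio
  # PSC amplitude of the 4E -> 2/3E projection is doubled
  weight_factors:
    - {target: 2/3E, source: 4E, factor: 2.0}
delays:
  mean_exc_ms: 1.5
  mean_inh_ms: 0.75
  std_rel: 0.5        # std as fraction of the mean (base model)
external:
  indegrees: [1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100]
  rate_per_s: 8.0
# indegrees[target][source], populations ordered as in `labels`
indegrees:
  - [2199.864859, 1079.320060, 979.241268, 467.578115, 159.240811, 0.000000, 109.819845, 0.000000]
  - [2990.005831, 860.261030, 703.691825, 289.693845, 380.735800, 0.000000, 60.586320, 0.000000]
  - [159.875414, 34.522542, 1117.173137, 794.596199, 32.604347, 0.319548, 667.325193, 0.000000]
  - [1480.973501, 16.943179, 1813.020213, 953.325755, 16.031466, 0.000000, 1608.122867, 0.000000]
  - [2188.366015, 374.651145, 1135.629790, 31.319645, 420.770781, 496.472049, 296.694679, 0.000000]
  - [1165.667663, 159.083991, 570.579247, 12.067078, 300.095679, 404.172654, 124.332395, 0.000000]
  - [325.197989, 38.632026, 467.354615, 91.714755, 285.670371, 21.189912, 581.635943, 752.183217]
  - [766.905120, 5.836919, 74.637956, 2.740185, 136.240764, 8.554261, 979.791792, 459.402826]
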