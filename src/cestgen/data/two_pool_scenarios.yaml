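# Two-pool (water + one solute / semisolid) imaging scenarios used for
# dynamic signal generation and MRF dictionary studies.
#
# All free ranges must lie inside `training_ranges` (the dynamic-network
# training range); the loader enforces this.  Canonical parameter-table
# columns use the generic pool name "solute" so that one dynamic network can
# be trained across scenarios with a shared feature list.
#
# The per-element pseudo-random B1 (and, for semisolid-mt, offset) series of
# the original acquisition protocols are not published; each scenario ships a
# surrogate series drawn uniformly from the training range with the seed
# recorded here, so schedules are reproducible.
schema: cestgen-two-pool-1

training_ranges:
  water.t1_s: [1.3, 3.4]
  water.t2_s: [0.04, 1.2]
  solute.t1_s: [1.3, 3.4]
  solute.t2_s: [4.0e-5, 0.04]
  solute.f: [1.8182e-4, 0.272727]          # 20/110000 .. 30000/110000
  solute.k_sw: [5.0, 1500.0]
  solute.delta_ppm: [-3.5, 4.3]
  tp_s: [1.0, 10.0]
  trec_s: [1.0, 10.0]
  fa_deg: [60.0, 90.0]
  b1_ut: [0.25, 6.0]
  offset_ppm: [-3.5, 20.0]

scenarios:
  l-arginine:
    n_elements: 30
    pulse_shape: continuous-wave
    compound: L-arginine (amine protons)
    lineshape: full-3-component
    delta_ppm: 3.0
    offset_policy: fixed          # saturation always at the solute shift
    b1_series_seed: 93236
    template:
      water.t1_s: 2.5
      water.t2_s: 0.8
      solute.t1_s: 2.5
      solute.t2_s: 0.01
      solute.f: 1.3636e-3         # 50 mM x 3 protons / 110000
      solute.k_sw: 400.0
    free: [water.t1_s, water.t2_s, solute.t1_s, solute.t2_s, solute.f, solute.k_sw]
    scan_defaults: {tp_s: 3.0, trec_s: 3.0, fa_deg: 90.0, n_p: 1, gap_s: 0.0}
    scan_free: [tp_s, trec_s, fa_deg]

  amide:
    n_elements: 10
    pulse_shape: continuous-wave
    compound: amide protons (proteins/peptides)
    lineshape: full-3-component
    delta_ppm: 3.5
    offset_policy: fixed
    b1_series_seed: 41901
    template:
      water.t1_s: 1.8
      water.t2_s: 0.06
      solute.t1_s: 1.8
      solute.t2_s: 0.01
      solute.f: 2.0e-3
      solute.k_sw: 50.0
    free: [water.t1_s, water.t2_s, solute.t1_s, solute.t2_s, solute.f, solute.k_sw]
    scan_defaults: {tp_s: 3.0, trec_s: 3.0, fa_deg: 90.0, n_p: 1, gap_s: 0.0}
    scan_free: [tp_s, trec_s, fa_deg]

  amine:
    n_elements: 10
    pulse_shape: continuous-wave
    compound: amine protons (e.g. glutamate)
    lineshape: full-3-component
    delta_ppm: 3.0
    offset_policy: fixed
    b1_series_seed: 58144
    template:
      water.t1_s: 1.8
      water.t2_s: 0.06
      solute.t1_s: 1.8
      solute.t2_s: 0.005
      solute.f: 2.0e-3
      solute.k_sw: 1000.0
    free: [water.t1_s, water.t2_s, solute.t1_s, solute.t2_s, solute.f, solute.k_sw]
    scan_defaults: {tp_s: 3.0, trec_s: 3.0, fa_deg: 90.0, n_p: 1, gap_s: 0.0}
    scan_free: [tp_s, trec_s, fa_deg]

  rnoe:
    n_elements: 10
    pulse_shape: continuous-wave
    compound: aliphatic relayed-NOE protons
    lineshape: full-3-component
    delta_ppm: -3.5
    offset_policy: fixed
    b1_series_seed: 76410
    template:
      water.t1_s: 1.8
      water.t2_s: 0.06
      solute.t1_s: 1.8
      solute.t2_s: 0.001
      solute.f: 4.0e-3
      solute.k_sw: 20.0
    free: [water.t1_s, water.t2_s, solute.t1_s, solute.t2_s, solute.f, solute.k_sw]
    scan_defaults: {tp_s: 3.0, trec_s: 3.0, fa_deg: 90.0, n_p: 1, gap_s: 0.0}
    scan_free: [tp_s, trec_s, fa_deg]

  iohexol:
    n_elements: 10
    pulse_shape: continuous-wave
    compound: iohexol amide protons
    lineshape: full-3-component
    delta_ppm: 4.3
    offset_policy: fixed
    b1_series_seed: 30517
    template:
      water.t1_s: 2.5
      water.t2_s: 0.5
      solute.t1_s: 2.5
      solute.t2_s: 0.01
      solute.f: 1.0e-3
      solute.k_sw: 800.0
    free: [water.t1_s, water.t2_s, solute.t1_s, solute.t2_s, solute.f, solute.k_sw]
    scan_defaults: {tp_s: 3.0, trec_s: 3.0, fa_deg: 90.0, n_p: 1, gap_s: 0.0}
    scan_free: [tp_s, trec_s, fa_deg]

  semisolid-mt:
    n_elements: 30
    pulse_shape: continuous-wave
    compound: semisolid macromolecular protons
    lineshape: super-lorentzian
    delta_ppm: -2.4
    offset_policy: series         # both B1 and offset vary per element
    offset_series_ppm: [6.0, 14.0]
    b1_series_seed: 67214
    template:
      water.t1_s: 1.8
      water.t2_s: 0.04
      solute.t1_s: 1.4
      solute.t2_s: 4.0e-5
      solute.f: 0.1
      solute.k_sw: 30.0
    free: [water.t1_s, water.t2_s, solute.f, solute.k_sw]
    scan_defaults: {tp_s: 2.5, trec_s: 3.0, fa_deg: 90.0, n_p: 1, gap_s: 0.0}
    scan_free: [tp_s, trec_s, fa_deg]
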