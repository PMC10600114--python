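# Seven-pool human-brain CEST scenario: water, five CEST/NOE solute pools and
# a Lorentzian semisolid-MT pool, acquired with a sinc-Gaussian saturation
# pulse train and a fixed 34-element offset schedule.
#
# The fixed tissue values below (chemical shifts, solute relaxation times and
# the exchange rates of the non-amide pools) are ASSUMED literature-typical
# brain values; edit this file to match a specific reference parameter set.
# The free ranges are the application-optimized training ranges and are the
# authoritative bounds the loader validates against.
schema: cestgen-seven-pool-1

n_elements: 34
pulse:
  shape: sinc-gaussian
  n_segments: 64
  b1_ut: 2.0           # fixed saturation amplitude for this scenario
  gap_s: 0.01          # inter-pulse delay; duty cycle 83-91% for tp 0.05-0.1 s
  fa_deg: 90.0
# Z-spectrum saturation offsets, ppm (34 values, -6 .. 6)
offsets_ppm: [-6.0, -5.636, -5.273, -4.909, -4.545, -4.182, -3.818, -3.455,
              -3.091, -2.727, -2.364, -2.0, -1.636, -1.273, -0.909, -0.545,
              -0.182, 0.182, 0.545, 0.909, 1.273, 1.636, 2.0, 2.364,
              2.727, 3.091, 3.455, 3.818, 4.182, 4.545, 4.909, 5.273,
              5.636, 6.0]

pools:
  water:     {t1_s: 1.2, t2_s: 0.08}
  amide:     {delta_ppm: 3.5,  t1_s: 1.0, t2_s: 1.0e-2, f: 2.0e-3, k_sw: 50.0}
  guanidine: {delta_ppm: 2.0,  t1_s: 1.0, t2_s: 1.0e-2, f: 1.0e-3, k_sw: 1100.0}
  amine:     {delta_ppm: 3.0,  t1_s: 1.0, t2_s: 5.0e-3, f: 2.0e-3, k_sw: 5500.0}
  oh:        {delta_ppm: 1.3,  t1_s: 1.0, t2_s: 5.0e-3, f: 2.0e-3, k_sw: 2000.0}
  noe:       {delta_ppm: -3.5, t1_s: 1.0, t2_s: 5.0e-4, f: 4.0e-3, k_sw: 20.0}
  mt:        {delta_ppm: -2.4, t1_s: 1.0, t2_s: 4.0e-5, f: 0.1,   k_sw: 30.0,
              lineshape: lorentzian}

training_ranges:
  water.t1_s: [0.8, 1.6]
  water.t2_s: [0.04, 0.12]
  amide.f: [5.0e-4, 4.5e-3]
  amide.k_sw: [30.0, 90.0]
  guanidine.f: [5.0e-4, 1.4e-3]
  amine.f: [5.0e-4, 4.5e-3]
  oh.f: [5.0e-4, 4.5e-3]
  noe.f: [2.2e-3, 6.7e-3]
  mt.f: [0.018, 0.216]
  tp_s: [0.05, 0.1]
  trec_s: [2.5, 4.0]
  n_p: [10, 30]

free: [water.t1_s, water.t2_s, amide.f, amide.k_sw, guanidine.f, amine.f,
       oh.f, noe.f, mt.f]
scan_free: [tp_s, trec_s, n_p]
scan_defaults: {tp_s: 0.075, trec_s: 3.0, n_p: 20}
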