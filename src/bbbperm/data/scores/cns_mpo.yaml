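# CNS MPO desirability score (Wager et al.): six equally weighted
# piecewise-linear desirability functions, range 0-6, CNS-positivity
# cutoff 4. Knot tables are editable; the package fixes the machinery
# (interpolation, clamping, weighting, threshold), not these constants.
name: cns_mpo
threshold: 4
components:
  - descriptor: clogp
    weight: 1.0
    knots: [3.0, 5.0]
    values: [1.0, 0.0]
  - descriptor: clogd_74
    weight: 1.0
    knots: [2.0, 4.0]
    values: [1.0, 0.0]
  - descriptor: mw
    weight: 1.0
    knots: [360.0, 500.0]
    values: [1.0, 0.0]
  - descriptor: tpsa
    weight: 1.0
    knots: [20.0, 40.0, 90.0, 120.0]
    values: [0.0, 1.0, 1.0, 0.0]
  - descriptor: hbd
    weight: 1.0
    knots: [0.5, 3.5]
    values: [1.0, 0.0]
  - descriptor: pka_basic
    weight: 1.0
    knots: [8.0, 10.0]
    values: [1.0, 0.0]
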