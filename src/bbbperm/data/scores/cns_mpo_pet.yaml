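# CNS MPO variant tuned for PET radiotracer design (Zhang et al.):
# narrower optimum windows for lipophilicity and polarity, range 0-6,
# CNS-positivity cutoff 3. Piecewise-linear transcription of the
# published desirability curves; knots are editable config, the package
# validates only the scoring machinery.
name: cns_mpo_pet
threshold: 3
components:
  - descriptor: clogp
    weight: 1.0
    knots: [1.0, 2.0, 3.0, 5.0]
    values: [0.0, 1.0, 1.0, 0.0]
  - descriptor: clogd_74
    weight: 1.0
    knots: [0.5, 1.5, 2.5, 4.0]
    values: [0.0, 1.0, 1.0, 0.0]
  - descriptor: mw
    weight: 1.0
    knots: [305.0, 360.0, 500.0]
    values: [1.0, 0.5, 0.0]
  - descriptor: tpsa
    weight: 1.0
    knots: [32.0, 62.0, 92.0, 120.0]
    values: [0.0, 1.0, 1.0, 0.0]
  - descriptor: hbd
    weight: 1.0
    knots: [0.5, 2.5]
    values: [1.0, 0.0]
  - descriptor: pka_basic
    weight: 1.0
    knots: [7.2, 9.5]
    values: [1.0, 0.0]
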