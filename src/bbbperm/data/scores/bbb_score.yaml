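# BBB score (Gupta et al.): weighted sum over aromatic rings, heavy
# atoms, MWHBN = (HBD+HBA)/sqrt(MW), tPSA and basic pKa; range 0-6,
# CNS-positivity cutoff 4. The published stepwise/polynomial component
# functions are transcribed here as piecewise-linear knot tables
# (exact at integer ring counts, polynomials sampled at the knots);
# edit freely - the package fixes only the scoring machinery.
name: bbb_score
threshold: 4
components:
  - descriptor: aromatic_rings
    weight: 1.0
    knots: [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
    values: [0.336, 0.816, 1.0, 0.691, 0.199, 0.0]
  - descriptor: heavy_atoms
    weight: 1.0
    knots: [5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0]
    values: [0.108, 0.646, 0.925, 1.0, 0.923, 0.745, 0.520, 0.308, 0.156]
  - descriptor: mwhbn
    weight: 1.5
    knots: [0.05, 0.2, 0.3, 0.45]
    values: [0.3, 1.0, 1.0, 0.0]
  - descriptor: tpsa
    weight: 2.0
    knots: [0.0, 20.0, 40.0, 90.0, 120.0]
    values: [0.2, 1.0, 1.0, 0.5, 0.0]
  - descriptor: pka_basic
    weight: 0.5
    knots: [0.0, 6.0, 8.0, 10.0, 12.0]
    values: [0.2, 0.8, 1.0, 0.6, 0.0]
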