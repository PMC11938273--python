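# Methods

This note documents the models and procedures implemented in `bbbperm`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot establish.

## Geometry pipeline

Molecules enter as SMILES (no coordinates), SDF/MOL V2000, or XYZ.
SMILES structures receive explicit hydrogens immediately; all surface
operations reject implicit-hydrogen input. Coordinates are generated by
ETKDG distance geometry (seeded, bitwise reproducible) and minimized with
the Merck molecular force field (MMFF94): up to 9999 iterations, energy
tolerance 1e-7 kcal/mol, and the whole minimization repeated three times
on the running geometry. The minimizer is RDKit's BFGS-type
implementation; because a re-minimization from a converged point can
wiggle upward by numerical noise, each repeat keeps the better of the old
and new geometry, so the energy trajectory is non-increasing by
construction. Externally optimized structures (e.g. from quantum-chemical
refinement, which this package does not perform) can be injected via the
SDF/XYZ path and used directly.

Partial charges default to Gasteiger–Marsili (`model="gasteiger"`), with
MMFF94 bond-charge-increment charges (`"mmff94"`) and pass-through input
charges (`"input"`) as alternatives. Gasteiger was chosen as the default
because it is fast, dependency-light and fully reproducible; note that
Gasteiger magnitudes rarely exceed ±0.6 e on neutral N/O, so the optional
±0.6 charge filter (below) is conservative under this default and mainly
useful with charge schemes of larger magnitude supplied via `"input"`.
Van der Waals radii come from the packaged Bondi (1964) table
(`data/bondi_radii.tsv`, element⟨TAB⟩Å, editable and overridable).

## Dot-surface SASA and the 3D PSA

The solvent-accessible surface area uses the Shrake–Rupley dot
construction. Test points come from recursive icosahedron subdivision:
level *L* gives 10·4^L + 2 quasi-uniform unit vectors (level 4 → 2562
dots per atom, the default "dot density 4"). For atom *i* with vdW radius
r_i and probe radius 1.4 Å (water), dots are placed on the accessible
sphere of radius r_i + probe; a dot survives unless it falls strictly
inside another atom's accessible sphere (a dot exactly on a neighbor's
sphere counts as exposed, consistent with each sphere owning its own
surface). The atom's area is the surviving fraction of 4π(r_i+probe)².
Neighbor tests are restricted to atoms whose accessible spheres can
intersect; molecules in this domain are small (< 200 atoms) so no further
spatial indexing is used.

Numerical properties established by the test suite: agreement with the
closed-form sphere and two-sphere spherical-cap areas within 0.5%/1%;
relative change below 1% when refining from level 4 to level 5; rotation
and translation invariance within 0.5%.

The 3D PSA is the summed exposed area of polar atoms. The default polar
rule is element-based — nitrogen and oxygen plus hydrogens bonded to them.
An optional charge filter additionally requires |partial charge| ≥ 0.6 e
(attached hydrogens inherited). The two criteria are combined by
intersection when the filter is enabled; element-only is the default
because the interplay of the two published criteria is ambiguous, and the
flag makes either reading available. Sulfur and phosphorus are excluded
from the default rule (unlike the fragment-based tPSA convention) but the
element set is configurable, and polar area is monotone non-decreasing in
that set.

## Descriptors and multiparameter scores

tPSA is the Ertl fragment-contribution sum (RDKit implementation and
fragment table; optional S/P inclusion). Hydrogen-bond donors are N/O
atoms carrying at least one hydrogen; acceptors follow the Lipinski N+O
count; rotatable bonds are non-ring single bonds between non-terminal
heavy atoms with amide C–N excluded (counted on the hydrogen-suppressed
graph). MWHBN = (HBD+HBA)/√MW. Derived combinations (HBA+HBD, logP−HBA,
logD(7.4)−HBA, HPLC logP(7.4)−HBA) propagate missingness. Predicted pKa,
ClogP/ClogD and the chromatographic measurements (HPLC logP, K_IAM, P_m,
%HSA, logK) are consumed as input columns, never computed.

Multiparameter scores are weighted sums of piecewise-linear desirability
functions (knots strictly increasing, values in [0,1], clamped outside
the knot range), classified CNS-positive at or above a cutoff — 4 for the
BBB score, 4 for CNS MPO, 3 for CNS MPO PET. A score exactly at the
cutoff classifies positive; the boundary rule is configurable via the
threshold itself. The knot tables ship as editable YAML
(`data/scores/*.yaml`): CNS MPO is the exact published piecewise-linear
form; the BBB-score components, published as step functions and
polynomials, are transcribed piecewise-linearly (exact at integer ring
counts, polynomials sampled at the knots). The package's tests pin the
scoring machinery, not these transcribed constants.

## Group comparisons

Feature distributions between two classes are compared with a
Shapiro–Wilk gate at α = 0.05 on each group: both normal → two-sided
two-sample t-test, otherwise two-sided Mann–Whitney U (exact null
distribution for small tie-free samples, normal approximation with tie
correction otherwise — SciPy's `method="auto"`). Both groups must have at
least 3 non-missing values.

## Monte Carlo cross-validation

The pipeline draws independent unstratified random splits with
round(0.2·n) test rows (31 of 154), 100 folds by default. Within each
fold, fitted state derives from training rows only:

1. **Standardization** — train-column z-scores; zero-variance columns are
   centered, not divided (warning).
2. **kNN imputation** (k = 5) — missing cells replaced by the feature
   mean over the k nearest rows under nan-aware Euclidean distance; test
   rows are imputed against the training pool so no test statistic enters
   fitted state.
3. **mRMR** — greedy forward selection; relevance = one-way ANOVA F of
   feature vs class, redundancy = mean |Pearson r| with the already
   selected set, ranked by the quotient. First pick is the most relevant
   feature; ties break toward lower column index, so constant features
   (relevance 0) sink. Default 10 features kept.
4. **SMOTE** (k = 5, training rows only) — every minority class upsampled
   to the majority count by x + λ(x′−x), λ~U(0,1), x′ among the k nearest
   same-class rows.
5. **Random-search HPO** — 25 seeded draws per family, scored by macro
   AUC on an inner 80/20 split of the (balanced) training data.

Six classifier families are trained per fold: SVM (RBF/linear),
logistic regression, k-nearest neighbors, random forest, extreme gradient
boosting, and an explainable boosting machine implemented in-package as a
cyclic gradient-boosted additive model (per-feature shape functions grown
by round-robin boosting of ≤4-leaf single-feature trees under logistic
loss; multiclass one-vs-rest). Search spaces ship in
`bbbperm/mlcv/models.py`.

Two targets: `two_class` (CNS+ vs CNS−; efflux rows dropped by default or
merged into CNS+ via `efflux_policy="merge"`, since efflux substrates are
passively permeable) and `multiclass` (all three labels). Metrics: ACC,
SNS, SPC, PPV, NPV at the 0.5 probability cutoff (argmax label for
multiclass, one-vs-rest macro-averaged) and ROC AUC (macro mean of
one-vs-rest AUCs for multiclass; undefined ratios of an empty denominator
report 0). Fold metrics aggregate as the mean with percentile
(2.5/97.5) 95% confidence intervals. Every stochastic stage receives a
seed derived as base_seed + fold_index.

## Interpretation

Shapley attributions use a single-reference baseline (training-set
feature means). Exact mode enumerates all 2^p coalitions (capped at
p = 10), so efficiency, symmetry and the null-player axiom hold to
numerical precision; sampled mode uses seeded permutation sampling
(default 2048 permutations). Attributions target one probability output;
multiclass models are explained per class. The intended workflow computes
attributions on a final model refit on the full table after CV
performance estimation.

Surrogate distillation trains a depth-limited CART tree on the opaque
model's predicted labels and reports fidelity (the full metric set of
tree vs opaque predictions). Fidelity accuracy is non-decreasing in depth
on a fixed dataset. The text export prints split features, thresholds in
standardized units at 2 decimals, and per-node class distributions, and
round-trips through `parse_tree_text`.

## Synthetic data

`synthdata.generate_feature_table` emulates the study table: 154 rows
(68 CNS-positive / 42 CNS-negative / 44 efflux), 24 features, optional
equicorrelation and uniform missingness. The 3D PSA column uses the
reported per-class parameters — N(62.9, 34.7²), N(146.2, 94.4²),
N(149.6, 68.6²) Å², truncated at 0 by rejection sampling since those
normal tails cross zero. Truncation shifts the CNS-positive mean up by
≈2.8 Å² (< 0.7 standard errors at n = 68); the parameter-recovery test
allows for this. The remaining 23 features have no published group
statistics; they default to unit-variance normals whose class means
follow rotating offset patterns at effect size 1 SD — a plainly learnable
multivariate signal in which, as in the real data, CNS-negative and
efflux overlap completely on 3D PSA and are separated only by other
features. What the defaults do **not** model: the real covariance between
descriptors (MW, tPSA, scores are strongly dependent in practice),
non-normal marginals of counts, and any structure–feature consistency;
passing pipeline tests therefore demonstrate algorithmic correctness and
sensible behavior under the study's class geometry, not real-data
performance levels.

Fixture molecules (methane, water, ethanol, benzene, glycine) carry
frozen MMFF94-minimized coordinates so geometric tests are exact and
download-free.

## Problem sizes in the test-suite and acceptance script

The suite runs the pipeline at 20 folds (signal and label-permuted null)
with reduced HPO budgets (10 and 5 draws), a scale at which the
separability (macro AUC > 0.9) and null (AUC ≈ 0.5) conclusions are
already stable; `scripts/acceptance.py` draws 100 generator seeds and
reports the median Mann–Whitney p-value for the simulated CNS+ vs CNS−
3D PSA comparison. Full-scale runs (100 folds, 25 draws) use the same
code paths via `CVConfig`.

## Known limitations

* No conformer ensembles or Boltzmann weighting: one optimized conformer
  per molecule.
* No tautomer/protonation enumeration; formal charges are taken as drawn.
* The analytic (non-dot) SASA and solvent-excluded surfaces are out of
  scope.
* Gasteiger charges make the ±0.6 filter nearly empty on neutral
  molecules; supply external charges if the charge-based polar rule is
  the object of study.
* The EBM is a faithful but minimal additive-boosting implementation; it
  omits pairwise interaction terms and per-feature binning optimizations
  of larger EBM frameworks.
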