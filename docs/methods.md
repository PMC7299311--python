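# Methods

## Model and assumptions

Trajectory Profile Clustering treats a longitudinal cohort as a stack of
patient–variable bipartite graphs, one per visit, flattened into a single
binary trajectory profile per patient.  The central modeling assumptions
are:

- **Relative, not absolute, severity.**  Every continuous variable is
  reduced to "above / not above the training-population baseline median in
  the direction of disease progression".  This makes heterogeneous scales
  directly comparable but discards within-half magnitude information: a
  patient marginally above the median and one far above it contribute the
  same profile bit.
- **Strict thresholding.**  A value exactly at the median scores 0; there
  is no tolerance band.  With continuous (untied) data this pins the
  population baseline affected fraction at `⌊N/2⌋/N`, which is the
  "close to 0.5" appearance of the total-population panel; ties move it
  below that.
- **Equal weighting.**  By default every profile cell (variable × visit)
  carries weight 1 in the agreement score, so a variable measured at 5
  visits influences similarity 5 times as much as a static one.  Static
  variables (gender, genotype, age) are deliberately replicated across all
  visits so they participate in every visit's panel; the
  `WeightScheme.static_once` constructor restricts them to baseline for
  sensitivity analysis (implemented as zero weight at later visits so the
  profile invariant "static rows are constant" is preserved).
- **Modularity-optimal subtype count.**  The number of subtypes is not a
  parameter: it is whatever partition maximizes Newman–Girvan modularity at
  resolution 1 on the dense agreement network.  Self-links are excluded
  (self-agreement is the constant `Σw` and carries no information), and the
  network is not sparsified.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `test_fraction` | 0.2 | held-out share; size is round-half-up, so 194 → 39/155 |
| `min_size` | 10 | communities below this are kept in the partition but excluded from subtype profiles, reporting and prediction |
| `seed` | — | drives the Louvain sweep order and all simulation draws; identical seeds give bit-identical artifacts |
| `distance_profile` | `normalized` | prediction distance compares binary T against the normalized profile S (entries may exceed 1); `affected_fraction` compares against the raw member mean instead |
| `static_count_once` | `False` | see equal-weighting note above |

## Prediction

Assignment minimizes the squared Euclidean distance between the patient's
binary profile column and each retained subtype's S column at one visit.
Columns whose baseline normalizer `U_v0` is zero have undefined S and are
excluded from the distance for all subtypes symmetrically.  Ties are broken
to the lowest community id and flagged.  The distance sums over every
profile column present in the fitted model (clinical, demographic, and
genotype columns when fitted with genetic data); comparing binary T to
normalized S follows the definition of the distance even though the
heatmaps display the unnormalized fraction — the `distance_profile` switch
exposes the alternative.

## Subtype statistics

Raw (untransformed, undirected) values are used for medians and tests;
the severity direction is reported alongside each row.  Mann–Whitney U
tests are exact (permutation null) when the combined sample is ≤ 20 and
tie-free, asymptotic with tie correction otherwise; the method used is
recorded in the output table.  Unadjusted p-values are reported and flagged
against `α / n_c`, `n_c = n_p (V_d + 2 V_e)`: evolving continuous variables
count twice (baseline and final visit), demographics once.  Genotype
variables are not part of the comparison table.

## Synthetic cohorts

The generator plants `K` subtypes with mixing proportions, and for each
continuous variable and visit a target probability `p_vt` that a member
exceeds the population baseline median.  Values follow a Gaussian latent
model with probit-spaced means, `Y = Φ⁻¹(p_vt) + σ ε`, `ε ~ N(0,1)`: at the
default `σ = 1` the exceedance probability of the nominal threshold 0 is
exactly `p_vt`, while larger `σ` shrinks every probability toward 0.5 and
degrades subtype separation — the knob used for noise-robustness checks.
Gender is Bernoulli per subtype, genotypes are drawn from subtype-specific
class frequencies and held constant over time.

The packaged `ppmi_like_spec` fixture mirrors the shape of a 5-visit
Parkinson's progression study: 194 patients, 16 evolving clinical scales in
six domains (4 overall-severity, 1 disability, 6 cognition, 1 autonomic,
2 sleep, 2 mental-health; cognition and disability scales carry
`d_v = −1`), static age and gender, four biallelic SNP loci (30 one-hot
profile columns in total), and three planted subtypes: *mild* (below the
median everywhere), *severe* (above it with rising curves, older,
predominantly male), and *mixed* (severe motor/autonomic/sleep/mental
impairment with preserved cognition, younger, predominantly female).
Mixing proportions are 0.30/0.45/0.25.

What the generator does **not** emulate: within-domain correlation between
scales (cells are independent given the subtype), measurement dropout and
attrition, floor/ceiling effects of real instruments, and any calibration
to real cohort marginals.  Passing recovery tests therefore shows the
pipeline recovers planted block structure under realistic dimensions and
noise — not that real-cohort subtypes would be recovered at the same rate.

## Numerical choices

- Even-sized medians are the mean of the two central order statistics.
- The agreement matrix is computed via the binary identity
  `[a=b] = ab + (1−a)(1−b)` as two rank-`V'M` matrix products, then
  symmetrized exactly; a brute-force double loop serves as the test oracle.
- Louvain is delegated to networkx's seeded implementation; the modularity
  function is implemented independently from its definition and
  cross-checked against both an explicit double-sum and networkx.  On
  graphs small enough to enumerate every partition, the best of 10 seeds
  attains the exhaustive optimum in the test suite.
- Community ids are relabeled 1..K by decreasing size (ties by first
  patient index) so artifacts are stable across runs with the same seed.
- JSON artifacts serialize floats via Python's `repr`-based JSON encoder,
  so fit → save → load → predict is bit-identical to predicting in memory.

## Problem sizes in the test suite

Recovery checks run 20 simulated cohorts at the fixture's native size
(N = 194, 5 visits) and a 5-point noise grid at N = 120 with 20 seeds per
point; enumeration oracles cover networks up to N = 20, partitions up to
N = 8 (Bell-number exhaustive search), and rank tests up to a combined
n = 10.  Null calibration of the Bonferroni flag uses 1000 replicates of
three identically distributed groups of 20.  These sizes were chosen as the
smallest at which the checked properties are stable across seeds.

## Known limitations

- Median binarization is sensitive to heavy ties (ordinal scales with few
  levels); the affected-fraction "close to 0.5" property degrades there.
- Modularity values on dense agreement networks are small in absolute terms
  (high shared baseline agreement); compare partitions by Q differences,
  not by Q's magnitude.
- The prediction scheme assumes subtype profiles are stable enough between
  baseline and the final visit for nearest-profile assignment to be
  meaningful; strongly crossing trajectories would violate this.
- No imputation is provided: analysis is complete-case by design.
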