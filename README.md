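# trajpc — Trajectory Profile Clustering

`trajpc` identifies subtypes of a chronic progressive disease from
longitudinal cohort data and predicts an unseen patient's future subtype
from baseline measurements alone.  It is aimed at researchers working with
multi-year observational studies — clinical scale scores assessed at yearly
visits, demographics, and optionally genotype calls at disease-associated
SNP loci — who want a data-driven subtyping that respects *how* patients
progress, not just how severe they are at one visit.

## Method

Given a cohort `X_ivt` (patient `i`, variable `v`, visit `t`; visit 0 is
baseline):

1. **Severity alignment.** Each continuous variable gets a direction
   `d_v ∈ {+1, −1}` so that higher `Y_ivt = d_v X_ivt` always means more
   severe disease (e.g. cognitive scales where higher raw scores are
   healthier get `d_v = −1`).
2. **Trajectory profiles.** With `θ_v` the training-population baseline
   median of `Y`, each patient is reduced to a binary matrix
   `T^i_vt = 1` iff `Y_ivt > θ_v` (strict).  Gender contributes a 0/1 row;
   each biallelic SNP contributes three one-hot rows, one per diploid
   genotype class, replicated across visits.
3. **Patient network.** Patients are linked by profile agreement
   `P_ij = Σ_vt w_vt [T^i_vt = T^j_vt]` (unit weights by default), giving a
   dense weighted patient–patient network.
4. **Subtype detection.** Louvain community detection maximizes
   Newman–Girvan modularity `Q` on `P`; the number of subtypes is whatever
   maximizes `Q`.  Communities with fewer than 10 patients are flagged and
   excluded from reporting and prediction.
5. **Subtype profiles.** Each community `C_l` is summarized by
   `S^l_vt = Σ_{i∈C_l} T^i_vt / (N_l U_v0)`, normalized by the population
   baseline mean `U_v0`, alongside the unnormalized *affected fraction*
   (the grayscale quantity of the subtype heatmaps).
6. **Prediction.** A held-out patient is assigned at visit `t` to the
   subtype minimizing `d_t^{il} = Σ_v (T^i_vt − S^l_vt)²`.  Prediction
   accuracy is the fraction of test patients whose baseline-assigned
   subtype matches their final-visit subtype.

Subtypes are compared pairwise with Mann–Whitney U tests (evolving scales
at baseline and final visit; age once) and Fisher's exact test (gender),
flagged at a Bonferroni-adjusted level `α / n_c` with
`n_c = n_p (V_d + 2 V_e)`.

Because real multi-year clinical cohorts are typically access-restricted,
the package ships a synthetic-cohort generator with planted subtypes
(`trajpc.simulate`) that emulates the structure of such a study; every
stage of the pipeline is tested against it.

## Worked example

```python
from trajpc import fit, generate_cohort, ppmi_like_spec, predict, split_cohort

cohort, _ = generate_cohort(ppmi_like_spec(seed=1))   # 194 patients, 5 visits
split = split_cohort(cohort, test_fraction=0.2, seed=1)  # 155 train / 39 test
artifact = fit(split.train, seed=1)
print(artifact.partition.sizes(), round(artifact.partition.Q, 4))
print(round(predict(artifact, split.test).accuracy, 3))
```

prints

```
{1: 66, 2: 46, 3: 43} 0.047
0.872
```

Three subtypes of 66/46/43 training patients emerge from modularity
maximization (`Q = 0.047`; dense agreement networks have high baseline
similarity, so positive `Q` at this scale reflects real block structure),
and 87.2% of the 39 held-out patients keep their baseline-predicted subtype
at year 4.  The scripts in `examples/` walk through simulation, fitting,
prediction, reporting and subtype statistics one capability at a time, and
the same workflow is available from the shell:

```bash
trajpc simulate --out sim/
trajpc fit sim/cohort.csv sim/metadata.json --seed 1 --out model.json
trajpc predict model.json sim/cohort.csv sim/metadata.json --out pred.csv
trajpc stats model.json sim/cohort.csv sim/metadata.json --out stats.csv
trajpc report model.json --out report/
```

Cohorts are exchanged as long-format CSV plus a variable-metadata JSON;
see `docs/cohort_format.md`.

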