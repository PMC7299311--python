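# Cohort file formats

## Long-format cohort CSV

Header exactly: `patient_id,timepoint,variable,value`.  One row per
observed (patient, visit, variable) cell; omitted rows become missing cells
(handled by `complete_case_filter`).  Duplicate (patient, timepoint,
variable) rows are rejected.

| column | content |
|---|---|
| `patient_id` | any string, unique per patient |
| `timepoint` | one of the labels declared in the metadata, e.g. `bl`, `y1` |
| `variable` | a variable name declared in the metadata |
| `value` | number for continuous; `0`/`1` for binary; a genotype class label (e.g. `CT`) for genotype variables |

Static variables (e.g. `age`, `gender`, SNP loci) may be given at one visit
only; the reader broadcasts them across all visits.

## Variable-metadata JSON

```json
{
 "timepoints": ["bl", "y1", "y2", "y3", "y4"],
 "variables": [
  {"name": "UPDRS3", "domain_group": "PD severity", "kind": "continuous",
   "direction": 1, "static": false},
  {"name": "MOCA", "domain_group": "Cognition", "kind": "continuous",
   "direction": -1, "static": false},
  {"name": "age", "domain_group": "Demographic", "kind": "continuous",
   "direction": 1, "static": true},
  {"name": "gender", "domain_group": "Demographic", "kind": "binary",
   "static": true},
  {"name": "G1", "domain_group": "Genetic", "kind": "genotype",
   "static": true, "genotype_classes": ["CC", "CT", "TT"]}
 ]
}
```

- `timepoints` is the declared visit order; index 0 is baseline.
- `direction` is required for (and only for) continuous variables:
  `+1` if higher raw values mean greater severity, `-1` otherwise.
- `genotype_classes` is required for (and only for) genotype variables and
  fixes the one-hot column order of the trajectory profile.
- Binary variables are encoded with 1 = male for gender.

`write_cohort` / `read_cohort` round-trip these files bit-exactly for
continuous values and label-exactly for genotype classes.
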