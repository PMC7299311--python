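"""Cohort containers, long-format I/O, complete-case filtering and splitting.

A longitudinal cohort is an ``N x V x M`` array: ``N`` patients, ``V``
variables, ``M`` ordered timepoints (index 0 is baseline).  Continuous
variables hold real scale scores, binary variables hold {0, 1}, and
genotype variables hold the index of the patient's diploid genotype class
(the class labels live on the :class:`VariableSpec`).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("continuous", "binary", "genotype")


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one cohort variable.

    Parameters
    ----------
    name
        Unique variable identifier.
    domain_group
        Clinical domain label (e.g. ``"Cognition"``, ``"Sleep"``,
        ``"Demographic"``, ``"Genetic"``).
    kind
        One of ``continuous``, ``binary``, ``genotype``.
    direction
        Severity direction ``d_v`` in {+1, -1}; required for continuous
        variables and meaningless otherwise.  ``+1`` means higher raw values
        indicate greater disease severity.
    static
        Whether the value is constant over time (gender, genotype, age by
        default).
    genotype_classes
        Ordered diploid genotype class labels (e.g. ``["CC", "CT", "TT"]``);
        required for genotype variables.
    """

    name: str
    domain_group: str = ""
    kind: str = "continuous"
    direction: int | None = None
    static: bool = False
    genotype_classes: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "continuous":
            if self.direction not in (+1, -1):
                raise ValueError(
                    f"continuous variable {self.name!r} needs direction +1 or -1"
                )
        elif self.direction is not None:
            raise ValueError(f"direction only applies to continuous variables ({self.name!r})")
        if self.kind == "genotype":
            if not self.genotype_classes or len(self.genotype_classes) < 2:
                raise ValueError(
                    f"genotype variable {self.name!r} needs >=2 genotype classes"
                )
            object.__setattr__(self, "genotype_classes", tuple(self.genotype_classes))
            if not self.static:
                raise ValueError(f"genotype variable {self.name!r} must be static")
        elif self.genotype_classes is not None:
            raise ValueError(
                f"genotype_classes only applies to genotype variables ({self.name!r})"
            )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "domain_group": self.domain_group,
            "kind": self.kind,
            "static": self.static,
        }
        if self.kind == "continuous":
            d["direction"] = self.direction
        if self.kind == "genotype":
            d["genotype_classes"] = list(self.genotype_classes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        gc = d.get("genotype_classes")
        return cls(
            name=d["name"],
            domain_group=d.get("domain_group", ""),
            kind=d.get("kind", "continuous"),
            direction=d.get("direction"),
            static=bool(d.get("static", False)),
            genotype_classes=tuple(gc) if gc else None,
        )


@dataclass
class LongitudinalCohort:
    """Dense ``N x V x M`` cohort with a missing-value mask.

    ``values[i, v, t]`` is patient ``i``'s value for variable ``v`` at
    timepoint ``t``; genotype variables store the class index.  ``mask`` is
    True where the value is missing.
    """

    patient_ids: list[str]
    timepoints: list[str]
    variables: list[VariableSpec]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_patients, self.n_variables, self.n_timepoints):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({self.n_patients}, {self.n_variables}, {self.n_timepoints})"
            )
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        if len(self.timepoints) < 1:
            raise ValueError("need at least one timepoint")
        self._check_static()

    def _check_static(self):
        for v, spec in enumerate(self.variables):
            if not spec.static or self.n_timepoints < 2:
                continue
            vals = self.values[:, v, :]
            obs = ~self.mask[:, v, :]
            # static variables must not vary over time where observed
            for i in range(self.n_patients):
                seen = vals[i, obs[i]]
                if seen.size > 1 and not np.all(seen == seen[0]):
                    raise ValueError(
                        f"static variable {spec.name!r} varies over time for "
                        f"patient {self.patient_ids[i]!r}"
                    )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def variable_index(self, name: str) -> int:
        for v, spec in enumerate(self.variables):
            if spec.name == name:
                return v
        raise KeyError(name)

    def subset(self, indices) -> "LongitudinalCohort":
        """Cohort restricted to the given patient indices (order preserved)."""
        indices = list(indices)
        return LongitudinalCohort(
            patient_ids=[self.patient_ids[i] for i in indices],
            timepoints=list(self.timepoints),
            variables=list(self.variables),
            values=self.values[indices].copy(),
            mask=self.mask[indices].copy(),
        )

    def genotype_label(self, var: int, i: int, t: int = 0) -> str:
        spec = self.variables[var]
        return spec.genotype_classes[int(self.values[i, var, t])]


@dataclass(frozen=True)
class TrainTestSplit:
    train: LongitudinalCohort
    test: LongitudinalCohort
    seed: int


def _format_value(cohort: LongitudinalCohort, i: int, v: int, t: int) -> str:
    spec = cohort.variables[v]
    x = cohort.values[i, v, t]
    if spec.kind == "genotype":
        return spec.genotype_classes[int(x)]
    if spec.kind == "binary":
        return str(int(x))
    return repr(float(x))


def write_cohort(cohort: LongitudinalCohort, table_path, metadata_path) -> None:
    """Write a cohort as long-format CSV plus variable-metadata JSON.

    Missing cells are simply omitted from the CSV; continuous values are
    serialized with ``repr`` so the round-trip is bit-exact.
    """
    rows = []
    for i in range(cohort.n_patients):
        for v in range(cohort.n_variables):
            for t in range(cohort.n_timepoints):
                if cohort.mask[i, v, t]:
                    continue
                rows.append(
                    (
                        cohort.patient_ids[i],
                        cohort.timepoints[t],
                        cohort.variables[v].name,
                        _format_value(cohort, i, v, t),
                    )
                )
    pd.DataFrame(rows, columns=["patient_id", "timepoint", "variable", "value"]).to_csv(
        table_path, index=False
    )
    meta = {
        "timepoints": list(cohort.timepoints),
        "variables": [s.to_dict() for s in cohort.variables],
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_cohort(table_path, metadata_path) -> LongitudinalCohort:
    """Read a long-format cohort CSV plus its variable-metadata JSON.

    The CSV must have columns ``patient_id,timepoint,variable,value``.
    Every variable appearing in the table must be declared in the metadata;
    rows absent from the table become missing cells in the mask.

    Raises
    ------
    ValueError
        On unknown variable names, duplicate (patient, timepoint, variable)
        rows, non-numeric values for continuous variables, or genotype
        labels outside the declared classes.
    """
    with open(metadata_path) as fh:
        meta = json.load(fh)
    variables = [VariableSpec.from_dict(d) for d in meta["variables"]]
    timepoints = list(meta["timepoints"])
    var_idx = {s.name: v for v, s in enumerate(variables)}
    tp_idx = {t: j for j, t in enumerate(timepoints)}

    df = pd.read_csv(table_path, dtype=str)
    required = {"patient_id", "timepoint", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort CSV must have columns {sorted(required)}")

    unknown = set(df["variable"]) - set(var_idx)
    if unknown:
        raise ValueError(f"variables not declared in metadata: {sorted(unknown)}")
    unknown_tp = set(df["timepoint"]) - set(tp_idx)
    if unknown_tp:
        raise ValueError(f"timepoints not declared in metadata: {sorted(unknown_tp)}")

    dup = df.duplicated(subset=["patient_id", "timepoint", "variable"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["patient_id", "timepoint", "variable"]].iloc[0].tolist()
        raise ValueError(f"duplicate (patient, timepoint, variable) rows, e.g. {bad}")

    patient_ids = list(dict.fromkeys(df["patient_id"]))
    p_idx = {p: i for i, p in enumerate(patient_ids)}
    n, nv, m = len(patient_ids), len(variables), len(timepoints)
    values = np.zeros((n, nv, m), dtype=float)
    mask = np.ones((n, nv, m), dtype=bool)

    for pid, tp, var, raw in df.itertuples(index=False):
        i, v, t = p_idx[pid], var_idx[var], tp_idx[tp]
        spec = variables[v]
        if spec.kind == "genotype":
            if raw not in spec.genotype_classes:
                raise ValueError(
                    f"genotype label {raw!r} not in classes of {spec.name!r}"
                )
            x = float(spec.genotype_classes.index(raw))
        else:
            try:
                x = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {raw!r} for {spec.kind} variable {spec.name!r}"
                ) from None
            if spec.kind == "binary" and x not in (0.0, 1.0):
                raise ValueError(f"binary variable {spec.name!r} has value {raw!r}")
        values[i, v, t] = x
        mask[i, v, t] = False

    # static variables measured once are broadcast across timepoints
    for v, spec in enumerate(variables):
        if not spec.static:
            continue
        for i in range(n):
            obs = ~mask[i, v, :]
            if obs.any() and not obs.all():
                values[i, v, :] = values[i, v, obs][0]
                mask[i, v, :] = False

    return LongitudinalCohort(patient_ids, timepoints, variables, values, mask)


def complete_case_filter(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Drop every patient with at least one missing cell.

    Mirrors a complete-case analysis: no imputation, patients either have a
    fully observed ``V x M`` block or are excluded.
    """
    complete = ~cohort.mask.reshape(cohort.n_patients, -1).any(axis=1)
    kept = np.flatnonzero(complete)
    removed = cohort.n_patients - kept.size
    if kept.size == 0:
        raise ValueError("complete-case filter removed every patient")
    if removed:
        logger.info("complete-case filter removed %d of %d patients", removed, cohort.n_patients)
    return cohort.subset(kept)


def split_cohort(
    cohort: LongitudinalCohort, test_fraction: float, seed: int
) -> TrainTestSplit:
    """Uniform train/test split with a round-half-up test-set size.

    ``N_test = round(test_fraction * N)`` with ties rounded up, so a 20%
    split of 194 patients yields 39 test and 155 training patients.
    """
    n = cohort.n_patients
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(math.floor(test_fraction * n + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"degenerate split: N_test={n_test} of N={n} at fraction {test_fraction}"
        )
    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    test_set = set(test_idx.tolist())
    train_idx = [i for i in range(n) if i not in test_set]
    return TrainTestSplit(
        train=cohort.subset(train_idx), test=cohort.subset(test_idx), seed=seed
    )
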