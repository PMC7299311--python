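"""Binary trajectory profiles.

Raw values are first aligned with disease severity (``Y = d_v * X`` for
continuous variables), thresholds are taken as training-population baseline
medians, and each patient is reduced to a binary ``V' x M`` trajectory
profile: 1 where severity strictly exceeds the threshold, gender copied,
genotype one-hot over its diploid classes.  ``V'`` counts one column per
continuous/binary variable plus one per genotype class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import LongitudinalCohort, VariableSpec


@dataclass(frozen=True)
class ThresholdSet:
    """Per-variable thresholds ``theta_v`` (continuous variables only)."""

    theta: dict[str, float]
    source_n: int

    def __post_init__(self):
        for name, th in self.theta.items():
            if not np.isfinite(th):
                raise ValueError(f"non-finite threshold for {name!r}")


@dataclass
class TrajectoryProfile:
    """A patient's binary ``V' x M`` trajectory profile."""

    patient_id: str
    matrix: np.ndarray  # V' x M, uint8
    columns: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.columns):
            raise ValueError("profile matrix shape does not match column labels")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")


def profile_columns(variables: list[VariableSpec]) -> list[str]:
    """Expanded column labels: genotype loci contribute one column per class."""
    cols: list[str] = []
    for spec in variables:
        if spec.kind == "genotype":
            cols.extend(f"{spec.name}:{c}" for c in spec.genotype_classes)
        else:
            cols.append(spec.name)
    return cols


def apply_direction(cohort: LongitudinalCohort) -> np.ndarray:
    """Severity-align raw values: ``Y = d_v * X`` for continuous variables.

    Binary and genotype values pass through unchanged.  Returns a new
    ``N x V x M`` array.
    """
    y = cohort.values.copy()
    for v, spec in enumerate(cohort.variables):
        if spec.kind == "continuous":
            y[:, v, :] *= spec.direction
    return y


def compute_thresholds(train: LongitudinalCohort) -> ThresholdSet:
    """Training-baseline median thresholds for every continuous variable.

    The median of an even-sized sample is the mean of the two central order
    statistics.  Thresholds must come from training data only; test-patient
    profiles reuse them unchanged.
    """
    if train.n_patients == 0:
        raise ValueError("empty training cohort")
    if train.mask[:, :, 0].any():
        raise ValueError("missing baseline values; run complete_case_filter first")
    y = apply_direction(train)
    theta = {
        spec.name: float(np.median(y[:, v, 0]))
        for v, spec in enumerate(train.variables)
        if spec.kind == "continuous"
    }
    return ThresholdSet(theta=theta, source_n=train.n_patients)


def build_trajectory_profile(
    patient_id: str,
    directed_values: np.ndarray,
    variables: list[VariableSpec],
    thresholds: ThresholdSet,
) -> TrajectoryProfile:
    """Binarize one patient's severity-aligned ``V x M`` slice.

    Continuous entries are 1 on strict exceedance of ``theta_v`` (a value
    exactly at the median scores 0); binary values are copied; genotype
    values are one-hot over the declared classes and replicated across all
    timepoints.
    """
    directed_values = np.asarray(directed_values, dtype=float)
    m = directed_values.shape[1]
    rows = []
    for v, spec in enumerate(variables):
        if spec.kind == "continuous":
            rows.append(directed_values[v] > thresholds.theta[spec.name])
        elif spec.kind == "binary":
            rows.append(directed_values[v] != 0)
        else:
            idx = directed_values[v, 0]
            if not (idx == int(idx) and 0 <= idx < len(spec.genotype_classes)):
                raise ValueError(
                    f"genotype class index {idx} invalid for {spec.name!r}"
                )
            for c in range(len(spec.genotype_classes)):
                rows.append(np.full(m, c == int(idx), dtype=bool))
    return TrajectoryProfile(
        patient_id=patient_id,
        matrix=np.asarray(rows, dtype=np.uint8),
        columns=profile_columns(variables),
    )


def build_profiles(
    cohort: LongitudinalCohort, thresholds: ThresholdSet
) -> list[TrajectoryProfile]:
    """Trajectory profiles for every patient in the cohort."""
    if cohort.mask.any():
        raise ValueError("cohort has missing values; run complete_case_filter first")
    y = apply_direction(cohort)
    return [
        build_trajectory_profile(pid, y[i], cohort.variables, thresholds)
        for i, pid in enumerate(cohort.patient_ids)
    ]


def profile_stack(profiles: list[TrajectoryProfile]) -> np.ndarray:
    """Stack profiles into an ``N x V' x M`` array, checking label consistency."""
    if not profiles:
        raise ValueError("no profiles")
    cols = profiles[0].columns
    for p in profiles[1:]:
        if p.columns != cols:
            raise ValueError("profiles have inconsistent column labels")
    return np.stack([p.matrix for p in profiles]).astype(float)
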