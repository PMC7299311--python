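"""Subtype assignment for held-out patients and prediction accuracy.

A test patient is assigned at timepoint ``t`` to the retained subtype whose
profile column at ``t`` minimizes the squared-Euclidean distance

    d_t^{il} = sum_v (T^i_vt - S^l_vt)^2

(no square root — the argmin is unaffected).  Prediction accuracy is the
fraction of test patients whose baseline-assigned subtype equals their
final-timepoint-assigned subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import TrajectoryProfile
from .subtypes import SubtypeProfile

_TIE_TOL = 1e-12


@dataclass
class AssignmentResult:
    patient_id: str
    timepoint: int
    distances: dict[int, float]
    assigned: int
    tie_flag: bool


@dataclass
class PredictionReport:
    table: pd.DataFrame  # patient_id, predicted_subtype, final_subtype, concordant
    accuracy: float


def assign_at_time(
    profile: TrajectoryProfile,
    t: int,
    subtype_profiles: list[SubtypeProfile] | dict[int, SubtypeProfile],
    distance_profile: str = "normalized",
) -> AssignmentResult:
    """Nearest-subtype assignment of one patient at a single timepoint.

    ``distance_profile`` selects whether T is compared against the
    normalized subtype profile S (default, values may exceed 1) or against
    the raw affected fraction.  Columns whose S is undefined (population
    baseline normalizer zero) are dropped from the sum for all subtypes
    symmetrically.  Ties go to the lowest community id and are flagged.
    """
    if isinstance(subtype_profiles, dict):
        subtype_profiles = list(subtype_profiles.values())
    if not subtype_profiles:
        raise ValueError("no retained subtypes to assign to")
    if distance_profile not in ("normalized", "affected_fraction"):
        raise ValueError(f"unknown distance_profile {distance_profile!r}")
    cols = subtype_profiles[0].columns
    if profile.columns != cols:
        raise ValueError("patient profile columns do not match subtype profiles")
    valid = np.ones(len(cols), dtype=bool)
    if distance_profile == "normalized":
        for sp in subtype_profiles:
            valid &= ~sp.undefined_columns
    tvec = profile.matrix[:, t].astype(float)
    distances: dict[int, float] = {}
    for sp in subtype_profiles:
        ref = sp.S if distance_profile == "normalized" else sp.affected_fraction
        diff = tvec[valid] - ref[valid, t]
        distances[sp.community_id] = float((diff**2).sum())
    ids = sorted(distances)
    best = min(distances[c] for c in ids)
    winners = [c for c in ids if distances[c] <= best + _TIE_TOL]
    return AssignmentResult(
        patient_id=profile.patient_id,
        timepoint=t,
        distances=distances,
        assigned=winners[0],
        tie_flag=len(winners) > 1,
    )


def prediction_accuracy(
    baseline: list[AssignmentResult], final: list[AssignmentResult]
) -> PredictionReport:
    """Concordance between baseline and final-timepoint assignments."""
    base_by_pid = {r.patient_id: r for r in baseline}
    final_by_pid = {r.patient_id: r for r in final}
    if set(base_by_pid) != set(final_by_pid):
        raise ValueError("baseline and final assignments cover different patients")
    if not baseline:
        raise ValueError("no assignments")
    rows = []
    for r in baseline:
        f = final_by_pid[r.patient_id]
        rows.append(
            {
                "patient_id": r.patient_id,
                "predicted_subtype": r.assigned,
                "final_subtype": f.assigned,
                "concordant": r.assigned == f.assigned,
                "baseline_distance": r.distances[r.assigned],
            }
        )
    table = pd.DataFrame(rows)
    return PredictionReport(table=table, accuracy=float(table["concordant"].mean()))


def rank_by_confidence(results: list[AssignmentResult]) -> list[AssignmentResult]:
    """Stable sort by distance to the assigned subtype, most confident first."""
    return sorted(results, key=lambda r: r.distances[r.assigned])


def distance_table(
    assignments_by_time: dict[int, list[AssignmentResult]],
) -> pd.DataFrame:
    """Long table of per-patient, per-timepoint distances to every subtype."""
    rows = []
    for t, results in sorted(assignments_by_time.items()):
        for r in results:
            for cid, d in sorted(r.distances.items()):
                rows.append(
                    {
                        "patient_id": r.patient_id,
                        "timepoint": t,
                        "subtype": cid,
                        "distance": d,
                        "assigned": cid == r.assigned,
                    }
                )
    return pd.DataFrame(rows)
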