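"""Fitted-model artifact: the self-contained output of a TPC fit.

The artifact carries everything needed to profile and assign a new patient
-- variable specs, frozen thresholds, baseline normalizers, the partition,
and the subtype profiles -- serialized as human-auditable JSON with floats
at full precision, so fit -> save -> load -> predict is bit-identical to
predicting in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import __version__
from .cohort import LongitudinalCohort, VariableSpec
from .network import WeightScheme, build_similarity_matrix
from .predict import AssignmentResult, PredictionReport, assign_at_time, prediction_accuracy
from .profiles import ThresholdSet, build_profiles, profile_columns
from .subtypes import (
    DEFAULT_MIN_SIZE,
    SubtypePartition,
    SubtypeProfile,
    compute_subtype_profiles,
    louvain_partition,
)


@dataclass
class ModelArtifact:
    variables: list[VariableSpec]
    timepoints: list[str]
    thresholds: ThresholdSet
    columns: list[str]
    U: np.ndarray
    partition: SubtypePartition
    subtype_profiles: dict[int, SubtypeProfile]
    weights: WeightScheme
    version: str = __version__

    def retained_profiles(self) -> list[SubtypeProfile]:
        return [self.subtype_profiles[c] for c in sorted(self.subtype_profiles)]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "timepoints": list(self.timepoints),
            "variables": [v.to_dict() for v in self.variables],
            "thresholds": {"theta": self.thresholds.theta, "source_n": self.thresholds.source_n},
            "columns": list(self.columns),
            "U": self.U.tolist(),
            "weights": self.weights.w.tolist(),
            "partition": {
                "labels": self.partition.labels,
                "Q": self.partition.Q,
                "seed": self.partition.seed,
                "min_size": self.partition.min_size,
                "retained": sorted(self.partition.retained),
            },
            "subtype_profiles": {
                str(c): {
                    "N_l": sp.N_l,
                    "S": [[None if np.isnan(x) else x for x in row] for row in sp.S],
                    "affected_fraction": sp.affected_fraction.tolist(),
                }
                for c, sp in self.subtype_profiles.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelArtifact":
        variables = [VariableSpec.from_dict(v) for v in d["variables"]]
        columns = list(d["columns"])
        u = np.asarray(d["U"], dtype=float)
        part = SubtypePartition(
            labels={p: int(l) for p, l in d["partition"]["labels"].items()},
            Q=float(d["partition"]["Q"]),
            seed=int(d["partition"]["seed"]),
            min_size=int(d["partition"]["min_size"]),
            retained=set(int(c) for c in d["partition"]["retained"]),
        )
        profiles: dict[int, SubtypeProfile] = {}
        for cs, sp in d["subtype_profiles"].items():
            c = int(cs)
            s = np.array(
                [[np.nan if x is None else x for x in row] for row in sp["S"]], dtype=float
            )
            profiles[c] = SubtypeProfile(
                community_id=c,
                S=s,
                affected_fraction=np.asarray(sp["affected_fraction"], dtype=float),
                N_l=int(sp["N_l"]),
                U=u,
                columns=columns,
                undefined_columns=u == 0,
            )
        return cls(
            variables=variables,
            timepoints=list(d["timepoints"]),
            thresholds=ThresholdSet(
                theta={k: float(v) for k, v in d["thresholds"]["theta"].items()},
                source_n=int(d["thresholds"]["source_n"]),
            ),
            columns=columns,
            U=u,
            partition=part,
            subtype_profiles=profiles,
            weights=WeightScheme(np.asarray(d["weights"], dtype=float), columns),
            version=d.get("version", "unknown"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelArtifact":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit(
    train: LongitudinalCohort,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    static_count_once: bool = False,
    weights: WeightScheme | None = None,
) -> ModelArtifact:
    """Run the full subtype-identification pipeline on a training cohort.

    Steps: severity alignment and baseline-median thresholds, binary
    trajectory profiles, all-pairs agreement network, Louvain partition with
    the small-community filter, population normalizers and per-subtype
    profiles.
    """
    from .profiles import compute_thresholds

    thresholds = compute_thresholds(train)
    profs = build_profiles(train, thresholds)
    cols = profile_columns(train.variables)
    if weights is None:
        if static_count_once:
            static = {v.name for v in train.variables if v.static}
            weights = WeightScheme.static_once(cols, static, train.n_timepoints)
        else:
            weights = WeightScheme.unit(cols, train.n_timepoints)
    net = build_similarity_matrix(profs, weights)
    partition = louvain_partition(net, seed=seed, min_size=min_size)
    subtype_profiles = compute_subtype_profiles(profs, partition)
    from .subtypes import baseline_normalizers

    return ModelArtifact(
        variables=list(train.variables),
        timepoints=list(train.timepoints),
        thresholds=thresholds,
        columns=cols,
        U=baseline_normalizers(profs),
        partition=partition,
        subtype_profiles=subtype_profiles,
        weights=weights,
    )


def assign_cohort(
    artifact: ModelArtifact,
    cohort: LongitudinalCohort,
    t: int,
    distance_profile: str = "normalized",
) -> list[AssignmentResult]:
    """Assign every patient of a cohort to a retained subtype at timepoint t."""
    names_art = [v.name for v in artifact.variables]
    names_coh = [v.name for v in cohort.variables]
    if names_art != names_coh:
        raise ValueError("cohort variables do not match the fitted artifact")
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    profs = build_profiles(cohort, artifact.thresholds)
    refs = artifact.retained_profiles()
    if not refs:
        raise ValueError("artifact has no retained subtypes")
    t = range(len(artifact.timepoints))[t]
    return [assign_at_time(p, t, refs, distance_profile) for p in profs]


def predict(
    artifact: ModelArtifact,
    test: LongitudinalCohort,
    final_timepoint: int = -1,
    distance_profile: str = "normalized",
) -> PredictionReport:
    """Baseline subtype prediction for held-out patients, scored at a later visit."""
    baseline = assign_cohort(artifact, test, 0, distance_profile)
    final = assign_cohort(artifact, test, final_timepoint, distance_profile)
    return prediction_accuracy(baseline, final)
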