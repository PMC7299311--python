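"""Subtype detection: modularity maximization on the patient network.

Communities of the weighted agreement network are found with the Louvain
heuristic; the number of subtypes is not fixed a priori but emerges from
maximizing the Newman-Girvan modularity

    Q = sum_c [ W_c / W - (s_c / 2W)^2 ]

where ``W`` is the total edge weight, ``W_c`` the weight inside community
``c`` and ``s_c`` the summed node strength of ``c``.  Communities smaller
than ``min_size`` are kept in the partition but flagged as unretained:
their members are excluded from subtype profiles and from the prediction
reference set, not from the clustering itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import PatientNetwork
from .profiles import TrajectoryProfile, profile_stack

DEFAULT_MIN_SIZE = 10


@dataclass
class SubtypePartition:
    """Community label per patient plus the modularity achieved."""

    labels: dict[str, int]
    Q: float
    seed: int
    min_size: int = 1
    retained: set[int] | None = None

    def __post_init__(self):
        if self.retained is None:
            self.retained = set(self.labels.values())

    def community_ids(self) -> list[int]:
        return sorted(set(self.labels.values()))

    def members(self, cid: int) -> list[str]:
        return [p for p, l in self.labels.items() if l == cid]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for l in self.labels.values():
            out[l] = out.get(l, 0) + 1
        return out

    def unassigned_for_reporting(self) -> list[str]:
        """Patients whose community fell below the size filter."""
        return [p for p, l in self.labels.items() if l not in self.retained]


def modularity(network: PatientNetwork, labels: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity of a partition, self-loops excluded."""
    missing = [p for p in network.patient_ids if p not in labels]
    if missing:
        raise ValueError(f"no community label for patients {missing[:3]}")
    a = network.P
    two_w = a.sum()
    if two_w <= 0:
        raise ValueError("network has zero total weight")
    strength = a.sum(axis=1)
    lab = np.array([labels[p] for p in network.patient_ids])
    q = 0.0
    for c in np.unique(lab):
        idx = lab == c
        w_c = a[np.ix_(idx, idx)].sum() / two_w  # intra weight / W
        s_c = strength[idx].sum() / two_w
        q += w_c - s_c**2
    return float(q)


def louvain_partition(
    network: PatientNetwork, seed: int, min_size: int = DEFAULT_MIN_SIZE
) -> SubtypePartition:
    """Louvain community detection on the weighted patient network.

    The node sweep order is randomized under ``seed``, so repeated runs with
    the same seed return identical labels.  Community ids are reassigned
    1..K in order of decreasing size (ties by first patient) and the
    ``min_size`` retention filter is applied.
    """
    if len(network.patient_ids) < 2:
        raise ValueError("need at least 2 patients")
    if network.P.sum() <= 0:
        raise ValueError("network has zero total weight")
    g = network.to_networkx()
    comms = nx.community.louvain_communities(g, weight="weight", resolution=1.0, seed=seed)
    order = {p: i for i, p in enumerate(network.patient_ids)}
    comms = sorted(comms, key=lambda c: (-len(c), min(order[p] for p in c)))
    labels = {p: cid for cid, comm in enumerate(comms, start=1) for p in comm}
    part = SubtypePartition(labels=labels, Q=modularity(network, labels), seed=seed)
    return filter_small(part, min_size)


def filter_small(partition: SubtypePartition, min_size: int) -> SubtypePartition:
    """Mark communities below ``min_size`` as unretained; labels unchanged."""
    sizes = partition.sizes()
    retained = {c for c, n in sizes.items() if n >= min_size}
    if not retained:
        import warnings

        warnings.warn(
            f"no community reaches min_size={min_size}; retained set is empty",
            stacklevel=2,
        )
    return SubtypePartition(
        labels=dict(partition.labels),
        Q=partition.Q,
        seed=partition.seed,
        min_size=min_size,
        retained=retained,
    )


@dataclass
class SubtypeProfile:
    """Community-averaged trajectory profile.

    ``S[v, t] = (sum of member T) / (N_l * U_v0)`` where the normalizer
    ``U_v0`` is the baseline population mean of the profile column, so
    values above 1 mean above-population prevalence.  ``affected_fraction``
    is the unnormalized member mean of T (the grayscale quantity of the
    subtype heatmaps).  Columns with ``U_v0 = 0`` have undefined S (NaN) and
    are flagged for exclusion from prediction distances.
    """

    community_id: int
    S: np.ndarray
    affected_fraction: np.ndarray
    N_l: int
    U: np.ndarray  # baseline normalizers per column
    columns: list[str]
    undefined_columns: np.ndarray  # boolean per column, True where U==0

    def __post_init__(self):
        af = np.asarray(self.affected_fraction, float)
        if ((af < 0) | (af > 1)).any():
            raise ValueError("affected_fraction outside [0, 1]")


def baseline_normalizers(population: list[TrajectoryProfile]) -> np.ndarray:
    """Population baseline means ``U_v0`` per profile column.

    Computed once over the FULL training population (denominator N, not the
    community size) and frozen; communities never recompute it.
    """
    stack = profile_stack(population)
    return stack[:, :, 0].mean(axis=0)


def subtype_profile(
    community_id: int,
    members: list[TrajectoryProfile],
    U: np.ndarray,
) -> SubtypeProfile:
    """Normalized subtype profile S and affected fraction for one community."""
    if not members:
        raise ValueError("empty community")
    stack = profile_stack(members)
    affected = stack.mean(axis=0)
    u = np.asarray(U, float)
    undefined = u == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = affected / u[:, None]
    s[undefined, :] = np.nan
    return SubtypeProfile(
        community_id=community_id,
        S=s,
        affected_fraction=affected,
        N_l=len(members),
        U=u,
        columns=list(members[0].columns),
        undefined_columns=undefined,
    )


def compute_subtype_profiles(
    profiles: list[TrajectoryProfile], partition: SubtypePartition
) -> dict[int, SubtypeProfile]:
    """Subtype profiles for every retained community, shared normalizers U."""
    u = baseline_normalizers(profiles)
    by_id = {p.patient_id: p for p in profiles}
    out: dict[int, SubtypeProfile] = {}
    for cid in sorted(partition.retained):
        members = [by_id[p] for p in partition.members(cid) if p in by_id]
        out[cid] = subtype_profile(cid, members, u)
    return out
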