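"""Patient-patient trajectory-similarity network.

The agreement score between two patients counts the (optionally weighted)
profile cells on which their binary trajectory profiles coincide:

    P_ij = sum_{v,t} w_vt * [T^i_vt == T^j_vt]

With unit weights this is ``V'*M`` minus the Hamming distance.  The dense
network is kept unthresholded; the diagonal is zeroed because self-agreement
is the constant ``sum(w)`` and carries no community information.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .profiles import TrajectoryProfile, profile_stack


@dataclass
class WeightScheme:
    """Nonnegative per-cell weights ``w_vt`` on profile columns x timepoints."""

    w: np.ndarray  # V' x M
    columns: list[str]

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape[0] != len(self.columns):
            raise ValueError("weight matrix rows must match column labels")
        if not np.isfinite(self.w).all() or (self.w < 0).any():
            raise ValueError("weights must be finite and nonnegative")

    @classmethod
    def unit(cls, columns: list[str], n_timepoints: int) -> "WeightScheme":
        return cls(np.ones((len(columns), n_timepoints)), list(columns))

    @classmethod
    def static_once(
        cls, columns: list[str], static_columns: set[str], n_timepoints: int
    ) -> "WeightScheme":
        """Unit weights, but static columns count only at baseline.

        Sensitivity-analysis variant: a static variable otherwise enters the
        agreement sum once per timepoint.
        """
        w = np.ones((len(columns), n_timepoints))
        for r, c in enumerate(columns):
            if c in static_columns or c.split(":")[0] in static_columns:
                w[r, 1:] = 0.0
        return cls(w, list(columns))

    @property
    def total(self) -> float:
        """Maximum attainable pair agreement, ``sum_vt w_vt``."""
        return float(self.w.sum())

    def to_file(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"columns": list(self.columns), "w": self.w.tolist()}, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "WeightScheme":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["w"], dtype=float), list(d["columns"]))


@dataclass
class PatientNetwork:
    """Symmetric ``N x N`` agreement matrix with zeroed diagonal."""

    patient_ids: list[str]
    P: np.ndarray
    total_weight_per_pair_max: float

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.patient_ids)
        if self.P.shape != (n, n):
            raise ValueError("P shape does not match patient list")
        if not np.allclose(self.P, self.P.T):
            raise ValueError("P must be symmetric")

    def to_networkx(self) -> nx.Graph:
        """Weighted graph over all patients; zero-weight pairs carry no edge."""
        g = nx.Graph()
        g.add_nodes_from(self.patient_ids)
        n = len(self.patient_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.P[i, j] > 0:
                    g.add_edge(
                        self.patient_ids[i], self.patient_ids[j], weight=float(self.P[i, j])
                    )
        return g

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("patient_i\tpatient_j\tweight\n")
            n = len(self.patient_ids)
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(
                        f"{self.patient_ids[i]}\t{self.patient_ids[j]}\t{self.P[i, j]:g}\n"
                    )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def profile_agreement(
    a: TrajectoryProfile, b: TrajectoryProfile, weights: WeightScheme | None = None
) -> float:
    """Weighted count of profile cells on which two patients agree."""
    if a.columns != b.columns or a.matrix.shape != b.matrix.shape:
        raise ValueError("profiles have mismatched columns or shape")
    if weights is None:
        return float((a.matrix == b.matrix).sum())
    if weights.w.shape != a.matrix.shape:
        raise ValueError("weight matrix shape does not match profiles")
    return float((weights.w * (a.matrix == b.matrix)).sum())


def build_similarity_matrix(
    profiles: list[TrajectoryProfile], weights: WeightScheme | None = None
) -> PatientNetwork:
    """All-pairs agreement matrix over a list of trajectory profiles.

    Vectorized via the identity ``[a==b] = ab + (1-a)(1-b)`` for binary
    entries, so ``P = (wT) T^T + (w(1-T)) (1-T)^T`` flattened over cells.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    stack = profile_stack(profiles)  # N x V' x M
    n, vp, m = stack.shape
    if weights is None:
        weights = WeightScheme.unit(profiles[0].columns, m)
    if weights.w.shape != (vp, m):
        raise ValueError("weight matrix shape does not match profiles")
    t = stack.reshape(n, vp * m)
    w = weights.w.reshape(vp * m)
    p = (t * w) @ t.T + ((1.0 - t) * w) @ (1.0 - t).T
    p = (p + p.T) / 2.0  # exact symmetry against fp roundoff
    np.fill_diagonal(p, 0.0)
    return PatientNetwork(
        patient_ids=[pr.patient_id for pr in profiles],
        P=p,
        total_weight_per_pair_max=weights.total,
    )
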