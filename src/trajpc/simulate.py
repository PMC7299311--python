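"""Synthetic longitudinal cohorts with planted subtypes.

The generator emulates the structure of a multi-year observational cohort
of a progressive disease: ``K`` latent subtypes, each defined by a
per-variable, per-timepoint target probability ``p_vt`` that a member's
severity exceeds the population baseline median, plus static demographics
(continuous age, binary gender) and biallelic genotype loci with
subtype-specific class frequencies.

Continuous values follow a Gaussian latent model with probit-spaced means:
a member of subtype ``k`` has severity ``Z = Phi^-1(p_kvt) + sigma * eps``
with ``eps ~ N(0, 1)``, so at the default ``sigma = 1`` the probability of
exceeding zero (approximately the population baseline median) is exactly
``p_kvt``; larger ``sigma`` shrinks all exceedance probabilities toward 0.5
and degrades subtype separation.  Raw stored values are ``X = d_v * Z`` so
that severity alignment recovers ``Z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

from .cohort import LongitudinalCohort, VariableSpec


@dataclass
class SubtypeSpec:
    """One planted subtype: mixing weight and per-variable severity curves."""

    id: str
    mixing_proportion: float
    severity_curve: dict[str, list[float]]  # continuous variable -> M probabilities
    male_fraction: float = 0.5
    genotype_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.mixing_proportion <= 1:
            raise ValueError("mixing proportion must be in (0, 1]")
        for v, curve in self.severity_curve.items():
            if not all(0 < p < 1 for p in curve):
                raise ValueError(f"severity probabilities for {v!r} must be in (0, 1)")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        for locus, freqs in self.genotype_frequencies.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"genotype frequencies for {locus!r} must sum to 1")


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort draw."""

    N: int
    M: int
    subtypes: list[SubtypeSpec]
    variables: list[VariableSpec]
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.N < len(self.subtypes):
            raise ValueError("need at least one patient per subtype")
        if self.M < 2:
            raise ValueError("need at least 2 timepoints")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        total = sum(s.mixing_proportion for s in self.subtypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        cont = {v.name for v in self.variables if v.kind == "continuous"}
        loci = {v.name for v in self.variables if v.kind == "genotype"}
        for st in self.subtypes:
            missing = cont - set(st.severity_curve)
            if missing:
                raise ValueError(f"subtype {st.id!r} lacks curves for {sorted(missing)}")
            for v, curve in st.severity_curve.items():
                need = 1 if _is_static(self.variables, v) else self.M
                if len(curve) < need:
                    raise ValueError(f"curve for {v!r} in {st.id!r} shorter than {need}")
            if set(st.genotype_frequencies) != loci:
                raise ValueError(f"subtype {st.id!r} genotype loci do not match variables")

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "M": self.M,
            "sigma": self.sigma,
            "seed": self.seed,
            "variables": [v.to_dict() for v in self.variables],
            "subtypes": [
                {
                    "id": s.id,
                    "mixing_proportion": s.mixing_proportion,
                    "severity_curve": {k: list(map(float, c)) for k, c in s.severity_curve.items()},
                    "male_fraction": s.male_fraction,
                    "genotype_frequencies": s.genotype_frequencies,
                }
                for s in self.subtypes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        return cls(
            N=int(d["N"]),
            M=int(d["M"]),
            sigma=float(d.get("sigma", 1.0)),
            seed=int(d.get("seed", 0)),
            variables=[VariableSpec.from_dict(v) for v in d["variables"]],
            subtypes=[
                SubtypeSpec(
                    id=s["id"],
                    mixing_proportion=float(s["mixing_proportion"]),
                    severity_curve=s["severity_curve"],
                    male_fraction=float(s.get("male_fraction", 0.5)),
                    genotype_frequencies=s.get("genotype_frequencies", {}),
                )
                for s in d["subtypes"]
            ],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _is_static(variables: list[VariableSpec], name: str) -> bool:
    for v in variables:
        if v.name == name:
            return v.static
    raise KeyError(name)


def generate_cohort(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[LongitudinalCohort, np.ndarray]:
    """Draw a cohort from the spec; returns the cohort and true subtype labels.

    All randomness flows from one generator seeded with ``seed`` (default:
    the spec's seed), so equal seeds give bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = len(spec.subtypes)
    props = np.array([s.mixing_proportion for s in spec.subtypes])
    labels = rng.choice(k, size=spec.N, p=props)

    values = np.zeros((spec.N, len(spec.variables), spec.M))
    for v, var in enumerate(spec.variables):
        if var.kind == "continuous":
            mu = np.zeros((k, spec.M))
            for j, st in enumerate(spec.subtypes):
                curve = st.severity_curve[var.name]
                if var.static:
                    mu[j, :] = norm.ppf(curve[0])
                else:
                    mu[j, :] = norm.ppf(curve[: spec.M])
            if var.static:
                eps = rng.standard_normal(spec.N)[:, None]
            else:
                eps = rng.standard_normal((spec.N, spec.M))
            z = mu[labels] + spec.sigma * eps
            values[:, v, :] = var.direction * z
        elif var.kind == "binary":
            frac = np.array([s.male_fraction for s in spec.subtypes])
            values[:, v, :] = (rng.random(spec.N) < frac[labels]).astype(float)[:, None]
        else:
            classes = list(var.genotype_classes)
            for j, st in enumerate(spec.subtypes):
                idx = np.flatnonzero(labels == j)
                if idx.size == 0:
                    continue
                freqs = st.genotype_frequencies[var.name]
                p = np.array([freqs.get(c, 0.0) for c in classes])
                draws = rng.choice(len(classes), size=idx.size, p=p / p.sum())
                values[idx, v, :] = draws[:, None]

    patient_ids = [f"P{i:04d}" for i in range(spec.N)]
    timepoints = ["bl"] + [f"y{j}" for j in range(1, spec.M)]
    cohort = LongitudinalCohort(patient_ids, timepoints, list(spec.variables), values)
    return cohort, labels


# ---------------------------------------------------------------------------
# Packaged fixture: a cohort shaped like a 5-year Parkinson's progression
# study -- 194 complete-case patients, 16 evolving clinical scales in six
# domains, age and gender, four biallelic genotype loci, three subtypes
# (mixed / mild / severe).
# ---------------------------------------------------------------------------

_DOMAINS: list[tuple[str, str, int]] = [
    # (variable, domain, direction)
    ("UPDRS1", "PD severity", +1),
    ("UPDRS2", "PD severity", +1),
    ("UPDRS3", "PD severity", +1),
    ("TUPDRS", "PD severity", +1),
    ("SEADL", "Disability", -1),
    ("HVLT", "Cognition", -1),
    ("JOLO", "Cognition", -1),
    ("SFT", "Cognition", -1),
    ("LNS", "Cognition", -1),
    ("SDM", "Cognition", -1),
    ("MOCA", "Cognition", -1),
    ("SCOPA", "Autonomic", +1),
    ("ESS", "Sleep", +1),
    ("RBDQ", "Sleep", +1),
    ("GDS", "Mental Health", +1),
    ("STAI", "Mental Health", +1),
]

_LOCI = ("G1", "G2", "G3", "G4")

# qualitative per-domain exceedance curves over 5 yearly visits
_CURVES: dict[str, dict[str, list[float]]] = {
    "mixed": {
        "PD severity": [0.72, 0.75, 0.78, 0.80, 0.82],
        "Disability": [0.65, 0.70, 0.74, 0.78, 0.80],
        "Cognition": [0.20, 0.20, 0.22, 0.23, 0.25],
        "Autonomic": [0.78, 0.80, 0.82, 0.83, 0.85],
        "Sleep": [0.78, 0.80, 0.80, 0.82, 0.84],
        "Mental Health": [0.80, 0.80, 0.82, 0.83, 0.85],
    },
    "mild": {
        "PD severity": [0.22, 0.24, 0.26, 0.28, 0.30],
        "Disability": [0.25, 0.26, 0.28, 0.30, 0.32],
        "Cognition": [0.28, 0.28, 0.30, 0.30, 0.32],
        "Autonomic": [0.25, 0.26, 0.28, 0.28, 0.30],
        "Sleep": [0.25, 0.26, 0.26, 0.28, 0.30],
        "Mental Health": [0.22, 0.24, 0.25, 0.26, 0.28],
    },
    "severe": {
        "PD severity": [0.75, 0.80, 0.84, 0.87, 0.90],
        "Disability": [0.72, 0.76, 0.80, 0.84, 0.88],
        "Cognition": [0.78, 0.80, 0.84, 0.86, 0.90],
        "Autonomic": [0.58, 0.60, 0.62, 0.64, 0.66],
        "Sleep": [0.60, 0.62, 0.62, 0.64, 0.66],
        "Mental Health": [0.58, 0.60, 0.62, 0.63, 0.65],
    },
}

_AGE = {"mixed": [0.35], "mild": [0.50], "severe": [0.75]}
_MALE = {"mixed": 0.30, "mild": 0.50, "severe": 0.72}
_GENO = {
    "mixed": {
        "G1": {"CC": 0.50, "CT": 0.40, "TT": 0.10},
        "G2": {"CC": 0.60, "CT": 0.30, "TT": 0.10},
        "G3": {"CC": 0.30, "CT": 0.50, "TT": 0.20},
        "G4": {"CC": 0.40, "CT": 0.40, "TT": 0.20},
    },
    "mild": {
        "G1": {"CC": 0.20, "CT": 0.50, "TT": 0.30},
        "G2": {"CC": 0.25, "CT": 0.50, "TT": 0.25},
        "G3": {"CC": 0.40, "CT": 0.40, "TT": 0.20},
        "G4": {"CC": 0.30, "CT": 0.50, "TT": 0.20},
    },
    "severe": {
        "G1": {"CC": 0.30, "CT": 0.30, "TT": 0.40},
        "G2": {"CC": 0.10, "CT": 0.40, "TT": 0.50},
        "G3": {"CC": 0.20, "CT": 0.30, "TT": 0.50},
        "G4": {"CC": 0.20, "CT": 0.20, "TT": 0.60},
    },
}
_PROPORTIONS = {"mixed": 0.30, "mild": 0.45, "severe": 0.25}


def ppmi_like_variables(include_genetic: bool = True) -> list[VariableSpec]:
    out = [
        VariableSpec(name, domain, "continuous", direction=d) for name, domain, d in _DOMAINS
    ]
    out.append(VariableSpec("age", "Demographic", "continuous", direction=+1, static=True))
    out.append(VariableSpec("gender", "Demographic", "binary", static=True))
    if include_genetic:
        out.extend(
            VariableSpec(g, "Genetic", "genotype", static=True, genotype_classes=("CC", "CT", "TT"))
            for g in _LOCI
        )
    return out


def ppmi_like_spec(
    n: int = 194,
    sigma: float = 1.0,
    seed: int = 0,
    include_genetic: bool = True,
) -> SimulationSpec:
    """Packaged fixture spec for a 3-subtype, 5-visit progression cohort.

    The mild subtype sits below the population baseline median everywhere;
    the severe subtype above it with rising curves, older and predominantly
    male; the mixed subtype combines severe motor/autonomic/sleep/mental
    impairment with good cognition, younger and predominantly female.
    """
    variables = ppmi_like_variables(include_genetic)
    subtypes = []
    for name in ("mixed", "mild", "severe"):
        curves: dict[str, list[float]] = {}
        for var, domain, _ in _DOMAINS:
            curves[var] = list(_CURVES[name][domain])
        curves["age"] = list(_AGE[name])
        subtypes.append(
            SubtypeSpec(
                id=name,
                mixing_proportion=_PROPORTIONS[name],
                severity_curve=curves,
                male_fraction=_MALE[name],
                genotype_frequencies=_GENO[name] if include_genetic else {},
            )
        )
    return SimulationSpec(N=n, M=5, subtypes=subtypes, variables=variables, sigma=sigma, seed=seed)
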