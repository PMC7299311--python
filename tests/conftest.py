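import numpy as np
import pytest

from trajpc import LongitudinalCohort, VariableSpec


def cont(name, direction=+1, domain="Clinical", static=False):
    return VariableSpec(name, domain, "continuous", direction=direction, static=static)


def binary(name, domain="Demographic"):
    return VariableSpec(name, domain, "binary", static=True)


def genotype(name, classes=("CC", "CT", "TT"), domain="Genetic"):
    return VariableSpec(name, domain, "genotype", static=True, genotype_classes=classes)


def make_cohort(values, variables, timepoints=None, patient_ids=None, mask=None):
    """Dense cohort from an N x V x M array."""
    values = np.asarray(values, dtype=float)
    n, _, m = values.shape
    return LongitudinalCohort(
        patient_ids=patient_ids or [f"p{i}" for i in range(n)],
        timepoints=timepoints or (["bl"] + [f"y{t}" for t in range(1, m)]),
        variables=variables,
        values=values,
        mask=mask,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_var_cohort():
    """3 patients x 2 continuous variables x 2 timepoints, no missing data."""
    vals = np.array(
        [
            [[1.0, 2.0], [10.0, 11.0]],
            [[3.0, 4.0], [12.0, 13.0]],
            [[5.0, 6.0], [14.0, 15.0]],
        ]
    )
    return make_cohort(vals, [cont("a"), cont("b", direction=-1)])
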