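import numpy as np
import pytest

from cllburden.cohort import CohortSpec, clinical_to_frame, generate_cohort
from cllburden.survival import SurvivalData


def random_survival(rng, n, censor_frac=0.3, tie_prob=0.0):
    """Small random right-censored dataset, optionally with tied times."""
    t = rng.exponential(1.0, n)
    if tie_prob > 0:
        t = np.round(t, 1)  # coarse rounding creates genuine ties
    e = rng.random(n) >= censor_frac
    return SurvivalData(t, e)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def planted_spec():
    """Small cohort with two deleterious genes and three null genes."""
    genes = ("G1", "G2", "N1", "N2", "N3")
    return CohortSpec(
        n_patients=300, series_sizes=(300,), gene_panel=genes,
        mutation_freq={"G1": 0.2, "G2": 0.2, "N1": 0.15, "N2": 0.15, "N3": 0.15},
        hazard_ratio={"G1": 3.0, "G2": 3.0},
        censoring_rate=0.2, treated_fraction=0.0, seed=42)


@pytest.fixture
def planted_cohort(planted_spec):
    records, matrix = generate_cohort(planted_spec)
    clinical = clinical_to_frame(records)
    surv = SurvivalData.from_frame(clinical)
    return clinical, matrix, surv
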