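import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from pnetcohort.harmonize import CohortMatrix


def make_matrix(profiles, genes=None):
    """CohortMatrix from {patient_id: (lesion_type, set-of-mutated-genes)}."""
    if genes is None:
        genes = sorted({g for _, gs in profiles.values() for g in gs})
    patients = sorted(profiles)
    ind = pd.DataFrame(0, index=pd.Index(patients, name="patient_id"), columns=list(genes))
    for p, (_, gs) in profiles.items():
        for g in gs:
            ind.at[p, g] = 1
    stratum = pd.Series({p: lesion for p, (lesion, _) in profiles.items()}).reindex(patients)
    return CohortMatrix(indicator=ind, stratum=stratum)


@pytest.fixture
def toy_matrix():
    """10-patient cohort with hand-tabulated mutation profiles."""
    profiles = {
        "P01": ("primary", {"MEN1"}),
        "P02": ("primary", {"MEN1", "DAXX"}),
        "P03": ("primary", {"ATRX"}),
        "P04": ("primary", {"MEN1", "ATRX", "PTEN"}),
        "P05": ("primary", set()),
        "P06": ("primary", {"PTEN"}),
        "P07": ("metastasis", {"TP53", "KRAS"}),
        "P08": ("metastasis", {"MEN1"}),
        "P09": ("metastasis", {"TP53"}),
        "P10": ("metastasis", set()),
    }
    genes = ["ATRX", "DAXX", "KRAS", "MEN1", "PTEN", "TP53"]
    return make_matrix(profiles, genes)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared across read-only tests."""
    from pnetcohort.synthetic import default_config, generate_cohort

    config = default_config(seed=20240917)
    config.n_primary, config.n_metastasis = 300, 150
    return generate_cohort(config)
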