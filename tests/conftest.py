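import numpy as np
import pandas as pd
import pytest

from thrombopaf import (
    CaseCohortSample,
    CohortConfig,
    Panel,
    SnpDef,
    sample_case_cohort,
    simulate_cohort,
)

# carrier prevalence 0.2 at Hardy-Weinberg
Q_PREV20 = 1 - np.sqrt(0.8)


@pytest.fixture(scope="session")
def single_snp_panel():
    return Panel([
        SnpDef("rs0", "TEST", risk_allele_freq=Q_PREV20,
               log_hr_female=np.log(2), log_hr_male=np.log(2)),
    ])


@pytest.fixture(scope="session")
def two_snp_panel():
    """One causal SNP (HR 2) and one null SNP (HR 1)."""
    return Panel([
        SnpDef("rsA", "G1", risk_allele_freq=Q_PREV20,
               log_hr_female=np.log(2), log_hr_male=np.log(2)),
        SnpDef("rsB", "G2", risk_allele_freq=0.3),
    ])


@pytest.fixture(scope="session")
def sim_casecohort(single_snp_panel):
    """n=20,000 source cohort with a 2,000-strong subcohort."""
    cfg = CohortConfig(
        n_individuals=20_000, panel=single_snp_panel, seed=11,
        baseline_lambda=2.5e-5,
    )
    cohort = simulate_cohort(cfg)
    return sample_case_cohort(cohort, 2_000, seed=5)


@pytest.fixture()
def tiny_sample():
    """Six individuals, tied event ages, unbalanced binary exposure."""
    df = pd.DataFrame({
        "id": range(6),
        "sex": ["female"] * 6,
        "entry_age": [40.0, 42.0, 45.0, 41.0, 43.0, 44.0],
        "exit_age": [50.0, 50.0, 55.0, 55.0, 60.0, 62.0],
        "event": [1, 1, 1, 1, 0, 0],
        "bmi": 25.0,
        "in_subcohort": True,
        "is_case": [True, True, True, True, False, False],
    })
    return CaseCohortSample(df, subcohort_size=6, source_size=6)


@pytest.fixture()
def tiny_exposure():
    return np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0])


def make_sample(df: pd.DataFrame) -> CaseCohortSample:
    """Wrap a hand-built frame (everyone in the subcohort) as a sample."""
    df = df.copy()
    if "in_subcohort" not in df.columns:
        df["in_subcohort"] = True
    df["is_case"] = df["event"].astype(bool)
    return CaseCohortSample(
        df, subcohort_size=int(df["in_subcohort"].sum()), source_size=len(df)
    )
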