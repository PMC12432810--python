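"""Shared fixtures: small seeded synthetic cohorts."""

import pandas as pd
import pytest

from abomics.methylation import beta_to_m
from abomics.simulate import SimulationConfig, generate_cohort, null_cohort


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a strong promoter methylation effect (n=400)."""
    cfg = SimulationConfig(
        n_donors=400, n_cpgs=60, n_promoter_cpgs=5, n_proteins=12,
        effect_XM=0.8, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_small():
    """Cohort with all blood-group effects zeroed (n=300)."""
    cfg = SimulationConfig(
        n_donors=300, n_cpgs=100, n_promoter_cpgs=5, n_proteins=20, seed=13
    )
    return null_cohort(cfg)


@pytest.fixture(scope="session")
def typed_calls(effect_cohort):
    from abomics.blood_groups import type_cohort

    return type_cohort(effect_cohort.genotypes)


def mediation_covariates(cohort):
    """(cov_xm, cov_xmy) frames for the default mediation model."""
    cells = [c for c in cohort.covariates.columns if c.startswith("cell_")]
    cov_xm = pd.get_dummies(
        cohort.covariates[["sex", "age"] + cells], columns=["sex"],
        drop_first=True, dtype=float,
    )
    cov_xmy = pd.get_dummies(
        cohort.covariates[["sex", "age"]], columns=["sex"],
        drop_first=True, dtype=float,
    )
    return cov_xm, cov_xmy


def m_values(cohort):
    """Methylation matrix on the logit2 (M) scale."""
    return pd.DataFrame(
        beta_to_m(cohort.methylation.to_numpy()),
        index=cohort.methylation.index,
        columns=cohort.methylation.columns,
    )
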