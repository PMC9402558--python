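import numpy as np
import pandas as pd
import pytest

from longlme.synthetic_data import (
    GenerativeConfig,
    LongitudinalDataset,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cohort_small():
    """A ~200-subject five-group cohort from the default generative model."""
    return generate_cohort(GenerativeConfig().scaled(0.3), seed=42)


@pytest.fixture(scope="session")
def cohort_full():
    """The default balanced 670-subject cohort (four visits, no dropout)."""
    return generate_cohort(GenerativeConfig(), seed=7)


@pytest.fixture(scope="session")
def fit_small(cohort_small):
    from longlme.lme_core import ModelSpec, build_design, fit_lme

    return fit_lme(build_design(cohort_small, ModelSpec()))


def make_paired(n_subjects, time_effect, sd_subject, sd_resid, seed):
    """Balanced two-visit random-intercept data (the classical paired design)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0.0, sd_subject)
        for t in (0.0, 1.0):
            rows.append(
                dict(
                    subject_id=f"S{i:03d}",
                    group="sHC",
                    visit_time=t,
                    hv=time_effect * t + b + rng.normal(0.0, sd_resid),
                    icv=0.0,
                    baseline_age=70.0,
                    sex=0,
                    apoe=0,
                )
            )
    return LongitudinalDataset(pd.DataFrame(rows), standardized=True)


def make_balanced_oneway(n_subjects, n_visits, mu, sd_subject, sd_resid, seed):
    """Balanced one-way random-effects data (intercept-only fixed part)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0.0, sd_subject)
        for j in range(n_visits):
            rows.append(
                dict(
                    subject_id=f"S{i:03d}",
                    group="sHC",
                    visit_time=float(j),
                    hv=mu + b + rng.normal(0.0, sd_resid),
                    icv=0.0,
                    baseline_age=70.0,
                    sex=0,
                    apoe=0,
                )
            )
    return LongitudinalDataset(pd.DataFrame(rows), standardized=True)


def null_mci_config(n_per_group=40):
    """Two-group (sMCI/cMCI) configuration with equal atrophy slopes."""
    from dataclasses import replace

    base = GenerativeConfig()
    smci = [p for p in base.profiles if p.name == "sMCI"][0]
    cmci = [p for p in base.profiles if p.name == "cMCI"][0]
    profiles = (
        replace(smci, n_subjects=n_per_group, slope_offset=-0.05),
        replace(cmci, n_subjects=n_per_group, slope_offset=-0.05,
                intercept_offset=smci.intercept_offset),
    )
    return replace(base, profiles=profiles)
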