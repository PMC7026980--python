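import numpy as np
import pandas as pd
import pytest

from pmcox.simulate import LEAF_CAUSES, SimulationConfig, simulate_study

ALL_LEAVES = list(LEAF_CAUSES)


def uniform_rr(value: float, accidental: float = 1.0) -> dict:
    """Same planted RR for every non-accidental leaf cause."""
    return {c: (accidental if c == "accidental" else value) for c in ALL_LEAVES}


def tiny_config(**kw) -> SimulationConfig:
    """A seconds-scale world; correlation targets relaxed for few-ZIP worlds."""
    base = dict(
        n_beneficiaries=400,
        n_zips=8,
        n_months=48,
        subgroup_modifiers={},
        target_corr_pm_no2=0.40,
        target_corr_pm_o3=0.15,
        base_monthly_hazard_65=0.004,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_study():
    """Small deterministic study shared by read-only tests."""
    return simulate_study(tiny_config(), seed=101)


@pytest.fixture(scope="session")
def medium_study():
    """A moderately sized default-world study (full 108 months, 60 ZIPs)."""
    cfg = SimulationConfig(n_beneficiaries=6000, n_zips=60, subgroup_modifiers={})
    return simulate_study(cfg, seed=202)


def toy_cohort():
    """Three-beneficiary hand-built cohort for expansion semantics."""
    from pmcox.months import month_index

    jan2000 = month_index("2000-01")
    cohort = pd.DataFrame(
        {
            "id": [1, 2, 3],
            # 70y, 89y10m (crosses 90 mid-follow-up), 75y
            "birth_month": [
                jan2000 - 70 * 12,
                jan2000 - (89 * 12 + 10),
                jan2000 - 75 * 12,
            ],
            "sex": ["F", "M", "F"],
            "race": ["White", "White", "Black"],
            "follow_up_start": [jan2000] * 3,
            "follow_up_end": [jan2000 + 2, jan2000 + 5, jan2000 + 2],
            "death_month": [jan2000 + 2, np.nan, np.nan],
            "icd10_cause": pd.array(["I21", None, None], dtype="string"),
        }
    )
    residence = pd.DataFrame(
        {"id": [1, 2, 3], "start_month": [jan2000] * 3, "zip": [11, 11, 12]}
    )
    return cohort, residence, jan2000


def toy_covariates(cohort, value=10.0, n_months=18):
    """Constant exposure matrix aligned to the cohort's earliest entry."""
    start = int(cohort["follow_up_start"].min())
    return {"x": np.full((len(cohort), n_months), value)}, start
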