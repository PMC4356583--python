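"""Shared fixtures: hand-built records and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ihtsa import synth
from ihtsa.registry import Cohort, SCHEMA

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_RECORD_DEFAULTS = {
    "recipient_age": 54.0,
    "recipient_sex": "male",
    "recipient_height": 174.0,
    "recipient_weight": 77.0,
    "diagnosis": "ischemic_cm",
    "diabetes": 0.0,
    "hypertension": 0.0,
    "infection_2wk": 0.0,
    "antiarrhythmics": 0.0,
    "amiodarone": 0.0,
    "prior_transfusion": 0.0,
    "prior_transplant": 0.0,
    "prior_cardiac_surgery": 0.0,
    "icu": 0.0,
    "ventilator": 0.0,
    "ecmo": 0.0,
    "vad": 0.0,
    "era": "2006-2010",
    "spp": 42.0,
    "pvr": 2.1,
    "creatinine": 106.0,
    "bilirubin": 0.8,
    "pra_gt10": 0.0,
    "hladr_mismatch": 1,
    "recipient_bg": "A",
    "donor_age": 34.0,
    "donor_sex": "male",
    "donor_height": 176.0,
    "donor_weight": 75.0,
    "ischemia_min": 183.0,
    "codd_head_trauma": 1.0,
    "codd_cva": 0.0,
    "donor_bg": "A",
    "followup_years": 5.0,
    "death": 0.0,
}


def make_record(**overrides) -> dict:
    """One complete transplant record with field overrides."""
    rec = dict(_RECORD_DEFAULTS)
    rec.update(overrides)
    return rec


def make_cohort(rows: list[dict], name: str = "test") -> Cohort:
    df = pd.DataFrame(rows, columns=[v.name for v in SCHEMA])
    for var in SCHEMA:
        if var.kind != "categorical":
            df[var.name] = df[var.name].astype(float)
        else:
            df[var.name] = df[var.name].astype(object).where(df[var.name].notna(), None)
    return Cohort(df, name)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Complete synthetic cohort (n=300), default study conditions."""
    cohort, _ = synth.generate_cohort(synth.GeneratorConfig(n=300, seed=7))
    return cohort


@pytest.fixture(scope="session")
def masked_cohort() -> Cohort:
    """n=400 cohort with the default item-level missingness injected."""
    cfg = synth.GeneratorConfig(n=400, seed=11)
    cohort, _ = synth.generate_cohort(cfg)
    return synth.inject_missingness(cohort, cfg)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def cohort_factory():
    return make_cohort
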