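"""Shared fixtures: synthetic patients and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from sinoradiomics import cohort as co
from sinoradiomics import features as ft

#: Table 1 local-control means used as fitting ground truth across tests.
CONTROL = co.TABLE_CONTROL.means


@pytest.fixture(scope="session")
def noiseless_cfg() -> co.AcquisitionConfig:
    return co.AcquisitionConfig().without_noise()


@pytest.fixture(scope="session")
def noiseless_patient(noiseless_cfg) -> co.SyntheticPatient:
    """One noiseless synthetic patient (control-group draw)."""
    record = co.sample_cohort(n_control=1, n_failure=1, seed=42)[0]
    return co.synthesize_patient(record, noiseless_cfg, seed=7)


@pytest.fixture(scope="session")
def noiseless_vector(noiseless_patient) -> ft.PatientFeatureVector:
    p = noiseless_patient
    return ft.extract_all(
        patient_id=p.patient_id, t2=p.t2, dwi=p.dwi,
        asl_control=p.asl_control, asl_label=p.asl_label,
        tumor_mask=p.tumor_mask, muscle_mask=p.muscle_mask,
        clinical=p.clinical,
    )


@pytest.fixture(scope="session")
def cohort36():
    """A rendered 36-patient cohort under the default (noisy) acquisition."""
    return co.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def cohort36_table(cohort36):
    return co.extract_feature_table(cohort36)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
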