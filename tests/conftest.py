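import numpy as np
import pytest

from bpbench import preprocess
from bpbench.synth import (CohortSpec, PulseSpec, generate_cohort,
                           generate_pulse_train)


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless 6 s paired record at 125 Hz, 60 BPM, 135/65 mmHg."""
    spec = PulseSpec(heart_rate=60, sbp=135, dbp=65, notch_delay=0.30,
                     notch_depth=0.35, ppg_delay=0.0)
    return generate_pulse_train(spec, 6.0, 125.0, seed=1)


@pytest.fixture(scope="session")
def clean_segment(clean_record):
    seg = preprocess.Segment(
        subject_id="s0", record_id="r0", segment_index=0,
        fs=clean_record.fs, ppg=clean_record.ppg.copy(),
        abp=clean_record.abp.copy())
    return seg


@pytest.fixture(scope="session")
def artifact_cohort():
    """Cohort with 20% tagged artifact segments (ground truth in meta)."""
    spec = CohortSpec(n_subjects=40, segments_per_subject=5,
                      artifact_fraction=0.2, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def artifact_pipeline(artifact_cohort):
    return preprocess.run_pipeline(artifact_cohort)


@pytest.fixture(scope="session")
def correlated_cohort():
    """Strong within-subject label correlation, 8 segments per subject."""
    spec = CohortSpec(n_subjects=25, segments_per_subject=8,
                      within_subject_sd=1.0, seed=11)
    return generate_cohort(spec)


def make_cycles(onsets, peaks, offsets, fs=125.0):
    return preprocess.CycleSet(onsets=np.asarray(onsets),
                               peaks=np.asarray(peaks),
                               offsets=np.asarray(offsets), fs=fs)
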