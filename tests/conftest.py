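import numpy as np
import pandas as pd
import pytest

from frailwear import (
    CohortConfig,
    FeatureMatrix,
    ParticipantProfile,
    PhaseInterval,
    SegmentationConfig,
    Session,
    clean,
    generate_cohort,
)
from frailwear.features import FEATURE_NAMES, META_COLUMNS, build_matrix
from frailwear.sessions import PHASE_NAMES, SAMPLE_COLUMNS


def make_session(n_samples=100, rate=25.0, phase_bounds=None, age=75,
                 label="pre-frail", channel_values=None, hr=80,
                 participant_id="T001"):
    """Hand-built session: constant channels unless overridden, one or more
    phases covering the sample span."""
    t = np.arange(n_samples) / rate
    data = {"t": t}
    for ch in SAMPLE_COLUMNS[1:-1]:
        v = (channel_values or {}).get(ch, 0.0)
        data[ch] = np.full(n_samples, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)
    hr_arr = np.full(n_samples, hr, dtype=int) if np.isscalar(hr) else np.asarray(hr, int)
    data["hr"] = hr_arr
    end = n_samples / rate
    if phase_bounds is None:
        phase_bounds = [(1, 0.0, end)]
    phases = [PhaseInterval(pid, PHASE_NAMES[pid], a, b) for pid, a, b in phase_bounds]
    profile = ParticipantProfile(participant_id, age, "F", label, 50.0)
    return Session(profile=profile, sampling_rate=rate,
                   samples=pd.DataFrame(data, columns=list(SAMPLE_COLUMNS)),
                   phases=phases)


def matrix_from_arrays(X, y, feature_names=None):
    """Wrap bare arrays in a FeatureMatrix (synthetic metadata columns)."""
    X = np.asarray(X, dtype=float)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    rec = pd.DataFrame(X, columns=names)
    rec.insert(0, "session_id", [f"S{i}" for i in range(len(X))])
    rec.insert(1, "phase_id", 1)
    rec.insert(2, "phase", "sitting")
    rec.insert(3, "unit", "phase")
    rec.insert(4, "label", list(y))
    return FeatureMatrix(rec, list(names))


@pytest.fixture(scope="session")
def small_cohort():
    """Seven cleaned synthetic sessions (2 frail / 3 pre-frail / 2 non-frail)."""
    cfg = CohortConfig(n_per_class={"frail": 2, "pre-frail": 3, "non-frail": 2}, seed=123)
    return [clean(s, target_rate=25.0)[0] for s in generate_cohort(cfg)]


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """Phase-level 98 x 56 analysis matrix of the small cohort."""
    return build_matrix(small_cohort, SegmentationConfig(), unit="phase")


@pytest.fixture(scope="session")
def separable_cohort():
    """Study-sized cleaned cohort at high class separation."""
    cfg = CohortConfig(separation=2.0, seed=11)
    return [clean(s, target_rate=25.0)[0] for s in generate_cohort(cfg)]
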