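"""Session data model, on-disk format and cleaning.

A *session* is one participant's recording of the supermarket-shopping
protocol: a uniformly timestamped stream of seven channels (tri-axial
accelerometer, tri-axial gyroscope, heart rate) annotated with the fourteen
protocol phases, plus the participant header (age, sex, Fried frailty label,
walking distance to the supermarket).

On disk a cohort directory holds three plain-text files per session::

    <participant_id>_profile.json   # header record, schema-versioned
    <participant_id>_samples.csv    # t, acc_x..gyr_z (float), hr (int)
    <participant_id>_phases.csv     # phase_id, name, start_t, end_t

Cleaning consists of heart-rate anomaly removal (age-predicted maximum
HRmax = 220 - age; values above it are masked and re-interpolated, motion
channels untouched) followed by linear resampling onto a uniform grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ResamplingError

SCHEMA_VERSION = 1

#: The three Fried phenotype classes, in canonical order.
FRIED_LABELS = ("non-frail", "pre-frail", "frail")

#: The fourteen protocol phases of the shopping activity, in execution order.
PHASE_NAMES: dict[int, str] = {
    1: "sitting",
    2: "standing",
    3: "walking_to_supermarket",
    4: "in_supermarket",
    5: "looking_for_product",
    6: "picking_product",
    7: "going_to_checkout",
    8: "in_checkout",
    9: "paying",
    10: "go_to_exit",
    11: "in_outside",
    12: "coming_back",
    13: "standing_at_start",
    14: "sitting_back",
}
PHASE_IDS: dict[str, int] = {v: k for k, v in PHASE_NAMES.items()}

MOTION_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
CHANNELS = MOTION_CHANNELS + ("hr",)
SAMPLE_COLUMNS = ("t",) + CHANNELS


@dataclass(frozen=True)
class ParticipantProfile:
    """Header record for one study participant."""

    participant_id: str
    age: int
    sex: str
    fried_label: str
    center_distance: float  # metres from community centre to supermarket

    def __post_init__(self) -> None:
        if not 65 <= self.age <= 90:
            raise FormatError(f"age {self.age} outside the inclusion range [65, 90]")
        if self.fried_label not in FRIED_LABELS:
            raise FormatError(
                f"unknown Fried label {self.fried_label!r}; expected one of {FRIED_LABELS}"
            )
        if self.center_distance <= 0:
            raise FormatError("center_distance must be positive")

    @property
    def hr_max(self) -> int:
        """Age-predicted maximal heart rate (220 - age), the anomaly threshold."""
        return 220 - self.age


@dataclass(frozen=True)
class PhaseInterval:
    """Half-open time interval [start_t, end_t) labelled with one protocol phase."""

    phase_id: int
    name: str
    start_t: float
    end_t: float

    def __post_init__(self) -> None:
        if self.phase_id not in PHASE_NAMES:
            raise FormatError(f"phase_id {self.phase_id} outside 1..14")
        if PHASE_NAMES[self.phase_id] != self.name:
            raise FormatError(
                f"phase name {self.name!r} does not match id {self.phase_id} "
                f"({PHASE_NAMES[self.phase_id]!r})"
            )
        if not self.start_t < self.end_t:
            raise FormatError(f"phase {self.name!r}: start_t must precede end_t")


@dataclass
class Session:
    """One participant's labelled, phase-annotated multichannel recording.

    ``samples`` is a DataFrame with columns ``t, acc_x, acc_y, acc_z, gyr_x,
    gyr_y, gyr_z, hr``; timestamps are seconds since session start and must be
    non-decreasing. ``phases`` partition ``[0, phases[-1].end_t)``.
    """

    profile: ParticipantProfile
    sampling_rate: float
    samples: pd.DataFrame
    phases: list[PhaseInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(
                f"session {self.profile.participant_id}: missing channel column(s) {missing}"
            )
        t = self.samples["t"].to_numpy()
        if len(t) and np.any(np.diff(t) < 0):
            raise FormatError(
                f"session {self.profile.participant_id}: non-monotone timestamps"
            )
        for prev, cur in zip(self.phases, self.phases[1:]):
            if not np.isclose(prev.end_t, cur.start_t):
                raise FormatError(
                    f"session {self.profile.participant_id}: phases "
                    f"{prev.name!r} and {cur.name!r} are not contiguous"
                )

    @property
    def session_id(self) -> str:
        return self.profile.participant_id

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def phase_slice(self, phase: PhaseInterval) -> pd.DataFrame:
        """Samples falling inside one phase interval (half-open)."""
        t = self.samples["t"].to_numpy()
        lo, hi = np.searchsorted(t, [phase.start_t, phase.end_t], side="left")
        return self.samples.iloc[lo:hi]


# ---------------------------------------------------------------------------
# On-disk format


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    """Write sessions to a cohort directory (three text files per session)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        pid = s.profile.participant_id
        header = {
            "schema_version": SCHEMA_VERSION,
            "participant_id": pid,
            "age": s.profile.age,
            "sex": s.profile.sex,
            "fried_label": s.profile.fried_label,
            "center_distance": s.profile.center_distance,
            "sampling_rate": s.sampling_rate,
        }
        (path / f"{pid}_profile.json").write_text(json.dumps(header, indent=1))
        # %.17g guarantees exact float64 round-trip through the text format
        s.samples.to_csv(path / f"{pid}_samples.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            [
                {"phase_id": p.phase_id, "name": p.name, "start_t": p.start_t, "end_t": p.end_t}
                for p in s.phases
            ],
            columns=["phase_id", "name", "start_t", "end_t"],
        ).to_csv(path / f"{pid}_phases.csv", index=False, float_format="%.17g")


def read_sessions(path: str | Path) -> list[Session]:
    """Read every session stored in a cohort directory.

    Raises :class:`FormatError` identifying the offending file and record on
    any schema violation (missing channel column, unknown phase name,
    non-monotone timestamps).
    """
    path = Path(path)
    sessions = []
    for header_file in sorted(path.glob("*_profile.json")):
        header = json.loads(header_file.read_text())
        pid = header["participant_id"]
        profile = ParticipantProfile(
            participant_id=pid,
            age=int(header["age"]),
            sex=header["sex"],
            fried_label=header["fried_label"],
            center_distance=float(header["center_distance"]),
        )
        samples = pd.read_csv(path / f"{pid}_samples.csv", float_precision="round_trip")
        missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing:
            raise FormatError(f"{pid}_samples.csv: missing channel column(s) {missing}")
        phases_df = pd.read_csv(path / f"{pid}_phases.csv", float_precision="round_trip")
        phases = []
        for rec in phases_df.itertuples(index=False):
            if rec.name not in PHASE_IDS:
                raise FormatError(
                    f"{pid}_phases.csv: unknown phase name {rec.name!r}"
                )
            phases.append(
                PhaseInterval(int(rec.phase_id), rec.name, float(rec.start_t), float(rec.end_t))
            )
        samples = samples.astype({c: float for c in ("t",) + MOTION_CHANNELS} | {"hr": int})
        sessions.append(
            Session(
                profile=profile,
                sampling_rate=float(header["sampling_rate"]),
                samples=samples,
                phases=phases,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Cleaning


def filter_hr_anomalies(session: Session) -> tuple[Session, int]:
    """Remove physiologically impossible heart-rate values.

    A value is anomalous when it exceeds the age-predicted maximum
    ``220 - age`` (equality is retained: the maximum is attainable).
    Anomalous values are masked and linearly re-interpolated from the
    surrounding valid readings, leaving the motion channels untouched, so a
    single-channel artefact does not fragment motion windows. Returns the
    cleaned session and the number of values replaced; retained + replaced
    equals the input sample count.
    """
    threshold = session.profile.hr_max
    hr = session.samples["hr"].to_numpy(dtype=float)
    bad = hr > threshold
    n_dropped = int(bad.sum())
    if n_dropped == 0:
        return session, 0
    good = ~bad
    t = session.samples["t"].to_numpy()
    if good.any():
        hr[bad] = np.interp(t[bad], t[good], hr[good])
    else:  # no valid reading left: fall back to the threshold itself
        hr[:] = threshold
    samples = session.samples.copy()
    samples["hr"] = np.minimum(np.rint(hr), threshold).astype(int)
    return replace(session, samples=samples), n_dropped


def resample(session: Session, target_rate: float) -> Session:
    """Linearly resample every channel onto a uniform grid at ``target_rate``.

    The grid starts at the first timestamp and steps by ``1/target_rate`` up
    to the last timestamp (which is hit exactly when the span is an integer
    number of steps). Heart rate is rounded back to integer bpm. Requires at
    least two samples.
    """
    if target_rate <= 0:
        raise ResamplingError("target_rate must be positive")
    if session.n_samples < 2:
        raise ResamplingError(
            f"session {session.session_id}: need >= 2 samples to resample, "
            f"got {session.n_samples}"
        )
    t = session.samples["t"].to_numpy()
    dt = 1.0 / target_rate
    n_new = int(np.floor((t[-1] - t[0]) * target_rate + 1e-9)) + 1
    t_new = t[0] + np.arange(n_new) * dt
    out = {"t": t_new}
    for ch in CHANNELS:
        out[ch] = np.interp(t_new, t, session.samples[ch].to_numpy(dtype=float))
    samples = pd.DataFrame(out, columns=list(SAMPLE_COLUMNS))
    samples["hr"] = np.rint(samples["hr"]).astype(int)
    return replace(session, sampling_rate=float(target_rate), samples=samples)


def clean(session: Session, target_rate: float | None = None) -> tuple[Session, int]:
    """Fixed cleaning order: HR-anomaly filtering, then resampling."""
    cleaned, n_dropped = filter_hr_anomalies(session)
    if target_rate is not None:
        cleaned = resample(cleaned, target_rate)
    return cleaned, n_dropped
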