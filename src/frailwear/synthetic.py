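"""Seeded synthetic cohorts of supermarket-shopping wearable sessions.

No public dataset exists for the instrumented shopping protocol, so this
module generates cohorts with the class structure, phase structure and
signal statistics the downstream analysis assumes:

* cohort composition defaults to 12 frail / 47 pre-frail / 19 non-frail
  participants aged 65-90, sampled at 25 Hz;
* heart rate is class-conditional: frail participants centre near 78 bpm
  with wide within-session wander (values roughly 50-100 bpm, session means
  below 88), non-frail participants centre near 92 bpm in a narrow 80-100
  band (session means above 88), and pre-frail participants sit at the
  midpoint of the two, consistent with an ordered phenotype;
* motion channels follow phase-conditional regimes: walking phases carry a
  periodic gait component whose cadence and amplitude depend on the frailty
  class, in-supermarket phases mix attenuated gait with reaching bursts,
  and sitting/standing phases are low-variance noise around the gravity
  baseline.

A single ``separation`` knob scales how far the class-conditional means sit
from their common centre: 0 collapses the classes onto one distribution,
1 is the default calibration, larger values make the cohort easier to
classify. All randomness flows from one root seed through
``numpy.random.SeedSequence`` spawning (one child per participant), so a
(config, seed) pair is a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .sessions import (
    CHANNELS,
    FRIED_LABELS,
    PHASE_NAMES,
    ParticipantProfile,
    PhaseInterval,
    SAMPLE_COLUMNS,
    Session,
)

#: Median phase durations in seconds (walking phases are derived from the
#: centre-to-supermarket distance instead; see ``_phase_durations``).
PHASE_DURATION_MEDIANS: dict[int, float] = {
    1: 15.0,   # sitting
    2: 8.0,    # standing
    3: None,   # walking_to_supermarket  (distance / gait speed)
    4: 20.0,   # in_supermarket
    5: 40.0,   # looking_for_product
    6: 8.0,    # picking_product
    7: 20.0,   # going_to_checkout
    8: 30.0,   # in_checkout (waiting in turn)
    9: 25.0,   # paying
    10: 15.0,  # go_to_exit
    11: 10.0,  # in_outside
    12: None,  # coming_back  (distance / gait speed)
    13: 8.0,   # standing_at_start
    14: 15.0,  # sitting_back
}

WALKING_PHASES = frozenset({3, 12})
SHOPPING_PHASES = frozenset({4, 5, 6, 7, 8, 9, 10, 11})
STATIC_PHASES = frozenset({1, 2, 13, 14})

#: Relative motion intensity of each phase regime.
_PHASE_GAIT_LEVEL = {**{p: 1.0 for p in WALKING_PHASES},
                     **{p: 0.6 for p in SHOPPING_PHASES},
                     **{p: 0.0 for p in STATIC_PHASES}}
#: Heart-rate elevation (bpm) above the resting baseline per regime.
_PHASE_HR_OFFSET = {**{p: 8.0 for p in WALKING_PHASES},
                    **{p: 5.0 for p in SHOPPING_PHASES},
                    **{p: 0.0 for p in STATIC_PHASES}}

_GRAVITY = 9.81  # device-unit baseline on the vertical accelerometer axis


@dataclass(frozen=True)
class HrModel:
    """Class-conditional heart-rate parameters (all in bpm)."""

    mean: float          # class-level resting mean
    subject_sd: float    # between-participant spread of the resting baseline
    wander_sd: float     # within-session smooth wander amplitude


@dataclass(frozen=True)
class MotionModel:
    """Class-conditional gait parameters for the motion channels.

    ``amplitude`` is the peak accelerometer deviation (device units) of the
    gait oscillation during walking; gyroscope amplitude is half of it.
    ``cadence`` is the step frequency in Hz. ``noise_sd`` is the white
    sensor-noise floor shared by all phases; setting both the amplitude and
    the noise to zero produces constant channels.
    """

    amplitude: float
    cadence: float
    noise_sd: float = 0.3
    gait_speed: float = 1.0  # m/s, converts centre distance to walking time


_DEFAULT_HR: dict[str, HrModel] = {
    "frail": HrModel(mean=78.0, subject_sd=5.0, wander_sd=9.0),
    "pre-frail": HrModel(mean=85.0, subject_sd=4.0, wander_sd=6.0),  # midpoint mixture
    "non-frail": HrModel(mean=92.0, subject_sd=3.0, wander_sd=3.5),
}

_DEFAULT_MOTION: dict[str, MotionModel] = {
    "frail": MotionModel(amplitude=1.0, cadence=1.5, gait_speed=0.7),
    "pre-frail": MotionModel(amplitude=1.5, cadence=1.75, gait_speed=0.95),
    "non-frail": MotionModel(amplitude=2.0, cadence=2.0, gait_speed=1.2),
}

_HR_CENTRE = 85.0      # grand mean the separation knob pivots around
_MOTION_CENTRE = {"amplitude": 1.5, "cadence": 1.75, "gait_speed": 0.95}


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort.

    ``separation`` rescales the class-conditional means about their common
    centre; ``anomaly_rate`` injects physically impossible heart-rate values
    (above 220 - age) at the given per-sample probability so the cleaning
    stage can be exercised (off by default).
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"frail": 12, "pre-frail": 47, "non-frail": 19}
    )
    sampling_rate: float = 25.0
    phase_duration_model: Mapping[int, float | None] = field(
        default_factory=lambda: dict(PHASE_DURATION_MEDIANS)
    )
    duration_sigma: float = 0.15  # lognormal sigma of phase durations
    hr_model: Mapping[str, HrModel] = field(default_factory=lambda: dict(_DEFAULT_HR))
    motion_model: Mapping[str, MotionModel] = field(
        default_factory=lambda: dict(_DEFAULT_MOTION)
    )
    separation: float = 1.0
    anomaly_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in FRIED_LABELS:
                raise ConfigurationError(
                    f"unknown frailty class {cls!r}; expected one of {FRIED_LABELS}"
                )
            if n < 0:
                raise ConfigurationError(f"n_per_class[{cls!r}] must be >= 0")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if set(self.phase_duration_model) != set(PHASE_NAMES):
            raise ConfigurationError("phase_duration_model must cover all 14 phases")
        if self.duration_sigma < 0 or self.anomaly_rate < 0:
            raise ConfigurationError("spreads and rates must be >= 0")
        for cls in FRIED_LABELS:
            if cls not in self.hr_model or cls not in self.motion_model:
                raise ConfigurationError(f"hr_model/motion_model missing class {cls!r}")

    def effective_hr(self, fried_label: str) -> HrModel:
        """HR model with the separation knob applied to the class mean."""
        m = self.hr_model[fried_label]
        return HrModel(
            mean=_HR_CENTRE + self.separation * (m.mean - _HR_CENTRE),
            subject_sd=m.subject_sd,
            wander_sd=m.wander_sd,
        )

    def effective_motion(self, fried_label: str) -> MotionModel:
        m = self.motion_model[fried_label]
        s = self.separation
        return MotionModel(
            amplitude=max(0.0, _MOTION_CENTRE["amplitude"] + s * (m.amplitude - _MOTION_CENTRE["amplitude"])),
            cadence=max(0.1, _MOTION_CENTRE["cadence"] + s * (m.cadence - _MOTION_CENTRE["cadence"])),
            noise_sd=m.noise_sd,
            gait_speed=max(0.1, _MOTION_CENTRE["gait_speed"] + s * (m.gait_speed - _MOTION_CENTRE["gait_speed"])),
        )


def _phase_durations(profile: ParticipantProfile, config: CohortConfig,
                     rng: np.random.Generator) -> dict[int, float]:
    motion = config.effective_motion(profile.fried_label)
    durations = {}
    for pid in sorted(PHASE_NAMES):
        median = config.phase_duration_model[pid]
        if median is None:  # walking legs: time = distance / gait speed
            median = profile.center_distance / motion.gait_speed
        durations[pid] = float(median * rng.lognormal(0.0, config.duration_sigma))
    return durations


def _smooth_wander(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth fluctuation with stationary spread ~sd (AR(1))."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    rho = 0.999
    innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return x


def generate_session(profile: ParticipantProfile, config: CohortConfig,
                     rng: np.random.Generator | None = None) -> Session:
    """Generate one participant's phase-annotated session.

    Phases 1-14 are contiguous and non-overlapping, samples uniformly spaced
    at ``config.sampling_rate``, heart rate integer-valued and clipped to the
    physiological band [40, 220] before any anomaly injection.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate
    durations = _phase_durations(profile, config, rng)

    counts = {}
    for pid in sorted(PHASE_NAMES):
        n = int(round(durations[pid] * rate))
        if n <= 0:
            raise GenerationError(
                f"phase {PHASE_NAMES[pid]!r}: duration model yielded {n} samples"
            )
        counts[pid] = n
    total = sum(counts.values())
    t = np.arange(total) / rate

    phases: list[PhaseInterval] = []
    start = 0.0
    bounds: dict[int, tuple[int, int]] = {}
    offset = 0
    for pid in sorted(PHASE_NAMES):
        end = start + counts[pid] / rate
        phases.append(PhaseInterval(pid, PHASE_NAMES[pid], start, end))
        bounds[pid] = (offset, offset + counts[pid])
        start = end
        offset += counts[pid]

    hr_model = config.effective_hr(profile.fried_label)
    motion = config.effective_motion(profile.fried_label)

    baseline = rng.normal(hr_model.mean, hr_model.subject_sd)
    hr = baseline + _smooth_wander(total, hr_model.wander_sd, rng)
    gait_level = np.empty(total)
    hr_offset = np.empty(total)
    for pid, (lo, hi) in bounds.items():
        gait_level[lo:hi] = _PHASE_GAIT_LEVEL[pid]
        hr_offset[lo:hi] = _PHASE_HR_OFFSET[pid]
    hr = np.clip(np.rint(hr + hr_offset), 40, 220).astype(int)

    # Motion: class-conditional gait oscillation gated by the phase regime,
    # plus white sensor noise; shopping phases add sporadic reaching bursts
    # on the gyroscope.
    phase_angles = rng.uniform(0, 2 * np.pi, size=6)
    carrier = 2 * np.pi * motion.cadence * t
    channels = {}
    for i, ch in enumerate(("acc_x", "acc_y", "acc_z")):
        amp = motion.amplitude * (1.0 if ch != "acc_z" else 0.6)
        sig = amp * gait_level * np.sin(carrier + phase_angles[i])
        sig += rng.normal(0.0, motion.noise_sd, total) if motion.noise_sd else 0.0
        if ch == "acc_z":
            sig += _GRAVITY
        channels[ch] = sig
    burst = np.zeros(total)
    for pid in SHOPPING_PHASES:
        lo, hi = bounds[pid]
        n_bursts = rng.poisson(max(1, (hi - lo) // int(5 * rate)))
        for _ in range(n_bursts):
            c = rng.integers(lo, hi)
            width = int(0.5 * rate)
            sl = slice(max(lo, c - width), min(hi, c + width))
            burst[sl] += motion.amplitude * rng.uniform(0.5, 1.5)
    for i, ch in enumerate(("gyr_x", "gyr_y", "gyr_z")):
        amp = 0.5 * motion.amplitude
        sig = amp * gait_level * np.sin(carrier + phase_angles[3 + i]) + burst * 0.3
        sig += rng.normal(0.0, motion.noise_sd, total) if motion.noise_sd else 0.0
        channels[ch] = sig

    if config.anomaly_rate > 0:
        mask = rng.random(total) < config.anomaly_rate
        hr = hr.copy()
        hr[mask] = profile.hr_max + rng.integers(5, 40, size=int(mask.sum()))

    samples = pd.DataFrame({"t": t, **{ch: channels[ch] for ch in CHANNELS[:-1]}, "hr": hr},
                           columns=list(SAMPLE_COLUMNS))
    return Session(profile=profile, sampling_rate=rate, samples=samples, phases=phases)


def generate_cohort(config: CohortConfig) -> list[Session]:
    """Generate the full cohort: one session per participant.

    Participants are generated class-by-class in canonical label order, each
    from its own child of the root seed, so the output is byte-identical for
    identical (config, seed) and individual sessions are reproducible in
    isolation.
    """
    root = np.random.SeedSequence(config.seed)
    total = sum(config.n_per_class.get(cls, 0) for cls in FRIED_LABELS)
    children = root.spawn(total + 1)
    profile_rng = np.random.default_rng(children[0])

    sessions: list[Session] = []
    idx = 0
    for cls in FRIED_LABELS:
        for _ in range(config.n_per_class.get(cls, 0)):
            idx += 1
            profile = ParticipantProfile(
                participant_id=f"P{idx:03d}",
                age=int(profile_rng.integers(65, 91)),
                sex="F" if profile_rng.random() < 69 / 79 else "M",
                fried_label=cls,
                center_distance=float(profile_rng.choice([50.0, 50.0, 100.0])),
            )
            rng = np.random.default_rng(children[idx])
            sessions.append(generate_session(profile, config, rng))
    return sessions
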