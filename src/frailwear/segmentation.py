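"""Phase-bounded sliding-window segmentation with 50% overlap.

Windows restart at every phase boundary so each window carries exactly one
of the fourteen protocol phases (the per-phase experiments require
phase-pure windows). For a phase of N samples, window length
``w = floor(window_s * rate)`` and step ``max(1, floor(w * (1 - overlap)))``,
segmentation emits ``floor((N - w) / step) + 1`` windows when ``N >= w``;
shorter phases yield a single truncated window covering the whole phase so
every (participant, phase) pair contributes a feature record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sessions import Session

#: Window sizes explored in the analysis (seconds).
WINDOW_SIZES_S = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class SegmentationConfig:
    window_s: float = 0.5
    overlap: float = 0.5
    rate: float = 25.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ConfigurationError("window_s must be positive")
        if not 0 <= self.overlap < 1:
            raise ConfigurationError("overlap must be in [0, 1)")
        if self.rate <= 0:
            raise ConfigurationError("rate must be positive")

    @property
    def window_samples(self) -> int:
        """Window length in samples; non-integer products are floored
        (0.5 s at 25 Hz -> 12 samples)."""
        w = int(np.floor(self.window_s * self.rate))
        if w < 1:
            raise ConfigurationError(
                f"window of {self.window_s} s at {self.rate} Hz is shorter than one sample"
            )
        return w

    @property
    def step_samples(self) -> int:
        return max(1, int(np.floor(self.window_samples * (1 - self.overlap))))


@dataclass(frozen=True)
class Window:
    """One phase-pure slice of a session, labelled with the session's Fried class."""

    session_id: str
    phase_id: int
    label: str
    samples: pd.DataFrame
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.samples)


def n_windows(n_samples: int, w: int, step: int) -> int:
    """Window count for a phase of ``n_samples``: the closed-form sliding
    count when the phase fits at least one full window, else one truncated
    window."""
    if n_samples >= w:
        return (n_samples - w) // step + 1
    return 1


def segment(session: Session, config: SegmentationConfig) -> list[Window]:
    """Segment a cleaned, uniformly sampled session into overlapping windows.

    Windows never span phase boundaries.
    """
    w = config.window_samples
    step = config.step_samples
    windows: list[Window] = []
    for phase in session.phases:
        block = session.phase_slice(phase)
        n = len(block)
        if n == 0:
            continue
        if n < w:
            windows.append(
                Window(session.session_id, phase.phase_id, session.profile.fried_label,
                       block, truncated=True)
            )
            continue
        for k in range((n - w) // step + 1):
            windows.append(
                Window(session.session_id, phase.phase_id, session.profile.fried_label,
                       block.iloc[k * step : k * step + w])
            )
    return windows
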