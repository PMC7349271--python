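"""Window features and the analysis matrix.

Eight features per sensor channel per window — seven time-domain statistics
(mean, standard deviation, skewness, kurtosis, maximum, minimum, amplitude)
and one frequency-domain feature, the spectral energy

    energy = sum_k |FFT(x)_k|^2 / w

over the full complex FFT (DC included) normalised by the window sample
count w. By Parseval's identity this equals the time-domain sum of squares,
which is the independent oracle used in the tests. With 7 channels the full
feature space has 56 named dimensions, ordered channel-major
(``acc_x_mean, acc_x_sd, ..., hr_energy``).

Skewness is the Fisher-Pearson standardised third moment and kurtosis the
excess fourth standardised moment, both without bias correction and both
defined as 0 for constant windows (sd = 0).

The analysis matrix is assembled at one of two units: ``window`` (one row
per sliding window) or ``phase`` (default; the window-level vectors of each
(session, phase) pair are averaged, giving n_sessions x 14 rows — 1092 for
the 78-participant cohort). Phase packing replaces a set of phases by one
row per session holding the unweighted arithmetic mean of their features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AssemblyError, ComputationError
from .segmentation import SegmentationConfig, Window, segment
from .sessions import CHANNELS, PHASE_NAMES, Session

#: Per-channel statistics, in canonical order.
FEATURE_STATS = ("mean", "sd", "skewness", "kurtosis", "max", "min", "amplitude", "energy")

#: The 56 canonical feature names, channel-major.
FEATURE_NAMES: list[str] = [f"{ch}_{stat}" for ch in CHANNELS for stat in FEATURE_STATS]

#: Non-feature columns of the records table.
META_COLUMNS = ("session_id", "phase_id", "phase", "unit", "label")


def _feature_block(W: np.ndarray) -> np.ndarray:
    """Features for a stack of equal-length windows.

    W has shape (n_windows, w); returns (n_windows, 8) in FEATURE_STATS order.
    """
    w = W.shape[1]
    mean = W.mean(axis=1)
    centered = W - mean[:, None]
    m2 = np.mean(centered**2, axis=1)
    sd = np.sqrt(m2)
    mx = W.max(axis=1)
    mn = W.min(axis=1)
    amplitude = mx - mn
    energy = (np.abs(np.fft.fft(W, axis=1)) ** 2).sum(axis=1) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, np.mean(centered**3, axis=1) / np.where(m2 > 0, m2, 1) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, np.mean(centered**4, axis=1) / np.where(m2 > 0, m2, 1) ** 2 - 3.0, 0.0)
    return np.column_stack([mean, sd, skew, kurt, mx, mn, amplitude, energy])


def window_features(window: Window) -> pd.Series:
    """The 56-dimensional feature vector of one window."""
    if len(window) == 0:
        raise ComputationError("cannot compute features of an empty window")
    values = np.empty(len(FEATURE_NAMES))
    for i, ch in enumerate(CHANNELS):
        x = window.samples[ch].to_numpy(dtype=float)[None, :]
        values[i * 8 : (i + 1) * 8] = _feature_block(x)[0]
    return pd.Series(values, index=FEATURE_NAMES)


@dataclass
class FeatureMatrix:
    """Rectangular analysis matrix: metadata columns plus 56 feature columns."""

    records: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLUMNS, *self.feature_names)
                   if c not in self.records.columns]
        if missing:
            raise AssemblyError(f"feature matrix missing columns {missing}")
        if self.records[self.feature_names].isna().any().any():
            raise AssemblyError("feature matrix contains missing values")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def X(self) -> np.ndarray:
        return self.records[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.records["label"].to_numpy()

    def restrict_phases(self, phase_ids: Iterable[int]) -> "FeatureMatrix":
        """Rows whose phase is in ``phase_ids`` (packed rows have phase_id 0)."""
        wanted = set(phase_ids)
        mask = self.records["phase_id"].isin(wanted)
        return FeatureMatrix(self.records.loc[mask].reset_index(drop=True),
                             list(self.feature_names))

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise AssemblyError(f"unknown feature(s) {unknown}")
        cols = list(META_COLUMNS) + list(names)
        return FeatureMatrix(self.records[cols].copy(), list(names))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        records = pd.read_csv(path)
        names = [c for c in records.columns if c not in META_COLUMNS]
        return cls(records, names)


def _session_feature_rows(session: Session, seg_config: SegmentationConfig,
                          unit: str) -> list[dict]:
    """Vectorised per-phase feature extraction for one session."""
    w = seg_config.window_samples
    step = seg_config.step_samples
    rows: list[dict] = []
    present = {p.phase_id for p in session.phases}
    for pid in sorted(PHASE_NAMES):
        if pid not in present:
            raise AssemblyError(
                f"session {session.session_id} is missing phase {PHASE_NAMES[pid]!r}"
            )
    for phase in session.phases:
        block = session.phase_slice(phase)
        n = len(block)
        if n == 0:
            raise AssemblyError(
                f"session {session.session_id}: phase {phase.name!r} has no samples"
            )
        feats_per_channel = []
        for ch in CHANNELS:
            x = block[ch].to_numpy(dtype=float)
            if n >= w:
                W = np.lib.stride_tricks.sliding_window_view(x, w)[::step]
            else:
                W = x[None, :]
            feats_per_channel.append(_feature_block(W))
        F = np.hstack(feats_per_channel)  # (n_windows, 56)
        meta = {"session_id": session.session_id, "phase_id": phase.phase_id,
                "phase": phase.name, "label": session.profile.fried_label}
        if unit == "window":
            for row in F:
                rows.append({**meta, "unit": "window",
                             **dict(zip(FEATURE_NAMES, row))})
        else:
            rows.append({**meta, "unit": "phase",
                         **dict(zip(FEATURE_NAMES, F.mean(axis=0)))})
    return rows


def build_matrix(sessions: Iterable[Session], seg_config: SegmentationConfig | None = None,
                 unit: str = "phase") -> FeatureMatrix:
    """Assemble the analysis matrix from cleaned sessions.

    ``unit="phase"`` (default) averages each phase's window-level vectors into
    one record per (session, phase); ``unit="window"`` keeps one record per
    window. Every session must carry all 14 protocol phases.
    """
    if unit not in ("window", "phase"):
        raise AssemblyError(f"unknown analysis unit {unit!r}")
    seg_config = seg_config or SegmentationConfig()
    rows: list[dict] = []
    for session in sessions:
        rows.extend(_session_feature_rows(session, seg_config, unit))
    records = pd.DataFrame(rows, columns=list(META_COLUMNS) + FEATURE_NAMES)
    return FeatureMatrix(records, list(FEATURE_NAMES))


def pack_phases(matrix: FeatureMatrix, phase_ids: Sequence[int],
                packed_name: str = "packed_shopping") -> FeatureMatrix:
    """Merge the listed phases into one record per session.

    The merged record's features are the unweighted arithmetic mean of the
    listed phases' records; it carries ``phase_id = 0`` and ``packed_name``.
    Other records are untouched. Requires a phase-level matrix.
    """
    if not phase_ids:
        raise AssemblyError("phase_ids must be non-empty")
    unknown = [p for p in phase_ids if p not in PHASE_NAMES]
    if unknown:
        raise AssemblyError(f"unknown phase id(s) {unknown}")
    if not (matrix.records["unit"] == "phase").all():
        raise AssemblyError("pack_phases requires a phase-level matrix")
    wanted = set(phase_ids)
    rec = matrix.records
    inside = rec[rec["phase_id"].isin(wanted)]
    outside = rec[~rec["phase_id"].isin(wanted)]
    packed = (
        inside.groupby(["session_id", "label"], as_index=False, sort=False)[matrix.feature_names]
        .mean()
    )
    packed.insert(1, "phase_id", 0)
    packed.insert(2, "phase", packed_name)
    packed.insert(3, "unit", "phase")
    out = pd.concat([outside, packed], ignore_index=True)
    out = out.sort_values(["session_id", "phase_id"], kind="stable").reset_index(drop=True)
    return FeatureMatrix(out[list(META_COLUMNS) + matrix.feature_names], list(matrix.feature_names))
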