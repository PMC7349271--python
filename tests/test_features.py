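import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from frailwear import SegmentationConfig, build_matrix, pack_phases, window_features
from frailwear.errors import AssemblyError, ComputationError
from frailwear.features import FEATURE_NAMES, _feature_block
from frailwear.segmentation import Window, segment
from frailwear.synthetic import SHOPPING_PHASES

from conftest import make_session


def _window(values_by_channel, n=12):
    s = make_session(n, channel_values=values_by_channel,
                     hr=values_by_channel.get("hr", 80))
    return Window("T001", 1, "pre-frail", s.samples)


class TestWindowFeatures:
    def test_exactly_56_canonical_names(self):
        fv = window_features(_window({}))
        assert list(fv.index) == FEATURE_NAMES
        assert len(fv) == 56
        assert np.isfinite(fv.to_numpy()).all()

    def test_constant_channel(self):
        fv = window_features(_window({"acc_x": 3.0}))
        assert fv["acc_x_mean"] == pytest.approx(3.0)
        assert fv["acc_x_sd"] == 0.0
        assert fv["acc_x_amplitude"] == 0.0
        assert fv["acc_x_skewness"] == 0.0 and fv["acc_x_kurtosis"] == 0.0

    def test_zero_channel_zero_energy(self):
        fv = window_features(_window({"gyr_x": 0.0}))
        assert fv["gyr_x_energy"] == 0.0

    def test_constant_one_energy_equals_window_length(self):
        # DC FFT component is w, so energy = w^2 / w = w = 12
        fv = window_features(_window({"acc_y": 1.0}, n=12))
        assert fv["acc_y_energy"] == pytest.approx(12.0)

    def test_length_one_window_conventions(self):
        fv = window_features(_window({"acc_x": 5.0}, n=1))
        assert fv["acc_x_mean"] == 5.0
        assert fv["acc_x_sd"] == 0.0
        assert fv["acc_x_skewness"] == 0.0 and fv["acc_x_kurtosis"] == 0.0

    def test_empty_window_rejected(self):
        s = make_session(5)
        w = Window("T001", 1, "frail", s.samples.iloc[:0])
        with pytest.raises(ComputationError):
            window_features(w)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=64))
    def test_energy_parseval_identity(self, xs):
        # Eq-style spectral energy equals the time-domain sum of squares
        x = np.asarray(xs)
        energy = _feature_block(x[None, :])[0, 7]
        expected = float(np.sum(x**2))
        assert energy == pytest.approx(expected, rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_moments_match_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 40))
        f = _feature_block(x[None, :])[0]
        assert f[2] == pytest.approx(stats.skew(x, bias=True), abs=1e-10)
        assert f[3] == pytest.approx(stats.kurtosis(x, fisher=True, bias=True), abs=1e-10)
        assert f[1] == pytest.approx(np.std(x), abs=1e-12)


class TestBuildMatrix:
    def test_one_session_phase_level_has_14_records(self, small_cohort):
        m = build_matrix(small_cohort[:1], SegmentationConfig(), unit="phase")
        assert len(m) == 14
        assert sorted(m.records["phase_id"]) == list(range(1, 15))

    def test_window_level_counts_match_segmentation(self, small_cohort):
        s = small_cohort[0]
        m = build_matrix([s], SegmentationConfig(), unit="window")
        assert len(m) == len(segment(s, SegmentationConfig()))

    def test_phase_record_is_mean_of_window_features(self, small_cohort):
        s = small_cohort[0]
        cfg = SegmentationConfig()
        mw = build_matrix([s], cfg, unit="window")
        mp = build_matrix([s], cfg, unit="phase")
        for pid in (1, 5, 12):
            expected = mw.records.loc[mw.records["phase_id"] == pid,
                                      mw.feature_names].mean()
            got = mp.records.loc[mp.records["phase_id"] == pid,
                                 mp.feature_names].iloc[0]
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_missing_phase_names_session_and_phase(self):
        s = make_session(100, participant_id="T009")  # only phase 1
        with pytest.raises(AssemblyError, match="T009.*standing"):
            build_matrix([s], SegmentationConfig(), unit="phase")

    def test_no_missing_values(self, small_matrix):
        assert not small_matrix.records[small_matrix.feature_names].isna().any().any()

    def test_csv_roundtrip(self, small_matrix, tmp_path):
        p = tmp_path / "m.csv"
        small_matrix.to_csv(p)
        from frailwear.features import FeatureMatrix
        back = FeatureMatrix.from_csv(p)
        assert back.feature_names == small_matrix.feature_names
        np.testing.assert_allclose(back.X, small_matrix.X, rtol=1e-12)


class TestPackPhases:
    def test_packing_shopping_shrinks_by_seven_per_session(self, small_matrix):
        packed = pack_phases(small_matrix, sorted(SHOPPING_PHASES))
        n_sessions = small_matrix.records["session_id"].nunique()
        assert len(packed) == len(small_matrix) - 7 * n_sessions
        merged = packed.records[packed.records["phase"] == "packed_shopping"]
        assert len(merged) == n_sessions

    def test_packed_features_are_unweighted_mean(self, small_matrix):
        packed = pack_phases(small_matrix, sorted(SHOPPING_PHASES))
        sid = small_matrix.records["session_id"].iloc[0]
        src = small_matrix.records
        expected = src[(src["session_id"] == sid)
                       & (src["phase_id"].isin(SHOPPING_PHASES))][small_matrix.feature_names].mean()
        got = packed.records[(packed.records["session_id"] == sid)
                             & (packed.records["phase"] == "packed_shopping")]
        np.testing.assert_allclose(got[packed.feature_names].iloc[0], expected, rtol=1e-12)

    def test_pack_single_phase_only_renames(self, small_matrix):
        packed = pack_phases(small_matrix, [9], packed_name="solo")
        assert len(packed) == len(small_matrix)
        row = packed.records[packed.records["phase"] == "solo"]
        src = small_matrix.records[small_matrix.records["phase_id"] == 9]
        np.testing.assert_allclose(
            row[packed.feature_names].to_numpy(),
            src.sort_values("session_id")[small_matrix.feature_names].to_numpy(),
            rtol=1e-12,
        )

    def test_pack_all_collapses_to_one_record_per_session(self, small_matrix):
        packed = pack_phases(small_matrix, list(range(1, 15)), packed_name="whole")
        assert len(packed) == small_matrix.records["session_id"].nunique()

    def test_unknown_phase_id_rejected(self, small_matrix):
        with pytest.raises(AssemblyError):
            pack_phases(small_matrix, [99])
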