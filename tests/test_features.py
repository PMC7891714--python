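"""Window statistics, episode averaging, superficial regression, matrix assembly."""

from dataclasses import replace

import numpy as np
import pytest

from nirsload.features import (
    ActivationMatrix,
    FeatureError,
    build_feature_matrix,
    episode_activation,
    ssr,
    subject_activations,
    window_statistic,
)
from nirsload.preprocess import preprocess_recording
from nirsload.synthetic import TLXRecord, make_schedule, simulate_subject

FS = 8.138


class TestWindowStatistic:
    def test_constant_signal_sd_zero(self):
        out = window_statistic(np.full(100, 4.2), fs=1.0, window_s=10.0, statistic="sd")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_sinusoid_sd_closed_form(self):
        # amplitude A with integer periods per window -> SD = A / sqrt(2)
        fs, A = 10.0, 2.5
        t = np.arange(0, 100, 1 / fs)
        x = A * np.sin(2 * np.pi * 0.2 * t)  # 2 periods per 10 s window
        out = window_statistic(x, fs, 10.0, "sd")
        np.testing.assert_allclose(out, A / np.sqrt(2), rtol=0.01)

    def test_mean_statistic_identity(self):
        out = window_statistic(np.full(50, 3.0), fs=1.0, window_s=10.0, statistic="mean")
        np.testing.assert_allclose(out, 3.0)

    def test_skewness_and_kurtosis_available(self):
        x = np.random.default_rng(0).standard_normal(200)
        for stat in ("skewness", "kurtosis"):
            out = window_statistic(x, fs=1.0, window_s=10.0, statistic=stat)
            assert out.shape == (20,)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(FeatureError, match="unknown statistic"):
            window_statistic(np.zeros(50), 1.0, 10.0, statistic="mode")

    def test_offset_invariance_of_sd(self):
        x = np.random.default_rng(1).standard_normal(300)
        a = window_statistic(x, 1.0, 10.0, "sd")
        b = window_statistic(x + 57.0, 1.0, 10.0, "sd")
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestEpisodeActivation:
    def setup_method(self):
        self.sched = make_schedule(task_s=60.0, fs=1.0)  # windows align exactly

    def test_uniform_values(self):
        wv = np.full((24, 1), 5.0)
        mask = np.ones_like(wv, dtype=bool)
        out = episode_activation(wv, mask, self.sched, "task1", 1.0, 10.0)
        np.testing.assert_allclose(out, 5.0)

    def test_masked_mean_hand_computed(self):
        # task1 spans windows 6..11 at fs=1, window 10 s; use 4 of them
        wv = np.zeros((24, 1))
        wv[6:10, 0] = [1.0, 2.0, 3.0, 4.0]
        mask = np.ones_like(wv, dtype=bool)
        mask[8, 0] = False  # the '3' is flagged
        mask[10:12, 0] = False  # keep exactly windows 6,7,9 + none later
        wv[10:12, 0] = 99.0
        out = episode_activation(wv, mask, self.sched, "task1", 1.0, 10.0)
        np.testing.assert_allclose(out[0], np.mean([1.0, 2.0, 4.0]))

    def test_fewer_than_three_windows_is_missing(self):
        wv = np.ones((24, 1))
        mask = np.zeros_like(wv, dtype=bool)
        mask[6, 0] = mask[7, 0] = True  # only two retained in task1
        out = episode_activation(wv, mask, self.sched, "task1", 1.0, 10.0)
        assert np.isnan(out[0])

    def test_absent_episode_raises_with_name(self):
        wv = np.ones((24, 1))
        with pytest.raises(KeyError, match="task9"):
            episode_activation(wv, np.ones_like(wv, bool), self.sched, "task9", 1.0, 10.0)

    def test_doubling_amplitude_increases_long_channel_activation(
        self, small_layout, short_schedule, student_profile
    ):
        from nirsload.synthetic import SubjectProfile

        amps2 = {k: 2 * v for k, v in student_profile.cerebral_amplitude.items()}
        prof2 = SubjectProfile(
            "S01", "student", student_profile.latent_load, amps2,
            student_profile.superficial_amplitude, 0.0
        )
        prof1 = replace_motion(student_profile, 0.0)
        acts = []
        for prof in (prof1, prof2):
            rec = simulate_subject(prof, small_layout, short_schedule, seed=13)
            hb = preprocess_recording(rec)
            act = subject_activations(hb, small_layout)["task1"]
            acts.append(np.nanmean(act[small_layout.class_indices(3.35)]))
        assert acts[1] > acts[0]


def replace_motion(profile, rate):
    from nirsload.synthetic import SubjectProfile

    return SubjectProfile(
        profile.subject_id, profile.group, profile.latent_load,
        profile.cerebral_amplitude, profile.superficial_amplitude, rate
    )


class TestSSR:
    def test_perfect_regressor_gives_zero_residual(self, small_layout):
        rng = np.random.default_rng(0)
        n = 500
        series = np.zeros((n, small_layout.n_channels))
        long_i = int(small_layout.class_indices(3.0)[0])
        short_i = small_layout.nearest_short(long_i)
        s = rng.standard_normal(n)
        series[:, short_i] = s
        series[:, long_i] = 2.5 * s
        out = ssr(series, small_layout)
        rms_res = np.sqrt(np.mean(out[:, long_i] ** 2))
        rms_orig = np.sqrt(np.mean(series[:, long_i] ** 2))
        assert rms_res < 1e-9 * rms_orig

    def test_orthogonal_component_survives(self, small_layout):
        # y = s + c with c orthogonal to s: residual ~ c (normal-equation oracle)
        rng = np.random.default_rng(1)
        n = 2000
        s = rng.standard_normal(n)
        c = rng.standard_normal(n)
        c -= (c @ s) / (s @ s) * s  # exact orthogonalization
        series = np.zeros((n, small_layout.n_channels))
        long_i = int(small_layout.class_indices(3.0)[0])
        short_i = small_layout.nearest_short(long_i)
        series[:, short_i] = s
        series[:, long_i] = s + c
        out = ssr(series, small_layout)
        resid = out[:, long_i]
        beta_oracle = np.linalg.lstsq(s[:, None], (s + c)[:, None], rcond=None)[0][0, 0]
        np.testing.assert_allclose(resid, (s + c) - beta_oracle * s, atol=1e-10)
        corr = np.corrcoef(resid, s)[0, 1]
        assert abs(corr) < 0.02
        np.testing.assert_allclose(resid, c, atol=1e-8)

    def test_residual_orthogonal_to_regressor(self, small_layout):
        rng = np.random.default_rng(2)
        series = rng.standard_normal((800, small_layout.n_channels))
        out = ssr(series, small_layout)
        for i in small_layout.class_indices(3.35):
            j = small_layout.nearest_short(int(i))
            s = series[:, j]
            inner = abs(out[:, i] @ s)
            assert inner < 1e-8 * np.sqrt((out[:, i] @ out[:, i]) * (s @ s)) + 1e-8

    def test_zero_variance_regressor_warns_and_passes_through(self, small_layout):
        series = np.random.default_rng(3).standard_normal((300, small_layout.n_channels))
        series[:, small_layout.class_indices(1.5)] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = ssr(series, small_layout)
        long_idx = small_layout.class_indices(3.0)
        np.testing.assert_array_equal(out[:, long_idx], series[:, long_idx])

    def test_short_channels_unchanged(self, small_layout):
        series = np.random.default_rng(4).standard_normal((300, small_layout.n_channels))
        out = ssr(series, small_layout)
        short_idx = small_layout.class_indices(1.5)
        np.testing.assert_array_equal(out[:, short_idx], series[:, short_idx])


class TestBuildFeatureMatrix:
    def _activations(self, layout, sids, episodes=("task1", "task2"), value=1.0):
        C = layout.n_channels
        return {
            sid: {ep: np.full(C, value) for ep in episodes} for sid in sids
        }

    def _tlx(self, sids, episodes=("task1", "task2"), scores=None):
        recs = []
        for i, sid in enumerate(sids):
            for ep in episodes:
                score = 10.0 if scores is None else scores[i]
                recs.append(TLXRecord(sid, ep, tuple([score] * 6)))
        return recs

    def test_dimensions(self, small_layout):
        sids = [f"S{i}" for i in range(4)] + [f"A{i}" for i in range(4)]
        groups = {s: ("student" if s.startswith("S") else "attending") for s in sids}
        m = build_feature_matrix(
            self._activations(small_layout, sids), self._tlx(sids), groups, small_layout
        )
        assert m.values.shape == (16, small_layout.n_channels)
        assert list(m.col_meta["channel_id"]) == list(small_layout.ids)

    def test_missing_tlx_drops_row_with_warning(self, small_layout):
        sids = ["S1", "S2"]
        groups = {s: "student" for s in sids}
        tlx = self._tlx(["S1"])  # S2 has no TLX at all
        with pytest.warns(UserWarning, match="S2"):
            m = build_feature_matrix(
                self._activations(small_layout, sids), tlx, groups, small_layout
            )
        assert m.values.shape[0] == 2

    def test_median_imputation(self, small_layout):
        sids = ["S1", "S2", "S3", "S4"]
        groups = {s: "student" for s in sids}
        acts = self._activations(small_layout, sids, episodes=("task1",))
        acts["S1"]["task1"] = acts["S1"]["task1"].copy()
        acts["S2"]["task1"] = acts["S2"]["task1"].copy()
        acts["S3"]["task1"] = acts["S3"]["task1"].copy()
        acts["S4"]["task1"] = acts["S4"]["task1"].copy()
        acts["S1"]["task1"][0] = 1.0
        acts["S2"]["task1"][0] = 2.0
        acts["S3"]["task1"][0] = np.nan
        acts["S4"]["task1"][0] = 4.0
        m = build_feature_matrix(acts, self._tlx(sids, episodes=("task1",)),
                                 groups, small_layout)
        imputed_row = list(m.row_meta["subject_id"]).index("S3")
        assert m.values[imputed_row, 0] == 2.0
        assert m.missing[imputed_row, 0]

    def test_single_subject_labelled_low(self, small_layout):
        groups = {"S1": "student"}
        with pytest.warns(UserWarning, match="degenerate"):
            m = build_feature_matrix(
                self._activations(small_layout, ["S1"], episodes=("task1",)),
                self._tlx(["S1"], episodes=("task1",)), groups, small_layout
            )
        assert list(m.row_meta["load_label"]) == ["low"]

    def test_load_labels_split_within_group(self, small_layout):
        sids = ["S1", "S2", "S3", "S4"]
        groups = {s: "student" for s in sids}
        m = build_feature_matrix(
            self._activations(small_layout, sids, episodes=("task1",)),
            self._tlx(sids, episodes=("task1",), scores=[1.0, 5.0, 15.0, 19.0]),
            groups, small_layout
        )
        by_sid = dict(zip(m.row_meta["subject_id"], m.row_meta["load_label"]))
        assert by_sid == {"S1": "low", "S2": "low", "S3": "high", "S4": "high"}

    def test_csv_round_trip(self, small_layout, tmp_path):
        from nirsload.io import read_feature_matrix, write_feature_matrix

        sids = ["S1", "S2", "A1", "A2"]
        groups = {s: ("student" if s.startswith("S") else "attending") for s in sids}
        acts = self._activations(small_layout, sids)
        rng = np.random.default_rng(0)
        for sid in sids:
            for ep in acts[sid]:
                acts[sid][ep] = rng.uniform(0.1, 2.0, small_layout.n_channels)
        m = build_feature_matrix(acts, self._tlx(sids), groups, small_layout)
        path = tmp_path / "features.csv"
        write_feature_matrix(m, path)
        again = read_feature_matrix(path, small_layout)
        np.testing.assert_allclose(again.values, m.values, rtol=1e-8)
        assert list(again.row_meta["load_label"]) == list(m.row_meta["load_label"])

    def test_values_nonnegative_from_pipeline(self, simulated_subject, small_layout):
        hb = preprocess_recording(simulated_subject)
        acts = subject_activations(hb, small_layout)
        for vals in acts.values():
            assert np.all(vals[np.isfinite(vals)] >= 0)
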