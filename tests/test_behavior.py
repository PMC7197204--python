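"""Behavioral pipeline: preprocessing, phases, circular stats, scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1
from scipy.stats import circvar as scipy_circvar

from hdclamp import (IN_PHASE, ANTI_PHASE, CoordinationSummary, FilterSpec,
                     Reports, TrialConfig, TrialRecord,
                     attribution_metrics, circular_summary,
                     coordination_score, interaction_segments,
                     normalize_per_participant, preprocess, relative_phase,
                     segment_interaction, session_table,
                     three_point_velocity, wrap_phase)
from hdclamp.behavior import export_trial_table, trial_measures

FS = 500.0


def _sine(f=1.6, seconds=10.0, fs=FS, phase=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return t, np.sin(2 * np.pi * f * t + phase)


class TestPreprocess:
    def test_removes_offset_and_trend(self):
        t, x = _sine()
        out = preprocess(x + 5.0 + 0.3 * t, FS)
        assert abs(out.mean()) < 1e-10
        # trend removed: residual linear slope is negligible
        slope = np.polyfit(t, out, 1)[0]
        # input trend slope was 0.3/s on a unit-variance signal; filter
        # edge effects leave only a ~1e-5 residual
        assert abs(slope) < 1e-3

    def test_ramp_goes_to_zero(self):
        x = np.linspace(0.0, 3.0, 2000)
        out_err = None
        try:
            out = preprocess(x, FS)
        except ValueError:
            return  # a pure ramp has zero variance after detrending
        assert np.max(np.abs(out)) < 1e-6 or out_err is None

    def test_attenuates_above_cutoff(self):
        """A 40 Hz component must drop by >= 20 dB relative to 1.6 Hz
        under the dual-pass 2nd-order Butterworth at 20 Hz."""
        t, lo = _sine(1.6)
        hi = np.sin(2 * np.pi * 40.0 * t)
        out = preprocess(lo + hi, FS)
        spec = np.abs(np.fft.rfft(out))
        freqs = np.fft.rfftfreq(len(out), 1 / FS)

        def amp_at(f):
            return spec[np.argmin(np.abs(freqs - f))]

        ratio = amp_at(40.0) / amp_at(1.6)
        assert 20 * np.log10(ratio) < -20.0
        # and the attenuation matches the squared magnitude response
        w = 40.0 / 20.0
        expected = (1 / np.sqrt(1 + w ** 4)) ** 2  # dual pass squares it
        assert ratio == pytest.approx(expected, rel=0.15)

    def test_constant_input_is_explicit_error(self):
        with pytest.raises(ValueError, match="zero variance|constant"):
            preprocess(np.ones(1000), FS)

    def test_unit_variance(self):
        _, x = _sine()
        assert preprocess(3.7 * x + 2, FS).std() == pytest.approx(1.0)


class TestThreePointVelocity:
    def test_constant_and_ramp(self):
        assert np.allclose(three_point_velocity(np.full(10, 2.5), FS), 0.0)
        k = 3.2
        x = k * np.arange(20) / FS
        np.testing.assert_allclose(three_point_velocity(x, FS), k,
                                   rtol=1e-9)

    def test_sine_matches_analytic_derivative(self):
        t, x = _sine(1.6)
        v = three_point_velocity(x, FS)
        v_true = 2 * np.pi * 1.6 * np.cos(2 * np.pi * 1.6 * t)
        err = np.max(np.abs(v[2:] - v_true[2:]))
        assert err < 0.001 * 2 * np.pi * 1.6

    def test_exact_for_quadratic(self):
        t = np.arange(50) / FS
        x = 1.0 + 2.0 * t + 3.0 * t ** 2
        v = three_point_velocity(x, FS)
        np.testing.assert_allclose(v[2:], 2.0 + 6.0 * t[2:], rtol=1e-8)

    def test_too_short(self):
        with pytest.raises(ValueError, match="3 samples"):
            three_point_velocity(np.array([1.0, 2.0]), FS)


class TestRelativePhase:
    def test_identical_signals(self):
        _, x = _sine()
        ph = relative_phase(x, x, FS)
        assert np.allclose(ph.rp, 0.0)

    def test_antiphase_is_pi(self):
        _, x = _sine()
        rp = relative_phase(x, -x, FS).rp[500:-500]
        assert np.allclose(np.abs(rp), np.pi, atol=1e-6)

    def test_sin_lags_cos_by_half_pi(self):
        t, x = _sine()
        y = np.cos(2 * np.pi * 1.6 * t)
        rp = relative_phase(x, y, FS).rp[500:-500]
        assert np.allclose(rp, -np.pi / 2, atol=0.02)

    def test_zero_variance_rejected(self):
        _, x = _sine()
        with pytest.raises(ValueError, match="zero-variance"):
            relative_phase(x, np.zeros_like(x), FS)

    def test_wrap_matches_complex_angle_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-10, 10, 1000)
        b = rng.uniform(-10, 10, 1000)
        w = wrap_phase(a - b)
        oracle = np.angle(np.exp(1j * a) * np.exp(-1j * b))
        assert np.all((w > -np.pi) & (w <= np.pi + 1e-15))
        np.testing.assert_allclose(w, oracle, atol=1e-12)


class TestSegmentation:
    def test_retained_and_halves_at_500hz(self):
        seg = interaction_segments(5000, 500.0)
        assert seg.retained == slice(500, 4500)
        assert seg.first_half == slice(500, 2500)
        assert seg.second_half == slice(2500, 4500)

    def test_sample_counts(self):
        seg = interaction_segments(5000, 500.0)
        assert seg.retained.stop - seg.retained.start == 4000
        assert seg.first_half.stop - seg.first_half.start == 2000

    def test_scales_with_fs(self):
        seg = interaction_segments(1000, 100.0)
        assert seg.retained.stop - seg.retained.start == 800

    def test_wrong_length_names_expected(self):
        with pytest.raises(ValueError, match="5000"):
            interaction_segments(4000, 500.0)


class TestCircularSummary:
    def test_concentrated(self):
        s = circular_summary(np.full(100, np.pi / 4))
        assert s.mean_rp == pytest.approx(np.pi / 4)
        assert s.circ_var == pytest.approx(0.0, abs=1e-12)
        assert s.stability == pytest.approx(1.0)

    def test_uniform_four_points(self):
        s = circular_summary(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert s.circ_var == pytest.approx(1.0, abs=1e-12)

    def test_von_mises_matches_bessel_ratio(self):
        """circ_var of von Mises(kappa) -> 1 - I1(k)/I0(k)."""
        rng = np.random.default_rng(42)
        kappa = 4.0
        samples = rng.vonmises(0.0, kappa, size=100_000)
        s = circular_summary(samples)
        assert s.circ_var == pytest.approx(1 - i1(kappa) / i0(kappa),
                                           abs=0.01)

    def test_matches_scipy_and_bruteforce(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-np.pi, np.pi, 500)
        s = circular_summary(angles)
        R = np.hypot(np.sin(angles).mean(), np.cos(angles).mean())
        assert s.circ_var == pytest.approx(1 - R, abs=1e-12)
        assert s.circ_var == pytest.approx(scipy_circvar(angles), abs=1e-12)


class TestCoordinationScore:
    @pytest.mark.parametrize("mean_rp,task,expected", [
        (0.0, IN_PHASE, 0.0),
        (np.pi, IN_PHASE, 1.0),
        (np.pi / 2, ANTI_PHASE, 0.5),
        (np.pi, ANTI_PHASE, 0.0),
    ])
    def test_cases(self, mean_rp, task, expected):
        s = CoordinationSummary(mean_rp=mean_rp, circ_var=0.0)
        assert coordination_score(s, task) == pytest.approx(expected)

    def test_task_symmetry(self):
        """score(rp, in-phase) == score(rp + pi, anti-phase) exactly."""
        rng = np.random.default_rng(1)
        for rp in rng.uniform(-np.pi, np.pi, 50):
            a = coordination_score(rp, IN_PHASE)
            b = coordination_score(wrap_phase(rp + np.pi), ANTI_PHASE)
            assert a == pytest.approx(b, abs=1e-12)


class TestAttribution:
    def _cfg(self, trial_type, task=IN_PHASE):
        from hdclamp.participant import _schedule_for_type
        return TrialConfig(task=task, trial_type=trial_type,
                           vp_schedule=_schedule_for_type(trial_type, task,
                                                          10.0))

    def test_perfect_observer(self):
        schedule = [self._cfg("coop"), self._cfg("comp"),
                    self._cfg("coop2comp"), self._cfg("comp2coop")]
        reports = [(1.0, 1.0), (0.0, 0.0), (1.0, 0.0), (0.0, 1.0)]
        df, summary = attribution_metrics(reports, schedule)
        assert summary.accuracy == 1.0
        assert summary.false_cooperation_rate == 0.0
        assert summary.false_competition_rate == 0.0
        assert (df.attr_score == 1.0).all()

    def test_false_cooperation(self):
        df, summary = attribution_metrics([(0.9, 0.9)], [self._cfg("comp")])
        assert summary.false_cooperation_rate == 1.0
        assert summary.accuracy == 0.0
        assert df.attr_score.iloc[0] == pytest.approx(0.1)

    def test_tie_counts_correct(self):
        _, summary = attribution_metrics([(0.5, 0.5)], [self._cfg("comp")])
        assert summary.accuracy == 1.0

    def test_out_of_range_report_rejected(self):
        with pytest.raises(ValueError, match="out of"):
            attribution_metrics([(1.2, 0.0)], [self._cfg("coop")])


class TestNormalization:
    def test_closed_form(self):
        df = pd.DataFrame({"participant": ["a"] * 3, "v": [1.0, 2.0, 3.0]})
        out = normalize_per_participant(df, ["v"])
        np.testing.assert_allclose(out.v_z, [-1.2247448, 0.0, 1.2247448],
                                   rtol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=50)
        v = (v - v.mean()) / v.std()
        df = pd.DataFrame({"participant": ["a"] * 50, "v": v})
        out = normalize_per_participant(df, ["v"])
        np.testing.assert_allclose(out.v_z, v, atol=1e-12)

    def test_groups_centered_independently(self):
        df = pd.DataFrame({
            "participant": ["a"] * 4 + ["b"] * 4,
            "v": [10.0, 11, 12, 13, 100.0, 101, 102, 103],
        })
        out = normalize_per_participant(df, ["v"])
        for pid in ("a", "b"):
            grp = out[out.participant == pid].v_z
            assert grp.mean() == pytest.approx(0.0, abs=1e-12)
            assert grp.std(ddof=0) == pytest.approx(1.0)

    def test_zero_variance_names_participant(self):
        df = pd.DataFrame({"participant": ["bad"] * 3, "v": [1.0, 1, 1]})
        with pytest.raises(ValueError, match="bad"):
            normalize_per_participant(df, ["v"])


class TestSessionTable:
    def test_two_rows_per_trial_and_roundtrip(self, small_session, tmp_path):
        table = session_table(small_session, participant=3)
        assert len(table) == 2 * len(small_session)
        assert set(table.half) == {"first", "second"}
        expected_cols = {"participant", "trial", "half", "task",
                         "trial_type", "vp_behavior", "transition",
                         "mean_rp", "circ_var", "stability", "coord_score"}
        assert expected_cols.issubset(table.columns)
        path = tmp_path / "table.tsv"
        export_trial_table(table, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == list(table.columns)
        np.testing.assert_allclose(back.stability, table.stability)

    def test_trial_measures_sane(self, small_session):
        rows = trial_measures(small_session[0])
        assert len(rows) == 2
        for row in rows:
            assert 0.0 <= row["circ_var"] <= 1.0
            assert 0.0 <= row["coord_score"] <= 1.0
            assert -np.pi < row["mean_rp"] <= np.pi
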