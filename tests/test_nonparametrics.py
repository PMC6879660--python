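import numpy as np
import pytest

from acmkit.nonparametrics import (
    circadian_function_index,
    interdaily_stability,
    intradaily_variability,
    ml_levels,
    normalize_ra_cohort,
    relative_amplitude,
    window_hours,
)
from acmkit.timeseries import DailyWaveform

from _oracles import ml_window_brute_force
from conftest import make_series


def waveform(values):
    values = np.asarray(values, float)
    return DailyWaveform(
        variable="TAP",
        values=values,
        n_contributing=np.ones(values.size, int),
        epoch_minutes=1440 // values.size,
    )


class TestInterdailyStability:
    def test_identical_days_give_one(self):
        day = np.sin(np.linspace(0, 2 * np.pi, 144, endpoint=False))
        assert interdaily_stability(make_series(np.tile(day, 7))) == pytest.approx(1.0)

    def test_iid_noise_gives_near_zero(self):
        rng = np.random.default_rng(99)
        s = make_series(rng.normal(size=7 * 144))
        assert interdaily_stability(s) < 0.2

    def test_two_day_toy_hand_computed(self):
        # 4 slots/day (360-min epochs): day1 = 1,2,3,4; day2 = 3,4,5,6
        # slot means (2,3,4,5), grand mean 3.5 -> between-SS = 5, total-SS = 18
        # IS = (8*5)/(4*18) = 5/9
        s = make_series([1, 2, 3, 4, 3, 4, 5, 6], epoch_minutes=360)
        assert interdaily_stability(s, toy_mode=True) == pytest.approx(5 / 9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            interdaily_stability(make_series(np.ones(7 * 144)))


class TestIntradailyVariability:
    def test_smooth_sinusoid_is_nearly_zero(self):
        t = np.arange(7 * 144)
        s = make_series(np.sin(2 * np.pi * t / 144))
        assert intradaily_variability(s) < 0.05

    def test_alternating_series_is_about_four(self):
        s = make_series(np.tile([0.0, 1.0], 144), epoch_minutes=360)
        iv = intradaily_variability(s, toy_mode=True)
        assert iv > 2
        assert iv == pytest.approx(4.0, rel=0.01)

    def test_white_noise_is_about_two(self):
        rng = np.random.default_rng(123)
        s = make_series(rng.normal(size=1008))
        assert intradaily_variability(s) == pytest.approx(2.0, abs=0.1)

    def test_gaps_bridge_only_adjacent_valid_pairs(self):
        vals = np.sin(2 * np.pi * np.arange(7 * 144) / 144)
        valid = np.ones(vals.size, bool)
        valid[100:110] = False  # still >= 80% valid
        iv = intradaily_variability(make_series(vals, valid=valid))
        assert iv < 0.05


class TestMLLevels:
    def test_window_lengths_by_variable(self):
        assert window_hours("WT") == (5, 10)
        assert window_hours("S") == (5, 10)
        for v in ("L", "ET", "A", "P", "TAP"):
            assert window_hours(v) == (10, 5)

    def test_cosine_m10_centred_on_peak(self):
        # slot-centre sampling keeps the discrete optimum symmetric about 15:00
        centers = (np.arange(144) + 0.5) / 6.0
        wf = waveform(np.cos(2 * np.pi * (centers - 15.0) / 24.0))
        ml = ml_levels(wf, m_hours=10, l_hours=5)
        assert ml.m_onset_hours == pytest.approx(10.0)   # 10:00-20:00
        assert ml.m_midpoint_hours == pytest.approx(15.0)

    def test_constant_waveform_ties_to_earliest_onset(self):
        ml = ml_levels(waveform(np.full(144, 2.5)), m_hours=10, l_hours=5)
        assert ml.m_level == ml.l_level == pytest.approx(2.5)
        assert ml.m_onset_slot == 0 and ml.l_onset_slot == 0

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(2024)
        for i in range(50):
            vals = rng.integers(0, 5, size=144).astype(float)  # many exact ties
            wf = waveform(vals)
            ml = ml_levels(wf, m_hours=10, l_hours=5)
            (mx, mo), (mn, lo) = ml_window_brute_force(vals, 60)
            assert ml.m_level == pytest.approx(mx, abs=1e-12)
            assert ml.m_onset_slot == mo
            (mx5, _), (mn5, lo5) = ml_window_brute_force(vals, 30)
            assert ml.l_level == pytest.approx(mn5, abs=1e-12)
            assert ml.l_onset_slot == lo5

    def test_incomplete_waveform_rejected(self):
        wf = waveform(np.ones(144))
        wf.n_contributing[3] = 0
        with pytest.raises(ValueError, match="incomplete"):
            ml_levels(wf, m_hours=10, l_hours=5)


class TestRelativeAmplitude:
    @pytest.mark.parametrize("m,l,ra", [(3.0, 1.0, 0.5), (2.0, 0.0, 1.0), (2.0, 2.0, 0.0)])
    def test_examples(self, m, l, ra):
        assert relative_amplitude(m, l) == pytest.approx(ra)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_amplitude(1.0, 2.0)
        with pytest.raises(ValueError):
            relative_amplitude(0.0, 0.0)


class TestNormalizeRaCohort:
    def test_extremes_recode_to_zero_and_one(self):
        rng = np.random.default_rng(8)
        ra = rng.uniform(0.2, 0.8, 40)
        nra = normalize_ra_cohort(ra)
        assert nra[np.argmin(ra)] == 0.0
        assert nra[np.argmax(ra)] == 1.0
        assert ((nra >= 0) & (nra <= 1)).all()

    def test_uniform_grid_hand_computed(self):
        # 100 subjects at 0.00..0.99: p5 = 0.0495, p95 = 0.9405 (linear
        # interpolation), so RA = 0.50 maps to 0.4505/0.8910
        ra = np.arange(100) / 100.0
        nra = normalize_ra_cohort(ra)
        assert nra[50] == pytest.approx((0.50 - 0.0495) / (0.9405 - 0.0495))

    def test_small_cohort_warns_and_degenerate_rejected(self):
        with pytest.warns(UserWarning, match="unstable"):
            normalize_ra_cohort(np.linspace(0, 1, 10))
        with pytest.raises(ValueError, match="degenerate"):
            normalize_ra_cohort(np.full(30, 0.5))


class TestCFI:
    @pytest.mark.parametrize(
        "IS,IV,NRA,expected",
        [(1.0, 0.0, 1.0, 1.0), (0.0, 2.0, 0.0, 0.0), (0.5, 1.0, 0.5, 0.5)],
    )
    def test_endpoint_identities(self, IS, IV, NRA, expected):
        assert circadian_function_index(IS, IV, NRA) == pytest.approx(expected)

    def test_iv_clamped_at_white_noise_level(self):
        assert circadian_function_index(0.0, 5.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            circadian_function_index(1.2, 0.0, 0.0)


class TestSyntheticMonotonicity:
    """Indexes respond to the generator dials in the expected direction."""

    @staticmethod
    def _clean_tap(**kw):
        from acmkit.pipeline import analyze_subject
        from acmkit.synthetic import SubjectParams, generate_subject

        p = SubjectParams(seed=77, **kw)
        return analyze_subject(generate_subject(p).recording).clean["TAP"]

    def test_ra_increases_with_amplitude(self):
        from scipy.stats import spearmanr

        from acmkit.synthetic import DEFAULT_AMPLITUDE
        from acmkit.timeseries import mean_waveform

        scales = np.linspace(0.4, 2.0, 7)
        ras = []
        for c in scales:
            ch = self._clean_tap(
                amplitude={k: v * float(c) for k, v in DEFAULT_AMPLITUDE.items()}
            )
            ml = ml_levels(mean_waveform(ch))
            ras.append(relative_amplitude(ml.m_level, ml.l_level))
        assert spearmanr(scales, ras).statistic > 0.8
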