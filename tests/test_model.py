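import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from symdet.model import (
    CONDITIONS,
    CUED,
    DOUBLE_CORNER_PARAMS,
    HIGH,
    LOW,
    NONCUED,
    ChannelParams,
    Condition,
    DecisionConfig,
    ModelDomainError,
    NoThresholdError,
    TABLE1_PARAMS,
    TvDDataset,
    channel_response,
    control_response,
    dprime,
    excitation,
    pooled_response,
    threshold,
    thresholds,
    tvd_curve,
    tvd_slope,
)


class TestExcitation:
    def test_zero_density(self):
        assert excitation(1000.0, 0.0) == 0.0

    def test_zero_sensitivity(self):
        assert excitation(0.0, 0.5) == 0.0

    def test_linearity(self):
        assert excitation(250.0, 0.04) == pytest.approx(2 * excitation(250.0, 0.02))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            excitation(-1.0, 0.1)
        with pytest.raises(ValueError):
            excitation(1.0, -0.1)


class TestChannelResponse:
    def test_zero_densities_zero_response(self, cc_params, cued_high):
        assert channel_response(0.0, 0.0, cc_params, cued_high) == 0.0

    def test_no_noise_path_zero(self, cued_high):
        params = ChannelParams(
            s_et={(CUED, HIGH): 100.0, (CUED, LOW): 100.0,
                  (NONCUED, HIGH): 100.0, (NONCUED, LOW): 100.0},
            s_eb=0.0, s_it={HIGH: 10.0, LOW: 10.0}, s_ib=50.0,
            z_prime=1.0, p=2.0)
        assert channel_response(0.0, 0.5, params, cued_high) == 0.0

    def test_hand_computed_value(self, cc_params, cued_high):
        # independent arithmetic evaluation of the response formula with
        # the CC parameter row (S_et=1000, S_eb=1.68, S_it=890,
        # S_ib=1196, z'=0.15, p=2.17, q=2) at D_sym = D_rand = 0.01
        num = (1000 * 0.01 + 1.68 * 0.01) ** 2.17
        den = (890 * 0.01) ** 2 + (1196 * 0.01) ** 2 + 0.15
        expected = num / den
        assert expected == pytest.approx(0.6674888695510748, rel=1e-12)
        got = channel_response(0.01, 0.01, cc_params, cued_high)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_domain_error_zero_over_zero(self, cued_high):
        params = ChannelParams(
            s_et={(CUED, HIGH): 100.0, (CUED, LOW): 100.0,
                  (NONCUED, HIGH): 100.0, (NONCUED, LOW): 100.0},
            s_eb=1.0, s_it={HIGH: 10.0, LOW: 10.0}, s_ib=50.0,
            z_prime=0.0, p=2.0)
        with pytest.raises(ModelDomainError):
            channel_response(0.0, 0.0, params, cued_high)

    def test_summed_grouping_switch(self, cc_params, cued_high):
        alt = cc_params.copy()
        alt.grouping = "summed"
        num = (1000 * 0.01 + 1.68 * 0.01) ** 2.17
        den = (890 * 0.01 + 1196 * 0.01) ** 2 + 0.15
        assert channel_response(0.01, 0.01, alt, cued_high) == pytest.approx(num / den)

    def test_condition_selects_sensitivities(self, cc_params):
        r_high = channel_response(0.01, 0.0, cc_params, Condition(CUED, HIGH))
        r_low = channel_response(0.01, 0.0, cc_params, Condition(CUED, LOW))
        assert r_high != r_low


class TestControlResponse:
    def test_zero_target_reduces_to_channel_response(self, cc_params, cued_high):
        assert control_response(0.0, 0.02, cc_params, cued_high) == pytest.approx(
            channel_response(0.0, 0.02, cc_params, cued_high))

    def test_zero_both(self, cc_params, cued_high):
        assert control_response(0.0, 0.0, cc_params, cued_high) == 0.0

    def test_monotone_in_target_density_sparse(self, cc_params, cued_high):
        dts = np.linspace(0, 0.05, 30)
        resp = control_response(dts, 0.01, cc_params, cued_high)
        assert np.all(np.diff(resp) > 0)


class TestPooledResponse:
    def test_identity_single_channel(self):
        assert pooled_response(1.7, 99.0, 1, 1) == pytest.approx(1.7)

    def test_four_equal_channels(self):
        assert pooled_response(2.0, 2.0, 4, 4) == pytest.approx(4**0.25 * 2.0)

    def test_zero_nonresponding(self):
        assert pooled_response(3.0, 0.0, 4, 1) == pytest.approx(3.0)

    def test_invalid_m_n(self):
        with pytest.raises(ValueError):
            pooled_response(1.0, 1.0, 1, 2)


class TestDprime:
    @pytest.mark.parametrize("condition", CONDITIONS)
    @pytest.mark.parametrize("observer", sorted(TABLE1_PARAMS))
    def test_zero_target_gives_zero_exactly(self, observer, condition):
        assert dprime(0.0, 0.05, TABLE1_PARAMS[observer], condition) == 0.0

    def test_noncued_pooling_algebra(self, uniform_params):
        # with identical channel parameters across cue conditions the
        # non-cued d' equals the 4th-power-pooled difference over 0.71
        d_t, d_b = 0.01, 0.02
        cond = Condition(NONCUED, HIGH)
        rt = channel_response(d_t, d_b, uniform_params, cond)
        rc = control_response(d_t, d_b, uniform_params, cond)
        expected = ((rt**4 + 3 * rc**4) ** 0.25 - (4 * rc**4) ** 0.25) / 0.71
        assert dprime(d_t, d_b, uniform_params, cond) == pytest.approx(expected)

    def test_strictly_increasing_in_target_density(self, cc_params, cued_high):
        dts = np.logspace(-4, np.log10(0.2), 60)
        dp = dprime(dts, 0.01, cc_params, cued_high)
        assert np.all(np.diff(dp) > 0)


class TestThreshold:
    def test_unreachable_raises(self, cued_high):
        params = ChannelParams(
            s_et={(CUED, HIGH): 0.0, (CUED, LOW): 0.0,
                  (NONCUED, HIGH): 0.0, (NONCUED, LOW): 0.0},
            s_eb=0.0, s_it={HIGH: 10.0, LOW: 10.0}, s_ib=50.0,
            z_prime=1.0, p=2.0)
        with pytest.raises(NoThresholdError):
            threshold(0.01, params, cued_high)

    @pytest.mark.parametrize("observer,condition", [
        ("CC", Condition(CUED, HIGH)),
        ("CC", Condition(NONCUED, LOW)),
        ("TR", Condition(NONCUED, HIGH)),
        ("LY", Condition(CUED, HIGH)),
    ])
    @pytest.mark.parametrize("d_b", [0.0, 0.001, 0.03])
    def test_agrees_with_grid_oracle(self, observer, condition, d_b):
        # brute force: first of 10^4 log-spaced candidates reaching the
        # criterion; solver must agree within the grid spacing
        params = TABLE1_PARAMS[observer]
        grid = np.logspace(-6, 0, 10_000)
        dp = dprime(grid, d_b, params, condition)
        idx = np.argmax(dp >= 1.0)
        assert dp[idx] >= 1.0, "criterion never reached in oracle grid"
        t_oracle = grid[idx]
        t_solver = threshold(d_b, params, condition)
        spacing = 6.0 / 9999
        assert abs(np.log10(t_solver) - np.log10(t_oracle)) <= spacing + 1e-12

    def test_noncued_above_cued_when_control_response_substantial(self, uniform_params):
        # uncertainty pooling penalizes detection once the control
        # response is an appreciable fraction of the target response
        for d_b in (0.02, 0.05, 0.1):
            t_c = threshold(d_b, uniform_params, Condition(CUED, HIGH))
            t_n = threshold(d_b, uniform_params, Condition(NONCUED, HIGH))
            assert t_n >= t_c

    def test_vectorized_matches_scalar(self, cc_params, cued_high):
        d_b = np.array([0.0, 0.001, 0.01, 0.1])
        vec = thresholds(d_b, cc_params, cued_high)
        for db, tv in zip(d_b, vec):
            assert threshold(float(db), cc_params, cued_high) == pytest.approx(tv, rel=1e-9)

    def test_on_fail_nan(self, cued_high):
        params = ChannelParams(
            s_et={(CUED, HIGH): 0.0, (CUED, LOW): 0.0,
                  (NONCUED, HIGH): 0.0, (NONCUED, LOW): 0.0},
            s_eb=0.0, s_it={HIGH: 10.0, LOW: 10.0}, s_ib=50.0,
            z_prime=1.0, p=2.0)
        out = thresholds(np.array([0.01]), params, cued_high, on_fail="nan")
        assert np.isnan(out).all()


class TestTvDCurve:
    def test_ablate_z_prime_lowers_low_limb_only(self, cc_params, cued_high):
        lo = np.logspace(-4, -3.2, 5)
        hi = np.logspace(-1.5, -1, 5)
        base_lo = thresholds(lo, cc_params, cued_high)
        base_hi = thresholds(hi, cc_params, cued_high)
        abl_lo = thresholds(lo, cc_params.ablate("z_prime"), cued_high)
        abl_hi = thresholds(hi, cc_params.ablate("z_prime"), cued_high)
        assert np.all(abl_lo < base_lo)
        assert np.allclose(np.log10(abl_hi), np.log10(base_hi), atol=0.01)

    def test_ablate_s_it_changes_high_limb(self, cc_params, cued_high):
        hi = np.logspace(-1.5, -1, 5)
        base = thresholds(hi, cc_params, cued_high)
        abl = thresholds(hi, cc_params.ablate("s_it"), cued_high)
        assert np.all(np.abs(np.log10(abl) - np.log10(base)) > 0.05)

    def test_tvd_curve_dataset(self, cc_params, cued_high, masker_grid):
        tvd = tvd_curve(cc_params, cued_high, masker_grid)
        assert len(tvd) == len(masker_grid)
        assert (tvd.table["condition_cue"] == CUED).all()

    @pytest.mark.parametrize("observer", sorted(TABLE1_PARAMS))
    def test_masking_limb_monotone_up_to_facilitation_dip(self, observer, masker_grid):
        # thresholds rise with masker density on the masking limb; small
        # facilitation dips (< 0.05 log units) can occur when the noise
        # feeds the excitatory path strongly
        params = TABLE1_PARAMS[observer]
        for cond in CONDITIONS:
            thr = thresholds(masker_grid, params, cond, on_fail="nan")
            if np.isnan(thr).any():
                continue
            dips = np.diff(np.log10(thr))
            assert dips.min() > -0.05
            assert np.log10(thr[-1]) > np.log10(thr[0])


class TestTvDSlope:
    def _power_law(self, slope, c=0.05):
        d_b = np.logspace(-3, -1, 10)
        rows = [(Condition(CUED, HIGH), db, c * db**slope, 0.0) for db in d_b]
        return TvDDataset.from_rows(rows)

    def test_exact_power_law(self):
        assert tvd_slope(self._power_law(0.75)) == pytest.approx(0.75, abs=1e-10)

    def test_flat_data(self):
        d_b = np.logspace(-3, -1, 8)
        tvd = TvDDataset.from_rows(
            [(Condition(CUED, HIGH), db, 0.01, 0.0) for db in d_b])
        assert tvd_slope(tvd) == pytest.approx(0.0, abs=1e-12)

    def test_cc_cued_high_slope_below_one(self, cc_params, cued_high):
        tvd = tvd_curve(cc_params, cued_high, np.logspace(-2, -1, 10))
        slope = tvd_slope(tvd, density_range=(0.01, 0.1))
        assert 0.0 < slope < 1.0

    @pytest.mark.parametrize("observer", sorted(TABLE1_PARAMS))
    def test_all_table1_high_density_slopes_below_one(self, observer, masker_grid):
        params = TABLE1_PARAMS[observer]
        for cond in CONDITIONS:
            thr = thresholds(masker_grid, params, cond, on_fail="nan")
            if np.isnan(thr).any():
                continue
            tvd = TvDDataset.from_rows(
                [(cond, float(db), float(t), 0.0)
                 for db, t in zip(masker_grid, thr)])
            assert tvd_slope(tvd) < 1.0

    def test_too_few_points(self):
        tvd = TvDDataset.from_rows([(Condition(CUED, HIGH), 0.01, 0.005, 0.0)])
        with pytest.raises(ValueError):
            tvd_slope(tvd)


class TestDoubleCorner:
    def test_two_curvature_maxima(self):
        # the slope-increase rate of the log-log TvD function must show
        # two distinct local maxima (two "corners")
        grid = np.logspace(-4, -2.05, 80)
        thr = thresholds(grid, DOUBLE_CORNER_PARAMS, Condition(CUED, HIGH))
        lg, lt = np.log10(grid), np.log10(thr)
        slope = np.gradient(lt, lg)
        dslope = np.gradient(slope, lg)
        peaks, _ = find_peaks(dslope, height=0.08, prominence=0.08)
        assert len(peaks) >= 2
        assert lg[peaks[1]] - lg[peaks[0]] > 0.5


class TestDecisionConfig:
    def test_canonical_cued(self):
        d = DecisionConfig.for_condition(Condition(CUED, HIGH))
        assert (d.m, d.n, d.gamma) == (1, 1, 1.0)

    def test_canonical_noncued(self):
        d = DecisionConfig.for_condition(Condition(NONCUED, LOW))
        assert (d.m, d.n, d.gamma) == (4, 1, 0.71)

    def test_invalid(self):
        with pytest.raises(ValueError):
            DecisionConfig(m=1, n=2)


class TestTvDDataset:
    def test_csv_roundtrip_12_digits(self, tmp_path, cc_params, cued_high, masker_grid):
        tvd = tvd_curve(cc_params, cued_high, masker_grid)
        path = tmp_path / "tvd.csv"
        tvd.to_csv(path)
        back = TvDDataset.from_csv(path)
        np.testing.assert_allclose(
            back.table["threshold_density"], tvd.table["threshold_density"],
            rtol=1e-11)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            TvDDataset(pd.DataFrame({
                "condition_cue": [CUED], "condition_salience": [HIGH],
                "masker_density": [0.01], "threshold_density": [0.0],
                "se": [0.0]}))

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            Condition("sometimes", HIGH)
        with pytest.raises(ValueError):
            Condition(CUED, "medium")
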