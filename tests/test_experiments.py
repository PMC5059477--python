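"""The in silico experiment battery: signs, orderings, determinism.

These tests assert the central computational claims of the state-dependent
bAP calcium model: the composite inactivating scenario rewards the faster
(hyperpolarized-state) repolarization, the non-inactivating scenario does
not, a -60 mV preceding potential occludes the effect, distal commands are
offset-sensitive while proximal ones are not, theta-phase modulation is
distance-ordered, and recovery from inactivation is slow.
"""

import numpy as np
import pytest

import bapflux as bf
from bapflux.experiments import (
    completeness_scan,
    kinetics_scan,
    offset_scan,
    recovery_scan,
    state_comparison,
    theta_scan,
)

from conftest import state_pct


class TestStateComparison:
    def test_native_composite_is_positive(self, proximal_pair):
        assert state_comparison(proximal_pair, "HN_HI", "native") > 0

    def test_native_non_inactivating_is_null(self, proximal_pair):
        # without an inactivating component the hyperpolarized command no
        # longer drives more influx (small negative is fine, positive not)
        assert state_comparison(proximal_pair, "HN_only", "native") < 2.0

    def test_equalized_composite_stays_positive(self, proximal_pair):
        assert state_comparison(proximal_pair, "HN_HI", "equalized_-80") > 0

    def test_occlusion_at_minus60_abolishes_the_effect(self, proximal_pair):
        assert state_comparison(proximal_pair, "HN_HI", "occluded_-60") <= 0

    def test_unknown_mode_rejected(self, proximal_pair):
        with pytest.raises(ValueError, match="preceding"):
            state_comparison(proximal_pair, "HN_HI", "equalized_-120")


@pytest.fixture(scope="module")
def offset_result(params):
    prox = bf.generate_bap(24.0, "depolarized", params)
    dist = bf.generate_bap(150.0, "depolarized", params)
    return offset_scan([prox, dist], offsets_mV=[6.0, 0.0, -10.0, -20.0, -30.0])


@pytest.fixture(scope="module")
def kinetics_coarse(equalized_pair):
    return kinetics_scan(equalized_pair, act_scale_factors=[0.5, 1.0, 2.0],
                         inact_taus_ms=[0.5, 3.4, 50.0, 500.0])


@pytest.fixture(scope="module")
def completeness_results(params):
    prox = bf.generate_bap(24.0, "depolarized", params)
    dist = bf.generate_bap(150.0, "depolarized", params)
    exts = [0.0, 0.75, 2.0, 3.5, 5.0]
    return (completeness_scan(prox, exts), completeness_scan(dist, exts))


@pytest.fixture(scope="module")
def theta_result():
    return theta_scan(phases_deg=np.arange(0.0, 360.0, 30.0),
                      distances_um=(40.0, 150.0))


@pytest.fixture(scope="module")
def recovery_result():
    return recovery_scan("HI_only", interpulse_ms=[25.0, 100.0, 400.0, 1600.0])


class TestOffsetScan:
    def test_zero_offset_is_100_percent(self, offset_result):
        j = list(offset_result.axes["offset_mV"]).index(0.0)
        np.testing.assert_allclose(offset_result.values[:, j], 100.0, rtol=1e-12)

    def test_distal_charge_decreases_monotonically_with_negative_offset(
            self, offset_result):
        offs = offset_result.axes["offset_mV"]
        neg = offs <= 0.0
        distal_row = offset_result.values[1, neg]
        assert np.all(np.diff(distal_row) < 0)

    def test_proximal_insensitive_relative_to_distal(self, offset_result):
        offs = list(offset_result.axes["offset_mV"])
        prox_at_m30 = offset_result.values[0, offs.index(-30.0)]
        dist_at_m10 = offset_result.values[1, offs.index(-10.0)]
        assert abs(100.0 - prox_at_m30) < abs(100.0 - dist_at_m10)

    def test_empty_offsets_rejected(self, params):
        with pytest.raises(ValueError, match="offset"):
            offset_scan(bf.generate_bap(24.0, "depolarized", params), [])


class TestKineticsScan:
    def test_standard_kinetics_cell_is_positive(self, equalized_pair):
        # the shipped inactivation tau at the -30 mV reference is ~3.4 ms;
        # at standard activation kinetics the faster-repolarizing command
        # must gain influx
        res = kinetics_scan(equalized_pair, act_scale_factors=[1.0],
                            inact_taus_ms=[
                                float(bf.build_channel("HI").gating.h
                                      .time_constant(-30.0))])
        assert res.values[0, 0] > 0

    def test_non_inactivating_limit_is_nonpositive(self, kinetics_coarse):
        slow_col = kinetics_coarse.values[:, -1]  # tau_inact 500 ms
        valid = ~np.isnan(slow_col)
        assert np.all(slow_col[valid] <= 0)

    def test_identical_command_pair_gives_zero_everywhere(self, proximal_pair):
        dep = bf.splice_pair_preceding(proximal_pair, -80.0).depolarized
        pair = bf.BAPStatePair(depolarized=dep, hyperpolarized=dep,
                               distance_um=24.0,
                               align_index=dep.max_rate_of_rise_index())
        res = kinetics_scan(pair, act_scale_factors=[1.0],
                            inact_taus_ms=[3.0, 100.0])
        valid = res.values[~np.isnan(res.values)]
        np.testing.assert_allclose(valid, 0.0, atol=1e-9)

    def test_unrealistic_cells_are_masked(self, equalized_pair):
        # extremely fast inactivation with very slow activation leaves
        # almost no open probability: the cell must be excluded
        res = kinetics_scan(equalized_pair, act_scale_factors=[4.0],
                            inact_taus_ms=[0.05])
        assert res.exclusion_mask[0, 0]
        assert np.isnan(res.values[0, 0])

    def test_degenerate_grid_rejected(self, equalized_pair):
        with pytest.raises(ValueError, match="grid"):
            kinetics_scan(equalized_pair, act_scale_factors=[],
                          inact_taus_ms=[1.0])

    def test_window_sign_consistency_with_state_comparison(
            self, proximal_pair, equalized_pair, scenarios):
        # the 5-ms kinetics window and the 1-ms comparison window agree
        # in sign for the shipped inactivating model
        res = kinetics_scan(equalized_pair, act_scale_factors=[1.0],
                            inact_taus_ms=[
                                float(bf.build_channel("HI").gating.h
                                      .time_constant(-30.0))])
        one_ms = state_pct(equalized_pair, scenarios["HI_only"])
        assert np.sign(res.values[0, 0]) == np.sign(one_ms)


class TestCompletenessScan:
    def test_zero_extension_is_100_percent(self, completeness_results):
        for scan in completeness_results:
            assert scan.values[0] == pytest.approx(100.0, rel=1e-12)

    def test_proximal_growth_saturates(self, completeness_results):
        prox = completeness_results[0].values
        early_increment = prox[1] - prox[0]
        final_increment = prox[-1] - prox[-2]
        assert final_increment < early_increment
        # proximal spikes already activate most of the available current
        assert np.max(np.abs(prox - 100.0)) < 15.0

    def test_distal_growth_exceeds_proximal(self, completeness_results):
        prox, dist = completeness_results[0].values, completeness_results[1].values
        assert np.all(dist[1:] > prox[1:])
        assert dist[-1] > 150.0


class TestThetaScan:
    def test_distal_depolarized_phases_beat_trough_phases(self, theta_result):
        phases = theta_result.axes["phase_deg"]
        distal = theta_result.values[1]
        up = distal[(phases >= 40) & (phases <= 160)]
        down = distal[(phases >= 219) & (phases <= 339)]
        assert up.min() > down.max()
        assert up.mean() > 0          # larger than rest
        assert down.mean() < 0        # smaller than rest

    def test_proximal_modulation_weaker_than_distal(self, theta_result):
        spread = np.ptp(theta_result.values, axis=1)
        assert spread[0] < spread[1]

    def test_zero_amplitude_oscillation_gives_zero_change(self):
        from bapflux.waveform import ProtocolSpec
        proto = ProtocolSpec(kind="theta", theta_peak_mV=-73.3,
                             theta_trough_mV=-73.3, theta_rest_mV=-73.3)
        res = theta_scan(phases_deg=[0.0, 90.0, 270.0], distances_um=(40.0,),
                         protocol=proto)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-6)


class TestRecoveryScan:
    def test_ratio_monotone_and_approaches_one(self, recovery_result):
        ratios = recovery_result.values
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] > 0.95

    def test_short_interval_reflects_residual_availability(self, recovery_result):
        assert recovery_result.values[0] < 0.2

    def test_recovery_tau_matches_rest_inactivation_tau(self, recovery_result):
        # the fitted recovery time constant is the h time constant at the
        # holding potential (-80 mV), a few hundred ms
        tau = recovery_result.provenance["recovery_tau_ms"]
        expected = float(bf.build_channel("HI").gating.h.time_constant(-80.0))
        assert tau == pytest.approx(expected, rel=0.1)

    def test_non_inactivating_scenario_is_flat(self):
        res = recovery_scan("HN_only", interpulse_ms=[25.0, 400.0])
        np.testing.assert_allclose(res.values, 1.0, atol=1e-6)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            recovery_scan("HI_only", interpulse_ms=[0.0])


class TestDeterminism:
    def test_rerun_is_bit_identical(self, params):
        cmd = bf.generate_bap(24.0, "depolarized", params, dt=0.0025)
        a = offset_scan(cmd, offsets_mV=[0.0, -10.0])
        b = offset_scan(cmd, offsets_mV=[0.0, -10.0])
        assert np.array_equal(a.values, b.values)

    def test_scan_result_frame_shape(self, params):
        cmd = bf.generate_bap(24.0, "depolarized", params, dt=0.0025)
        res = offset_scan(cmd, offsets_mV=[0.0, -10.0])
        frame = res.to_frame()
        assert len(frame) == 2
        assert set(frame.columns) >= {"distance_um", "offset_mV", "value"}
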