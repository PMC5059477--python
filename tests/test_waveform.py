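"""Synthetic bAP generator: state dependence, editing ops, protocols."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bapflux as bf
from bapflux.waveform import ProtocolSpec, step_protocol, theta_protocol


class TestGenerateBap:
    def test_state_baselines_match_recorded_values(self, params):
        dep = bf.generate_bap(24.0, "depolarized", params)
        hyp = bf.generate_bap(24.0, "hyperpolarized", params)
        assert dep.samples[0] == pytest.approx(-64.6, abs=1e-9)
        assert hyp.samples[0] == pytest.approx(-77.2, abs=1e-9)

    def test_unknown_state_rejected(self, params):
        with pytest.raises(ValueError, match="state"):
            bf.generate_bap(24.0, "resting", params)

    def test_too_coarse_dt_rejected(self, params):
        with pytest.raises(ValueError, match="dt"):
            bf.generate_bap(24.0, "depolarized", params, dt=0.05)

    def test_proximal_peaks_equal_in_absolute_voltage(self, proximal_pair):
        dep_peak = proximal_pair.depolarized.samples.max()
        hyp_peak = proximal_pair.hyperpolarized.samples.max()
        assert hyp_peak == pytest.approx(dep_peak, abs=0.05)

    def test_distal_peak_deficit_tracks_baseline_offset(self, params):
        dep = bf.generate_bap(150.0, "depolarized", params)
        hyp = bf.generate_bap(150.0, "hyperpolarized", params)
        c = params.compensation(150.0)
        expected = (1.0 - c) * params.hyper_shift_mV
        assert dep.samples.max() - hyp.samples.max() == pytest.approx(
            expected, abs=0.05)

    def test_state_collapse_when_shift_and_speedup_zero(self, params):
        p = dataclasses.replace(params, hyper_shift_mV=0.0, repol_speedup=0.0)
        dep = bf.generate_bap(24.0, "depolarized", p)
        hyp = bf.generate_bap(24.0, "hyperpolarized", p)
        np.testing.assert_array_equal(dep.samples, hyp.samples)

    def test_depolarized_peak_monotone_in_distance(self, params):
        dists = np.linspace(0.0, 300.0, 13)
        peaks = [bf.generate_bap(d, "depolarized", params, 0.005).samples.max()
                 for d in dists]
        assert np.all(np.diff(peaks) <= 1e-9)

    def test_hyperpolarized_deficit_monotone_in_distance(self, params):
        dists = np.linspace(0.0, 300.0, 13)
        defs = []
        for d in dists:
            dep = bf.generate_bap(d, "depolarized", params, 0.005)
            hyp = bf.generate_bap(d, "hyperpolarized", params, 0.005)
            defs.append(dep.samples.max() - hyp.samples.max())
        # tolerance covers the discrete sampling of the peak (< 0.01 mV)
        assert np.all(np.diff(defs) >= -0.01)


class TestStatePair:
    def test_align_index_matches_bruteforce_argmax(self, proximal_pair):
        # oracle: exhaustive argmax of first differences on each trace
        for trace in (proximal_pair.depolarized, proximal_pair.hyperpolarized):
            dv = np.diff(trace.samples)
            brute = max(range(dv.size), key=lambda i: dv[i])
            assert trace.max_rate_of_rise_index() == brute
        assert (proximal_pair.depolarized.max_rate_of_rise_index()
                == proximal_pair.align_index)

    def test_difference_has_single_negative_extremum_after_peak(
            self, proximal_pair):
        i_pk = int(np.argmax(proximal_pair.depolarized.samples))
        diff = proximal_pair.difference()
        post = diff[i_pk: i_pk + int(5.0 / proximal_pair.dt)]
        assert post.min() < -3.0
        assert post[0] > post.min()  # dips after the peak, not at it

    def test_distal_difference_at_peak_is_baseline_offset_when_c_zero(
            self, params):
        p = dataclasses.replace(params, peak_compensation_c=0.0,
                                repol_speedup=0.0)
        pair = bf.generate_state_pair(150.0, p)
        i_pk = int(np.argmax(pair.depolarized.samples))
        assert pair.difference()[i_pk] == pytest.approx(
            -p.hyper_shift_mV, abs=0.05)

    def test_alignment_is_idempotent(self, proximal_pair):
        again = bf.align_state_pair(proximal_pair.depolarized,
                                    proximal_pair.hyperpolarized, 24.0)
        np.testing.assert_array_equal(again.depolarized.samples,
                                      proximal_pair.depolarized.samples)
        np.testing.assert_array_equal(again.hyperpolarized.samples,
                                      proximal_pair.hyperpolarized.samples)


class TestEditingOps:
    def test_offset_identity_and_uniform_shift(self, proximal_pair):
        tr = proximal_pair.depolarized
        assert bf.offset_trace(tr, 0.0).samples is not tr.samples
        np.testing.assert_array_equal(bf.offset_trace(tr, 0.0).samples,
                                      tr.samples)
        shifted = bf.offset_trace(tr, -30.0)
        assert shifted.samples.min() == pytest.approx(tr.samples.min() - 30.0)
        assert shifted.samples.max() == pytest.approx(tr.samples.max() - 30.0)
        assert shifted.n == tr.n and shifted.dt == tr.dt

    def test_offset_round_trips(self, proximal_pair):
        tr = proximal_pair.depolarized
        back = bf.offset_trace(bf.offset_trace(tr, 6.0), -6.0)
        np.testing.assert_allclose(back.samples, tr.samples, atol=1e-12)

    @pytest.mark.parametrize("v_pre", [-80.0, -60.0])
    def test_splice_pair_equalizes_pre_peak_segment(self, proximal_pair, v_pre):
        spliced = bf.splice_pair_preceding(proximal_pair, v_pre)
        i_pk = int(np.argmax(spliced.depolarized.samples))
        np.testing.assert_array_equal(
            spliced.depolarized.samples[: i_pk + 1],
            spliced.hyperpolarized.samples[: i_pk + 1])
        assert spliced.depolarized.samples[0] == v_pre
        # post-peak course untouched
        np.testing.assert_array_equal(
            spliced.hyperpolarized.samples[i_pk + 1:],
            proximal_pair.hyperpolarized.samples[i_pk + 1:])

    def test_splice_trace_already_at_target_changes_nothing_before_spike(
            self, params):
        p = dataclasses.replace(params, baseline_mV=-80.0, hyper_shift_mV=0.0)
        tr = bf.generate_bap(24.0, "depolarized", p)
        spliced = bf.splice_preceding(tr, -80.0)
        np.testing.assert_allclose(spliced.samples, tr.samples, atol=0.3)

    def test_plateau_extension_bookkeeping(self, proximal_pair):
        tr = proximal_pair.depolarized
        assert bf.extend_prepeak_plateau(tr, 0.0) is tr
        ext = bf.extend_prepeak_plateau(tr, 5.0)
        assert ext.n == tr.n + round(5.0 / tr.dt)

    def test_plateau_preserves_post_peak_segment(self, proximal_pair):
        tr = proximal_pair.depolarized
        ext = bf.extend_prepeak_plateau(tr, 2.0)
        i_pk = int(np.argmax(tr.samples))
        n_ext = round(2.0 / tr.dt)
        np.testing.assert_array_equal(ext.samples[i_pk + n_ext:],
                                      tr.samples[i_pk:])
        with pytest.raises(ValueError):
            bf.extend_prepeak_plateau(tr, -1.0)


class TestProtocols:
    def test_step_protocol_two_levels(self):
        spec = ProtocolSpec(kind="step", holding_mV=-80.0, test_mV=0.0,
                            baseline_ms=10.0, test_ms=3.0, dt_ms=0.01)
        tr = step_protocol(spec)
        assert set(np.unique(tr.samples)) == {-80.0, 0.0}
        n_test = int(np.sum(tr.samples == 0.0))
        assert n_test == round(3.0 / 0.01)

    def test_paired_pulse_zero_gap_merges(self):
        spec = ProtocolSpec(kind="paired_pulse", baseline_ms=10.0, test_ms=3.0,
                            interpulse_ms=0.0, dt_ms=0.01)
        tr = step_protocol(spec)
        assert int(np.sum(tr.samples == 0.0)) == 2 * round(3.0 / 0.01)
        # contiguous: one merged pulse
        idx = np.nonzero(tr.samples == 0.0)[0]
        assert np.all(np.diff(idx) == 1)

    def test_theta_onset_voltage_equals_sinusoid_value(self, params):
        spec = ProtocolSpec(kind="theta", ap_phase_deg=90.0)
        ap = bf.generate_bap(40.0, "depolarized", params, dt=0.0125)
        tr = theta_protocol(spec, ap)
        mid = 0.5 * (spec.theta_peak_mV + spec.theta_trough_mV)
        amp = 0.5 * (spec.theta_peak_mV - spec.theta_trough_mV)
        n_base = round((5 + 90.0 / 360.0) / 5.2 * 1000.0 / 0.0125)
        assert tr.samples[n_base] == pytest.approx(mid + amp, abs=0.01)

    def test_theta_rest_variant_is_flat(self, params):
        spec = ProtocolSpec(kind="theta", n_cycles=0)
        ap = bf.generate_bap(40.0, "depolarized", params, dt=0.0125)
        tr = theta_protocol(spec, ap)
        n_base = round(1000.0 / 5.2 / 0.0125)
        assert np.all(tr.samples[:n_base] == -73.3)

    def test_theta_phase_wraps_continuously(self, params):
        ap = bf.generate_bap(40.0, "depolarized", params, dt=0.0125)
        v0 = theta_protocol(ProtocolSpec(kind="theta", ap_phase_deg=0.0), ap)
        v360 = theta_protocol(
            ProtocolSpec(kind="theta", ap_phase_deg=359.99), ap)
        # onset voltages converge (one is a full cycle longer)
        i0 = np.argmax(v0.samples)
        i1 = np.argmax(v360.samples)
        assert v0.samples[i0] == pytest.approx(v360.samples[i1], abs=0.05)

    def test_theta_requires_five_cycles(self):
        with pytest.raises(ValueError, match="cycles"):
            ProtocolSpec(kind="theta", n_cycles=3)


class TestGiaPair:
    def test_pre_peak_segments_identical_and_difference_negative(self):
        ap = bf.generate_bap(0.0, "depolarized", bf.somatic_ap_params())
        ctrl, mod = bf.generate_gia_pair(ap)
        i_pk = int(np.argmax(ctrl.samples))
        np.testing.assert_array_equal(ctrl.samples[:i_pk], mod.samples[:i_pk])
        diff = mod.samples - ctrl.samples
        assert diff[i_pk:].min() < -2.0
        assert int(np.argmin(diff)) > i_pk

    def test_zero_speedup_is_identity(self):
        ap = bf.generate_bap(0.0, "depolarized", bf.somatic_ap_params())
        ctrl, mod = bf.generate_gia_pair(ap, speedup=0.0)
        assert mod is ap

    def test_requires_an_action_potential(self):
        flat = bf.VoltageTrace(dt=0.01, samples=np.full(100, -70.0))
        with pytest.raises(ValueError, match="action potential"):
            bf.generate_gia_pair(flat)

    def test_difference_statistics_match_conductance_clamp_values(self):
        # printed comparison: -3.2 +/- 0.6 mV, 0.75 +/- 0.17 ms after the
        # peak, half-duration 1.35 +/- 0.18 ms
        ap = bf.generate_bap(0.0, "depolarized", bf.somatic_ap_params())
        ctrl, mod = bf.generate_gia_pair(ap)
        i = ctrl.max_rate_of_rise_index()
        pair = bf.BAPStatePair(depolarized=ctrl, hyperpolarized=mod,
                               distance_um=0.0, align_index=i)
        stats = bf.difference_stats(pair)
        assert stats.extremum_mV == pytest.approx(-3.2, abs=0.6)
        assert stats.latency_after_peak_ms == pytest.approx(0.75, abs=0.17)
        assert stats.half_duration_ms == pytest.approx(1.35, abs=0.18)


@settings(max_examples=20, deadline=None)
@given(distance=st.floats(0.0, 300.0),
       delta=st.floats(-20.0, 6.0))
def test_editing_preserves_dt_and_length(distance, delta):
    tr = bf.generate_bap(distance, "depolarized", bf.default_params(), 0.005)
    for edited in (bf.offset_trace(tr, delta), bf.splice_preceding(tr, -80.0)):
        assert edited.dt == tr.dt
        assert edited.n == tr.n
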