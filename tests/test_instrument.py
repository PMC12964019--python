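import numpy as np
import pytest

from mhqpeldor import instrument as inst
from mhqpeldor._utils import round_half_up
from mhqpeldor.exceptions import (
    FitError,
    InvalidFlowError,
    InvalidGeometryError,
    OutOfModelError,
)

# transport/aging times (us) for the standard nozzle distances, as measured
TABLE3 = {
    3: (47, 82), 5: (66, 99), 7: (85, 116), 10: (113, 142), 17: (179, 201),
    23: (236, 252), 29: (292, 303), 41: (405, 405), 52: (509, 498),
    61: (594, 574), 72: (697, 668),
}


class TestJetTransport:
    def test_jet_velocity_reference_setting(self, geometry, flow):
        # 2 mL/min through a 20 um orifice -> ~106 m/s
        v = inst.jet_velocity(geometry, flow)
        assert v == pytest.approx(1.061e5, rel=1e-3)

    def test_jet_velocity_linear_in_flow(self, geometry, flow):
        doubled = inst.FlowSettings(flow.per_channel_flow * 2, flow.n_channels)
        assert inst.jet_velocity(geometry, doubled) == pytest.approx(
            2 * inst.jet_velocity(geometry, flow))

    def test_invalid_flow_rejected(self):
        with pytest.raises(InvalidFlowError):
            inst.FlowSettings(per_channel_flow=0.0)

    def test_invalid_orifice_rejected(self):
        with pytest.raises(InvalidGeometryError):
            inst.MhqGeometry(orifice_radius=0.0)

    @pytest.mark.parametrize("dist,tt,ta", [(d, *v) for d, v in TABLE3.items()])
    def test_aging_time_table_reproduces_measured_values(
            self, geometry, flow, dist, tt, ta):
        assert round_half_up(inst.transport_time(geometry, flow, dist)) == tt
        assert round_half_up(inst.aging_time(geometry, flow, dist)) == ta

    def test_aging_time_table_frame(self, geometry, flow):
        df = inst.aging_time_table(geometry, flow)
        for _, row in df.iterrows():
            tt, ta = TABLE3[int(row.distance_mm)]
            assert abs(row.tt_us - tt) <= 1
            assert abs(row.ta_us - ta) <= 1

    def test_zero_distance_zero_offset(self, flow):
        geom = inst.MhqGeometry(internal_jet_offset=0.0)
        assert inst.transport_time(geom, flow, 0.0) == 0.0
        assert inst.aging_time(geom, flow, 0.0) == geom.cryofixation_time_tc

    def test_offset_calibration_from_measured_table(self, geometry, flow):
        d = sorted(TABLE3)
        tt = [TABLE3[x][0] for x in d]
        off = inst.calibrate_jet_offset(d, tt, geometry, flow)
        assert off == pytest.approx(2.0, abs=0.05)


class TestMixerArmSynchronisation:
    def test_dead_volume(self, geometry):
        assert round_half_up(inst.dead_volume(geometry)) == 94

    def test_dead_volume_linear_in_length(self, geometry, flow):
        doubled = inst.MhqGeometry(tubing_length_h=2 * geometry.tubing_length_h)
        assert inst.dead_volume(doubled) == pytest.approx(
            2 * inst.dead_volume(geometry))

    def test_loop_to_mixer_time(self, geometry, flow):
        # the printed 5.63 s uses the rounded dead volume (94 uL / 16.7 uL/s);
        # the unrounded chain agrees within 0.5%
        t = inst.loop_to_mixer_time(geometry, flow)
        assert t == pytest.approx(5.63, rel=5e-3)
        assert round_half_up(94.0 / 16.7, 2) == 5.63

    def test_loop_to_mixer_simple_ratio(self, geometry):
        # V_d = 100 uL at 10 uL/s -> 10 s
        geom = inst.MhqGeometry(tubing_length_h=100 / (np.pi * 0.127**2),
                                tubing_radius_r=0.127)
        t = inst.loop_to_mixer_time(geom, inst.FlowSettings(10.0))
        assert t == pytest.approx(10.0)

    def test_mixer_arm_velocity(self, geometry, flow):
        v_mm, v_ust = inst.mixer_arm_velocity(geometry, flow, 200.0)
        assert round_half_up(v_mm, 1) == 16.5
        assert v_ust == pytest.approx(1.33e5, rel=5e-3)

    def test_mixer_arm_velocity_halves_with_flow(self, geometry, flow):
        half = inst.FlowSettings(flow.per_channel_flow / 2, flow.n_channels)
        v_full, _ = inst.mixer_arm_velocity(geometry, flow, 200.0)
        v_half, _ = inst.mixer_arm_velocity(geometry, half, 200.0)
        assert v_half == pytest.approx(v_full / 2)

    def test_mixer_dead_time(self, geometry):
        assert round_half_up(inst.mixer_dead_time(geometry, 16.533), 2) == 1.13
        geom = inst.MhqGeometry(approach_distance_dmc=33.0)
        assert inst.mixer_dead_time(geom, 16.5) == pytest.approx(2.0)

    def test_optimal_wait_time(self, geometry, flow):
        w = inst.optimal_wait_time(geometry, flow, 200.0)
        assert round_half_up(w.wait_time_s, 1) == 4.5
        assert w.reachable

    def test_wait_time_monotone_in_sample_volume(self, geometry, flow):
        # larger samples slow the arm sweep, so the dead time grows and the
        # wait-time shrinks; at 1.4 mL the theoretical optimum is not
        # reachable with the standard pumps and the report flags it
        volumes = np.array([100.0, 200.0, 400.0, 800.0])
        waits = []
        for vs in volumes:
            waits.append(inst.optimal_wait_time(geometry, flow, vs).wait_time_s)
        assert np.all(np.diff(waits) < 0)

    def test_wait_time_strictly_decreasing_in_flow(self, geometry):
        # both the loop transit and the arm approach shrink with faster flow
        per_channel = np.linspace(8.0, 40.0, 9)
        waits = [
            inst.optimal_wait_time(geometry, inst.FlowSettings(f), 200.0).wait_time_s
            for f in per_channel
        ]
        assert np.all(np.diff(waits) < 0)

    def test_unreachable_wait_time_warns(self, geometry, flow):
        with pytest.warns(UserWarning, match="negative wait-time"):
            w = inst.optimal_wait_time(geometry, flow, 1400.0)
        assert not w.reachable
        assert w.wait_time_s < 0


class TestDilutionModel:
    def test_minimum_at_t0(self):
        assert inst.dilution_factor(5.33, 5.33, 16.67, 100, 200) == pytest.approx(2.0)

    def test_reference_evaluation(self):
        f = inst.dilution_factor(4.5, 5.33, 16.67, 100, 200)
        assert f == pytest.approx(200 / (100 - 16.67 * 0.83**2), rel=1e-12)
        assert f == pytest.approx(2.26, abs=0.01)

    def test_even_in_time_offset(self):
        for d in (0.3, 0.7, 1.2):
            assert inst.dilution_factor(5.33 + d, 5.33, 16.67, 100, 200) == \
                pytest.approx(inst.dilution_factor(5.33 - d, 5.33, 16.67, 100, 200))

    def test_out_of_model_domain(self):
        with pytest.raises(OutOfModelError):
            inst.dilution_factor(10.5, 5.33, 16.67, 100, 200)

    def test_ratio_is_clamped_inverse(self):
        r = inst.dilution_ratio([5.33, 10.5], 5.33, 16.67, 100, 200)
        assert r[0] == pytest.approx(0.5)
        assert r[1] == 0.0

    def test_fit_recovers_t0_noiseless(self):
        tw = np.array([2.5, 3.5, 4.5, 6.5, 8.5, 10.5])
        series = inst.DilutionSeries(
            tw, inst.dilution_ratio(tw, 5.33, 16.67, 100, 200))
        fit = inst.fit_dilution_profile(series, 16.67, 100, 200)
        assert fit.t0 == pytest.approx(5.33, abs=1e-6)

    def test_fit_underdetermined_guard(self):
        with pytest.raises(FitError):
            inst.fit_dilution_profile(
                inst.DilutionSeries([4.0, 5.0], [0.4, 0.5]), 16.67, 100, 200)
        with pytest.raises(FitError):
            inst.fit_dilution_profile(
                inst.DilutionSeries([5.0, 5.0, 5.0], [0.4, 0.5, 0.45]),
                16.67, 100, 200)

    def test_fit_coverage_under_noise(self):
        # 2-sigma interval covers the true t0 in >= 90% of 500 noisy series
        tw = np.linspace(3.0, 8.0, 7)
        truth = inst.dilution_ratio(tw, 5.33, 16.67, 100, 200)
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(500):
            series = inst.DilutionSeries(tw, truth + rng.normal(0, 0.02, 7))
            fit = inst.fit_dilution_profile(series, 16.67, 100, 200)
            hits += abs(fit.t0 - 5.33) <= fit.t0_2sigma
        assert hits / 500 >= 0.90


class TestDeposition:
    def test_reference_report(self, geometry, flow):
        rep = inst.deposition_model(geometry, flow, 200.0)
        assert round_half_up(rep.circumference_U) == 408
        assert round_half_up(rep.film_thickness_x) == 11
        assert 2 < rep.n_layers < 3

    def test_layers_proportional_to_flow_and_volume_free(self, geometry):
        # laying the whole jet as one layer takes a fixed time; expelling
        # the sample faster piles it up in proportionally more layers, and
        # the sample volume cancels out of the ratio
        flows = np.linspace(10.0, 40.0, 5)
        for vs in (100.0, 200.0, 400.0):
            n = np.array([
                inst.deposition_model(geometry, inst.FlowSettings(f), vs).n_layers
                for f in flows
            ])
            assert np.allclose(n / flows, n[0] / flows[0], rtol=1e-12)
            assert np.allclose(
                n, [inst.deposition_model(geometry, inst.FlowSettings(f), 200.0).n_layers
                    for f in flows], rtol=1e-12)


class TestCommandsAndPrep:
    @pytest.mark.parametrize("args,expected", [
        ((4500, 50000, 600000), "/1H04M4500A50000A600000R"),
        ((2500, 50000, 600000), "/1H04M2500A50000A600000R"),
        ((0, 0, 0), "/1H04M0A0A0R"),
    ])
    def test_lincontrol_format(self, args, expected):
        assert inst.lincontrol_command(*args) == expected

    def test_lincontrol_rejects_non_integers(self):
        with pytest.raises(TypeError):
            inst.lincontrol_command(4500.5, 50000, 600000)
        with pytest.raises(ValueError):
            inst.lincontrol_command(-1, 0, 0)

    def test_dye_stock_concentration(self):
        # 128 mg methylene blue (319.85 g/mol) in 100 mL -> ~4 mM
        c = inst.stock_concentration(128.0, 319.85, 100.0)
        assert round_half_up(c) == 4

    def test_round_half_up_ties(self):
        assert round_half_up(5.625, 2) == 5.63
        assert round_half_up(1.125, 2) == 1.13
        assert round_half_up(82.5) == 83
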