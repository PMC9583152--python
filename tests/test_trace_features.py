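import math

import numpy as np
import pytest

from tdprisk.trace_features import (
    FEATURE_NAMES,
    FeatureVector,
    ap_features,
    average_over_concentrations,
    ca_features,
    qinward,
    qnet,
    select_worst_beat,
)
from tdprisk.synthetic import surrogate_trace

from conftest import bundle_from_beats, make_beat

DT = 0.1


class TestApFeatures:
    def test_trapezoid_closed_form(self, trapezoid_beat):
        f = ap_features(trapezoid_beat)
        # analytic: slope 120/1 ms up, -120/100 ms down, activation mid-upstroke
        assert f["dvmdt_max"] == pytest.approx(120.0, abs=1e-6)
        assert f["dvmdt_max_repol"] == pytest.approx(-1.2, abs=1e-6)
        assert f["vm_peak"] == pytest.approx(35.0)
        assert f["apd50"] == pytest.approx(249.5, abs=DT)
        assert f["apd90"] == pytest.approx(289.5, abs=DT)
        assert f["apd_tri"] == pytest.approx(40.0, abs=2 * DT)
        assert f["apd_tri"] == f["apd90"] - f["apd50"]

    def test_time_translation_invariance(self, trapezoid_beat):
        shifted = make_beat(vm_knots=([0.0, 50.0, 51.0, 250.0, 350.0],
                                      [-85.0, -85.0, 35.0, 35.0, -85.0]))
        a = ap_features(trapezoid_beat)
        b = ap_features(shifted)
        for key in a:
            assert b[key] == pytest.approx(a[key], abs=1e-9)

    def test_constant_trace_has_no_ap(self):
        with pytest.raises(ValueError, match="no AP"):
            ap_features(make_beat())

    def test_repolarisation_failure_yields_missing_not_error(self):
        # Vm never returns below the APD90 level within the beat
        beat = make_beat(vm_knots=([0.0, 1.0, 400.0], [-85.0, 35.0, 30.0]))
        f = ap_features(beat)
        assert math.isnan(f["apd90"]) and math.isnan(f["apd50"])
        assert math.isnan(f["apd_tri"])
        assert f["vm_peak"] == pytest.approx(35.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_interpolated_crossing_within_one_grid_step_of_scan(self, seed):
        """Interpolated APD agrees with a brute-force all-grid-points scan."""
        rng = np.random.default_rng(seed)
        apd_end = rng.uniform(150.0, 350.0)
        plateau = rng.uniform(30.0, 100.0)
        beat = make_beat(vm_knots=([0.0, 1.0, plateau, apd_end],
                                   [-85.0, 35.0, 35.0, -85.0]))
        f = ap_features(beat)
        slopes = np.gradient(beat.vm, DT)
        i_act = int(np.argmax(slopes[1:-1])) + 1
        peak = int(np.argmax(beat.vm))
        for frac, key in ((0.9, "apd90"), (0.5, "apd50")):
            level = beat.vm[peak] - frac * (beat.vm[peak] - beat.vm[0])
            below = np.flatnonzero(beat.vm[peak:] < level) + peak
            brute = beat.time[below[0]] - beat.time[i_act]
            assert abs(f[key] - brute) <= DT + 1e-9


class TestCaFeatures:
    def test_triangle_closed_form(self, triangle_ca_beat):
        f = ca_features(triangle_ca_beat)
        # onset mid-rise at 5 ms; decay crossings at 205 ms (50%) and 361 ms (90%)
        assert f["ca_peak"] == pytest.approx(4e-4)
        assert f["cad50"] == pytest.approx(200.0, abs=DT)
        assert f["cad90"] == pytest.approx(356.0, abs=DT)
        assert f["cad_tri"] == pytest.approx(156.0, abs=2 * DT)
        assert f["cad_tri"] == f["cad90"] - f["cad50"]

    def test_flat_cai_has_no_transient(self):
        with pytest.raises(ValueError, match="no transient"):
            ca_features(make_beat())

    def test_amplitude_scaling_leaves_durations_unchanged(self, triangle_ca_beat):
        doubled = make_beat(duration_ms=500.0,
                            cai_knots=([0.0, 10.0, 400.0], [1e-4, 7e-4, 1e-4]))
        a = ca_features(triangle_ca_beat)
        b = ca_features(doubled)
        assert b["ca_peak"] == pytest.approx(2 * a["ca_peak"] - 1e-4)
        assert b["cad50"] == pytest.approx(a["cad50"], abs=1e-9)
        assert b["cad90"] == pytest.approx(a["cad90"], abs=1e-9)


class TestChargeFeatures:
    def test_all_zero_currents_integrate_to_zero(self):
        beat = make_beat(current_knots={c: ([0.0, 400.0], [0.0, 0.0])
                                        for c in ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")})
        assert qnet(beat) == 0.0

    def test_rectangular_current_charge(self):
        knots = {c: ([0.0, 400.0], [0.0, 0.0])
                 for c in ("INaL", "ICaL", "IKs", "IK1", "Ito")}
        # 0.1 A/F over ~100 ms (0.1 ms on-grid ramps at the edges)
        knots["IKr"] = ([99.9, 100.0, 200.0, 200.1], [0.0, 0.1, 0.1, 0.0])
        beat = make_beat(current_knots=knots)
        analytic = 0.1 * (100.0 + 0.1) * 1e-3  # trapezoid area, uC/uF
        assert qnet(beat) == pytest.approx(analytic, abs=1e-12)
        assert qnet(beat) == pytest.approx(0.01, abs=2e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_piecewise_linear_matches_symbolic_integral(self, seed):
        rng = np.random.default_rng(seed)
        knots, analytic = {}, 0.0
        for c in ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito"):
            kt = np.sort(rng.choice(np.arange(0.0, 400.0, DT), 5, replace=False))
            kt = np.round(kt, 1)
            kv = rng.uniform(-1.0, 1.0, 5)
            kv[0] = kv[-1] = 0.0
            knots[c] = (kt.tolist(), kv.tolist())
            analytic += np.sum(0.5 * (kv[1:] + kv[:-1]) * np.diff(kt)) * 1e-3
        beat = make_beat(current_knots=knots)
        assert qnet(beat) == pytest.approx(analytic, abs=1e-12)

    def test_qnet_is_linear_in_currents(self):
        rng = np.random.default_rng(0)
        beats = []
        for _ in range(2):
            knots = {}
            for c in ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito"):
                kt = [0.0, 100.0, 250.0, 399.9]
                knots[c] = (kt, [0.0, *rng.uniform(-1, 1, 2), 0.0])
            beats.append(make_beat(current_knots=knots))
        summed = make_beat()
        summed.currents = {c: beats[0].currents[c] + beats[1].currents[c]
                           for c in beats[0].currents}
        assert qnet(summed) == pytest.approx(qnet(beats[0]) + qnet(beats[1]), abs=1e-12)

    def test_missing_current_is_named(self):
        beat = make_beat(current_knots={"IKr": ([0.0, 400.0], [0.0, 0.0])})
        with pytest.raises(ValueError, match="INaL"):
            qnet(beat)

    def _inward_beat(self, a_cal, a_nal):
        return make_beat(current_knots={
            "ICaL": ([10.0, 20.0, 110.0, 120.0], [0.0, -a_cal, -a_cal, 0.0]),
            "INaL": ([10.0, 20.0, 110.0, 120.0], [0.0, -a_nal, -a_nal, 0.0]),
        })

    def test_qinward_of_control_is_one(self):
        ctl = self._inward_beat(1.5, 0.2)
        assert qinward(ctl, ctl) == pytest.approx(1.0)

    def test_qinward_halved_charges(self):
        ctl = self._inward_beat(1.5, 0.2)
        assert qinward(self._inward_beat(0.75, 0.1), ctl) == pytest.approx(0.5)

    def test_qinward_mean_of_unequal_ratios(self):
        ctl = self._inward_beat(1.0, 1.0)
        drug = self._inward_beat(0.8, 0.4)   # qCaL ratio 0.8, qNaL ratio 0.4
        assert qinward(drug, ctl) == pytest.approx(0.6)

    def test_qinward_degenerate_control(self):
        ctl = self._inward_beat(0.0, 0.2)
        with pytest.raises(ValueError, match="degenerate control"):
            qinward(self._inward_beat(1.0, 0.2), ctl)


class TestWorstBeat:
    def _trapezoid(self, fall_end):
        return make_beat(vm_knots=([0.0, 1.0, 200.0, fall_end],
                                   [-85.0, 35.0, 35.0, -85.0]))

    def test_steepest_repolarisation_wins(self):
        beats = [self._trapezoid(300.0) for _ in range(5)]
        beats[3] = self._trapezoid(280.0)   # slope -1.5 vs -1.2 elsewhere
        assert select_worst_beat(bundle_from_beats(beats)) == 3

    def test_ties_go_to_the_latest_beat(self):
        beats = [self._trapezoid(300.0) for _ in range(4)]
        assert select_worst_beat(bundle_from_beats(beats)) == 3

    def test_single_beat(self):
        assert select_worst_beat(bundle_from_beats([self._trapezoid(300.0)])) == 0


class TestAveraging:
    def _fv(self, apd90=300.0):
        vals = dict(zip(FEATURE_NAMES, np.linspace(1.0, 12.0, 12)))
        vals["apd90"] = apd90
        vals["apd_tri"] = vals["apd90"] - vals["apd50"]
        return FeatureVector(**vals)

    def test_four_identical_vectors_average_to_themselves(self):
        fv = self._fv()
        out = average_over_concentrations([fv] * 4)
        np.testing.assert_allclose(out.to_array(), fv.to_array())

    def test_componentwise_mean(self):
        out = average_over_concentrations([self._fv(a) for a in (300, 310, 320, 330)])
        assert out.apd90 == pytest.approx(315.0)

    def test_missing_component_propagates(self):
        vecs = [self._fv() for _ in range(4)]
        vecs[2].apd90 = math.nan
        out = average_over_concentrations(vecs)
        assert math.isnan(out.apd90)
        assert not math.isnan(out.apd50)

    def test_requires_exactly_four(self):
        with pytest.raises(ValueError, match="4"):
            average_over_concentrations([self._fv()] * 3)


class TestGridRefinement:
    def test_halving_dt_changes_smooth_features_under_point1_percent(self):
        scales = {"IKr": 0.6, "ICaL": 0.8}
        coarse = surrogate_trace(scales, dt=0.1)
        fine = surrogate_trace(scales, dt=0.05)
        from tdprisk.trace_features import extract_features
        ctl_c = surrogate_trace(dt=0.1).beat(0)
        ctl_f = surrogate_trace(dt=0.05).beat(0)
        a = extract_features(coarse.beat(0), ctl_c).to_array()
        b = extract_features(fine.beat(0), ctl_f).to_array()
        np.testing.assert_allclose(a, b, rtol=1e-3)
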