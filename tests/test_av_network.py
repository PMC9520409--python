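import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avnode.av_network import (
    DEFAULT_CN_PARAMS,
    FULLY_RECOVERED,
    ModelParams,
    NodeState,
    PathwayParams,
    ScalingSchedule,
    build_network,
    conduction_delay,
    excitation_gap,
    refractory_period,
    simulate,
)

from reference_impl import reference_simulate


class TestRefractoryPeriod:
    def test_gap_zero_gives_r_min(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        assert refractory_period(p, 0.0) == 300.0

    def test_fully_recovered_gives_asymptote(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        assert refractory_period(p, FULLY_RECOVERED) == 600.0

    def test_closed_form_value(self):
        # independent high-precision evaluation of the closed form
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        expected = 300.0 + 300.0 * (1.0 - math.exp(-1.0))  # 489.6362...
        assert refractory_period(p, 100.0) == pytest.approx(expected, abs=1e-12)
        assert refractory_period(p, 100.0) == pytest.approx(489.64, abs=0.01)

    def test_scaling_is_exactly_linear(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        for gap in (0.0, 37.5, 211.0, FULLY_RECOVERED):
            assert refractory_period(p, gap, 0.95) == 0.95 * refractory_period(p, gap)

    def test_negative_gap_rejected(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        with pytest.raises(ValueError):
            refractory_period(p, -1.0)

    def test_nonpositive_scale_rejected(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        with pytest.raises(ValueError):
            refractory_period(p, 10.0, a_r=0.0)

    @given(g1=st.floats(0, 5000), g2=st.floats(0, 5000))
    def test_monotone_in_gap(self, g1, g2):
        p = PathwayParams(250, 400, 120, 0, 0, 1)
        lo, hi = sorted([g1, g2])
        assert refractory_period(p, lo) <= refractory_period(p, hi)


class TestConductionDelay:
    def test_gap_zero(self):
        p = PathwayParams(1, 0, 1, 20, 39, 171)
        assert conduction_delay(p, 0.0) == 59.0

    def test_fully_recovered(self):
        p = PathwayParams(1, 0, 1, 20, 39, 171)
        assert conduction_delay(p, FULLY_RECOVERED) == 20.0

    def test_scaled_value(self):
        p = PathwayParams(1, 0, 1, 20, 39, 171)
        assert conduction_delay(p, 0.0, a_d=0.9) == pytest.approx(53.1, abs=1e-12)

    @given(g1=st.floats(0, 5000), g2=st.floats(0, 5000))
    def test_antitone_in_gap(self, g1, g2):
        p = PathwayParams(1, 0, 1, 10, 50, 140)
        lo, hi = sorted([g1, g2])
        assert conduction_delay(p, lo) >= conduction_delay(p, hi)


class TestExcitationGap:
    def test_direct_arithmetic(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)  # R(inf) = 600
        st_ = NodeState(params=p, last_conducted_arrival=0.0)
        assert excitation_gap(800.0, st_) == pytest.approx(200.0)

    def test_blocked_is_negative(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        st_ = NodeState(params=p, last_conducted_arrival=0.0)
        assert excitation_gap(400.0, st_) == pytest.approx(-200.0)

    def test_fresh_node_fully_recovered(self):
        p = PathwayParams(300, 300, 100, 0, 0, 1)
        assert excitation_gap(123.0, NodeState(params=p)) == FULLY_RECOVERED


class TestTopology:
    def test_node_count(self):
        assert build_network().n_nodes == 21

    def test_degrees(self):
        topo = build_network()
        assert topo.degree(topo.cn) == 2
        assert topo.degree(topo.chain_length - 1) == 3          # SP distal
        assert topo.degree(2 * topo.chain_length - 1) == 3      # FP distal
        assert topo.degree(topo.sp_entry) == 1
        assert topo.degree(topo.fp_entry) == 1

    def test_edges_are_bidirectional(self):
        topo = build_network()
        for u, nbrs in enumerate(topo.neighbors):
            for v in nbrs:
                assert u in topo.neighbors[v]

    def test_roles(self):
        topo = build_network()
        assert topo.roles[0] == "SP_1"
        assert topo.roles[10] == "FP_1"
        assert topo.roles[20] == "CN"

    def test_chain_length_one(self):
        topo = build_network(1)
        assert topo.n_nodes == 3
        assert topo.degree(topo.cn) == 2


class TestSimulateOracles:
    def test_single_impulse_transits_fp_chain(self):
        # hand event-trace: 10 fresh FP nodes, d_min = 5 each; SP wavefront
        # and retrograde fronts are blocked everywhere else
        sp = PathwayParams(339, 232, 160, 20, 39, 171)
        fp = PathwayParams(493, 369, 162, 5, 23, 163)
        v = simulate([0.0], ModelParams(sp=sp, fp=fp))
        assert v.tolist() == [50.0]

    def test_one_to_one_conduction(self):
        # all refractory periods < 1000 ms and gap-independent curves
        sp = PathwayParams(300, 0, 100, 20, 0, 100)
        fp = PathwayParams(400, 0, 100, 5, 0, 100)
        aa = np.arange(20) * 1000.0
        v = simulate(aa, ModelParams(sp=sp, fp=fp))
        assert v.size == 20
        assert np.diff(v).tolist() == [1000.0] * 19

    def test_two_to_one_block(self):
        # arrivals every 400 ms against R = 600: gap alternates -200 / +200
        sp = PathwayParams(600, 0, 100, 20, 0, 100)
        fp = PathwayParams(600, 0, 100, 5, 0, 100)
        aa = np.arange(40) * 400.0
        v = simulate(aa, ModelParams(sp=sp, fp=fp))
        assert v.size == 20
        assert np.diff(v).tolist() == [800.0] * 19

    def test_empty_input(self):
        sp = PathwayParams(300, 0, 100, 20, 0, 100)
        v = simulate([], ModelParams(sp=sp, fp=sp))
        assert v.size == 0

    def test_non_increasing_aa_rejected(self, reference_params):
        with pytest.raises(ValueError):
            simulate([0.0, 0.0], reference_params)
        with pytest.raises(ValueError):
            simulate([100.0, 50.0], reference_params)


class TestSimulateProperties:
    def _random_aa(self, rng, n=300, mean=160.0):
        return np.cumsum(rng.gamma(4.0, mean / 4.0, n))

    def test_determinism(self, rng, reference_params):
        aa = self._random_aa(rng)
        v1 = simulate(aa, reference_params)
        v2 = simulate(aa, reference_params)
        assert np.array_equal(v1, v2)

    def test_output_strictly_increasing_with_cn_refractory_spacing(
        self, rng, reference_params
    ):
        for a_r in (0.9, 1.0, 1.1):
            mp = reference_params.with_scales(a_r, 1.0)
            v = simulate(self._random_aa(rng), mp)
            assert v.size > 10
            d = np.diff(v)
            assert np.all(d > 0)
            assert np.all(d >= a_r * mp.cn.r_min - 1e-9)

    def test_unit_scales_reproduce_unscaled_model(self, rng, reference_params):
        aa = self._random_aa(rng)
        v1 = simulate(aa, reference_params)
        v2 = simulate(aa, reference_params.with_scales(1.0, 1.0))
        v3 = simulate(aa, reference_params,
                      schedule=ScalingSchedule.constant(1.0, 1.0))
        assert np.array_equal(v1, v2)
        assert np.array_equal(v1, v3)

    def test_max_beats_truncates(self, rng, reference_params):
        aa = self._random_aa(rng)
        full = simulate(aa, reference_params)
        head = simulate(aa, reference_params, max_beats=5)
        assert head.tolist() == full[:5].tolist()

    def test_matches_reference_on_single_node_chains(self, rng, reference_params):
        # independent straightforward re-implementation, 100 random inputs
        for _ in range(100):
            n = int(rng.integers(5, 40))
            aa = np.cumsum(rng.uniform(80.0, 400.0, n))
            got = simulate(aa, reference_params, chain_length=1)
            want = reference_simulate(aa, reference_params, chain_length=1)
            assert got.tolist() == pytest.approx(want, abs=1e-9)

    def test_matches_reference_on_full_network(self, rng, reference_params):
        for _ in range(25):
            n = int(rng.integers(20, 120))
            aa = np.cumsum(rng.uniform(80.0, 400.0, n))
            got = simulate(aa, reference_params)
            want = reference_simulate(aa, reference_params)
            assert got.tolist() == pytest.approx(want, abs=1e-9)

    def test_matches_reference_with_scales(self, rng, reference_params):
        for a_r, a_d in [(0.9, 1.1), (1.05, 0.9)]:
            aa = np.cumsum(rng.uniform(80.0, 400.0, 80))
            got = simulate(aa, reference_params.with_scales(a_r, a_d))
            want = reference_simulate(aa, reference_params, a_r=a_r, a_d=a_d)
            assert got.tolist() == pytest.approx(want, abs=1e-9)

    def test_mean_rr_increases_with_a_r(self, reference_params):
        # statistical monotonicity over seeded runs
        means = {0.95: [], 1.05: []}
        for seed in range(20):
            r = np.random.default_rng(seed)
            aa = np.cumsum(r.gamma(4.0, 150.0 / 4.0, 1500))
            for a_r in means:
                v = simulate(aa, reference_params.with_scales(a_r, 1.0))
                means[a_r].append(np.mean(np.diff(v)))
        assert np.mean(means[1.05]) > np.mean(means[0.95])

    def test_schedule_switches_scaling_mid_run(self, reference_params):
        rng = np.random.default_rng(7)
        aa = np.cumsum(rng.gamma(4.0, 150.0 / 4.0, 2000))
        half = aa[-1] / 2.0
        sched = ScalingSchedule(np.array([0.0, half]),
                                np.array([1.0, 1.1]),
                                np.array([1.0, 1.0]))
        v_sched = simulate(aa, reference_params, schedule=sched)
        v_flat = simulate(aa, reference_params)
        # identical prefix before the switch, different behavior after
        n_pre = np.searchsorted(v_flat, half)
        assert v_sched[: n_pre - 1].tolist() == v_flat[: n_pre - 1].tolist()
        assert np.mean(np.diff(v_sched[v_sched > half])) > np.mean(
            np.diff(v_flat[v_flat > half])
        )


class TestParamValidation:
    def test_invalid_pathway_params(self):
        with pytest.raises(ValueError):
            PathwayParams(0, 0, 1, 0, 0, 1)
        with pytest.raises(ValueError):
            PathwayParams(300, -1, 1, 0, 0, 1)
        with pytest.raises(ValueError):
            PathwayParams(300, 0, 0, 0, 0, 1)

    def test_invalid_scales(self):
        sp = PathwayParams(300, 0, 100, 20, 0, 100)
        with pytest.raises(ValueError):
            ModelParams(sp=sp, fp=sp, a_r=0.0)

    def test_roundtrip_dict(self, reference_params):
        d = reference_params.to_dict()
        assert ModelParams.from_dict(d) == reference_params

    def test_default_cn(self):
        assert DEFAULT_CN_PARAMS.r_min == 250.0
        assert DEFAULT_CN_PARAMS.d_min == 0.0
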