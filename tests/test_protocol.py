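"""Assay-protocol simulation, summaries, AUC, sweeps and comparisons."""

import numpy as np
import pytest

import bsbind as b
from bsbind.kinetics import IL6R, IL8R, ReceptorSpecies
from bsbind.protocol import SolverSettings, TimeCourse

from conftest import equilibrium_bs1

ENDPOINT = SolverSettings(points_per_phase=0)


def make_timecourse(network, states, times=None, doses=None):
    """Hand-built trajectory for exercising the summary arithmetic."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if times is None:
        times = np.arange(len(states), dtype=float)
    schedule = b.DoseSchedule(doses_nM=doses or {}, association_duration=float(times[-1]),
                              washout=False)
    return TimeCourse(times=np.asarray(times, dtype=float), states=states,
                      network=network, rates=b.REFERENCE_RATES,
                      schedule=schedule, ctx=b.DEFAULT_UNIT_CONTEXT,
                      solver=ENDPOINT)


class TestSimulate:
    def test_zero_dose_keeps_all_complexes_zero(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates, b.DoseSchedule(doses_nM={"BS1": 0.0}),
                        ctx)
        for sp in ("BS1.IL6R", "BS1.IL8R", "IL6R.BS1.IL8R"):
            assert np.all(tc.series(sp) == 0.0)

    def test_monovalent_occupancy_half_at_dose_equal_kd(self, rates, ctx):
        """1:1 closed form: occupancy = dose/(dose+KD) = 1/2 at dose = KD."""
        mono = b.restrict_monovalent(rates)
        kd = rates.koff_6R / rates.kon_6R
        net = b.build_network(b.BS1, [ReceptorSpecies(IL6R, 10.0)], ctx)
        tc = b.simulate(net, mono,
                        b.DoseSchedule(doses_nM={"BS1": kd},
                                       association_duration=86400.0, washout=False),
                        ctx)
        occ = b.summarize(tc).occupancy[IL6R]
        assert occ == pytest.approx(0.5, abs=0.005)

    def test_washout_ternary_rises_while_binaries_fall(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates,
                        b.DoseSchedule(doses_nM={"BS1": 100.0}), ctx)
        post = tc.times >= 7200.0
        tern = tc.series("IL6R.BS1.IL8R")[post]
        b6 = tc.series("BS1.IL6R")[post]
        b8 = tc.series("BS1.IL8R")[post]
        # non-decreasing within integration tolerance
        assert np.all(np.diff(tern) >= -1e-6 * tern[:-1])
        assert b6[-1] < b6[0] and b8[-1] < b8[0]
        assert np.all(tc.series("BS1")[tc.times > 7200.0] == 0.0)
        # total surface-bound antibody is non-increasing once the medium is washed
        surf = b6 + b8 + tern
        assert np.all(np.diff(surf) <= 1e-9 * surf[:-1])

    def test_conservation_along_trajectory(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates,
                        b.DoseSchedule(doses_nM={"BS1": 100.0}), ctx)
        net = tc.network
        for rec, total in ((IL6R, 3.16e5), (IL8R, 6.18e5)):
            totals = np.array([net.receptor_total(y, rec) for y in tc.states])
            assert np.allclose(totals, total, rtol=1e-6)
        pre = tc.times <= 7200.0
        ab = np.array([net.antibody_total_nM(y, "BS1", ctx.alpha)
                       for y in tc.states[pre]])
        assert np.allclose(ab, 100.0, rtol=1e-6)

    def test_integration_failure_raises_with_diagnostics(self, bs1_network, ctx):
        from bsbind.kinetics import RateConstantSet
        broken = RateConstantSet(kon_6R=1e308, kon_8R=1e308, kon_6R_star=1e308,
                                 kon_8R_star=1e308, koff_6R=1e-5, koff_8R=1e-5,
                                 chi=1.0)
        with pytest.raises(b.protocol.SimulationError):
            b.simulate(bs1_network, broken,
                       b.DoseSchedule(doses_nM={"BS1": 1e6}), ctx)


class TestSummarize:
    def test_ternary_only_state(self, bs1_network):
        y = np.zeros(6)
        y[bs1_network.index("IL6R.BS1.IL8R")] = 50.0
        s = b.summarize(make_timecourse(bs1_network, [y], doses={"BS1": 1.0}))
        assert s.bound_ternary == 100.0
        assert s.bound_binary == 0.0
        assert s.bound_antibody_signal == 50.0

    def test_mixed_complex_accounting(self, bs1_network):
        y = np.zeros(6)
        y[bs1_network.index("BS1.IL6R")] = 10.0
        y[bs1_network.index("BS1.IL8R")] = 20.0
        y[bs1_network.index("IL6R.BS1.IL8R")] = 5.0
        s = b.summarize(make_timecourse(bs1_network, [y], doses={"BS1": 1.0}))
        assert s.bound_total == 10 + 20 + 2 * 5
        assert s.bound_antibody_signal == 10 + 20 + 5

    def test_homoternary_counts_two_receptors_one_antibody(self):
        net = b.build_network(b.TOCILIZUMAB, "IL6R+")
        y = np.zeros(net.n_species)
        y[net.index("IL6R.tocilizumab.IL6R")] = 7.0
        s = b.summarize(make_timecourse(net, [y], doses={"tocilizumab": 1.0}))
        assert s.bound_ternary == 14.0
        assert s.bound_antibody_signal == 7.0

    def test_total_occupancy_is_expression_weighted_mean(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates,
                        b.DoseSchedule(doses_nM={"BS1": 10.0}), ctx, ENDPOINT)
        s = b.summarize(tc)
        r6, r8 = s.receptor_totals[IL6R], s.receptor_totals[IL8R]
        weighted = (s.occupancy[IL6R] * r6 + s.occupancy[IL8R] * r8) / (r6 + r8)
        assert s.occupancy["total"] == pytest.approx(weighted, rel=1e-9)

    def test_time_outside_range_rejected(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates,
                        b.DoseSchedule(doses_nM={"BS1": 1.0}), ctx, ENDPOINT)
        with pytest.raises(ValueError):
            b.summarize(tc, at_time=1e9)


class TestBoundAntibodySignal:
    def test_all_free_state_gives_zero(self, bs1_network):
        y = np.zeros(6)
        y[bs1_network.index("BS1")] = 5.0
        y[bs1_network.index(IL6R)] = 1e5
        tc = make_timecourse(bs1_network, [y], doses={"BS1": 5.0})
        assert b.bound_antibody_signal(tc) == 0.0

    def test_homobivalent_saturated_signal_is_half_receptor_total(self):
        net = b.build_network(b.TOCILIZUMAB, "IL6R+")
        y = np.zeros(net.n_species)
        y[net.index("IL6R.tocilizumab.IL6R")] = 2.54e5  # all receptor in pairs
        tc = make_timecourse(net, [y], doses={"tocilizumab": 1.0})
        assert b.bound_antibody_signal(tc) == pytest.approx(5.08e5 / 2)

    def test_excess_dose_drives_monospecific_to_monovalent_saturation(self, rates, ctx):
        """At vast excess, every receptor holds its own antibody: signal ≈ R_total."""
        net = b.build_network(b.TOCILIZUMAB, "IL6R+")
        tc = b.simulate(net, rates,
                        b.DoseSchedule(doses_nM={"tocilizumab": 1e6},
                                       association_duration=86400.0, washout=False),
                        ctx, ENDPOINT)
        assert b.bound_antibody_signal(tc) == pytest.approx(5.08e5, rel=0.01)


class TestAuc:
    def test_constant_output(self, bs1_network):
        y = np.zeros(6)
        y[bs1_network.index("BS1.IL6R")] = 3.0
        tc = make_timecourse(bs1_network, [y, y], times=[0.0, 10.0],
                             doses={"BS1": 1.0})
        assert b.auc(tc, "bound_binary", (0.0, 10.0)) == pytest.approx(30.0)

    def test_linear_ramp(self, bs1_network):
        y0 = np.zeros(6)
        y1 = np.zeros(6)
        y1[bs1_network.index("BS1.IL6R")] = 4.0
        tc = make_timecourse(bs1_network, [y0, y1], times=[0.0, 10.0],
                             doses={"BS1": 1.0})
        assert b.auc(tc, "bound_binary", (0.0, 10.0)) == pytest.approx(20.0)

    def test_refinement_oracle(self, bs1_network, rates, ctx):
        """Default grid AUC within 0.1% of a 10x finer-grid integral."""
        sched = b.DoseSchedule(doses_nM={"BS1": 10.0},
                               association_duration=7200.0, washout=False)
        coarse = b.simulate(bs1_network, rates, sched, ctx,
                            SolverSettings(points_per_phase=200))
        fine = b.simulate(bs1_network, rates, sched, ctx,
                          SolverSettings(points_per_phase=2000))
        a1 = b.auc(coarse, "bound_ternary", (0.0, 7200.0))
        a2 = b.auc(fine, "bound_ternary", (0.0, 7200.0))
        assert a1 == pytest.approx(a2, rel=1e-3)

    def test_empty_window_rejected(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates, b.DoseSchedule(doses_nM={"BS1": 1.0}),
                        ctx, ENDPOINT)
        with pytest.raises(ValueError):
            b.auc(tc, "bound_total", (10.0, 10.0))


class TestMonovalentInvariance:
    def test_occupancy_invariant_across_receptor_range_at_excess_dose(self, rates, ctx):
        mono = b.restrict_monovalent(rates)
        occs = []
        for R in (1e2, 1e3, 1e4, 1e5):
            sw = b.sweep(b.BS1, [100.0], [(R, R)], mono, ctx=ctx)
            occs.append(sw["occupancy_total"].iloc[0])
        assert (max(occs) - min(occs)) / np.mean(occs) < 0.01

    def test_monovalent_equilibrium_matches_closed_form(self, rates, ctx):
        """With <1% depletion, per-receptor occupancy = dose/(dose+KD)."""
        mono = b.restrict_monovalent(rates)
        dose = 5.0
        sw = b.sweep(b.BS1, [dose], [(1e3, 1e3)], mono, ctx=ctx).iloc[0]
        kd6 = rates.koff_6R / rates.kon_6R
        kd8 = rates.koff_8R / rates.kon_8R
        assert sw["occupancy_IL6R"] == pytest.approx(dose / (dose + kd6), rel=5e-3)
        assert sw["occupancy_IL8R"] == pytest.approx(dose / (dose + kd8), rel=5e-3)


class TestSweep:
    def test_bispecific_equals_one_to_one_combination_at_equal_receptors(self, rates, ctx):
        doses = [0.1, 10.0, 1000.0]
        recs = [(1e3, 1e3), (1e5, 1e5), (1e7, 1e7)]
        s_bs1 = b.sweep(b.BS1, doses, recs, rates, ctx=ctx)
        s_cmb = b.sweep([b.TOCILIZUMAB, b.ANTIBODY_10H2], doses, recs, rates, ctx=ctx)
        for col in ("occupancy_total", "ternary_occupancy_total"):
            assert np.allclose(s_bs1[col], s_cmb[col], atol=0.01)

    def test_autoinhibition_ternary_unimodal_in_dose(self, rates, ctx):
        doses = np.geomspace(1e-2, 1e6, 17)
        sw = b.sweep(b.BS1, doses, [(1e5, 1e5)], rates, ctx=ctx)
        t = sw["ternary_occupancy_total"].to_numpy()
        peak = int(np.argmax(t))
        assert 0 < peak < len(t) - 1
        assert np.all(np.diff(t[:peak + 1]) >= -1e-9)
        assert np.all(np.diff(t[peak:]) <= 1e-9)

    def test_infinite_dose_limit_is_all_binary(self, rates, ctx):
        sw = b.sweep(b.BS1, [1e6], [(1e5, 1e5)], rates, ctx=ctx).iloc[0]
        assert sw["ternary_occupancy_total"] < 0.01
        assert sw["binary_occupancy_total"] == pytest.approx(
            sw["occupancy_total"], abs=0.01)

    def test_endpoint_matches_algebraic_steady_state(self, rates, ctx):
        """Equilibrated (dose >= 10 nM) endpoints agree with the mass-action
        equilibrium solved independently of the ODE path, to 0.5%."""
        for dose, r6, r8 in [(100.0, 3.16e5, 6.18e5), (10.0, 5e4, 5e4),
                             (1000.0, 1e3, 1e3), (10.0, 1e6, 1e6)]:
            eq = equilibrium_bs1(rates, ctx, dose, r6, r8)
            sw = b.sweep(b.BS1, [dose], [(r6, r8)], rates, ctx=ctx).iloc[0]
            assert sw["bound_total"] == pytest.approx(eq["bound_total"], rel=5e-3)


class TestRelativeBinding:
    def test_identical_summaries_give_unity(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates, b.DoseSchedule(doses_nM={"BS1": 10.0}),
                        ctx, ENDPOINT)
        s = b.summarize(tc)
        rel = b.relative_binding(s, s)
        assert all(v == pytest.approx(1.0) for v in rel.values())

    def test_zero_denominator_flagged_as_nan(self, bs1_network, rates, ctx):
        tc = b.simulate(bs1_network, rates, b.DoseSchedule(doses_nM={"BS1": 10.0}),
                        ctx, ENDPOINT)
        tc0 = b.simulate(bs1_network, rates, b.DoseSchedule(doses_nM={"BS1": 0.0}),
                         ctx, ENDPOINT)
        rel = b.relative_binding(b.summarize(tc), b.summarize(tc0))
        assert all(np.isnan(v) for v in rel.values())

    def test_bispecific_favors_limited_receptor(self, rates, ctx):
        s1 = b.sweep(b.BS1, [10.0], [(1e3, 1e6)], rates, ctx=ctx).iloc[0]
        s2 = b.sweep([b.TOCILIZUMAB, b.ANTIBODY_10H2], [10.0], [(1e3, 1e6)],
                     rates, ctx=ctx).iloc[0]
        assert s1["occupancy_IL6R"] > s2["occupancy_IL6R"]
        assert s1["occupancy_IL8R"] < s2["occupancy_IL8R"]
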