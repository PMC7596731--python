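"""Site-resolved ROS accounting, flux splitting and curve classification."""

import numpy as np
import pytest

import ciiros as c
from ciiros.network import Reaction, Species
from ciiros.observables import fit_michaelis


def _classify(sw, rid, grid):
    return c.classify_curve(grid, sw.observable(lambda s: s.flux(rid)))


class TestRosBreakdown:
    def test_all_components_zero_without_succinate(self, assembled, params):
        st = c.solve_steady(assembled, params.copy(succ=0.0))
        rb = c.ros_breakdown(st)
        for name in ("v22", "v23", "v24", "v25", "v26", "v28", "vh2o2tot"):
            assert getattr(rb, name) == pytest.approx(0.0, abs=1e-9)

    def test_total_is_sum_of_flavin_h2o2_and_dismutation(self, baseline_steady):
        rb = c.ros_breakdown(baseline_steady)
        assert rb.vh2o2tot == rb.v22 + rb.v22d + rb.v28   # by definition
        # ... and equals the H2O2 efflux from the matrix at steady state
        assert rb.vh2o2tot == pytest.approx(baseline_steady.flux("30"), abs=1e-9)

    def test_dismutation_is_half_of_superoxide_production(self, assembled,
                                                          params):
        for succ in (30.0, 300.0, 3000.0):
            st = c.solve_steady(assembled, params.copy(succ=succ))
            rb = c.ros_breakdown(st)
            assert rb.v28 == pytest.approx(0.5 * rb.superoxide_total(),
                                           rel=1e-9, abs=1e-12)

    def test_component_rates_non_negative_at_steady_state(self, sweep_cache):
        for cond in ({}, {"aa5": 0.25}, {"kf29": 0.01}):
            sw = sweep_cache(**cond)
            for st in sw.states:
                rb = c.ros_breakdown(st)
                for name in ("v22", "v23", "v24", "v25", "v26", "v28"):
                    assert getattr(rb, name) > -1e-12

    def test_mixed_topology_accounts_for_disintegrated_sites(self, mixed):
        net, p = mixed
        st = c.solve_steady(net, p.copy(succ=300.0))
        rb = c.ros_breakdown(st)
        assert rb.v22d > 0 and rb.v23d > 0 and rb.v25d > 0
        assert rb.vh2o2tot == pytest.approx(st.flux("30"), abs=1e-9)


class TestFluxSplit:
    def test_netto_is_forward_minus_reverse(self, baseline_steady):
        fs = c.flux_split(baseline_steady.network, baseline_steady.x,
                          baseline_steady.params, "6")
        assert fs.netto == fs.forward - fs.reverse
        assert fs.forward >= 0 and fs.reverse >= 0

    def test_isolated_reaction_at_equilibrium_has_zero_netto(self):
        net = c.Network(
            [Species("A", concentration=2.0), Species("B", concentration=6.0)],
            [Reaction("1", (("A", 1),), (("B", 1),))],
        )
        p = c.ParameterSet(kf1=3.0, kr1=1.0)   # Keq = 3 = [B]/[A]
        fs = c.flux_split(net, np.array([2.0, 6.0]), p, "1")
        assert fs.netto == pytest.approx(0.0, abs=1e-12)
        assert fs.forward == pytest.approx(fs.reverse)

    def test_irreversible_reaction_is_structural_error(self, baseline_steady):
        with pytest.raises(c.NetworkError):
            c.flux_split(baseline_steady.network, baseline_steady.x,
                         baseline_steady.params, "28")

    def test_mainstream_flow_splits_bell_but_netto_hyperbolic(
            self, assembled, params, succ_grid):
        # under CIII inhibition the unidirectional flavin->[2Fe-2S] flows are
        # bell-shaped and nearly coincident, while their difference stays
        # monotone (hyperbolic): common-mode in-phase changes cancel
        sw = c.sweep(assembled, params.copy(kf29=0.1), "succinate", succ_grid)
        fwd = sw.observable(lambda s: s.flux_forward("6"))
        rev = sw.observable(lambda s: s.flux_reverse("6"))
        net = sw.observable(lambda s: s.flux("6"))
        assert c.classify_curve(succ_grid, fwd).classification == "bell"
        assert c.classify_curve(succ_grid, rev).classification == "bell"
        assert c.classify_curve(succ_grid, net).classification == \
            "hyperbolic-monotone"
        # the unidirectional flows dwarf their difference at the bell peak
        i = int(np.argmax(fwd))
        assert fwd[i] > 20 * net[i]

    def test_superoxide_flow_reverse_is_small_where_flux_runs(
            self, assembled, params, succ_grid):
        sw = c.sweep(assembled, params.copy(kf29=0.1), "succinate", succ_grid)
        fwd = sw.observable(lambda s: s.flux_forward("23"))
        rev = sw.observable(lambda s: s.flux_reverse("23"))
        net = sw.observable(lambda s: s.flux("23"))
        i = int(np.argmax(fwd))
        assert rev[i] < 0.5 * fwd[i]
        # netto tracks the forward flow and keeps its bell shape
        assert c.classify_curve(succ_grid, net).classification == "bell"


class TestClassifyCurve:
    def test_recovers_michaelis_parameters_from_exact_data(self):
        x = np.linspace(5, 2000, 20)
        y = 2.0 * x / (50.0 + x)
        cs = c.classify_curve(x, y)
        assert cs.classification == "hyperbolic-monotone"
        assert cs.vmax == pytest.approx(2.0, rel=0.01)
        assert cs.km == pytest.approx(50.0, rel=0.01)

    def test_constructed_interior_maximum_is_bell(self):
        x = np.geomspace(1, 1000, 15)
        y = np.exp(-((np.log(x) - np.log(30)) ** 2))
        cs = c.classify_curve(x, y)
        assert cs.classification == "bell"
        assert cs.peak_x == pytest.approx(30.0, rel=0.15)

    def test_sigmoid_rise_is_not_called_hyperbolic(self):
        x = np.linspace(1, 1000, 30)
        y = x ** 4 / (300.0 ** 4 + x ** 4)
        cs = c.classify_curve(x, y)
        assert cs.classification == "sigmoid-monotone"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            c.classify_curve([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            c.classify_curve([1, 2, 2, 3, 4], [1, 2, 3, 4, 5])


class TestInhibitionPattern:
    """The Q-site/CIII inhibition phenotype of the ROS sites."""

    def test_flavin_sites_bell_under_strong_inhibition(self, sweep_cache,
                                                       succ_grid):
        for cond in ({"aa5": 0.15}, {"aa5": 0.25}, {"kf29": 0.01}):
            sw = sweep_cache(**cond)
            for rid in ("22", "23", "24"):
                assert _classify(sw, rid, succ_grid).classification == "bell"

    def test_cluster_and_semiquinone_sites_stay_monotone(self, sweep_cache,
                                                         succ_grid):
        for cond in ({}, {"aa5": 0.05}, {"aa5": 0.25}, {"kf29": 0.01}):
            sw = sweep_cache(**cond)
            for rid in ("25", "26"):
                cls = _classify(sw, rid, succ_grid).classification
                assert cls.endswith("monotone"), (cond, rid, cls)

    def test_peak_moves_to_lower_succinate_as_inhibition_strengthens(
            self, sweep_cache, succ_grid):
        for series in ([{"aa5": 0.05}, {"aa5": 0.15}, {"aa5": 0.25}],
                       [{"kf29": 0.1}, {"kf29": 0.01}, {"kf29": 0.005}]):
            peaks = [_classify(sweep_cache(**cond), "22", succ_grid).peak_x
                     for cond in series]
            assert peaks[0] > peaks[1] > peaks[2], (series, peaks)

    def test_inhibition_raises_total_ros_release(self, assembled, params):
        sw = c.sweep(assembled, params.copy(succ=100.0), "AA5",
                     [0.0, 0.05, 0.1, 0.15, 0.25])
        y = sw.observable(lambda s: c.ros_breakdown(s).vh2o2tot)
        assert np.all(np.diff(y) > 0)

    def test_disintegrated_matches_strongly_inhibited_assembled(
            self, sweep_cache, succ_grid):
        # full disintegration abolishes the quinone acceptor entirely; the
        # flavin-site ROS curves match the strongly inhibited assembled
        # enzyme in class and (within one grid cell) in peak position
        pD = c.ParameterSet(CIIt=0.0, ABt=235.0, CDt=235.0)
        netD = c.build_network("disintegrated_only", pD)
        swD = c.sweep(netD, pD, "succinate", succ_grid)
        cell = np.log(succ_grid[1] / succ_grid[0])
        for rid_d, rid_a in (("22d", "22"), ("23d", "23"), ("24d", "24")):
            cd = _classify(swD, rid_d, succ_grid)
            ca = _classify(sweep_cache(aa5=0.25), rid_a, succ_grid)
            assert cd.classification == ca.classification == "bell"
            assert abs(np.log(cd.peak_x / ca.peak_x)) <= 1.5 * cell
        cd25 = _classify(swD, "25d", succ_grid)
        assert cd25.classification.endswith("monotone")

    def test_slower_succinate_binding_shifts_peak_right_and_down(
            self, assembled, params, succ_grid):
        # transport-limited succinate entry, emulated through k1
        peaks = []
        for k1 in (1.0, 0.2, 0.05):
            sw = c.sweep(assembled, params.copy(aa5=0.25, kf1=k1),
                         "succinate", succ_grid)
            cs = _classify(sw, "22", succ_grid)
            assert cs.classification == "bell"
            peaks.append((cs.peak_x, cs.peak_y))
        xs, ys = zip(*peaks)
        assert xs[0] < xs[1] < xs[2]
        assert ys[0] > ys[1] > ys[2]


class TestInhibitionDiagnostics:
    def test_apparent_vmax_decreases_with_inhibitor(self, sweep_cache):
        sweeps = {a: sweep_cache(aa5=a) for a in (0.0, 0.05, 0.25)}
        table = c.inhibition_diagnostics(sweeps, "v20")
        assert table["ok"].all()
        assert table["vmax"].is_monotonic_decreasing
        assert np.all(np.isfinite(table["km"]))

    def test_duplicate_conditions_give_identical_fits(self, sweep_cache):
        sw = sweep_cache()
        t1 = c.inhibition_diagnostics({0.0: sw}, "v20")
        t2 = c.inhibition_diagnostics({0.0: sw}, "v20")
        assert t1.equals(t2)

    def test_michaelis_fit_initialisation_from_half_max(self):
        x = np.geomspace(1, 5000, 25)
        vmax, km, resid = fit_michaelis(x, 7.5 * x / (220.0 + x))
        assert vmax == pytest.approx(7.5, rel=1e-3)
        assert km == pytest.approx(220.0, rel=1e-3)
        assert resid < 1e-6
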