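"""Network structure: stoichiometry, conserved moieties, rate laws."""

from fractions import Fraction

import numpy as np
import pytest
import sympy

import ciiros as c
from ciiros.network import Reaction, Species, reaction_rates


@pytest.fixture(scope="module")
def full():
    p = c.ParameterSet(CIIt=100.0, ABt=135.0, CDt=135.0)
    return c.build_network("mixed", p), p


class TestStructure:
    def test_full_network_has_53_reactions(self, full):
        net, _ = full
        assert net.n_reactions == 53

    def test_full_network_has_35_independent_odes(self, full):
        net, _ = full
        assert net.n_odes() == 35
        assert np.linalg.matrix_rank(net.N) == 35

    def test_rank_plus_conservations_equals_species(self, full):
        net, _ = full
        assert np.linalg.matrix_rank(net.N) + len(net.conserved_moieties()) \
            == net.n_free

    def test_assembled_only_excludes_disintegrated_reactions(self, params):
        net = c.build_network("assembled_only", params)
        assert not any(r.rid.endswith("d") for r in net.reactions)

    def test_mixed_with_empty_pools_gives_zero_disintegrated_flux(self):
        p = c.ParameterSet(CIIt=235.0, ABt=0.0, CDt=0.0)
        net = c.build_network("mixed", p)
        rng = np.random.default_rng(3)
        x = net.initial_state(p)
        # perturb only assembled species; d-pools stay empty
        for sid in ("fadh2", "fes3_red", "b_red", "qh2", "o2m", "h2o2"):
            x[net.free_index(sid)] = rng.uniform(0.1, 5.0)
        net_rates, _, _ = reaction_rates(net, x, p)
        d_idx = [j for j, r in enumerate(net.reactions) if r.rid.endswith("d")
                 and r.rid not in ("10d", "20d", "27d")]  # pool-only binding
        assert np.allclose(net_rates[d_idx], 0.0)

    def test_negative_pool_total_rejected(self):
        with pytest.raises(ValueError):
            c.ParameterSet(CIIt=-1.0)

    def test_assembled_topology_requires_empty_subcomplex_pools(self):
        p = c.ParameterSet(ABt=10.0, CDt=10.0)
        with pytest.raises(ValueError):
            c.build_network("assembled_only", p)

    def test_unknown_topology_rejected(self, params):
        with pytest.raises(c.NetworkError):
            c.build_network("half_disintegrated", params)

    def test_duplicate_species_ids_rejected(self):
        sp = [Species("a"), Species("a")]
        with pytest.raises(c.NetworkError):
            c.Network(sp, [])


class TestConservedMoieties:
    def test_toy_isomerisation_has_single_moiety(self):
        net = c.Network(
            [Species("A", concentration=1.0), Species("B")],
            [Reaction("1", (("A", 1),), (("B", 1),))],
        )
        (m,) = net.conserved_moieties()
        assert m == {"A": Fraction(1), "B": Fraction(1)}

    def test_basis_annihilates_stoichiometry_exactly(self, full):
        net, _ = full
        for m in net.conserved_moieties():
            y = np.zeros(net.n_free)
            for sid, coeff in m.items():
                y[net.free_index(sid)] = float(coeff)
            assert np.all(y @ net.N == 0.0)   # exact: integer arithmetic

    def test_span_matches_rational_nullspace_oracle(self, full):
        # independent oracle: sympy's exact left null space of N
        net, _ = full
        N = sympy.Matrix(net.N.astype(int))
        oracle = N.T.nullspace()
        ours = net.conserved_moieties()
        assert len(oracle) == len(ours)
        M_oracle = sympy.Matrix([[v[i] for i in range(net.n_free)]
                                 for v in oracle])
        M_ours = sympy.Matrix([
            [m.get(sid, Fraction(0)) for sid in net.free_ids] for m in ours
        ])
        stacked = M_oracle.col_join(M_ours)
        assert stacked.rank() == len(ours)    # identical span

    def test_natural_pools_are_conserved(self, full):
        # the physical pools (each redox centre, the Q site, the Q pool) are
        # left-null vectors of the stoichiometry and start at their totals
        net, p = full
        pools = {
            "CIIt": ["fad", "fad_s", "fad_f", "fadh2_f", "fadh2", "fadh2_s",
                     "fadhsq"],
            "CIIt_fes3": ["fes3_ox", "fes3_red"],
            "CIIt_b": ["b_ox", "b_red"],
            "CIIt_site": ["cii", "cii_q", "cii_qm", "cii_qh", "cii_qhm",
                          "cii_qh2", "cii_aa5"],
            "ABt": ["fad_d", "fad_s_d", "fad_f_d", "fadh2_f_d", "fadh2_d",
                    "fadh2_s_d", "fadhsq_d"],
            "CDt": ["bd_ox", "bd_red"],
            "Qt": ["q", "qh2", "cii_q", "cii_qm", "cii_qh", "cii_qhm",
                   "cii_qh2", "cd_q", "cd_qm", "cd_qh", "cd_qhm", "cd_qh2"],
        }
        x0 = net.initial_state(p)
        for name, ids in pools.items():
            y = np.zeros(net.n_free)
            for sid in ids:
                y[net.free_index(sid)] = 1.0
            assert np.all(y @ net.N == 0.0), name
            assert y @ x0 == pytest.approx(p[name.split("_")[0]])


class TestRateLaws:
    def test_all_zero_state_with_zero_clamps_gives_zero_rates(self, full):
        net, p = full
        p0 = p.copy(succ=0.0, fum=0.0, aa5=0.0, o2=0.0, h=0.0)
        net_r, fwd, rev = reaction_rates(net, np.zeros(net.n_free), p0)
        assert np.all(net_r == 0) and np.all(fwd == 0) and np.all(rev == 0)

    def test_reverse_rate_zero_when_products_absent(self, full):
        net, p = full
        x = np.zeros(net.n_free)
        x[net.free_index("fes3_red")] = 10.0
        x[net.free_index("b_ox")] = 10.0
        j = net.rid_index("9")
        _, fwd, rev = reaction_rates(net, x, p)
        assert fwd[j] > 0 and rev[j] == 0.0

    def test_forward_reverse_decomposition(self, full):
        net, p = full
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 10.0, net.n_free)
        net_r, fwd, rev = reaction_rates(net, x, p)
        assert np.all(fwd >= 0) and np.all(rev >= 0)
        assert np.allclose(net_r, fwd - rev, rtol=1e-12, atol=1e-12)
        irrev = [j for j, r in enumerate(net.reactions) if not r.reversible]
        assert np.all(rev[irrev] == 0.0)

    def test_against_independent_mass_action_oracle(self, full):
        # recompute every rate by direct products over the reaction's own
        # reactant/product lists -- independent of the vectorised path
        net, p = full
        clamp_of = {"succ": "succ", "fum": "fum", "aa5": "aa5", "o2": "o2",
                    "h": "h"}
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.uniform(0.0, 50.0, net.n_free)
            _, fwd, rev = reaction_rates(net, x, p)
            for j, r in enumerate(net.reactions):
                kf, kr = r.constants(p)
                conc = lambda sid: (x[net.free_index(sid)]
                                    if sid in net._free_index
                                    else p[clamp_of[sid]])
                terms = r.fwd_orders if r.fwd_orders is not None else r.reactants
                vf = kf
                for sid, order in terms:
                    vf *= conc(sid) ** order
                assert fwd[j] == pytest.approx(vf, rel=1e-12, abs=1e-300)
                if r.reversible:
                    vr = kr
                    for sid, order in r.products:
                        vr *= conc(sid) ** order
                    assert rev[j] == pytest.approx(vr, rel=1e-12, abs=1e-300)

    def test_negative_concentration_rejected(self, full):
        net, p = full
        x = np.zeros(net.n_free)
        x[0] = -1.0
        with pytest.raises(ValueError, match="negative concentration"):
            reaction_rates(net, x, p)

    def test_jacobian_matches_finite_differences(self, full):
        net, p = full
        from ciiros.network import rate_jacobian
        rng = np.random.default_rng(7)
        x = rng.uniform(0.5, 20.0, net.n_free)
        J = rate_jacobian(net, x, p)
        eps = 1e-4   # rate laws are at most bilinear: central FD is exact
        for j in rng.choice(net.n_free, size=8, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            # difference unidirectional rates (no near-equilibrium cancellation)
            _, fp, rp = reaction_rates(net, xp, p)
            _, fm, rm = reaction_rates(net, xm, p)
            fd = (fp - fm) / (2 * eps) - (rp - rm) / (2 * eps)
            scale = np.max(np.abs(fd)) + 1.0
            assert np.all(np.abs(J[:, j] - fd) / scale < 1e-5)
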