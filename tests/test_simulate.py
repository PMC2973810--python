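"""Steady states, partition equilibria, probes and dose responses."""

import math

import numpy as np
import pytest

import allonet as an
from allonet import library as lib
from allonet.simulate import (
    ODESystem,
    conservation_matrix,
    dose_response,
    equilibrium_partition,
    probe_value,
    simulate_trajectory,
    steady_state,
)

from conftest import adaptor_partition_oracle, initial_concentrations, monomer_label


class TestSteadyState:
    def test_single_reversible_binding_closed_form(self):
        # A + X <-> AX with K = 1 and unit totals: [AX] = (3 - sqrt 5)/2
        m = lib.build("divalent_adaptor", K_RT=1.0, K_RX=1.0, K_TX=1.0,
                      K_RY=1e-12, K_TY=1e-12, X_tot=1.0, Y_tot=0.0)
        net = an.enumerate_network(m)
        ss = steady_state(net, initial_concentrations(net, {"A": 1.0, "X": 1.0}))
        bound = probe_value(net, ss, m.probes["bound_X"])
        assert bound == pytest.approx((3.0 - math.sqrt(5.0)) / 2.0, rel=1e-8)

    def test_conformational_preequilibrium_without_ligand(self, adaptor_network):
        net = adaptor_network
        ss = steady_state(net, initial_concentrations(net, {"A": 1.0}))
        r = ss[monomer_label(net, "A")]
        t_label = [l for l in net.species if l.startswith("A(c=T)") and "+" not in l][0]
        assert ss[t_label] / r == pytest.approx(1e-3, rel=1e-6)  # [T]/[R] = K_RT

    def test_ode_agrees_with_partition_equilibrium(self, adaptor_network):
        net = adaptor_network
        ss = steady_state(
            net, initial_concentrations(net, {"A": 1.0, "Y": 1.0}), clamped={"X": 0.5}
        )
        ep = equilibrium_partition(net, totals={"A": 1.0, "Y": 1.0}, clamped={"X": 0.5})
        for lbl, v in ep.items():
            assert ss[lbl] == pytest.approx(v, rel=1e-6, abs=1e-12)

    def test_partition_refuses_catalytic_networks(self):
        net = an.enumerate_network(lib.build("kinase_cascade"))
        with pytest.raises(ValueError, match="binding"):
            equilibrium_partition(net, totals={"K": 1.0})

    def test_enzyme_is_conserved_through_catalysis(self):
        m = lib.build("kinase_cascade")
        net = an.enumerate_network(m)
        ss = steady_state(net, initial_concentrations(net, m.init))
        assert probe_value(net, ss, m.probes["total_K"]) == pytest.approx(1.0, rel=1e-9)

    def test_mass_conservation_along_trajectory(self, adaptor_network):
        net = adaptor_network
        init = initial_concentrations(net, {"A": 1.0, "X": 0.7, "Y": 1.0})
        sys = ODESystem(net)
        c0 = sys.initial_vector(init)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(sys.rhs, (0, 50.0), c0, method="LSODA",
                        t_eval=np.linspace(0, 50, 21), rtol=1e-10, atol=1e-13)
        _, L = conservation_matrix(net)
        totals = L @ sol.y
        assert np.allclose(totals, totals[:, :1], rtol=1e-8)


class TestPartitionEquilibrium:
    def test_two_state_probability_ratio(self, adaptor_network):
        conc = equilibrium_partition(adaptor_network, totals={"A": 1.0})
        r = conc[monomer_label(adaptor_network, "A")]
        t = conc["A(c=T)"]
        assert t / r == pytest.approx(1e-3, rel=1e-12)

    def test_cube_probabilities_match_brute_force_oracle(self, adaptor_network):
        net = adaptor_network
        x, y = 0.8, 2.5
        conc = equilibrium_partition(net, totals={"A": 1.0}, clamped={"X": x, "Y": y})
        oracle = adaptor_partition_oracle(1e-3, 0.1, 10.0, 0.01, 100.0, x, y)
        p_rxy = conc["A(c=R)+X()+Y()|0.c.X-1.c.b;0.c.Y-2.c.b"]
        total_A = sum(v for l, v in conc.items() if "A(" in l)
        assert p_rxy / total_A == pytest.approx(oracle[("R", 1, 1)], rel=1e-9)

    def test_concerted_tetramer_matches_mwc_binding_curve(self, concerted_network):
        from conftest import mwc_occupancy

        probe = concerted_network.model.probes["bound_L0"]
        for l in (0.01, 0.2, 1.0, 20.0):
            conc = equilibrium_partition(concerted_network, totals={"P": 1.0}, clamped={"L0": l})
            assert probe_value(concerted_network, conc, probe) == pytest.approx(
                mwc_occupancy(l, 1e3, 10.0, 0.1), rel=1e-9
            )


class TestInvariances:
    def test_phi_invariance_of_equilibria(self):
        nets = {}
        for phi in (0.15, 0.85):
            m = lib.build("divalent_adaptor", phi=phi)
            net = an.enumerate_network(m)
            nets[phi] = steady_state(
                net, initial_concentrations(net, {"A": 1.0, "Y": 1.0}), clamped={"X": 1.0}
            )
        for lbl, v in nets[0.15].items():
            assert nets[0.85][lbl] == pytest.approx(v, rel=1e-6, abs=1e-12)

    def test_rate_rescaling_leaves_dose_response_unchanged(self):
        import dataclasses

        m1 = lib.build("divalent_adaptor")
        m2 = lib.build("divalent_adaptor")
        m2.rules = [dataclasses.replace(r, kf=r.kf * 37.0, kb=r.kb * 37.0) for r in m2.rules]
        m2.allosteric = {k: an.AllostericConstants(K0=v.K0, kf0=v.kf0 * 37.0)
                         for k, v in m2.allosteric.items()}
        grid = np.logspace(-3, 3, 25)
        c1 = dose_response(an.enumerate_network(m1), "X", grid, m1.probes["bound_Y"],
                           totals={"A": 1.0, "Y": 1.0})
        c2 = dose_response(an.enumerate_network(m2), "X", grid, m2.probes["bound_Y"],
                           totals={"A": 1.0, "Y": 1.0})
        assert np.allclose(c1.values, c2.values, rtol=1e-9)

    def test_linear_free_energy_relationship_across_contexts(self, concerted_network):
        # equal-Phi modifiers: log kf affine in log K over all conformational
        # transitions of the compiled network, slope = Phi
        pts = [
            (math.log(r.kf / r.mult_f) - math.log(r.kb / r.mult_b), math.log(r.kf / r.mult_f))
            for r in concerted_network.reactions
            if r.kind == "conformational"
        ]
        assert len(pts) >= 3
        (x0, y0), (x1, y1) = pts[0], pts[1]
        slope = (y1 - y0) / (x1 - x0)
        assert slope == pytest.approx(0.5, abs=1e-9)
        for x, y in pts[2:]:
            assert y == pytest.approx(y0 + slope * (x - x0), abs=1e-9)


class TestDoseResponse:
    def test_adaptor_recruitment_curve_is_monotone(self, adaptor_network):
        m = adaptor_network.model
        grid = np.logspace(-4, 4, 49)
        curve = dose_response(adaptor_network, "X", grid, m.probes["bound_Y"],
                              totals={"A": 1.0, "Y": 1.0})
        assert np.all(np.diff(curve.values) > 0)
        assert curve.values[-1] > 0.7  # saturating X recruits most of Y

    def test_total_protein_probe_is_constant(self, adaptor_network):
        m = adaptor_network.model
        grid = np.logspace(-3, 3, 13)
        curve = dose_response(adaptor_network, "X", grid, m.probes["total_A"],
                              totals={"A": 1.0, "Y": 1.0})
        assert np.allclose(curve.values, 1.0, rtol=1e-9)

    def test_gpcr_has_constitutive_basal_signalling(self, quartic_network):
        m = quartic_network.model
        grid = np.logspace(-4, 3, 36)
        curve = dose_response(quartic_network, "L1", grid, m.probes["signalling"],
                              totals={"R": 1.0, "G1": 1.0})
        assert curve.values[0] > 0.1  # constitutive activity at [L] -> 0
        assert np.all(np.diff(curve.values) > -1e-12)

    def test_decreasing_grid_is_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            an.DoseResponse(input="X", grid=[1.0, 0.5], values=[0.0, 1.0])


class TestStimuli:
    def test_step_stimulus_drives_clamped_species(self, adaptor_network):
        net = adaptor_network
        stim = an.Stimulus(target="X", kind="step", times=(0.0, 10.0), values=(0.0, 2.0))
        init = initial_concentrations(net, {"A": 1.0, "Y": 1.0})
        labels, t, y = simulate_trajectory(net, init, np.linspace(0, 40, 81), stimuli=[stim])
        x_idx = labels.index(monomer_label(net, "X"))
        assert y[x_idx, 0] == pytest.approx(0.0, abs=1e-12)
        assert y[x_idx, -1] == pytest.approx(2.0, rel=1e-6)
        probe = net.model.probes["bound_Y"]
        bound_pre = probe_value(net, dict(zip(labels, y[:, 20])), probe)
        bound_post = probe_value(net, dict(zip(labels, y[:, -1])), probe)
        assert bound_post > bound_pre
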