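"""Cooperativity, Hill, assembly and rank-order analyses."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import allonet as an
from allonet.analysis import (
    HillSummary,
    apparent_affinity,
    assembly_metrics,
    cooperativity_theta,
    ec_point,
    hill_coefficient,
    hill_summary,
    rank_order,
    theta_optimum,
    trimer_equilibrium,
)
from allonet.simulate import DoseResponse

from conftest import adaptor_theta_oracle


def hill_curve(n, ec50=1.0, lo=None, hi=None, pts=200, ymax=1.0):
    # default range wide enough that the end values sit on the asymptotes
    lo = lo if lo is not None else math.log10(ec50) - 14.0 / n
    hi = hi if hi is not None else math.log10(ec50) + 14.0 / n
    grid = np.logspace(lo, hi, pts)
    y = ymax * grid**n / (ec50**n + grid**n)
    return DoseResponse(input="L", grid=grid, values=y)


class TestTheta:
    def test_trivial_limits(self):
        assert cooperativity_theta(1e-3, 1.0, 1e4) == pytest.approx(1.0)
        assert cooperativity_theta(1e-12, 100.0, 100.0) == pytest.approx(1.0, abs=1e-6)

    def test_adaptor_reference_parameters(self):
        assert cooperativity_theta(1e-3, 100.0, 1e4) == pytest.approx(82.81, abs=0.01)

    def test_symmetry_in_the_two_ligands(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            K, a, b = 10.0 ** rng.uniform(-4, 2, 3)
            assert cooperativity_theta(K, a, b) == pytest.approx(
                cooperativity_theta(K, b, a), rel=1e-12
            )

    def test_closed_form_matches_eight_state_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            K_RT = 10.0 ** rng.uniform(-4, 2)
            K_RX, K_RY = 10.0 ** rng.uniform(-2, 1, 2)
            gx, gy = 10.0 ** rng.uniform(-3, 3, 2)
            oracle = adaptor_theta_oracle(K_RT, K_RX, gx * K_RX, K_RY, gy * K_RY)
            assert cooperativity_theta(K_RT, gx, gy) == pytest.approx(oracle, rel=1e-6)


class TestThetaOptimum:
    @pytest.mark.parametrize(
        "gx,gy,expected",
        [(100.0, 100.0, 1e-2), (1e4, 1e2, 1e-3), (1.0, 1.0, 1.0)],
    )
    def test_closed_form(self, gx, gy, expected):
        assert theta_optimum(gx, gy) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_numerical_maximization(self):
        for gx, gy in [(50.0, 2e3), (7.0, 7.0), (1e4, 30.0)]:
            res = minimize_scalar(
                lambda lk: -cooperativity_theta(math.exp(lk), gx, gy),
                bounds=(-25, 10), method="bounded",
                options={"xatol": 1e-12},
            )
            assert math.exp(res.x) == pytest.approx(theta_optimum(gx, gy), rel=1e-6)

    def test_degenerate_flat_maximum(self):
        for K in (1e-3, 1.0, 1e3):
            assert cooperativity_theta(K, 1.0, 1.0) == pytest.approx(1.0)


class TestApparentAffinity:
    def test_limits(self):
        assert apparent_affinity(0.1, 10.0, 1e-12) == pytest.approx(0.1)
        assert apparent_affinity(0.1, 10.0, 1e12) == pytest.approx(10.0)

    def test_against_four_state_partition(self):
        # conformation-summed affinity measured from state probabilities
        from conftest import adaptor_partition_oracle

        K_R, K_T, K_RT = 0.1, 10.0, 1e-3
        eps = 1e-9
        p = adaptor_partition_oracle(K_RT, K_R, K_T, 1e-30, 1e-30, eps, 0.0)
        bound = sum(v for (c, bx, by), v in p.items() if bx)
        measured = bound / ((1 - bound) * eps)
        assert apparent_affinity(K_R, K_T, K_RT) == pytest.approx(measured, rel=1e-6)


class TestHill:
    @pytest.mark.parametrize("method", ["midpoint", "ec1090"])
    @pytest.mark.parametrize("n", [0.5, 1.0, 2.0, 3.7])
    def test_exact_hill_curves_are_recovered(self, n, method):
        assert hill_coefficient(hill_curve(n), method=method) == pytest.approx(n, abs=1e-6)

    def test_michaelian_curve_gives_unity(self):
        assert hill_coefficient(hill_curve(1.0, ec50=3.3)) == pytest.approx(1.0, abs=1e-6)

    def test_ec_point_interpolation(self):
        curve = hill_curve(2.0, ec50=0.7)
        assert ec_point(curve, 0.5) == pytest.approx(0.7, rel=1e-4)

    def test_unbracketed_ec_point_raises(self):
        curve = hill_curve(1.0, ec50=1e-6, lo=-2, hi=4)
        with pytest.raises(ValueError, match="bracket"):
            ec_point(curve, 0.10)

    def test_non_monotone_curve_raises(self):
        grid = np.logspace(-2, 2, 30)
        y = np.sin(np.linspace(0, 3, 30)) + 2
        with pytest.raises(ValueError, match="monotone"):
            hill_coefficient(DoseResponse(input="L", grid=grid, values=y))

    def test_concerted_hill_never_exceeds_site_count(self, concerted_network):
        from allonet.analysis import sweep_saturating

        probe = concerted_network.model.probes["bound_L0"]
        for K_RT in (1e3,):
            curve = sweep_saturating(concerted_network, "L0", probe, totals={"P": 1e-9})
            assert 1.0 < hill_coefficient(curve) < 4.0


class TestAssembly:
    def test_reference_metrics(self):
        am = assembly_metrics([1.0, 1e4])
        assert am[1.0]["range_decades"] == pytest.approx(1.3, abs=0.1)
        assert am[1e4]["range_decades"] == pytest.approx(4.0, abs=0.1)
        ratio = am[1e4]["max_complex"] / am[1.0]["max_complex"]
        assert ratio == pytest.approx(5.7, abs=0.2)

    def test_range_is_monotone_in_theta(self):
        thetas = [1.0, 10.0, 1e2, 1e3, 1e4]
        am = assembly_metrics(thetas)
        ranges = [am[t]["range_decades"] for t in thetas]
        assert all(b >= a for a, b in zip(ranges, ranges[1:]))

    def test_prozone_effect(self):
        # excess linker suppresses the complex: the curve decreases again
        conc_low, _ = trimer_equilibrium(1.0, theta=1.0)
        conc_high, _ = trimer_equilibrium(1e4, theta=1.0)
        assert conc_high["XAY"] < 0.05 * conc_low["XAY"]

    def test_truncated_grid_raises(self):
        with pytest.raises(ValueError, match="truncated"):
            assembly_metrics([1.0], log10_A_range=(-0.5, 0.5))

    def test_coarse_grained_model_matches_full_allosteric_network(self):
        # the theta-parameterized 4-species model against a compiled
        # adaptor network with affinities chosen by inverting theta/K_app
        from allonet import library as lib

        theta = 100.0
        m = lib.build("trimer_assembly", theta=theta)
        net = an.enumerate_network(m)
        probe = m.probes["trimer"]
        for A_tot in (0.3, 3.0, 30.0):
            conc = an.equilibrium_partition(net, totals={"A": A_tot, "X": 1.0, "Y": 1.0})
            full = an.probe_value(net, conc, probe)
            coarse = trimer_equilibrium(A_tot, theta=theta)[0]["XAY"]
            assert full == pytest.approx(coarse, rel=1e-8)


class TestRankOrder:
    def _summary(self, potency, efficacy, basal=0.1):
        return HillSummary(n_H=1.0, ec50=10.0**-potency, potency=potency,
                           efficacy=efficacy, basal=basal)

    def test_ordering_and_selectivity_flags(self):
        summaries = {
            ("L1", "G1"): self._summary(2.0, 0.9),
            ("L2", "G1"): self._summary(1.0, 0.6),
            ("L1", "G2"): self._summary(0.5, 0.5),
            ("L2", "G2"): self._summary(1.5, 0.8),
        }
        out = rank_order(summaries)
        assert out["order"] == {"G1": ["L1", "L2"], "G2": ["L2", "L1"]}
        assert out["selective"] is True
        assert out["inverse_agonists"] == set()

    def test_inverse_agonist_flag(self):
        summaries = {
            ("L3", "G1"): self._summary(1.0, 0.5, basal=0.2),
            ("L3", "G2"): self._summary(1.0, 0.05, basal=0.2),
        }
        out = rank_order(summaries)
        assert out["inverse_agonists"] == {("L3", "G2")}
        assert out["selective"] is True  # agonist on one pathway only
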