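"""Model library builders and the random-model generator."""

import math

import numpy as np
import pytest

import allonet as an
from allonet import library as lib
from allonet.library import CubicTernaryComplex, quartic_to_cubic
from allonet.model import validate_model
from allonet.modelfile import parse_model, serialize_model

from conftest import initial_concentrations

COMPILABLE = [
    ("divalent_adaptor", {}),
    ("trimer_assembly", {"theta": 50.0}),
    ("concerted_tetramer", {}),
    ("sequential_tetramer_tetrahedral", {}),
    ("sequential_tetramer_square", {}),
    ("tertiary_two_state", {}),
    ("gpcr_quartic", {}),
    ("kinase_cascade", {}),
]


class TestBuilders:
    @pytest.mark.parametrize("name,kwargs", COMPILABLE)
    def test_builders_compile_and_balance(self, name, kwargs):
        m = lib.build(name, **kwargs)
        assert not [d for d in validate_model(m) if d.level == "error"]
        net = an.enumerate_network(m)
        residuals = an.detailed_balance_residuals(net)
        assert all(r.residual < 1e-9 for r in residuals)

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown model"):
            lib.build("nonexistent")

    def test_unknown_override_raises(self):
        with pytest.raises(TypeError):
            lib.build("divalent_adaptor", K_bogus=1.0)

    def test_adaptor_has_eight_protein_states(self, adaptor_network):
        protein = [l for l, s in adaptor_network.species.items() if "A" in s.composition]
        assert len(protein) == 8

    def test_sequential_coupling_counts(self):
        tet = lib.build("sequential_tetramer_tetrahedral").structures["P"]
        sq = lib.build("sequential_tetramer_square").structures["P"]

        def pair_count(struct):
            pairs = set()
            for cpath, comp in struct.components().items():
                for cpl in comp.couplings:
                    if cpl.modifier in struct.components():
                        pairs.add(frozenset((cpath, cpl.modifier)))
            return len(pairs)

        assert pair_count(tet) == 6  # K4 edges
        assert pair_count(sq) == 4  # C4 edges

    def test_quartic_receptor_context_count(self, quartic_network):
        # 4 joint conformations x 2 ligation x 2 G-binding states
        receptor = [
            l for l, s in quartic_network.species.items() if "R" in s.composition
        ]
        assert len(receptor) == 16

    def test_model_files_round_trip_through_the_parser(self, tmp_path):
        for name, kwargs in COMPILABLE[:4]:
            m = lib.build(name, **kwargs)
            path = tmp_path / f"{name}.yaml"
            path.write_text(serialize_model(m))
            assert parse_model(path.read_text()) == m


class TestTertiaryTwoState:
    def test_two_ligand_species_count_matches_combinatorial_oracle(self):
        # subunit state space: 2 tertiary conformations x (empty | ligand A
        # | ligand B) = 6; multisets of 4 subunits: C(9,4) = 126; times 2
        # quaternary conformations = 252 receptor species
        m = lib.build(
            "tertiary_two_state", ligands=("LA", "LB"), gammas={"LA": 0.01, "LB": 0.02}
        )
        net = an.enumerate_network(m)
        receptor = [l for l, s in net.species.items() if "P" in s.composition]
        assert math.comb(9, 4) * 2 == 252
        assert len(receptor) == 252


class TestQuarticCubicProjection:
    @pytest.mark.parametrize("ligand,gprot", [("L1", "G1"), ("L2", "G2"), ("L3", "G2")])
    def test_marginalized_quartic_equals_cubic_closed_form(self, ligand, gprot):
        m = lib.build("gpcr_quartic", ligands=(ligand,), gproteins=(gprot,))
        net = an.enumerate_network(m)
        cubic = quartic_to_cubic(ligand, gprot)
        for L in (0.0, 0.05, 1.0, 50.0):
            conc = an.equilibrium_partition(
                net, totals={"R": 1.0, gprot: 1.0}, clamped={ligand: L}
            )
            sig = an.probe_value(net, conc, m.probes["signalling"])
            assert sig == pytest.approx(cubic.signalling_fraction(L), rel=1e-9, abs=1e-12)

    def test_projected_parameters_are_concentration_independent(self):
        # the cubic gamma/delta derived from the quartic model are fixed
        # numbers, not free per-pair knobs: recomputing the projection from
        # marginal weights at different concentrations gives the same values
        cubic = quartic_to_cubic("L2", "G2")
        w1 = cubic.weights(0.1, 0.3)
        w2 = cubic.weights(5.0, 0.01)
        for a in (0, 1):
            g1 = w1[(a, 1, 1)] * w1[(a, 0, 0)] / (w1[(a, 1, 0)] * w1[(a, 0, 1)])
            g2 = w2[(a, 1, 1)] * w2[(a, 0, 0)] / (w2[(a, 1, 0)] * w2[(a, 0, 1)])
            assert g1 == pytest.approx(g2, rel=1e-12)

    def test_basal_signalling_is_constitutive(self, quartic_network):
        m = quartic_network.model
        conc = an.equilibrium_partition(
            quartic_network, totals={"R": 1.0, "G1": 1.0}, clamped={"L1": 0.0}
        )
        assert an.probe_value(quartic_network, conc, m.probes["signalling"]) > 0.0


class TestRandomModels:
    def test_same_seed_same_model(self):
        assert lib.random_model(123) == lib.random_model(123)
        assert lib.random_model(123) != lib.random_model(124)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_models_are_valid_and_balanced(self, seed):
        m = lib.random_model(seed)
        assert not [d for d in validate_model(m) if d.level == "error"]
        net = an.enumerate_network(m)
        residuals = an.detailed_balance_residuals(net)
        assert all(r.residual < 1e-9 for r in residuals)

    def test_covalent_variant_has_catalysis_and_conserves_enzyme(self):
        m = lib.random_model(3, covalent=True)
        net = an.enumerate_network(m)
        assert not net.is_binding_only()
        ss = an.steady_state(net, initial_concentrations(net, m.init))
        total_E = sum(
            v * net.species[l].composition.get("E", 0) for l, v in ss.items()
        )
        assert total_E == pytest.approx(m.init["E"], rel=1e-8)
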