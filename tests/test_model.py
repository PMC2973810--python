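"""Model validation, parameter accounting and structure symmetry."""

import dataclasses

import pytest

import allonet as an
from allonet import library as lib
from allonet.model import (
    AllostericConstants,
    ComponentSpec,
    ModifierCoupling,
    SiteSpec,
    StructureSpec,
    biomolecule_centric_count,
    classify_parameters,
    interaction_centric_count,
    structure_automorphisms,
    validate_model,
)


class TestValidation:
    @pytest.mark.parametrize(
        "name",
        ["divalent_adaptor", "concerted_tetramer", "sequential_tetramer_tetrahedral",
         "sequential_tetramer_square", "tertiary_two_state", "gpcr_quartic",
         "gpcr_cubic", "kinase_cascade"],
    )
    def test_library_models_are_valid(self, name):
        diags = [d for d in validate_model(lib.build(name)) if d.level == "error"]
        assert diags == []

    def test_negative_gamma_is_diagnosed(self):
        m = lib.build("sequential_tetramer_tetrahedral")
        su1 = m.structures["P"].root.children[0]
        bad = dataclasses.replace(
            su1, couplings=tuple(
                dataclasses.replace(c, gamma=-1.0 if c.gamma is not None else None)
                for c in su1.couplings
            ),
        )
        m.structures["P"] = StructureSpec(
            "P",
            dataclasses.replace(
                m.structures["P"].root, children=(bad,) + m.structures["P"].root.children[1:]
            ),
        )
        msgs = [d.message for d in validate_model(m) if d.level == "error"]
        assert any("gamma must be positive" in msg for msg in msgs)

    def test_non_reciprocal_component_coupling_is_diagnosed(self):
        comp_b = ComponentSpec(
            name="B", allosteric=True, conformations=("r", "t"),
            sites=(SiteSpec("s", "binding"),),
        )
        comp_a = ComponentSpec(
            name="A", allosteric=True, conformations=("r", "t"),
            couplings=(ModifierCoupling(modifier="c.B", gamma=10.0),),
        )
        root = ComponentSpec(name="c", children=(comp_a, comp_b))
        m = an.ModelSpec(
            structures={"P": StructureSpec("P", root)},
            allosteric={
                "P.c.A": AllostericConstants(K0=1.0),
                "P.c.B": AllostericConstants(K0=1.0),
            },
        )
        msgs = [d.message for d in validate_model(m) if d.level == "error"]
        assert any("detailed balance" in msg for msg in msgs)

    def test_missing_allosteric_constant_is_diagnosed(self):
        m = lib.build("divalent_adaptor")
        m.allosteric = {}
        msgs = [d.message for d in validate_model(m) if d.level == "error"]
        assert any("missing allosteric constants" in msg for msg in msgs)

    def test_phi_outside_unit_interval_warns(self):
        m = lib.build("divalent_adaptor", phi=1.4)
        warns = [d for d in validate_model(m) if d.level == "warning"]
        assert any("outside [0, 1]" in d.message for d in warns)
        assert not [d for d in validate_model(m) if d.level == "error"]


class TestParameterAccounting:
    def test_quartic_gpcr_counts(self):
        assert classify_parameters(lib.build("gpcr_quartic", ligands=4, gproteins=10)) == {
            "intensive": 3, "extensive": 56, "total": 59,
        }
        # single ligand/G-protein pair: 11 parameters, 3 intensive
        one = classify_parameters(lib.build("gpcr_quartic"))
        assert one["total"] == 11 and one["intensive"] == 3

    def test_cubic_gpcr_counts(self):
        assert classify_parameters(lib.build("gpcr_cubic", ligands=4, gproteins=10))[
            "total"
        ] == 109
        # single pair: 7 parameters, 1 intensive
        one = classify_parameters(lib.build("gpcr_cubic"))
        assert one["total"] == 7 and one["intensive"] == 1

    def test_generic_model_rate_constant_count(self):
        m = lib.build("generic_two_state", n_sites=6, n_ligands=5)
        assert classify_parameters(m, level="kinetic")["total"] == 91

    def test_counting_formulas_match_explicit_models(self):
        for n, l in [(2, 2), (3, 1), (6, 5)]:
            m = lib.build("generic_two_state", n_sites=n, n_ligands=l)
            assert classify_parameters(m, level="kinetic")["total"] == biomolecule_centric_count(n, l)

    def test_interaction_centric_explosion(self):
        assert interaction_centric_count(6, 5) == 233280
        assert interaction_centric_count(6, 5) > 233000

    def test_additivity_and_linear_scaling(self):
        # adding one ligand to the generic model adds a constant number of
        # parameters per site, independent of N and L
        def total(n, l):
            return classify_parameters(
                lib.build("generic_two_state", n_sites=n, n_ligands=l), level="kinetic"
            )["total"]

        d1 = total(3, 3) - total(3, 2)
        d2 = total(3, 5) - total(3, 4)
        d3 = total(5, 3) - total(5, 2)
        assert d1 == d2  # independent of L
        assert d3 / 5 == d1 / 3  # proportional to N only


class TestAutomorphisms:
    def test_concerted_tetramer_full_site_symmetry(self, concerted_model):
        auts = structure_automorphisms(concerted_model.structures["P"])
        assert len(auts) == 24  # S4 on the four identical sites

    def test_coupling_graph_restricts_symmetry(self):
        tet = lib.build("sequential_tetramer_tetrahedral").structures["P"]
        sq = lib.build("sequential_tetramer_square").structures["P"]
        assert len(structure_automorphisms(tet)) == 24  # K4: all of S4
        assert len(structure_automorphisms(sq)) == 8  # C4 ring: dihedral group

    def test_rule_filter_breaks_shape_symmetry(self, adaptor_model):
        from allonet.species import Canonicalizer

        # the adaptor's X and Y sites are identical in shape (swap is a
        # structural symmetry) but bind different ligands with different
        # rates, so the usable group must reduce to the identity
        assert len(structure_automorphisms(adaptor_model.structures["A"])) == 2
        assert len(Canonicalizer(adaptor_model).automorphisms("A")) == 1
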