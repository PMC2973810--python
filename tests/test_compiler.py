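"""Network compilation: canonical labels, statistical factors, enumeration."""

import pytest

import allonet as an
from allonet import library as lib
from allonet.compiler import enumerate_network, reaction_multiplicity
from allonet.species import Canonicalizer, make_monomer


def bind_ligand(raw, lig_raw, protein_site, n_before=None):
    """Helper: bond a ligand monomer onto a protein site."""
    from allonet.compiler import _merge

    return _merge(raw, lig_raw, (0, protein_site), (0, "c.b"))


class TestCanonicalLabels:
    def test_equivalent_tetramer_sites_are_identified(self, concerted_model):
        canon = Canonicalizer(concerted_model)
        prot = make_monomer(concerted_model, "P")
        lig = make_monomer(concerted_model, "L0")
        on_s1 = bind_ligand(prot, lig, "c.s1")
        on_s3 = bind_ligand(prot, lig, "c.s3")
        assert canon.label(on_s1) == canon.label(on_s3)

    def test_conformations_distinguish_species(self, adaptor_model):
        from allonet.species import RawSpecies

        canon = Canonicalizer(adaptor_model)
        a_r = make_monomer(adaptor_model, "A")
        a_t = RawSpecies((a_r.instances[0].with_conf("c", "T"),), frozenset())
        assert canon.label(a_r) != canon.label(a_t)

    def test_instance_order_is_irrelevant(self, adaptor_model):
        from allonet.compiler import _merge

        canon = Canonicalizer(adaptor_model)
        a = make_monomer(adaptor_model, "A")
        x = make_monomer(adaptor_model, "X")
        y = make_monomer(adaptor_model, "Y")
        ax = _merge(a, x, (0, "c.X"), (0, "c.b"))
        axy = _merge(ax, y, (0, "c.Y"), (0, "c.b"))
        ya = _merge(y, a, (0, "c.b"), (0, "c.Y"))
        yax = _merge(ya, x, (1, "c.X"), (0, "c.b"))
        assert canon.label(axy) == canon.label(yax)

    def test_square_vs_tetrahedral_lumping_differs(self):
        # two ligands on adjacent vs opposite subunits: distinct in the
        # square (ring) geometry, identical under tetrahedral symmetry
        for geometry, expect_equal in [("tetrahedral", True), ("square", False)]:
            m = lib.build(f"sequential_tetramer_{geometry}", ligands=("L0",))
            canon = Canonicalizer(m)
            from allonet.compiler import _merge

            prot = make_monomer(m, "P")
            lig = make_monomer(m, "L0")
            adjacent = _merge(
                _merge(prot, lig, (0, "c.su1.b"), (0, "c.b")),
                lig, (0, "c.su2.b"), (0, "c.b"),
            )
            opposite = _merge(
                _merge(prot, lig, (0, "c.su1.b"), (0, "c.b")),
                lig, (0, "c.su3.b"), (0, "c.b"),
            )
            assert (canon.label(adjacent) == canon.label(opposite)) is expect_equal


class TestMultiplicity:
    def test_first_binding_to_empty_tetramer_has_four_embeddings(self, concerted_model):
        prot = make_monomer(concerted_model, "P")
        lig = make_monomer(concerted_model, "L0")
        rule = concerted_model.rules[0]  # R-context binding
        groups = reaction_multiplicity(concerted_model, prot, rule, partner=lig)
        assert list(groups.values()) == [4]

    def test_full_tetramer_dissociation_has_four_embeddings(self, concerted_model):
        from allonet.compiler import _merge

        prot = make_monomer(concerted_model, "P")
        lig = make_monomer(concerted_model, "L0")
        full = prot
        for i in range(1, 5):
            full = _merge(full, lig, (0, f"c.s{i}"), (0, "c.b"))
        rule = concerted_model.rules[0]
        groups = reaction_multiplicity(concerted_model, full, rule)
        assert list(groups.values()) == [4]

    def test_distinct_adaptor_sites_have_unit_multiplicity(self, adaptor_model):
        a = make_monomer(adaptor_model, "A")
        x = make_monomer(adaptor_model, "X")
        groups = reaction_multiplicity(adaptor_model, x, adaptor_model.rules[0], partner=a)
        assert list(groups.values()) == [1]


class TestEnumeration:
    def test_adaptor_cube_species_and_reactions(self, adaptor_network):
        net = adaptor_network
        assert len(net.species) == 10  # 8 adaptor states + free X + free Y
        assert net.n_reversible == 12  # edges of the 3-cube
        kinds = {}
        for r in net.reactions:
            kinds[r.kind] = kinds.get(r.kind, 0) + 1
        assert kinds == {"conformational": 4, "binding": 8}

    def test_concerted_tetramer_lumped_count(self, concerted_network):
        # 2 conformations x 0..4 ligands + free ligand
        assert len(concerted_network.species) == 11

    def test_no_rules_means_conformational_reactions_only(self, adaptor_model):
        m = lib.build("divalent_adaptor")
        m.rules = []
        net = enumerate_network(m)
        assert sorted(s.size for s in net.species.values()) == [1, 1, 1, 1]
        assert all(r.kind == "conformational" for r in net.reactions)

    def test_idempotence(self, adaptor_network):
        seeds = [sp.raw for sp in adaptor_network.species.values()]
        net2 = enumerate_network(adaptor_network.model, seeds=seeds)
        assert set(net2.species) == set(adaptor_network.species)
        assert len(net2.reactions) == len(adaptor_network.reactions)

    def test_instance_conservation_in_every_reaction(self, quartic_network):
        from collections import Counter

        for r in quartic_network.reactions:
            lhs, rhs = Counter(), Counter()
            for l in r.reactants:
                lhs += quartic_network.composition(l)
            for l in r.products:
                rhs += quartic_network.composition(l)
            assert lhs == rhs

    def test_deterministic_output(self, adaptor_model):
        n1 = enumerate_network(lib.build("divalent_adaptor"))
        n2 = enumerate_network(lib.build("divalent_adaptor"))
        assert n1.species_order() == n2.species_order()
        assert [str(r) for r in n1.reactions] == [str(r) for r in n2.reactions]

    def test_species_cap_raises(self, adaptor_model):
        with pytest.raises(an.ModelError, match="cap"):
            enumerate_network(adaptor_model, max_species=3)


class TestLumpingCorrectness:
    @pytest.mark.parametrize("seed", [1, 4, 11])
    def test_random_symmetric_models_lump_to_microstate_equilibria(self, seed):
        m = lib.random_model(seed, n_sites=3, n_ligands=1, symmetric=True)
        lumped = enumerate_network(m)
        micro = enumerate_network(m, lump=False)
        assert len(micro.species) >= len(lumped.species)
        probe = m.probes["bound_L1"]
        for conc_l in (0.1, 2.0):
            cl = an.equilibrium_partition(lumped, totals={"P": 1.0}, clamped={"L1": conc_l})
            cm = an.equilibrium_partition(micro, totals={"P": 1.0}, clamped={"L1": conc_l})
            vl = an.probe_value(lumped, cl, probe)
            vm = an.probe_value(micro, cm, probe)
            assert vl == pytest.approx(vm, rel=1e-6)

    def test_concerted_tetramer_matches_microstate_network(
        self, concerted_model, concerted_network
    ):
        micro = enumerate_network(concerted_model, lump=False)
        assert len(micro.species) == 33  # 2 x 2^4 microstates + free ligand
        probe = concerted_model.probes["bound_L0"]
        for conc_l in (0.05, 0.5, 5.0):
            cl = an.equilibrium_partition(
                concerted_network, totals={"P": 1.0}, clamped={"L0": conc_l}
            )
            cm = an.equilibrium_partition(micro, totals={"P": 1.0}, clamped={"L0": conc_l})
            assert an.probe_value(concerted_network, cl, probe) == pytest.approx(
                an.probe_value(micro, cm, probe), rel=1e-6
            )
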