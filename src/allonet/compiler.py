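"""Iterative compilation of a model into a reaction network.

Starting from the reference-state monomers, the compiler repeatedly applies
every rule to every species (and pair of species) discovered so far,
canonicalizing each product, until no new species appear.  For every species
it also emits the conformational transitions of each allosteric component,
with rates derived from the component's unligated transition and the
regulatory factors of its currently active modifiers — this is what makes
every conformational/bimolecular cycle of the output thermodynamically
consistent by construction.

Symmetric sites contribute statistical factors: the lumped rate constant of
a reaction is the rule's rate times the number of site-level embeddings that
yield the same canonical product.
"""

from __future__ import annotations

import fnmatch
from collections import Counter, deque
from dataclasses import dataclass, field

from .model import ModelSpec, ModelError, RuleSpec
from .species import (
    Canonicalizer,
    Instance,
    RawSpecies,
    _norm_bond,
    make_monomer,
    match_site_pattern,
    _context_ok,
)
from .thermo import AllostericTransition, ModifierEffect, effective_rates

__all__ = ["Species", "Reaction", "ReactionNetwork", "enumerate_network", "reaction_multiplicity"]


@dataclass(frozen=True)
class Species:
    label: str
    raw: RawSpecies

    @property
    def size(self) -> int:
        return len(self.raw.instances)

    @property
    def composition(self) -> Counter:
        return Counter(inst.structure for inst in self.raw.instances)


@dataclass
class Reaction:
    """A (possibly reversible) lumped reaction.

    ``kf`` applies to reactants -> products, ``kb`` (None or 0 for
    irreversible steps) to the reverse.  Statistical factors are already
    folded into the lumped rates and recorded in ``mult_f``/``mult_b``.
    """

    kind: str  # "binding" | "conformational" | "catalytic"
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kf: float | None = None
    kb: float | None = None
    provenance: str = ""
    mult_f: int = 1
    mult_b: int = 1
    intramolecular: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        arrow = "<->" if self.kb else "->"
        return (
            f"{' + '.join(self.reactants)} {arrow} {' + '.join(self.products)}"
            f"  kf={self.kf} kb={self.kb} [{self.provenance}]"
        )


@dataclass
class ReactionNetwork:
    model: ModelSpec
    species: dict[str, Species]
    reactions: list[Reaction]
    canonicalizer: Canonicalizer
    warnings: list[str] = field(default_factory=list)

    def species_order(self) -> list[str]:
        return sorted(self.species)

    def seed_labels(self) -> list[str]:
        out = []
        for name in sorted(self.model.structures):
            lbl = self.canonicalizer.label(make_monomer(self.model, name))
            if lbl in self.species:
                out.append(lbl)
        return out

    def composition(self, label: str) -> Counter:
        return self.species[label].composition

    @property
    def n_reversible(self) -> int:
        return sum(1 for r in self.reactions if r.kb)

    def is_binding_only(self) -> bool:
        return all(r.kind != "catalytic" for r in self.reactions)

    # -- export ----------------------------------------------------------
    def species_frame(self):
        import pandas as pd

        rows = []
        for lbl in self.species_order():
            sp = self.species[lbl]
            comp = ",".join(f"{k}:{v}" for k, v in sorted(sp.composition.items()))
            rows.append({"label": lbl, "size": sp.size, "composition": comp})
        return pd.DataFrame(rows)

    def reaction_frame(self):
        import pandas as pd

        rows = []
        for r in sorted(self.reactions, key=lambda r: (r.reactants, r.products)):
            rows.append(
                {
                    "kind": r.kind,
                    "reactants": " + ".join(r.reactants),
                    "products": " + ".join(r.products),
                    "kf": r.kf,
                    "kb": r.kb,
                    "mult_f": r.mult_f,
                    "mult_b": r.mult_b,
                    "provenance": r.provenance,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, species_path, reactions_path) -> None:
        self.species_frame().to_csv(species_path, sep="\t", index=False)
        self.reaction_frame().to_csv(reactions_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rule application helpers
# ---------------------------------------------------------------------------

def _pattern_matches_at(model, raw, i, site_rel, pattern) -> bool:
    inst = raw.instances[i]
    if not fnmatch.fnmatchcase(f"{inst.structure}.{site_rel}", pattern.site):
        return False
    return _context_ok(model, raw, i, site_rel, pattern)


def _merge(s1: RawSpecies, s2: RawSpecies, a, b) -> RawSpecies:
    off = len(s1.instances)
    bonds = set(s1.bonds)
    for x, y in s2.bonds:
        bonds.add(_norm_bond((x[0] + off, x[1]), (y[0] + off, y[1])))
    bonds.add(_norm_bond(a, (b[0] + off, b[1])))
    return RawSpecies(s1.instances + s2.instances, frozenset(bonds))


def _add_bond(s: RawSpecies, a, b) -> RawSpecies:
    return RawSpecies(s.instances, s.bonds | {_norm_bond(a, b)})


def _split(raw: RawSpecies) -> list[RawSpecies]:
    """Connected components after bond edits."""
    n = len(raw.instances)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in raw.bonds:
        ra, rb = find(a[0]), find(b[0])
        parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for idxs in groups.values():
        remap = {old: new for new, old in enumerate(idxs)}
        insts = tuple(raw.instances[i] for i in idxs)
        bonds = frozenset(
            _norm_bond((remap[a[0]], a[1]), (remap[b[0]], b[1]))
            for a, b in raw.bonds
            if a[0] in remap
        )
        out.append(RawSpecies(insts, bonds))
    return out


def _remove_bond(raw: RawSpecies, bond) -> RawSpecies:
    return RawSpecies(raw.instances, raw.bonds - {bond})


def _bond_rules(model, raw, bond) -> list[tuple[RuleSpec, bool]]:
    """Rules governing a bond in the species' current context.

    Returns (rule, flipped) pairs; ``flipped`` means pattern b matched the
    first bond endpoint.
    """
    (i, sa), (j, sb) = bond
    out = []
    for rule in model.rules:
        if _pattern_matches_at(model, raw, i, sa, rule.a) and _pattern_matches_at(
            model, raw, j, sb, rule.b
        ):
            out.append((rule, False))
        elif _pattern_matches_at(model, raw, j, sb, rule.a) and _pattern_matches_at(
            model, raw, i, sa, rule.b
        ):
            out.append((rule, True))
    return out


def _transition_effects(model: ModelSpec, raw: RawSpecies, i: int, cpath: str):
    """Active modifier effects on component ``cpath`` of instance ``i``.

    Returns (effects, blocked): ``blocked`` is set when a bound modifier has
    no rule covering one of the two conformations, which makes the
    transition unreachable in this context.
    """
    inst = raw.instances[i]
    struct = model.structures[inst.structure]
    comp = struct.components()[cpath]
    ref, alt = comp.conformations
    effects: list[ModifierEffect] = []
    for cpl in comp.couplings:
        m = cpl.modifier
        sites = struct.sites()
        if m in sites:
            spec = sites[m][0]
            if spec.kind == "covalent":
                if inst.state_dict()[m] != spec.states[0]:
                    effects.append(ModifierEffect(gamma=cpl.gamma, phi=cpl.phi))
            else:  # binding or catalytic site: occupancy is the input
                if raw.is_bonded(i, m):
                    bond = _find_bond(raw, i, m)
                    K_by_conf = {}
                    for conf in (ref, alt):
                        variant = RawSpecies(
                            tuple(
                                inst2.with_conf(cpath, conf) if k == i else inst2
                                for k, inst2 in enumerate(raw.instances)
                            ),
                            raw.bonds,
                        )
                        rules = _bond_rules(model, variant, bond)
                        if len(rules) > 1:
                            raise ModelError(
                                f"bond {bond} covered by multiple rules in one context"
                            )
                        if rules:
                            K_by_conf[conf] = rules[0][0].K
                    if len(K_by_conf) < 2:
                        return effects, True  # transition blocked by this bond
                    gamma = K_by_conf[alt] / K_by_conf[ref]
                    if gamma != 1.0:
                        effects.append(ModifierEffect(gamma=gamma, phi=cpl.phi))
        else:  # another allosteric component of the same structure
            partner = struct.components()[m]
            if inst.conf_dict()[m] == partner.conformations[1]:
                effects.append(ModifierEffect(gamma=cpl.gamma, phi=cpl.phi))
    return effects, False


def _find_bond(raw: RawSpecies, i: int, site: str):
    for a, b in raw.bonds:
        if a == (i, site) or b == (i, site):
            return (a, b)
    return None


# ---------------------------------------------------------------------------
# Network enumeration
# ---------------------------------------------------------------------------

class _Compiler:
    def __init__(self, model, lump, max_complex_size, max_species):
        self.model = model
        self.canon = Canonicalizer(model, lump=lump)
        self._canon_cache: dict[RawSpecies, tuple[str, RawSpecies]] = {}
        self.max_complex_size = max_complex_size
        self.max_species = max_species
        self.species: dict[str, Species] = {}
        self.reactions: dict[tuple, Reaction] = {}
        self.warnings: list[str] = []
        # static pattern tables: rule side -> set of (structure, site_rel)
        self._side_sites: dict[tuple[int, str], set] = {}
        self._side_structs: dict[tuple[int, str], set] = {}
        for ri, rule in enumerate(model.rules):
            for side_name, pat in (("a", rule.a), ("b", rule.b)):
                hits = set()
                for full in model.match_sites(pat.site):
                    sname, rel = model.split_site(full)
                    hits.add((sname, rel))
                self._side_sites[(ri, side_name)] = hits
                self._side_structs[(ri, side_name)] = {s for s, _ in hits}

    # -- caching canonicalization ---------------------------------------
    def canonical(self, raw: RawSpecies) -> tuple[str, RawSpecies]:
        hit = self._canon_cache.get(raw)
        if hit is None:
            hit = self.canon.canonical(raw)
            self._canon_cache[raw] = hit
        return hit

    def intern(self, raw: RawSpecies, queue) -> str:
        label, canon_raw = self.canonical(raw)
        if label not in self.species:
            if len(self.species) >= self.max_species:
                raise ModelError("species cap exceeded; network may not terminate")
            self.species[label] = Species(label, canon_raw)
            queue.append(label)
        return label

    # -- matching --------------------------------------------------------
    def _matches(self, raw: RawSpecies, ri: int, side: str, free_only=True):
        pat = self.model.rules[ri].a if side == "a" else self.model.rules[ri].b
        table = self._side_sites[(ri, side)]
        out = []
        bonded = raw.bonded_sites()
        for i, inst in enumerate(raw.instances):
            for sname, rel in table:
                if sname != inst.structure:
                    continue
                if free_only and (i, rel) in bonded:
                    continue
                if _context_ok(self.model, raw, i, rel, pat):
                    out.append((i, rel))
        return out

    # -- event generators --------------------------------------------------
    def associations(self, s1: Species, s2: Species, queue):
        comp1, comp2 = set(s1.composition), set(s2.composition)
        for ri, rule in enumerate(self.model.rules):
            sa_structs = self._side_structs[(ri, "a")]
            sb_structs = self._side_structs[(ri, "b")]
            orderings = [(s1, s2)]
            if s1.label != s2.label:
                orderings.append((s2, s1))
            for xa, xb in orderings:
                if not (set(xa.composition) & sa_structs):
                    continue
                if not (set(xb.composition) & sb_structs):
                    continue
                if xa.size + xb.size > self.max_complex_size:
                    continue
                ea = self._matches(xa.raw, ri, "a")
                if not ea:
                    continue
                eb = self._matches(xb.raw, ri, "b")
                if not eb:
                    continue
                groups: dict[str, int] = {}
                for a in ea:
                    for b in eb:
                        if xa is xb and a == b:
                            continue
                        prod = _merge(xa.raw, xb.raw, a, b)
                        lbl = self.intern(prod, queue)
                        groups[lbl] = groups.get(lbl, 0) + 1
                for lbl, mult in groups.items():
                    eff_mult = mult
                    if xa.label == xb.label:
                        eff_mult = mult / 2  # ordered embeddings double-count
                    reactants = tuple(sorted((xa.label, xb.label)))
                    key = (reactants, (lbl,), ri)
                    rxn = self.reactions.get(key)
                    if rxn is None:
                        rxn = Reaction(
                            kind="binding",
                            reactants=reactants,
                            products=(lbl,),
                            provenance=rule.name or f"rule[{ri}]",
                        )
                        self.reactions[key] = rxn
                    rxn.kf = rule.kf * eff_mult
                    rxn.mult_f = eff_mult

    def intramolecular_associations(self, s: Species, queue):
        for ri, rule in enumerate(self.model.rules):
            ea = self._matches(s.raw, ri, "a")
            if not ea:
                continue
            eb = self._matches(s.raw, ri, "b")
            groups: dict[str, int] = {}
            for a in ea:
                for b in eb:
                    if a == b:
                        continue
                    prod = _add_bond(s.raw, a, b)
                    lbl = self.intern(prod, queue)
                    groups[lbl] = groups.get(lbl, 0) + 1
            for lbl, mult in groups.items():
                key = ((s.label,), (lbl,), ri)
                rxn = self.reactions.get(key)
                if rxn is None:
                    rxn = Reaction(
                        kind="binding",
                        reactants=(s.label,),
                        products=(lbl,),
                        provenance=(rule.name or f"rule[{ri}]") + " (intramolecular)",
                        intramolecular=True,
                    )
                    self.reactions[key] = rxn
                    self.warnings.append(
                        f"intramolecular association {s.label} -> {lbl}: detailed "
                        "balance not guaranteed for ring-closure cycles"
                    )
                rxn.kf = rule.kf * mult
                rxn.mult_f = mult

    def dissociations(self, s: Species, queue):
        per_rule: dict[int, dict[tuple, int]] = {}
        for bond in s.raw.bonds:
            matches = _bond_rules(self.model, s.raw, bond)
            if len(matches) > 1:
                raise ModelError(f"bond {bond} covered by multiple rules in one context")
            if not matches:
                continue
            rule, _flipped = matches[0]
            ri = self.model.rules.index(rule)
            if rule.kb == 0:
                continue
            pieces = _split(_remove_bond(s.raw, bond))
            labels = tuple(sorted(self.intern(p, queue) for p in pieces))
            per_rule.setdefault(ri, {}).setdefault(labels, 0)
            per_rule[ri][labels] += 1
        for ri, groups in per_rule.items():
            rule = self.model.rules[ri]
            for labels, mult in groups.items():
                intra = len(labels) == 1
                key = (labels, (s.label,), ri)
                rxn = self.reactions.get(key)
                if rxn is None:
                    rxn = Reaction(
                        kind="binding",
                        reactants=labels,
                        products=(s.label,),
                        provenance=rule.name or f"rule[{ri}]",
                        intramolecular=intra,
                    )
                    self.reactions[key] = rxn
                rxn.kb = rule.kb * mult
                rxn.mult_b = mult

    def conformational(self, s: Species, queue):
        fwd: dict[tuple, list] = {}
        back: dict[tuple, list] = {}
        for i, inst in enumerate(s.raw.instances):
            struct = self.model.structures[inst.structure]
            for cpath, comp in struct.allosteric_components().items():
                ref, alt = comp.conformations
                cur = inst.conf_dict()[cpath]
                ac = self.model.allosteric[f"{inst.structure}.{cpath}"]
                effects, blocked = _transition_effects(self.model, s.raw, i, cpath)
                if blocked:
                    self.warnings.append(
                        f"transition of {inst.structure}.{cpath} blocked in {s.label}: "
                        "a bound modifier has no rule for one conformation"
                    )
                    continue
                t = AllostericTransition.from_K(ac.K0, ac.kf0)
                kf, kb = effective_rates(t, effects)
                other = alt if cur == ref else ref
                flipped = RawSpecies(
                    tuple(
                        inst2.with_conf(cpath, other) if k == i else inst2
                        for k, inst2 in enumerate(s.raw.instances)
                    ),
                    s.raw.bonds,
                )
                lbl = self.intern(flipped, queue)
                bucket = fwd if cur == ref else back
                bucket.setdefault((lbl,), []).append((kf, kb))
        for (lbl,), rates in fwd.items():
            kf = rates[0][0]
            if any(abs(k - kf) > 1e-9 * kf for k, _ in rates):
                raise ModelError("inconsistent lumped conformational rates")
            key = ("conf", s.label, lbl)
            rxn = self.reactions.get(key)
            if rxn is None:
                rxn = Reaction(
                    kind="conformational",
                    reactants=(s.label,),
                    products=(lbl,),
                    provenance="conformational",
                )
                self.reactions[key] = rxn
            rxn.kf = kf * len(rates)
            rxn.mult_f = len(rates)
        for (lbl,), rates in back.items():
            kb = rates[0][1]
            if any(abs(k - kb) > 1e-9 * kb for _, k in rates):
                raise ModelError("inconsistent lumped conformational rates")
            key = ("conf", lbl, s.label)
            rxn = self.reactions.get(key)
            if rxn is None:
                rxn = Reaction(
                    kind="conformational",
                    reactants=(lbl,),
                    products=(s.label,),
                    provenance="conformational",
                )
                self.reactions[key] = rxn
            rxn.kb = kb * len(rates)
            rxn.mult_b = len(rates)

    def catalytic(self, s: Species, queue):
        groups: dict[tuple, list] = {}
        for bond in s.raw.bonds:
            matches = _bond_rules(self.model, s.raw, bond)
            if not matches:
                continue
            rule, flipped = matches[0]
            if rule.kind != "enzymatic":
                continue
            ri = self.model.rules.index(rule)
            (p, sp_), (q, sq_) = bond
            sub = (q, sq_) if not flipped else (p, sp_)
            modified = RawSpecies(
                tuple(
                    inst.with_state(sub[1], rule.product_state) if k == sub[0] else inst
                    for k, inst in enumerate(s.raw.instances)
                ),
                s.raw.bonds - {bond},
            )
            pieces = _split(modified)
            labels = tuple(sorted(self.intern(piece, queue) for piece in pieces))
            groups.setdefault((ri, labels), []).append(bond)
        for (ri, labels), bonds in groups.items():
            rule = self.model.rules[ri]
            key = ("cat", (s.label,), labels, ri)
            self.reactions[key] = Reaction(
                kind="catalytic",
                reactants=(s.label,),
                products=labels,
                kf=rule.kp * len(bonds),
                kb=None,
                provenance=(rule.name or f"rule[{ri}]") + " (kp)",
                mult_f=len(bonds),
            )


def enumerate_network(
    model: ModelSpec,
    lump: bool = True,
    seeds: list[RawSpecies] | None = None,
    max_complex_size: int = 12,
    max_species: int = 20000,
) -> ReactionNetwork:
    """Compile the complete reaction network implied by a model.

    ``lump=False`` disables symmetry lumping and produces the fully
    distinguishable microstate network.  ``seeds`` defaults to the
    reference-state monomer of every declared structure.
    """
    comp = _Compiler(model, lump, max_complex_size, max_species)
    queue: deque[str] = deque()
    if seeds is None:
        seeds = [make_monomer(model, name) for name in sorted(model.structures)]
    for raw in seeds:
        comp.intern(raw, queue)

    processed: list[str] = []
    while queue:
        lbl = queue.popleft()
        s = comp.species[lbl]
        comp.conformational(s, queue)
        comp.dissociations(s, queue)
        comp.catalytic(s, queue)
        comp.intramolecular_associations(s, queue)
        for other_lbl in processed + [lbl]:
            comp.associations(s, comp.species[other_lbl], queue)
        processed.append(lbl)

    reactions = sorted(
        comp.reactions.values(), key=lambda r: (r.kind, r.reactants, r.products)
    )
    # binding reactions need a forward rate; pure-dissociation entries can
    # only arise from rules with kf == 0 (declared one-way), fill kf = 0
    for r in reactions:
        if r.kf is None:
            r.kf = 0.0
    return ReactionNetwork(
        model=model,
        species=comp.species,
        reactions=reactions,
        canonicalizer=comp.canon,
        warnings=comp.warnings,
    )


def reaction_multiplicity(model: ModelSpec, raw: RawSpecies, rule: RuleSpec, partner: RawSpecies | None = None, lump: bool = True):
    """Embedding counts of a rule application, keyed by canonical product.

    For an association give both reactant species (``raw`` matches the rule's
    ``a`` side, ``partner`` its ``b`` side); for a dissociation give the
    complex alone.  Returns {product label(s): multiplicity}.
    """
    canon = Canonicalizer(model, lump=lump)
    out: dict = {}
    if partner is not None:
        pairs = [(raw, rule.a, partner, rule.b)]
        if not match_site_pattern(model, raw, rule.a):
            pairs = [(partner, rule.a, raw, rule.b)]
        for xa, pat_a, xb, pat_b in pairs:
            for a in match_site_pattern(model, xa, pat_a):
                if xa.is_bonded(*a):
                    continue
                for b in match_site_pattern(model, xb, pat_b):
                    if xb.is_bonded(*b):
                        continue
                    lbl = canon.label(_merge(xa, xb, a, b))
                    out[lbl] = out.get(lbl, 0) + 1
    else:
        for bond in raw.bonds:
            matches = _bond_rules(model, raw, bond)
            if not matches or matches[0][0] is not rule:
                continue
            pieces = _split(_remove_bond(raw, bond))
            labels = tuple(sorted(canon.label(p) for p in pieces))
            out[labels] = out.get(labels, 0) + 1
    return out
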