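"""Species representation and symmetry-aware canonical labelling.

A species is a connected complex of structure instances: each instance
carries a conformation label per allosteric component and a covalent state
per covalent site; bonds pair sites across (or within) instances.  Two
species are the same chemical entity iff they are related by a permutation
of identical instances combined with structure automorphisms (permutations
of equivalent sibling sites/components that preserve the coupling graph).
The canonical label is the lexicographic minimum of the serialized form
over that symmetry group, so identical species always collide on the label.
"""

from __future__ import annotations

import fnmatch
import itertools
from dataclasses import dataclass

from .model import ModelSpec, ModelError, StructureSpec, structure_automorphisms

__all__ = ["Instance", "RawSpecies", "Canonicalizer", "make_monomer", "probe_weight"]


@dataclass(frozen=True)
class Instance:
    structure: str
    conf: tuple[tuple[str, str], ...]  # ((component rel path, label), ...) sorted
    states: tuple[tuple[str, str], ...]  # ((covalent site rel path, label), ...) sorted

    def conf_dict(self) -> dict[str, str]:
        return dict(self.conf)

    def state_dict(self) -> dict[str, str]:
        return dict(self.states)

    def with_conf(self, comp: str, label: str) -> "Instance":
        d = self.conf_dict()
        d[comp] = label
        return Instance(self.structure, tuple(sorted(d.items())), self.states)

    def with_state(self, site: str, label: str) -> "Instance":
        d = self.state_dict()
        d[site] = label
        return Instance(self.structure, self.conf, tuple(sorted(d.items())))


def _norm_bond(e1, e2):
    return (e1, e2) if e1 <= e2 else (e2, e1)


@dataclass(frozen=True)
class RawSpecies:
    """A complex before canonicalization; bonds are ((i, site), (j, site))."""

    instances: tuple[Instance, ...]
    bonds: frozenset

    @property
    def size(self) -> int:
        return len(self.instances)

    def bonded_sites(self) -> set[tuple[int, str]]:
        out = set()
        for a, b in self.bonds:
            out.add(a)
            out.add(b)
        return out

    def is_bonded(self, i: int, site: str) -> bool:
        return (i, site) in self.bonded_sites()

    def partner(self, i: int, site: str):
        for a, b in self.bonds:
            if a == (i, site):
                return b
            if b == (i, site):
                return a
        return None


def make_monomer(model: ModelSpec, structure: str) -> RawSpecies:
    """The reference-state monomer: all components in their first-listed
    conformation, all covalent sites in their first-listed state."""
    struct = model.structures[structure]
    conf = tuple(
        sorted((p, c.conformations[0]) for p, c in struct.allosteric_components().items())
    )
    states = tuple(
        sorted(
            (p, spec.states[0])
            for p, (spec, _par) in struct.sites().items()
            if spec.kind == "covalent"
        )
    )
    return RawSpecies((Instance(structure, conf, states),), frozenset())


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------

class Canonicalizer:
    """Produces canonical labels/forms for RawSpecies under a model's symmetry.

    With ``lump=False`` the automorphism group is the identity, yielding the
    fully distinguishable microstate network (the brute-force reference for
    lumping-correctness checks).
    """

    def __init__(self, model: ModelSpec, lump: bool = True):
        self.model = model
        self.lump = lump
        self._auts: dict[str, list[dict[str, str]]] = {}

    def automorphisms(self, structure: str) -> list[dict[str, str]]:
        if structure not in self._auts:
            struct = self.model.structures[structure]
            if self.lump:
                auts = structure_automorphisms(struct)
                self._auts[structure] = [
                    a for a in auts if self._rule_compatible(structure, a)
                ]
            else:
                ident = {p: p for p in struct.components()}
                ident.update({p: p for p in struct.sites()})
                self._auts[structure] = [ident]
        return self._auts[structure]

    def _rule_compatible(self, structure: str, mapping: dict[str, str]) -> bool:
        """A structural symmetry is usable only if it commutes with every
        rule's static pattern matching (site patterns, explicit context keys
        and occupancy keys) — otherwise sites equivalent in shape but with
        distinct rates would be wrongly identified."""
        struct = self.model.structures[structure]
        paths = list(struct.sites()) + list(struct.components())
        patterns: list[str] = []
        for rule in self.model.rules:
            for pat in (rule.a, rule.b):
                patterns.append(pat.site)
                patterns.extend(k for k, _v in pat.conf if k != ".")
                patterns.extend(k for k, _v in pat.occupancy)
        for term_probe in self.model.probes.values():
            for term in term_probe.terms:
                patterns.extend(k for k, _v in term.conf)
                patterns.extend(k for k, _v in term.bound)
                patterns.extend(k for k, _v in term.state)
        for pat in patterns:
            for p in paths:
                full, mapped = f"{structure}.{p}", f"{structure}.{mapping.get(p, p)}"
                if fnmatch.fnmatchcase(full, pat) != fnmatch.fnmatchcase(mapped, pat):
                    return False
        return True

    # -- core ------------------------------------------------------------
    def canonical(self, raw: RawSpecies) -> tuple[str, RawSpecies]:
        best = None
        best_raw = None
        aut_sets = [self.automorphisms(inst.structure) for inst in raw.instances]
        for combo in itertools.product(*aut_sets):
            insts = tuple(
                _apply_aut(inst, mapping) for inst, mapping in zip(raw.instances, combo)
            )
            bonds = frozenset(
                _norm_bond((a[0], combo[a[0]].get(a[1], a[1])), (b[0], combo[b[0]].get(b[1], b[1])))
                for a, b in raw.bonds
            )
            for perm in _instance_orderings(insts, bonds):
                inv = {old: new for new, old in enumerate(perm)}
                ordered = tuple(insts[i] for i in perm)
                rbonds = tuple(
                    sorted(
                        _norm_bond((inv[a[0]], a[1]), (inv[b[0]], b[1])) for a, b in bonds
                    )
                )
                cand = _serialize((ordered, rbonds))
                if best is None or cand < best:
                    best = cand
                    best_raw = RawSpecies(ordered, frozenset(rbonds))
        return best, best_raw

    def label(self, raw: RawSpecies) -> str:
        return self.canonical(raw)[0]


def _apply_aut(inst: Instance, mapping: dict[str, str]) -> Instance:
    conf = tuple(sorted((mapping.get(p, p), l) for p, l in inst.conf))
    states = tuple(sorted((mapping.get(p, p), l) for p, l in inst.states))
    return Instance(inst.structure, conf, states)


def _instance_orderings(insts, bonds):
    """Orderings of instances consistent with sorting by base key; ties are
    broken by trying every permutation within tied groups (small species)."""
    keys = [(inst.structure, inst.conf, inst.states) for inst in insts]
    order = sorted(range(len(insts)), key=lambda i: keys[i])
    groups = []
    for _, grp in itertools.groupby(order, key=lambda i: keys[i]):
        groups.append(list(grp))
    if all(len(g) == 1 for g in groups):
        yield order
        return
    total = 1
    for g in groups:
        for k in range(2, len(g) + 1):
            total *= k
    if total > 5040:  # refuse pathological symmetry explosions
        raise ModelError("species too symmetric to canonicalize by enumeration")
    for combo in itertools.product(*(itertools.permutations(g) for g in groups)):
        perm = [i for grp in combo for i in grp]
        yield perm


def _serialize(cand) -> str:
    insts, bonds = cand
    parts = []
    for inst in insts:
        bits = [f"{p}={l}" for p, l in inst.conf] + [f"{p}:{l}" for p, l in inst.states]
        parts.append(f"{inst.structure}({','.join(bits)})")
    bond_str = ";".join(f"{a[0]}.{a[1]}-{b[0]}.{b[1]}" for a, b in bonds)
    label = "+".join(parts)
    if bond_str:
        label += "|" + bond_str
    return label


# ---------------------------------------------------------------------------
# Pattern matching against species (rules and probes)
# ---------------------------------------------------------------------------

def full_site_path(inst: Instance, site_rel: str) -> str:
    return f"{inst.structure}.{site_rel}"


def match_site_pattern(model: ModelSpec, raw: RawSpecies, pattern) -> list[tuple[int, str]]:
    """All (instance index, site rel path) embeddings of a rule site pattern,
    checking the conformational, covalent-state and occupancy context."""
    out = []
    for i, inst in enumerate(raw.instances):
        struct = model.structures[inst.structure]
        for site_rel, (spec, _parent) in struct.sites().items():
            if not fnmatch.fnmatchcase(f"{inst.structure}.{site_rel}", pattern.site):
                continue
            if not _context_ok(model, raw, i, site_rel, pattern):
                continue
            out.append((i, site_rel))
    return out


def _context_ok(model: ModelSpec, raw: RawSpecies, i: int, site_rel: str, pattern) -> bool:
    inst = raw.instances[i]
    struct = model.structures[inst.structure]
    conf = inst.conf_dict()
    if pattern.state is not None:
        if inst.state_dict().get(site_rel) != pattern.state:
            return False
    for key, wanted in pattern.conf:
        if key == ".":
            comp = struct.enclosing_allosteric(site_rel)
            if comp is None:
                return False
            if conf[comp] != wanted:
                return False
        else:
            # key addresses components of the same instance (full path)
            matched = False
            for cpath in conf:
                if fnmatch.fnmatchcase(f"{inst.structure}.{cpath}", key):
                    matched = True
                    if conf[cpath] != wanted:
                        return False
            if not matched:
                return False
    for site_key, want_bound in pattern.occupancy:
        hit = False
        for other_rel in struct.sites():
            if fnmatch.fnmatchcase(f"{inst.structure}.{other_rel}", site_key):
                hit = True
                if raw.is_bonded(i, other_rel) != want_bound:
                    return False
        if not hit:
            return False
    return True


def probe_weight(model: ModelSpec, raw: RawSpecies, probe) -> float:
    """Per-molecule probe weight of a species (sum over terms and matching
    instances); multiply by the species concentration to read out."""
    total = 0.0
    for term in probe.terms:
        for i, inst in enumerate(raw.instances):
            if term.structure is not None and inst.structure != term.structure:
                continue
            conf = inst.conf_dict()
            ok = True
            for key, wanted in term.conf:
                sname, _, rel = key.partition(".")
                if sname != inst.structure or conf.get(rel) != wanted:
                    ok = False
                    break
            if ok:
                for key, want_bound in term.bound:
                    sname, _, rel = key.partition(".")
                    if sname != inst.structure or raw.is_bonded(i, rel) != want_bound:
                        ok = False
                        break
            if ok:
                states = inst.state_dict()
                for key, wanted in term.state:
                    sname, _, rel = key.partition(".")
                    if sname != inst.structure or states.get(rel) != wanted:
                        ok = False
                        break
            if ok:
                total += term.weight
    return total
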