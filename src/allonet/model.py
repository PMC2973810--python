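"""Model definition layer: structures, rules, parameters, probes.

A model consists of *structures* (hierarchical descriptions of biomolecules
with two-state allosteric components and interaction sites) and *rules*
(binding or Michaelis-Menten enzymatic interaction templates between sites,
optionally conditioned on the conformational context of the enclosing
allosteric components).  Regulatory logic lives in the structures: every
interaction site or coupled component declared as a *modifier* of an
allosteric component shifts that component's conformational equilibrium by a
regulatory factor Gamma, with the kinetic split between forward and backward
transition rates set by a Phi value (linear free-energy relationship).

Paths
-----
Components and sites are addressed by dot-joined paths.  Within a structure,
paths are relative to the structure (``core`` or ``core.ED`` for components,
``core.X`` for sites).  Model-level references (rules, probes, allosteric
constants) prepend the structure name: ``A.core.X``.  Rule site patterns may
use shell-style wildcards (``P.core.s*``) to address families of equivalent
sites; the context key ``"."`` denotes the nearest allosteric component
enclosing the matched site.
"""

from __future__ import annotations

import fnmatch
import itertools
from dataclasses import dataclass, field, replace

__all__ = [
    "SiteSpec",
    "ModifierCoupling",
    "ComponentSpec",
    "StructureSpec",
    "SitePattern",
    "RuleSpec",
    "AllostericConstants",
    "ProbeTerm",
    "Probe",
    "Stimulus",
    "ModelSpec",
    "Diagnostic",
    "ModelError",
    "validate_model",
    "classify_parameters",
    "interaction_centric_count",
    "biomolecule_centric_count",
    "structure_automorphisms",
]

SITE_KINDS = ("binding", "covalent", "catalytic")


class ModelError(Exception):
    """Raised for unrecoverable model definition problems."""


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    message: str
    location: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.level}: {self.message}{loc}"


@dataclass(frozen=True)
class SiteSpec:
    """An interaction site.

    ``kind`` is one of ``binding`` (ligand binding), ``covalent`` (a site
    carrying a covalent state such as a phosphorylation, with ``states``
    listing the labels, first label = unmodified reference) or ``catalytic``
    (an enzymatic site that binds covalent sites of substrates).
    """

    name: str
    kind: str = "binding"
    states: tuple[str, ...] = ()


@dataclass(frozen=True)
class ModifierCoupling:
    """Declares *modifier* as an input to the enclosing allosteric component.

    ``modifier`` is a structure-relative path to a site (binding occupancy or
    covalent state acts as the input) or to another allosteric component
    (whose conformation acts as the input).  ``gamma`` is the regulatory
    factor applied to the component's conformational equilibrium constant
    when the modifier leaves its reference state; for binding sites gamma is
    derived at compile time from the affinity ratio of the bound partner and
    must be omitted here.  ``phi`` splits the equilibrium shift between the
    forward (Gamma**phi) and backward (Gamma**(phi-1)) transition rates.
    """

    modifier: str
    gamma: float | None = None
    phi: float = 0.5


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    allosteric: bool = False
    conformations: tuple[str, str] | None = None
    sites: tuple[SiteSpec, ...] = ()
    children: tuple["ComponentSpec", ...] = ()
    couplings: tuple[ModifierCoupling, ...] = ()


@dataclass(frozen=True)
class StructureSpec:
    """A biomolecule: a tree of components with interaction sites."""

    name: str
    root: ComponentSpec

    # -- introspection ---------------------------------------------------
    def components(self) -> dict[str, ComponentSpec]:
        """Relative path -> ComponentSpec, in pre-order."""
        out: dict[str, ComponentSpec] = {}

        def walk(comp: ComponentSpec, path: str) -> None:
            out[path] = comp
            for child in comp.children:
                walk(child, f"{path}.{child.name}")

        walk(self.root, self.root.name)
        return out

    def sites(self) -> dict[str, tuple[SiteSpec, str]]:
        """Relative site path -> (SiteSpec, parent component path)."""
        out: dict[str, tuple[SiteSpec, str]] = {}
        for cpath, comp in self.components().items():
            for s in comp.sites:
                out[f"{cpath}.{s.name}"] = (s, cpath)
        return out

    def allosteric_components(self) -> dict[str, ComponentSpec]:
        return {p: c for p, c in self.components().items() if c.allosteric}

    def enclosing_allosteric(self, path: str) -> str | None:
        """Nearest allosteric component on the path to ``path`` (inclusive)."""
        comps = self.components()
        parts = path.split(".")
        for n in range(len(parts), 0, -1):
            cand = ".".join(parts[:n])
            comp = comps.get(cand)
            if comp is not None and comp.allosteric:
                return cand
        return None

    def covalent_reference(self, site_path: str) -> str:
        spec, _ = self.sites()[site_path]
        if spec.kind != "covalent":
            raise ModelError(f"{site_path} is not a covalent site")
        return spec.states[0]


@dataclass(frozen=True)
class SitePattern:
    """One side of a rule: a site pattern plus its required context.

    ``conf`` maps component paths (or ``"."``) to required conformations of
    the *same* structure instance as the matched site.  ``state`` constrains
    the covalent state of the matched site itself.  ``occupancy`` supports ad
    hoc interaction-centric rules: it constrains whether other sites of the
    instance are bound.
    """

    site: str
    conf: tuple[tuple[str, str], ...] = ()
    state: str | None = None
    occupancy: tuple[tuple[str, bool], ...] = ()

    def conf_dict(self) -> dict[str, str]:
        return dict(self.conf)


@dataclass(frozen=True)
class RuleSpec:
    """A binding or enzymatic interaction template.

    ``kf`` is the association rate (1/(conc*time)), ``kb`` the dissociation
    rate (1/time).  Enzymatic rules additionally carry ``kp`` (product
    formation rate, 1/time) and ``product_state`` (the covalent label written
    to the substrate site); their ``b`` side must match a covalent site and
    their ``a`` side a catalytic site.  ``factors`` names ad hoc cooperativity
    factors folded into the rate constants of interaction-centric rules (used
    only for parameter accounting).
    """

    a: SitePattern
    b: SitePattern
    kf: float
    kb: float
    kp: float | None = None
    product_state: str | None = None
    name: str = ""
    factors: tuple[str, ...] = ()

    @property
    def kind(self) -> str:
        return "enzymatic" if self.kp is not None else "binding"

    @property
    def K(self) -> float:
        return self.kf / self.kb


@dataclass(frozen=True)
class AllostericConstants:
    """Unligated transition parameters of one allosteric component.

    ``K0`` is the equilibrium constant [alternate]/[reference] of the bare
    component; ``kf0`` the forward (reference->alternate) rate.  The backward
    rate is kf0/K0.
    """

    K0: float
    kf0: float = 1.0

    @property
    def kb0(self) -> float:
        return self.kf0 / self.K0


@dataclass(frozen=True)
class ProbeTerm:
    structure: str | None = None
    conf: tuple[tuple[str, str], ...] = ()  # full component path -> label
    bound: tuple[tuple[str, bool], ...] = ()  # full site path -> bound?
    state: tuple[tuple[str, str], ...] = ()  # full site path -> covalent label
    weight: float = 1.0


@dataclass(frozen=True)
class Probe:
    """A weighted collection of molecules measuring network output.

    Each term counts matching structure instances in every species, weighted,
    times the species concentration.
    """

    name: str
    terms: tuple[ProbeTerm, ...]


@dataclass(frozen=True)
class Stimulus:
    """Input waveform applied to a clamped species: step or ramp."""

    target: str  # structure name
    kind: str = "step"  # "step" | "ramp"
    times: tuple[float, ...] = (0.0,)
    values: tuple[float, ...] = (0.0,)

    def __call__(self, t: float) -> float:
        import numpy as np

        times, values = self.times, self.values
        if self.kind == "step":
            idx = int(np.searchsorted(times, t, side="right")) - 1
            return values[max(idx, 0)]
        return float(np.interp(t, times, values))


@dataclass
class ModelSpec:
    structures: dict[str, StructureSpec] = field(default_factory=dict)
    rules: list[RuleSpec] = field(default_factory=list)
    allosteric: dict[str, AllostericConstants] = field(default_factory=dict)
    parameters: dict[str, tuple[float, str]] = field(default_factory=dict)
    init: dict[str, float] = field(default_factory=dict)
    stimuli: list[Stimulus] = field(default_factory=list)
    probes: dict[str, Probe] = field(default_factory=dict)

    # -- path helpers ----------------------------------------------------
    def split_site(self, full: str) -> tuple[str, str]:
        """Full site path -> (structure name, relative path)."""
        sname, _, rel = full.partition(".")
        return sname, rel

    def site_paths(self) -> dict[str, tuple[str, SiteSpec]]:
        out = {}
        for sname, struct in self.structures.items():
            for rel, (spec, _parent) in struct.sites().items():
                out[f"{sname}.{rel}"] = (sname, spec)
        return out

    def component_paths(self) -> dict[str, tuple[str, ComponentSpec]]:
        out = {}
        for sname, struct in self.structures.items():
            for rel, comp in struct.components().items():
                out[f"{sname}.{rel}"] = (sname, comp)
        return out

    def match_sites(self, pattern: str) -> list[str]:
        return [p for p in self.site_paths() if fnmatch.fnmatchcase(p, pattern)]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _resolve_modifier(struct: StructureSpec, path: str):
    """Return ('site', SiteSpec) or ('component', ComponentSpec) or None."""
    sites = struct.sites()
    if path in sites:
        return "site", sites[path][0]
    comps = struct.components()
    if path in comps:
        return "component", comps[path]
    return None


def validate_model(model: ModelSpec) -> list[Diagnostic]:
    """Check every structural invariant; returns an empty list iff valid."""
    diags: list[Diagnostic] = []
    err = lambda msg, loc="": diags.append(Diagnostic("error", msg, loc))
    warn = lambda msg, loc="": diags.append(Diagnostic("warning", msg, loc))

    for sname, struct in model.structures.items():
        if sname != struct.name:
            err(f"structure key {sname!r} != name {struct.name!r}", sname)
        seen: set[str] = set()
        for path, comp in struct.components().items():
            if path in seen:
                err("duplicate component path", f"{sname}.{path}")
            seen.add(path)
            if comp.allosteric != (comp.conformations is not None):
                err(
                    "conformations must be present iff component is allosteric",
                    f"{sname}.{path}",
                )
            if comp.conformations is not None and len(set(comp.conformations)) != 2:
                err("conformations must be two distinct labels", f"{sname}.{path}")
            names = [s.name for s in comp.sites] + [c.name for c in comp.children]
            if len(names) != len(set(names)):
                err("duplicate child name", f"{sname}.{path}")
            for s in comp.sites:
                if s.kind not in SITE_KINDS:
                    err(f"unknown site kind {s.kind!r}", f"{sname}.{path}.{s.name}")
                if s.kind == "covalent" and len(s.states) < 2:
                    err("covalent sites need >= 2 state labels", f"{sname}.{path}.{s.name}")
                if s.kind != "covalent" and s.states:
                    err("only covalent sites carry a state list", f"{sname}.{path}.{s.name}")
            for cpl in comp.couplings:
                if not comp.allosteric:
                    err("coupling declared on non-allosteric component", f"{sname}.{path}")
                    continue
                res = _resolve_modifier(struct, cpl.modifier)
                if res is None:
                    err(f"unresolved modifier reference {cpl.modifier!r}", f"{sname}.{path}")
                    continue
                kind, spec = res
                if kind == "site" and spec.kind in ("binding", "catalytic"):
                    if cpl.gamma is not None:
                        warn(
                            "gamma on a binding-site coupling is ignored "
                            "(derived from rule affinities)",
                            f"{sname}.{path}",
                        )
                else:
                    if cpl.gamma is None:
                        err(
                            "gamma required for covalent/component couplings",
                            f"{sname}.{path}<-{cpl.modifier}",
                        )
                    elif cpl.gamma <= 0:
                        err("gamma must be positive", f"{sname}.{path}<-{cpl.modifier}")
                if not (0.0 <= cpl.phi <= 1.0):
                    warn(f"phi={cpl.phi} outside [0, 1]", f"{sname}.{path}<-{cpl.modifier}")
                if kind == "component":
                    if not spec.allosteric:
                        err(
                            "component modifier must itself be allosteric",
                            f"{sname}.{path}<-{cpl.modifier}",
                        )
                        continue
                    # reciprocity with a shared regulatory factor is required
                    # for the two-component four-state cycle to close.
                    back = [
                        c
                        for c in spec.couplings
                        if c.modifier == path and c.gamma is not None
                    ]
                    if not back or (cpl.gamma is not None and back[0].gamma != cpl.gamma):
                        err(
                            "component-component coupling must be reciprocal with a "
                            "shared gamma (detailed balance of the 4-state cycle)",
                            f"{sname}.{path}<->{cpl.modifier}",
                        )
        if not struct.sites() and not struct.allosteric_components():
            warn("structure has no sites or allosteric components", sname)
        for cpath, comp in struct.allosteric_components().items():
            if f"{sname}.{cpath}" not in model.allosteric:
                err("missing allosteric constants", f"{sname}.{cpath}")

    for full, ac in model.allosteric.items():
        comps = model.component_paths()
        if full not in comps:
            err(f"allosteric constants for unknown component {full!r}")
        elif not comps[full][1].allosteric:
            err(f"allosteric constants for non-allosteric component {full!r}")
        if ac.K0 <= 0 or ac.kf0 <= 0:
            err("allosteric constants must be positive", full)

    site_paths = model.site_paths()
    for i, rule in enumerate(model.rules):
        loc = rule.name or f"rules[{i}]"
        for pat in (rule.a, rule.b):
            if not model.match_sites(pat.site):
                err(f"rule site pattern {pat.site!r} matches no declared site", loc)
        if rule.kf < 0 or rule.kb < 0:
            err("kf and kb must be non-negative", loc)
        if rule.kind == "enzymatic":
            kinds_a = {site_paths[p][1].kind for p in model.match_sites(rule.a.site)}
            kinds_b = {site_paths[p][1].kind for p in model.match_sites(rule.b.site)}
            if kinds_a != {"catalytic"} or kinds_b != {"covalent"}:
                err("enzymatic rules must pair one catalytic with one covalent site", loc)
            if rule.product_state is None:
                err("enzymatic rules require a product_state", loc)

    # a rule set for one site pair must cover each context at most once
    seen_ctx: set = set()
    for i, rule in enumerate(model.rules):
        key = (
            rule.a.site,
            rule.b.site,
            rule.a.conf,
            rule.b.conf,
            rule.a.state,
            rule.b.state,
            rule.a.occupancy,
            rule.b.occupancy,
        )
        if key in seen_ctx:
            err("duplicate rule for the same site pair and context", rule.name or f"rules[{i}]")
        seen_ctx.add(key)

    for sname, amount in model.init.items():
        if sname not in model.structures:
            err(f"initial amount for unknown structure {sname!r}")
        if amount < 0:
            err("initial amounts must be >= 0", sname)

    diags.extend(_undeclared_modifier_warnings(model))
    return diags


def _undeclared_modifier_warnings(model: ModelSpec) -> list[Diagnostic]:
    """Warn when rules give a site conformation-dependent affinities but the
    site is not declared as a modifier of the distinguished component: the
    compiled network would then violate detailed balance, because no
    regulatory factor is applied to the bound transition."""
    from collections import defaultdict

    out: list[Diagnostic] = []
    groups: dict = defaultdict(list)
    for rule in model.rules:
        key = (
            rule.a.site,
            rule.b.site,
            rule.a.state,
            rule.b.state,
            rule.a.occupancy,
            rule.b.occupancy,
        )
        groups[key].append(rule)
    for rules in groups.values():
        if len({r.K for r in rules}) <= 1:
            continue  # conformation-blind interaction: no coupling required
        for side in ("a", "b"):
            patterns = [getattr(r, side) for r in rules]
            if all(not p.conf for p in patterns):
                continue
            for full in model.match_sites(patterns[0].site):
                sname, rel = model.split_site(full)
                struct = model.structures[sname]
                comps = set()
                for p in patterns:
                    for key_, _conf in p.conf:
                        if key_ == ".":
                            c = struct.enclosing_allosteric(rel)
                            if c:
                                comps.add(c)
                        else:
                            for cpath in struct.allosteric_components():
                                if fnmatch.fnmatchcase(f"{sname}.{cpath}", key_):
                                    comps.add(cpath)
                for cpath in comps:
                    declared = {
                        cpl.modifier
                        for cpl in struct.components()[cpath].couplings
                    }
                    if rel not in declared:
                        out.append(
                            Diagnostic(
                                "warning",
                                f"rules give {full} conformation-dependent "
                                f"affinities but it is not a declared modifier of "
                                f"{sname}.{cpath}; compiled cycles will not balance",
                                full,
                            )
                        )
    return out


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def _coupling_inventory(model: ModelSpec):
    """Yield (structure, component path, coupling, modifier kind)."""
    for sname, struct in model.structures.items():
        for cpath, comp in struct.components().items():
            for cpl in comp.couplings:
                res = _resolve_modifier(struct, cpl.modifier)
                kind = res[0] if res else "unresolved"
                if kind == "site":
                    kind = res[1].kind + "_site"
                yield sname, cpath, cpl, kind


def classify_parameters(model: ModelSpec, level: str = "equilibrium") -> dict[str, int]:
    """Count independent model parameters.

    *Intensive* parameters are attributes of structures: one allosteric
    constant per allosteric component, one regulatory factor per reciprocal
    component-component coupling and one per covalent-site coupling.
    *Extensive* parameters are attributes of rules: one affinity (or ad hoc
    cooperativity factor) per binding-rule context, plus kf/kb(/kp) detail at
    the kinetic level.

    ``level="equilibrium"`` counts equilibrium-determining parameters only.
    ``level="kinetic"`` additionally counts one Phi per modifier interaction
    (per distinct ligand partner for binding-site couplings) — the number of
    independent rate constants of the model.
    """
    if level not in ("equilibrium", "kinetic"):
        raise ValueError(f"unknown level {level!r}")

    intensive = len(model.allosteric)
    comp_pairs: set = set()
    cov_couplings = 0
    for sname, cpath, cpl, kind in _coupling_inventory(model):
        if kind == "component":
            comp_pairs.add((sname, frozenset((cpath, cpl.modifier))))
        elif kind == "covalent_site":
            cov_couplings += 1
    intensive += len(comp_pairs) + cov_couplings

    extensive = 0
    factor_names: set[str] = set()
    for rule in model.rules:
        if rule.factors:
            # interaction-centric rule: its rate is a base affinity (counted
            # by the base-context rule) times ad hoc cooperativity factors;
            # only the distinct factors are new parameters.
            factor_names.update(rule.factors)
        elif rule.kind == "binding":
            extensive += 1  # one affinity per rule context
        else:
            extensive += 3 if level == "kinetic" else 2  # kf, kb, kp / K, kp
    extensive += len(factor_names)

    if level == "kinetic":
        # one Phi per (coupling, interaction partner)
        for sname, cpath, cpl, kind in _coupling_inventory(model):
            if kind == "binding_site" or kind == "catalytic_site":
                extensive += _n_partners(model, sname, cpl.modifier)
            elif kind == "covalent_site":
                intensive += 1
            elif kind == "component":
                intensive += 1  # Phi is directional (one per coupling entry)

    return {"intensive": intensive, "extensive": extensive, "total": intensive + extensive}


def _n_partners(model: ModelSpec, sname: str, site_rel: str) -> int:
    """Distinct partner structures whose rules bind the given site."""
    full = f"{sname}.{site_rel}"
    partners: set[str] = set()
    for rule in model.rules:
        for own, other in ((rule.a, rule.b), (rule.b, rule.a)):
            if fnmatch.fnmatchcase(full, own.site):
                for p in model.match_sites(other.site):
                    partners.add(model.split_site(p)[0])
    return len(partners)


def interaction_centric_count(n_sites: int, n_ligands: int) -> int:
    """Parameters of the context-explicit scheme for the generic N-site,
    L-ligand two-state protein: one constant per binding reaction in every
    occupancy context of the other sites, N*L*(L+1)**(N-1)."""
    return n_sites * n_ligands * (n_ligands + 1) ** (n_sites - 1)


def biomolecule_centric_count(n_sites: int, n_ligands: int) -> int:
    """Independent rate constants of the structure-encoded scheme for the
    same model: per site-ligand interaction {affinity to each conformation,
    Phi} plus one global allosteric constant, 3*N*L + 1."""
    return 3 * n_sites * n_ligands + 1


# ---------------------------------------------------------------------------
# Structure automorphisms (symmetry of equivalent sites / components)
# ---------------------------------------------------------------------------

def _site_signature(site: SiteSpec):
    return ("site", site.kind, site.states)


def _component_signature(comp: ComponentSpec):
    return (
        "component",
        comp.allosteric,
        comp.conformations,
        tuple(sorted(_site_signature(s) for s in comp.sites)),
        tuple(sorted(_component_signature(c) for c in comp.children)),
    )


def _subtree_mappings(comp: ComponentSpec, path: str, cap: list[int]):
    """All candidate relabelings of ``comp``'s subtree (path -> path)."""
    # permutations of identical sites within this component
    site_groups: dict = {}
    for s in comp.sites:
        site_groups.setdefault(_site_signature(s), []).append(s.name)
    site_perm_sets = []
    for names in site_groups.values():
        site_perm_sets.append([dict(zip(names, p)) for p in itertools.permutations(names)])

    # permutations of identical children, combined with their internal maps
    child_groups: dict = {}
    for c in comp.children:
        child_groups.setdefault(_component_signature(c), []).append(c)
    child_by_name = {c.name: c for c in comp.children}
    child_perm_sets = []
    for group in child_groups.values():
        names = [c.name for c in group]
        child_perm_sets.append([dict(zip(names, p)) for p in itertools.permutations(names)])

    child_internal = {
        c.name: _subtree_mappings(c, f"{path}.{c.name}", cap) for c in comp.children
    }

    results = []
    for site_maps in itertools.product(*site_perm_sets):
        smap = {}
        for m in site_maps:
            smap.update(m)
        for child_maps in itertools.product(*child_perm_sets):
            cmap = {}
            for m in child_maps:
                cmap.update(m)
            for internals in itertools.product(
                *(child_internal[c.name] for c in comp.children)
            ):
                mapping = {path: path}
                for name, target in smap.items():
                    mapping[f"{path}.{name}"] = f"{path}.{target}"
                ok = True
                for c, internal in zip(comp.children, internals):
                    target_name = cmap.get(c.name, c.name)
                    src_prefix = f"{path}.{c.name}"
                    dst_prefix = f"{path}.{target_name}"
                    for k, v in internal.items():
                        mapping[k] = dst_prefix + v[len(src_prefix):]
                if ok:
                    results.append(mapping)
                cap[0] -= 1
                if cap[0] < 0:
                    raise ModelError("structure automorphism group too large")
    return results


def structure_automorphisms(struct: StructureSpec) -> list[dict[str, str]]:
    """All symmetry mappings of a structure's component/site paths.

    Candidate relabelings permute identical sibling sites and identical
    sibling component subtrees; candidates are then filtered to those that
    preserve the declared modifier-coupling graph (so e.g. a ring of coupled
    subunits keeps only its dihedral symmetries).
    """
    cands = _subtree_mappings(struct.root, struct.root.name, cap=[100000])
    couplings = set()
    for cpath, comp in struct.components().items():
        for cpl in comp.couplings:
            couplings.add((cpath, cpl.modifier, cpl.gamma, cpl.phi))
    out = []
    for mapping in cands:
        mapped = {
            (mapping.get(t, t), mapping.get(m, m), g, p) for (t, m, g, p) in couplings
        }
        if mapped == couplings:
            out.append(mapping)
    return out
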