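"""Plain-text model documents (YAML dialect).

A model file has the top-level keys ``schema``, ``structures``, ``rules``,
``allosteric``, ``parameters``, ``init``, ``stimuli`` and ``probes``.
Unknown keys are errors — model files are meant to be bit-exact,
reproducible fixtures.  Binding strengths may be given either as explicit
(kf, kb) rates or as an association constant ``K`` (with kb defaulting to
1); omitted Phi values default to 0.5 (symmetric linear free-energy
relationship); the first-listed conformation / covalent state is the
reference.

``parse_model`` and ``serialize_model`` round-trip: parse(serialize(m))
reproduces the model exactly.
"""

from __future__ import annotations

import yaml

from .model import (
    AllostericConstants,
    ComponentSpec,
    ModelSpec,
    ModelError,
    ModifierCoupling,
    Probe,
    ProbeTerm,
    RuleSpec,
    SitePattern,
    SiteSpec,
    Stimulus,
    StructureSpec,
)

__all__ = ["parse_model", "serialize_model", "load_model", "save_model", "SCHEMA"]

SCHEMA = "allonet-model/1"


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ModelError(f"unknown key(s) {sorted(unknown)} in {where}")


def _pairs(d: dict | None, where: str, value_type=None) -> tuple:
    if d is None:
        return ()
    if not isinstance(d, dict):
        raise ModelError(f"{where} must be a mapping")
    return tuple(sorted(d.items()))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_site(d: dict, where: str) -> SiteSpec:
    _check_keys(d, {"name", "kind", "states"}, where)
    return SiteSpec(
        name=str(d["name"]),
        kind=d.get("kind", "binding"),
        states=tuple(str(s) for s in d.get("states", ())),
    )


def _parse_component(d: dict, where: str) -> ComponentSpec:
    _check_keys(
        d, {"name", "allosteric", "conformations", "sites", "children", "couplings"}, where
    )
    name = str(d["name"])
    conf = d.get("conformations")
    couplings = []
    for c in d.get("couplings", []):
        _check_keys(c, {"modifier", "gamma", "phi"}, f"{where}.{name}.couplings")
        couplings.append(
            ModifierCoupling(
                modifier=str(c["modifier"]),
                gamma=None if c.get("gamma") is None else float(c["gamma"]),
                phi=float(c.get("phi", 0.5)),
            )
        )
    return ComponentSpec(
        name=name,
        allosteric=bool(d.get("allosteric", False)),
        conformations=None if conf is None else (str(conf[0]), str(conf[1])),
        sites=tuple(_parse_site(s, f"{where}.{name}.sites") for s in d.get("sites", [])),
        children=tuple(
            _parse_component(c, f"{where}.{name}") for c in d.get("children", [])
        ),
        couplings=tuple(couplings),
    )


def _parse_pattern(d: dict, where: str) -> SitePattern:
    _check_keys(d, {"site", "conf", "state", "occupancy"}, where)
    return SitePattern(
        site=str(d["site"]),
        conf=_pairs(d.get("conf"), f"{where}.conf"),
        state=None if d.get("state") is None else str(d["state"]),
        occupancy=_pairs(d.get("occupancy"), f"{where}.occupancy"),
    )


def _parse_rule(d: dict, i: int) -> RuleSpec:
    where = d.get("name") or f"rules[{i}]"
    _check_keys(
        d, {"name", "a", "b", "K", "kf", "kb", "kp", "product_state", "factors"}, where
    )
    if "K" in d:
        if "kf" in d:
            raise ModelError(f"{where}: give either K or kf, not both")
        kb = float(d.get("kb", 1.0))
        kf = float(d["K"]) * kb
    else:
        kf = float(d["kf"])
        kb = float(d.get("kb", 1.0))
    return RuleSpec(
        a=_parse_pattern(d["a"], f"{where}.a"),
        b=_parse_pattern(d["b"], f"{where}.b"),
        kf=kf,
        kb=kb,
        kp=None if d.get("kp") is None else float(d["kp"]),
        product_state=None if d.get("product_state") is None else str(d["product_state"]),
        name=str(d.get("name", "")),
        factors=tuple(d.get("factors", ())),
    )


def _parse_probe(name: str, terms: list, where: str) -> Probe:
    out = []
    for t in terms:
        _check_keys(t, {"structure", "conf", "bound", "state", "weight"}, where)
        out.append(
            ProbeTerm(
                structure=t.get("structure"),
                conf=_pairs(t.get("conf"), f"{where}.conf"),
                bound=_pairs(t.get("bound"), f"{where}.bound"),
                state=_pairs(t.get("state"), f"{where}.state"),
                weight=float(t.get("weight", 1.0)),
            )
        )
    return Probe(name=name, terms=tuple(out))


def parse_model(text: str) -> ModelSpec:
    """Parse a model document; raises :class:`ModelError` on schema errors
    and propagates YAML syntax errors (with line/column positions)."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ModelError(f"model document is not valid YAML: {e}") from e
    if not isinstance(doc, dict):
        raise ModelError("model document must be a mapping")
    _check_keys(
        doc,
        {"schema", "structures", "rules", "allosteric", "parameters", "init", "stimuli", "probes"},
        "document",
    )
    if doc.get("schema", SCHEMA) != SCHEMA:
        raise ModelError(f"unsupported schema {doc.get('schema')!r}")

    structures = {}
    for s in doc.get("structures", []):
        _check_keys(s, {"name", "root"}, "structures")
        name = str(s["name"])
        structures[name] = StructureSpec(
            name=name, root=_parse_component(s["root"], name)
        )

    allosteric = {}
    for path, v in (doc.get("allosteric") or {}).items():
        _check_keys(v, {"K0", "kf0"}, f"allosteric.{path}")
        allosteric[str(path)] = AllostericConstants(
            K0=float(v["K0"]), kf0=float(v.get("kf0", 1.0))
        )

    rules = [_parse_rule(r, i) for i, r in enumerate(doc.get("rules", []))]

    parameters = {}
    for pname, v in (doc.get("parameters") or {}).items():
        _check_keys(v, {"value", "class"}, f"parameters.{pname}")
        klass = v.get("class", "extensive")
        if klass not in ("intensive", "extensive"):
            raise ModelError(f"parameters.{pname}: class must be intensive or extensive")
        parameters[str(pname)] = (float(v["value"]), klass)

    stimuli = []
    for st in doc.get("stimuli", []):
        _check_keys(st, {"target", "kind", "times", "values"}, "stimuli")
        stimuli.append(
            Stimulus(
                target=str(st["target"]),
                kind=st.get("kind", "step"),
                times=tuple(float(t) for t in st.get("times", (0.0,))),
                values=tuple(float(v) for v in st.get("values", (0.0,))),
            )
        )

    probes = {
        str(n): _parse_probe(str(n), terms, f"probes.{n}")
        for n, terms in (doc.get("probes") or {}).items()
    }

    model = ModelSpec(
        structures=structures,
        rules=rules,
        allosteric=allosteric,
        parameters=parameters,
        init={str(k): float(v) for k, v in (doc.get("init") or {}).items()},
        stimuli=stimuli,
        probes=probes,
    )

    _resolve_check(model)
    return model


def _resolve_check(model: ModelSpec) -> None:
    """Fail fast on unresolved cross-references (full validation is separate)."""
    from .model import validate_model

    errors = [d for d in validate_model(model) if d.level == "error"]
    unresolved = [d for d in errors if "unresolved" in d.message or "matches no" in d.message]
    if unresolved:
        raise ModelError("; ".join(str(d) for d in unresolved))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _site_doc(s: SiteSpec) -> dict:
    d = {"name": s.name, "kind": s.kind}
    if s.states:
        d["states"] = list(s.states)
    return d


def _component_doc(c: ComponentSpec) -> dict:
    d: dict = {"name": c.name}
    if c.allosteric:
        d["allosteric"] = True
        d["conformations"] = list(c.conformations)
    if c.sites:
        d["sites"] = [_site_doc(s) for s in c.sites]
    if c.couplings:
        d["couplings"] = [
            {
                "modifier": cp.modifier,
                **({"gamma": cp.gamma} if cp.gamma is not None else {}),
                "phi": cp.phi,
            }
            for cp in c.couplings
        ]
    if c.children:
        d["children"] = [_component_doc(ch) for ch in c.children]
    return d


def _pattern_doc(p: SitePattern) -> dict:
    d: dict = {"site": p.site}
    if p.conf:
        d["conf"] = dict(p.conf)
    if p.state is not None:
        d["state"] = p.state
    if p.occupancy:
        d["occupancy"] = dict(p.occupancy)
    return d


def serialize_model(model: ModelSpec) -> str:
    doc: dict = {"schema": SCHEMA}
    doc["structures"] = [
        {"name": s.name, "root": _component_doc(s.root)}
        for s in model.structures.values()
    ]
    if model.allosteric:
        doc["allosteric"] = {
            path: {"K0": ac.K0, "kf0": ac.kf0} for path, ac in model.allosteric.items()
        }
    if model.rules:
        doc["rules"] = []
        for r in model.rules:
            d = {
                **({"name": r.name} if r.name else {}),
                "a": _pattern_doc(r.a),
                "b": _pattern_doc(r.b),
                "kf": r.kf,
                "kb": r.kb,
            }
            if r.kp is not None:
                d["kp"] = r.kp
                d["product_state"] = r.product_state
            if r.factors:
                d["factors"] = list(r.factors)
            doc["rules"].append(d)
    if model.parameters:
        doc["parameters"] = {
            n: {"value": v, "class": k} for n, (v, k) in model.parameters.items()
        }
    if model.init:
        doc["init"] = dict(model.init)
    if model.stimuli:
        doc["stimuli"] = [
            {"target": s.target, "kind": s.kind, "times": list(s.times), "values": list(s.values)}
            for s in model.stimuli
        ]
    if model.probes:
        doc["probes"] = {}
        for name, probe in model.probes.items():
            terms = []
            for t in probe.terms:
                td: dict = {}
                if t.structure is not None:
                    td["structure"] = t.structure
                if t.conf:
                    td["conf"] = dict(t.conf)
                if t.bound:
                    td["bound"] = dict(t.bound)
                if t.state:
                    td["state"] = dict(t.state)
                td["weight"] = t.weight
                terms.append(td)
            doc["probes"][name] = terms
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def load_model(path) -> ModelSpec:
    with open(path) as fh:
        return parse_model(fh.read())


def save_model(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_model(model))
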