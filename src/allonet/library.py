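"""Programmatic builders for the worked model family.

Every builder returns a fully parameterized :class:`~allonet.model.ModelSpec`
carrying its published default parameter values; keyword arguments override
them.  The family covers the divalent allosteric adaptor and its trimer
assembly variant, concerted (MWC) and sequential (KNF, tetrahedral or square
coupling geometry) homotetramers, the nested tertiary two-state model,
competing-ligand variants of the tetramers, cubic and quartic ternary
complex GPCR models, a kinase/substrate enzymatic example, the generic
N-site/L-ligand two-state protein used for parameter accounting, and a
seeded random-model generator for property tests.

All concentrations and times are in arbitrary units; binding affinities are
association constants K = kf/kb with kb defaulting to 1.
"""

from __future__ import annotations

import numpy as np

from .model import (
    AllostericConstants,
    ComponentSpec,
    ModelSpec,
    ModifierCoupling,
    Probe,
    ProbeTerm,
    RuleSpec,
    SitePattern,
    SiteSpec,
    StructureSpec,
)

__all__ = [
    "MODEL_NAMES",
    "build",
    "random_model",
    "ligand_structure",
    "CubicTernaryComplex",
    "quartic_to_cubic",
    "QUARTIC_LIGANDS",
    "QUARTIC_GPROTEINS",
    "COMPETING_GAMMAS",
]

DEFAULT_KB = 1.0

# Quartic ternary complex tables: (K', a_t, a_a, a_at) — affinity to the
# reference (s,i) receptor state and affinity ratios for the (t,i), (s,a)
# and (t,a) states.
QUARTIC_LIGANDS = {
    "L1": (10.0, 0.1, 10.0, 1.0),
    "L2": (1.0, 20.0, 20.0, 400.0),
    "L3": (0.1, 10.0, 10.0, 0.01),
    "L4": (100.0, 0.1, 0.4, 0.01),
    "L5": (20.0, 20.0, 0.05, 5.0),
}
QUARTIC_GPROTEINS = {
    "G1": (10.0, 0.1, 10.0, 1.0),
    "G2": (1.0, 10.0, 10.0, 100.0),
}

# Competing-ligand regulatory factors: L0/L1 prefer the reference (high
# ligand affinity) conformation, L2 is conformation-blind, L3 prefers the
# alternate one.
COMPETING_GAMMAS = {"L0": 0.01, "L1": 0.01, "L2": 1.0, "L3": 100.0}


def ligand_structure(name: str) -> StructureSpec:
    """A monovalent ligand: one binding site ``<name>.c.b``."""
    return StructureSpec(
        name=name,
        root=ComponentSpec(name="c", sites=(SiteSpec("b", "binding"),)),
    )


def _bind(a_site, b_site, K, kb=DEFAULT_KB, conf_b=(), name="", occupancy_b=(), factors=()):
    """Binding rule helper: ``a`` is the ligand side, ``b`` the target site
    with its conformational/occupancy context."""
    return RuleSpec(
        a=SitePattern(site=a_site),
        b=SitePattern(site=b_site, conf=tuple(conf_b), occupancy=tuple(occupancy_b)),
        kf=K * kb,
        kb=kb,
        name=name,
        factors=tuple(factors),
    )


# ---------------------------------------------------------------------------
# Divalent adaptor and trimer assembly
# ---------------------------------------------------------------------------

def divalent_adaptor(
    K_RT: float = 1e-3,
    K_RX: float = 0.1,
    K_TX: float = 10.0,
    K_RY: float = 0.01,
    K_TY: float = 100.0,
    A_tot: float = 1.0,
    Y_tot: float = 1.0,
    X_tot: float = 0.0,
    phi: float = 0.5,
) -> ModelSpec:
    """Two-state adaptor A with one site for X and one for Y.

    Both ligands bind the alternate (T) conformation more tightly, so X
    occupancy recruits Y cooperatively; compilation yields the 8-state
    adaptor cube plus the two free ligands.
    """
    adaptor = StructureSpec(
        name="A",
        root=ComponentSpec(
            name="c",
            allosteric=True,
            conformations=("R", "T"),
            sites=(SiteSpec("X", "binding"), SiteSpec("Y", "binding")),
            couplings=(
                ModifierCoupling(modifier="c.X", phi=phi),
                ModifierCoupling(modifier="c.Y", phi=phi),
            ),
        ),
    )
    model = ModelSpec(
        structures={"A": adaptor, "X": ligand_structure("X"), "Y": ligand_structure("Y")},
        allosteric={"A.c": AllostericConstants(K0=K_RT)},
        rules=[
            _bind("X.c.b", "A.c.X", K_RX, conf_b=((".", "R"),), name="X-A(R)"),
            _bind("X.c.b", "A.c.X", K_TX, conf_b=((".", "T"),), name="X-A(T)"),
            _bind("Y.c.b", "A.c.Y", K_RY, conf_b=((".", "R"),), name="Y-A(R)"),
            _bind("Y.c.b", "A.c.Y", K_TY, conf_b=((".", "T"),), name="Y-A(T)"),
        ],
        init={"A": A_tot, "X": X_tot, "Y": Y_tot},
        probes={
            "bound_Y": Probe("bound_Y", (ProbeTerm(structure="Y", bound=(("Y.c.b", True),)),)),
            "bound_X": Probe("bound_X", (ProbeTerm(structure="X", bound=(("X.c.b", True),)),)),
            "trimer": Probe(
                "trimer",
                (
                    ProbeTerm(
                        structure="A",
                        bound=(("A.c.X", True), ("A.c.Y", True)),
                    ),
                ),
            ),
            "total_A": Probe("total_A", (ProbeTerm(structure="A"),)),
        },
    )
    return model


def trimer_assembly(theta: float = 1.0, K_app: float = 1.0, **kw) -> ModelSpec:
    """Divalent adaptor parameterized to a target cooperativity theta with
    equal apparent affinities K_X = K_Y = ``K_app``.

    Uses the theta-optimal allosteric constant K_RT = 1/Gamma with equal
    regulatory factors, inverting theta = (2 + G + 1/G)/4, then scales the
    conformation-specific affinities so the coarse-grained affinity is
    ``K_app``.
    """
    import math

    if theta < 1.0:
        raise ValueError("this parameterization covers theta >= 1")
    g = (2.0 * theta - 1.0) + math.sqrt((2.0 * theta - 1.0) ** 2 - 1.0)
    K_RT = 1.0 / g
    K_R = K_app * (1.0 + K_RT) / (1.0 + K_RT * g)
    K_T = g * K_R
    return divalent_adaptor(
        K_RT=K_RT, K_RX=K_R, K_TX=K_T, K_RY=K_R, K_TY=K_T, X_tot=1.0, Y_tot=1.0, **kw
    )


# ---------------------------------------------------------------------------
# Tetramers: concerted, sequential, tertiary two-state
# ---------------------------------------------------------------------------

def _tetramer_ligand_rules(ligands: dict[str, float], site_pattern: str, ref: str, alt: str):
    """Competing-ligand rules: K_ref = Gamma^(-1/2), K_alt = Gamma^(1/2)."""
    rules = []
    for name, gamma in ligands.items():
        rules.append(
            _bind(f"{name}.c.b", site_pattern, gamma ** -0.5, conf_b=((".", ref),), name=f"{name}({ref})")
        )
        rules.append(
            _bind(f"{name}.c.b", site_pattern, gamma ** 0.5, conf_b=((".", alt),), name=f"{name}({alt})")
        )
    return rules


def _ligand_probes(ligands):
    return {
        f"bound_{name}": Probe(
            f"bound_{name}",
            (ProbeTerm(structure=name, bound=((f"{name}.c.b", True),)),),
        )
        for name in ligands
    }


def concerted_tetramer(
    K_RT: float = 1e3,
    ligands: tuple[str, ...] = ("L0",),
    gammas: dict[str, float] | None = None,
    phi: float = 0.5,
    P_tot: float = 1.0,
) -> ModelSpec:
    """MWC homotetramer: one allosteric component, four identical sites.

    The unligated protein favours the alternate (T) state (K_RT >> 1) while
    ligands with Gamma < 1 prefer the reference (R) state, producing
    cooperative binding.
    """
    gammas = dict(gammas or {k: COMPETING_GAMMAS[k] for k in ligands})
    prot = StructureSpec(
        name="P",
        root=ComponentSpec(
            name="c",
            allosteric=True,
            conformations=("R", "T"),
            sites=tuple(SiteSpec(f"s{i}", "binding") for i in range(1, 5)),
            couplings=tuple(ModifierCoupling(modifier=f"c.s{i}", phi=phi) for i in range(1, 5)),
        ),
    )
    structures = {"P": prot}
    structures.update({name: ligand_structure(name) for name in ligands})
    return ModelSpec(
        structures=structures,
        allosteric={"P.c": AllostericConstants(K0=K_RT)},
        rules=_tetramer_ligand_rules(gammas, "P.c.s?", "R", "T"),
        init={"P": P_tot, **{name: 0.0 for name in ligands}},
        probes=_ligand_probes(ligands),
    )


def sequential_tetramer(
    geometry: str = "tetrahedral",
    K_rt: float = 0.1,
    Gamma_S: float = 10.0,
    ligands: tuple[str, ...] = ("L0",),
    gammas: dict[str, float] | None = None,
    phi_lb: float = 0.5,
    phi_s: float = 0.5,
    P_tot: float = 1.0,
) -> ModelSpec:
    """KNF homotetramer: four individually switching subunits coupled with
    regulatory factor Gamma_S along tetrahedral (all pairs) or square (ring)
    geometry; like conformations of coupled subunits stabilize each other.
    """
    gammas = dict(gammas or {k: COMPETING_GAMMAS[k] for k in ligands})
    if geometry == "tetrahedral":
        edges = [(i, j) for i in range(1, 5) for j in range(1, 5) if i != j]
    elif geometry == "square":
        ring = [(1, 2), (2, 3), (3, 4), (4, 1)]
        edges = ring + [(j, i) for i, j in ring]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    neighbours = {i: sorted(j for a, j in edges if a == i) for i in range(1, 5)}

    def subunit(i: int) -> ComponentSpec:
        couplings = [ModifierCoupling(modifier=f"c.su{i}.b", phi=phi_lb)]
        couplings += [
            ModifierCoupling(modifier=f"c.su{j}", gamma=Gamma_S, phi=phi_s)
            for j in neighbours[i]
        ]
        return ComponentSpec(
            name=f"su{i}",
            allosteric=True,
            conformations=("r", "t"),
            sites=(SiteSpec("b", "binding"),),
            couplings=tuple(couplings),
        )

    prot = StructureSpec(
        name="P",
        root=ComponentSpec(name="c", children=tuple(subunit(i) for i in range(1, 5))),
    )
    structures = {"P": prot}
    structures.update({name: ligand_structure(name) for name in ligands})
    return ModelSpec(
        structures=structures,
        allosteric={f"P.c.su{i}": AllostericConstants(K0=K_rt) for i in range(1, 5)},
        rules=_tetramer_ligand_rules(gammas, "P.c.su?.b", "r", "t"),
        init={"P": P_tot, **{name: 0.0 for name in ligands}},
        probes=_ligand_probes(ligands),
    )


def tertiary_two_state(
    K_RT: float = 1e-2,
    K_rt: float = 0.1,
    Gamma: float = 10.0,
    ligands: tuple[str, ...] = ("L0",),
    gammas: dict[str, float] | None = None,
    phi_q: float = 0.5,
    phi_t: float = 0.5,
    P_tot: float = 1.0,
) -> ModelSpec:
    """Nested allostery: a quaternary two-state component contains four
    tertiary two-state subunits, each reciprocally coupled to the quaternary
    transition with strength Gamma and carrying one ligand site."""
    gammas = dict(gammas or {k: 0.01 for k in ligands})

    def subunit(i: int) -> ComponentSpec:
        return ComponentSpec(
            name=f"su{i}",
            allosteric=True,
            conformations=("r", "t"),
            sites=(SiteSpec("b", "binding"),),
            couplings=(
                ModifierCoupling(modifier=f"c.su{i}.b", phi=0.5),
                ModifierCoupling(modifier="c", gamma=Gamma, phi=phi_q),
            ),
        )

    prot = StructureSpec(
        name="P",
        root=ComponentSpec(
            name="c",
            allosteric=True,
            conformations=("R", "T"),
            children=tuple(subunit(i) for i in range(1, 5)),
            couplings=tuple(
                ModifierCoupling(modifier=f"c.su{i}", gamma=Gamma, phi=phi_t)
                for i in range(1, 5)
            ),
        ),
    )
    structures = {"P": prot}
    structures.update({name: ligand_structure(name) for name in ligands})
    allosteric = {"P.c": AllostericConstants(K0=K_RT)}
    allosteric.update({f"P.c.su{i}": AllostericConstants(K0=K_rt) for i in range(1, 5)})
    return ModelSpec(
        structures=structures,
        allosteric=allosteric,
        rules=_tetramer_ligand_rules(gammas, "P.c.su?.b", "r", "t"),
        init={"P": P_tot, **{name: 0.0 for name in ligands}},
        probes=_ligand_probes(ligands),
    )


def competing_ligands(
    variant: str = "concerted",
    ligands: tuple[str, ...] = ("L0", "L1", "L2", "L3"),
    **kw,
) -> ModelSpec:
    """Tetramer plus the standard competing-ligand panel (L0 and up to three
    competitors with Gamma = 0.01, 1, 100)."""
    if variant == "concerted":
        return concerted_tetramer(ligands=ligands, **kw)
    if variant == "sequential_tetrahedral":
        return sequential_tetramer(geometry="tetrahedral", ligands=ligands, **kw)
    if variant == "sequential_square":
        return sequential_tetramer(geometry="square", ligands=ligands, **kw)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Ternary complex GPCR models
# ---------------------------------------------------------------------------

def _as_table(entries, table, prefix):
    if isinstance(entries, int):
        names = [f"{prefix}{i}" for i in range(1, entries + 1)]
        vals = list(table.values())
        return {n: vals[i % len(vals)] for i, n in enumerate(names)}
    return {n: table[n] for n in entries}


def gpcr_quartic(
    ligands=("L1",),
    gproteins=("G1",),
    K_actL: float = 1.0,
    K_actG: float = 0.05,
    Gamma: float = 1.0,
    R_tot: float = 1.0,
    G_tot: float = 1.0,
    phi: float = 0.5,
) -> ModelSpec:
    """Quartic ternary complex receptor: two reciprocally coupled two-state
    components — the extracellular domain ED (s<->t, constant K_actL) and the
    intracellular domain ID (i<->a, constant K_actG) — with the ligand and
    G-protein sites allosterically coupled to *both*, so each binder sees
    four receptor conformations and needs four affinities, no pair-specific
    cooperativity parameters.

    ``ligands``/``gproteins`` may be name tuples (drawn from the default
    tables) or integers (synthetic entries, for parameter accounting).
    """
    lig_table = _as_table(ligands, QUARTIC_LIGANDS, "L")
    g_table = _as_table(gproteins, QUARTIC_GPROTEINS, "G")

    receptor = StructureSpec(
        name="R",
        root=ComponentSpec(
            name="c",
            sites=(SiteSpec("LB", "binding"), SiteSpec("GB", "binding")),
            children=(
                ComponentSpec(
                    name="ED",
                    allosteric=True,
                    conformations=("s", "t"),
                    couplings=(
                        ModifierCoupling(modifier="c.LB", phi=phi),
                        ModifierCoupling(modifier="c.GB", phi=phi),
                        ModifierCoupling(modifier="c.ID", gamma=Gamma, phi=phi),
                    ),
                ),
                ComponentSpec(
                    name="ID",
                    allosteric=True,
                    conformations=("i", "a"),
                    couplings=(
                        ModifierCoupling(modifier="c.LB", phi=phi),
                        ModifierCoupling(modifier="c.GB", phi=phi),
                        ModifierCoupling(modifier="c.ED", gamma=Gamma, phi=phi),
                    ),
                ),
            ),
        ),
    )

    structures = {"R": receptor}
    rules = []
    contexts = [
        (("s", "i"), lambda K, at, aa, aat: K),
        (("t", "i"), lambda K, at, aa, aat: K * at),
        (("s", "a"), lambda K, at, aa, aat: K * aa),
        (("t", "a"), lambda K, at, aa, aat: K * aat),
    ]
    for name, params in lig_table.items():
        structures[name] = ligand_structure(name)
        for (ed, idc), f in contexts:
            rules.append(
                _bind(
                    f"{name}.c.b",
                    "R.c.LB",
                    f(*params),
                    conf_b=(("R.c.ED", ed), ("R.c.ID", idc)),
                    name=f"{name}({ed}{idc})",
                )
            )
    for name, params in g_table.items():
        structures[name] = ligand_structure(name)
        for (ed, idc), f in contexts:
            rules.append(
                _bind(
                    f"{name}.c.b",
                    "R.c.GB",
                    f(*params),
                    conf_b=(("R.c.ED", ed), ("R.c.ID", idc)),
                    name=f"{name}({ed}{idc})",
                )
            )

    init = {"R": R_tot}
    init.update({n: 0.0 for n in lig_table})
    init.update({n: G_tot for n in g_table})
    probes = {
        "signalling": Probe(
            "signalling",
            (ProbeTerm(structure="R", conf=(("R.c.ID", "a"),), bound=(("R.c.GB", True),)),),
        ),
        "active": Probe("active", (ProbeTerm(structure="R", conf=(("R.c.ID", "a"),)),)),
        "total_R": Probe("total_R", (ProbeTerm(structure="R"),)),
    }
    return ModelSpec(
        structures=structures,
        allosteric={
            "R.c.ED": AllostericConstants(K0=K_actL),
            "R.c.ID": AllostericConstants(K0=K_actG),
        },
        rules=rules,
        init=init,
        probes=probes,
    )


def gpcr_cubic(
    ligands=("L1",),
    gproteins=("G1",),
    K_act: float = 0.05,
    lig_table: dict | None = None,
    g_table: dict | None = None,
    pair_table: dict | None = None,
) -> ModelSpec:
    """Cubic ternary complex receptor in interaction-centric form.

    One two-state component (i<->a); each ligand has (K_a, alpha), each G
    protein (K_g, beta), and every ligand/G-protein pair needs ad hoc
    cooperativity factors (gamma, delta) attached to occupancy-conditioned
    rules.  These pair factors violate the modifier-independence paradigm,
    so this builder exists for parameter accounting and as the projection
    target of the quartic model; its equilibria should be computed with
    :class:`CubicTernaryComplex` rather than by compilation.
    """
    lig_table = dict(
        lig_table
        or {
            n: (v[0], v[2])  # K_a, alpha: affinity and its active-state ratio
            for n, v in _as_table(ligands, QUARTIC_LIGANDS, "L").items()
        }
    )
    g_table = dict(
        g_table
        or {n: (v[0], v[2]) for n, v in _as_table(gproteins, QUARTIC_GPROTEINS, "G").items()}
    )
    pair_table = dict(
        pair_table or {(l, g): (1.0, 1.0) for l in lig_table for g in g_table}
    )

    receptor = StructureSpec(
        name="R",
        root=ComponentSpec(
            name="c",
            allosteric=True,
            conformations=("i", "a"),
            sites=(SiteSpec("LB", "binding"), SiteSpec("GB", "binding")),
            couplings=(
                ModifierCoupling(modifier="c.LB", phi=0.5),
                ModifierCoupling(modifier="c.GB", phi=0.5),
            ),
        ),
    )
    structures = {"R": receptor}
    rules = []
    for l, (Ka, alpha) in lig_table.items():
        structures[l] = ligand_structure(l)
        rules.append(
            _bind(f"{l}.c.b", "R.c.LB", Ka, conf_b=((".", "i"),),
                  occupancy_b=(("R.c.GB", False),), name=f"{l}(i)")
        )
        rules.append(
            _bind(f"{l}.c.b", "R.c.LB", Ka * alpha, conf_b=((".", "a"),),
                  occupancy_b=(("R.c.GB", False),), name=f"{l}(a)")
        )
    for g, (Kg, beta) in g_table.items():
        structures[g] = ligand_structure(g)
        rules.append(
            _bind(f"{g}.c.b", "R.c.GB", Kg, conf_b=((".", "i"),),
                  occupancy_b=(("R.c.LB", False),), name=f"{g}(i)")
        )
        rules.append(
            _bind(f"{g}.c.b", "R.c.GB", Kg * beta, conf_b=((".", "a"),),
                  occupancy_b=(("R.c.LB", False),), name=f"{g}(a)")
        )
    for (l, g), (gam, delta) in pair_table.items():
        Ka, alpha = lig_table[l]
        Kg, beta = g_table[g]
        fg, fd = f"gamma[{l},{g}]", f"delta[{l},{g}]"
        rules += [
            _bind(f"{l}.c.b", "R.c.LB", Ka * gam, conf_b=((".", "i"),),
                  occupancy_b=(("R.c.GB", g),), name=f"{l}(i|{g})", factors=(fg,)),
            _bind(f"{l}.c.b", "R.c.LB", Ka * alpha * gam * delta, conf_b=((".", "a"),),
                  occupancy_b=(("R.c.GB", g),), name=f"{l}(a|{g})", factors=(fg, fd)),
            _bind(f"{g}.c.b", "R.c.GB", Kg * gam, conf_b=((".", "i"),),
                  occupancy_b=(("R.c.LB", l),), name=f"{g}(i|{l})", factors=(fg,)),
            _bind(f"{g}.c.b", "R.c.GB", Kg * beta * gam * delta, conf_b=((".", "a"),),
                  occupancy_b=(("R.c.LB", l),), name=f"{g}(a|{l})", factors=(fg, fd)),
        ]
    init = {"R": 1.0}
    init.update({n: 0.0 for n in lig_table})
    init.update({n: 1.0 for n in g_table})
    return ModelSpec(
        structures=structures,
        allosteric={"R.c": AllostericConstants(K0=K_act)},
        rules=rules,
        init=init,
        probes={
            "signalling": Probe(
                "signalling",
                (ProbeTerm(structure="R", conf=(("R.c", "a"),), bound=(("R.c.GB", True),)),),
            )
        },
    )


class CubicTernaryComplex:
    """Closed-form 8-state equilibrium of the cubic ternary complex model.

    States are (active?, ligand bound?, G bound?) with statistical weights
    1, K_act, Ka*[L], Kg*[G] and the alpha/beta/gamma/delta multipliers of
    the scheme.  Free [L] is clamped; free [G] is solved from its total.
    """

    def __init__(self, K_act, Ka, alpha, Kg, beta, gamma=1.0, delta=1.0):
        self.K_act, self.Ka, self.alpha = K_act, Ka, alpha
        self.Kg, self.beta = Kg, beta
        self.gamma, self.delta = gamma, delta

    def weights(self, L: float, G: float) -> dict[tuple[int, int, int], float]:
        w = {}
        for a in (0, 1):
            for l in (0, 1):
                for g in (0, 1):
                    v = (self.K_act**a) * ((self.Ka * L) ** l) * ((self.Kg * G) ** g)
                    v *= self.alpha ** (a * l) * self.beta ** (a * g)
                    v *= self.gamma ** (l * g) * self.delta ** (a * l * g)
                    w[(a, l, g)] = v
        return w

    def equilibrium(self, L: float, R_tot: float = 1.0, G_tot: float = 1.0):
        """Receptor-state probabilities and free G at clamped free ligand."""
        from scipy.optimize import brentq

        def g_balance(logG):
            G = np.exp(logG)
            w = self.weights(L, G)
            Z = sum(w.values())
            bound = R_tot * sum(v for k, v in w.items() if k[2]) / Z
            return G + bound - G_tot

        logG = brentq(g_balance, np.log(G_tot) - 60, np.log(G_tot) + 1e-9, xtol=1e-15)
        G = float(np.exp(logG))
        w = self.weights(L, G)
        Z = sum(w.values())
        return {k: v / Z for k, v in w.items()}, G

    def signalling_fraction(self, L: float, R_tot: float = 1.0, G_tot: float = 1.0) -> float:
        p, _ = self.equilibrium(L, R_tot, G_tot)
        return sum(v for k, v in p.items() if k[0] == 1 and k[2] == 1)


def quartic_to_cubic(
    ligand: str = "L1",
    gprotein: str = "G1",
    K_actL: float = 1.0,
    K_actG: float = 0.05,
    Gamma: float = 1.0,
) -> CubicTernaryComplex:
    """Project a quartic parameter set onto effective cubic parameters by
    summing receptor weights over the extracellular-domain conformations.

    The marginal weights remain of mass-action form because each binder's
    weight is multilinear in the occupancies, so the derived parameters are
    concentration independent; gamma and delta emerge as correlated
    (non-free) combinations of the quartic affinity ratios.
    """
    Ka, at, aa, aat = QUARTIC_LIGANDS[ligand]
    Kg, bt, ba, bat = QUARTIC_GPROTEINS[gprotein]

    lig_ratio = {(0, 0): 1.0, (1, 0): at, (0, 1): aa, (1, 1): aat}
    g_ratio = {(0, 0): 1.0, (1, 0): bt, (0, 1): ba, (1, 1): bat}

    def W(active, lig, g):
        # sum over ED in {s, t}
        total = 0.0
        for ed in (0, 1):
            v = (K_actL**ed) * (K_actG**active) * (Gamma ** (ed * active))
            if lig:
                v *= Ka * lig_ratio[(ed, active)]
            if g:
                v *= Kg * g_ratio[(ed, active)]
            total += v
        return total

    K_act = W(1, 0, 0) / W(0, 0, 0)
    Ka_eff = W(0, 1, 0) / W(0, 0, 0)
    Kg_eff = W(0, 0, 1) / W(0, 0, 0)
    alpha = W(1, 1, 0) * W(0, 0, 0) / (W(1, 0, 0) * W(0, 1, 0))
    beta = W(1, 0, 1) * W(0, 0, 0) / (W(1, 0, 0) * W(0, 0, 1))
    gamma = W(0, 1, 1) * W(0, 0, 0) / (W(0, 1, 0) * W(0, 0, 1))
    delta = (W(1, 1, 1) * W(1, 0, 0) / (W(1, 1, 0) * W(1, 0, 1))) / gamma
    return CubicTernaryComplex(K_act, Ka_eff, alpha, Kg_eff, beta, gamma, delta)


# ---------------------------------------------------------------------------
# Enzymatic example and generic counting model
# ---------------------------------------------------------------------------

def kinase_cascade(
    Gamma_Y1: float = 50.0,
    Gamma_Y2: float = 50.0,
    K_IA: float = 1e-3,
) -> ModelSpec:
    """Kinase K with two activating phosphorylation sites and a catalytic
    site; an upstream kinase U phosphorylates K, each phosphorylation biasing
    K toward its active conformation; active (and, weakly, inactive) K then
    phosphorylates substrate S by a Michaelis-Menten mechanism."""
    kinase = StructureSpec(
        name="K",
        root=ComponentSpec(
            name="c",
            allosteric=True,
            conformations=("I", "A"),
            sites=(
                SiteSpec("y1", "covalent", states=("u", "p")),
                SiteSpec("y2", "covalent", states=("u", "p")),
                SiteSpec("kin", "catalytic"),
            ),
            couplings=(
                ModifierCoupling(modifier="c.y1", gamma=Gamma_Y1, phi=0.5),
                ModifierCoupling(modifier="c.y2", gamma=Gamma_Y2, phi=0.5),
                # substrate occupancy of the catalytic site distinguishes the
                # conformations (different ES affinities), so it is a modifier
                ModifierCoupling(modifier="c.kin", phi=0.5),
            ),
        ),
    )
    upstream = StructureSpec(
        name="U",
        root=ComponentSpec(name="c", sites=(SiteSpec("kin", "catalytic"),)),
    )
    substrate = StructureSpec(
        name="S",
        root=ComponentSpec(name="c", sites=(SiteSpec("y", "covalent", states=("u", "p")),)),
    )

    def enz(a_site, b_site, kf, kb, kp, conf_a=(), name=""):
        return RuleSpec(
            a=SitePattern(site=a_site, conf=tuple(conf_a)),
            b=SitePattern(site=b_site, state="u"),
            kf=kf,
            kb=kb,
            kp=kp,
            product_state="p",
            name=name,
        )

    return ModelSpec(
        structures={"K": kinase, "U": upstream, "S": substrate},
        allosteric={"K.c": AllostericConstants(K0=K_IA)},
        rules=[
            enz("U.c.kin", "K.c.y?", 10.0, 1.0, 5.0, name="U-phos-K"),
            enz("K.c.kin", "S.c.y", 10.0, 1.0, 5.0, conf_a=((".", "A"),), name="K(A)-phos-S"),
            enz("K.c.kin", "S.c.y", 10.0, 100.0, 0.05, conf_a=((".", "I"),), name="K(I)-phos-S"),
        ],
        init={"K": 1.0, "U": 0.1, "S": 1.0},
        probes={
            "phospho_S": Probe(
                "phospho_S", (ProbeTerm(structure="S", state=(("S.c.y", "p"),)),)
            ),
            "total_K": Probe("total_K", (ProbeTerm(structure="K"),)),
        },
    )


def generic_two_state(n_sites: int = 6, n_ligands: int = 5, K_RT: float = 0.1) -> ModelSpec:
    """Generic two-conformation protein with ``n_sites`` distinct binding
    sites, each binding every one of ``n_ligands`` ligands with its own pair
    of conformation-specific affinities — the parameter-accounting model."""
    prot = StructureSpec(
        name="P",
        root=ComponentSpec(
            name="c",
            allosteric=True,
            conformations=("R", "T"),
            sites=tuple(SiteSpec(f"s{i}", "binding") for i in range(1, n_sites + 1)),
            couplings=tuple(
                ModifierCoupling(modifier=f"c.s{i}", phi=0.5) for i in range(1, n_sites + 1)
            ),
        ),
    )
    structures = {"P": prot}
    rules = []
    for j in range(1, n_ligands + 1):
        lname = f"L{j}"
        structures[lname] = ligand_structure(lname)
        for i in range(1, n_sites + 1):
            # distinct (site, ligand) affinities: every site is unique
            K_R = 1.0 + 0.1 * (i + n_sites * j)
            K_T = 2.0 + 0.05 * (i * j)
            rules.append(
                _bind(f"{lname}.c.b", f"P.c.s{i}", K_R, conf_b=((".", "R"),), name=f"{lname}-s{i}(R)")
            )
            rules.append(
                _bind(f"{lname}.c.b", f"P.c.s{i}", K_T, conf_b=((".", "T"),), name=f"{lname}-s{i}(T)")
            )
    return ModelSpec(
        structures=structures,
        allosteric={"P.c": AllostericConstants(K0=K_RT)},
        rules=rules,
        init={"P": 1.0, **{f"L{j}": 0.0 for j in range(1, n_ligands + 1)}},
    )


# ---------------------------------------------------------------------------
# Random models (property-test fixtures)
# ---------------------------------------------------------------------------

def random_model(
    seed: int,
    n_sites: int = 2,
    n_ligands: int = 2,
    covalent: bool = False,
    symmetric: bool | None = None,
) -> ModelSpec:
    """Deterministic random two-state protein model.

    ``symmetric=True`` shares one wildcard rule set across all sites
    (equivalent sites, lumped under the symmetric group); ``False`` gives
    every site its own affinities.  ``covalent=True`` adds a covalently
    modifiable site plus a kinase acting on it.  The same seed always
    produces the identical model.
    """
    rng = np.random.default_rng(seed)
    if symmetric is None:
        symmetric = bool(rng.integers(0, 2))
    lg = lambda lo, hi: float(10.0 ** rng.uniform(lo, hi))

    sites = [SiteSpec(f"s{i}", "binding") for i in range(1, n_sites + 1)]
    couplings = [
        ModifierCoupling(modifier=f"c.s{i}", phi=float(rng.uniform(0, 1)))
        for i in range(1, n_sites + 1)
    ]
    if symmetric:
        phi = float(rng.uniform(0, 1))
        couplings = [ModifierCoupling(modifier=f"c.s{i}", phi=phi) for i in range(1, n_sites + 1)]
    if covalent:
        sites.append(SiteSpec("y", "covalent", states=("u", "p")))
        couplings.append(ModifierCoupling(modifier="c.y", gamma=lg(-1.5, 1.5), phi=0.5))

    prot = StructureSpec(
        name="P",
        root=ComponentSpec(
            name="c",
            allosteric=True,
            conformations=("R", "T"),
            sites=tuple(sites),
            couplings=tuple(couplings),
        ),
    )
    structures = {"P": prot}
    rules = []
    for j in range(1, n_ligands + 1):
        lname = f"L{j}"
        structures[lname] = ligand_structure(lname)
        if symmetric:
            KR, KT = lg(-1, 1), lg(-1, 1)
            rules.append(_bind(f"{lname}.c.b", "P.c.s?", KR, conf_b=((".", "R"),), name=f"{lname}(R)"))
            rules.append(_bind(f"{lname}.c.b", "P.c.s?", KT, conf_b=((".", "T"),), name=f"{lname}(T)"))
        else:
            for i in range(1, n_sites + 1):
                KR, KT = lg(-1, 1), lg(-1, 1)
                rules.append(
                    _bind(f"{lname}.c.b", f"P.c.s{i}", KR, conf_b=((".", "R"),), name=f"{lname}-s{i}(R)")
                )
                rules.append(
                    _bind(f"{lname}.c.b", f"P.c.s{i}", KT, conf_b=((".", "T"),), name=f"{lname}-s{i}(T)")
                )
    if covalent:
        structures["E"] = StructureSpec(
            name="E", root=ComponentSpec(name="c", sites=(SiteSpec("kin", "catalytic"),))
        )
        rules.append(
            RuleSpec(
                a=SitePattern(site="E.c.kin"),
                b=SitePattern(site="P.c.y", state="u"),
                kf=lg(0, 1),
                kb=lg(-0.5, 0.5),
                kp=lg(-0.5, 0.5),
                product_state="p",
                name="E-phos-P",
            )
        )
    init = {"P": 1.0, **{f"L{j}": float(rng.uniform(0.2, 2.0)) for j in range(1, n_ligands + 1)}}
    if covalent:
        init["E"] = 0.2
    probes = _ligand_probes([f"L{j}" for j in range(1, n_ligands + 1)])
    return ModelSpec(
        structures=structures,
        allosteric={"P.c": AllostericConstants(K0=lg(-2, 2))},
        rules=rules,
        init=init,
        probes=probes,
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_BUILDERS = {
    "divalent_adaptor": divalent_adaptor,
    "trimer_assembly": trimer_assembly,
    "concerted_tetramer": concerted_tetramer,
    "sequential_tetramer_tetrahedral": lambda **kw: sequential_tetramer(geometry="tetrahedral", **kw),
    "sequential_tetramer_square": lambda **kw: sequential_tetramer(geometry="square", **kw),
    "tertiary_two_state": tertiary_two_state,
    "competing_ligands": competing_ligands,
    "gpcr_cubic": gpcr_cubic,
    "gpcr_quartic": gpcr_quartic,
    "kinase_cascade": kinase_cascade,
    "generic_two_state": generic_two_state,
}

MODEL_NAMES = tuple(sorted(_BUILDERS))


def build(name: str, **overrides) -> ModelSpec:
    """Build a library model by name with optional parameter overrides."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}")
    return builder(**overrides)
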