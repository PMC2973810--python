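"""Thermodynamic engine for two-state allosteric transitions.

The conformational equilibrium of an allosteric component under a set of
modifiers follows the Monod-Wyman-Changeux independence assumption: each
modifier i that is out of its reference state multiplies the bare
equilibrium constant ``K0 = [alternate]/[reference]`` by its regulatory
factor ``Gamma_i``::

    K_eff = K0 * prod_i Gamma_i

For a ligand, Gamma is the ratio of its association constants to the two
conformations (``Gamma = K_alt / K_ref``); for a covalent modification or a
coupled allosteric component it is an independent parameter.  The same
independence is assumed for the transition state, so the kinetic rates pick
up the shift through the linear free-energy split parameterized by Phi::

    kf_eff = kf0 * prod_i Gamma_i**Phi_i
    kb_eff = kb0 * prod_i Gamma_i**(Phi_i - 1)

which guarantees ``kf_eff / kb_eff == K_eff`` identically, so every
thermodynamic cycle built from conformational transitions and bimolecular
binding steps closes by construction (detailed balance).  kT is set to 1:
all free energies are expressed through dimensionless equilibrium constants.

This module also verifies detailed balance of compiled networks by
propagating formation weights over the reversible reactions and measuring
the log-residual of every independent cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AllostericTransition",
    "ModifierEffect",
    "CycleResidual",
    "effective_equilibrium",
    "effective_rates",
    "gamma_from_affinities",
    "propagate_weights",
    "detailed_balance_residuals",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class AllostericTransition:
    """Unligated reference<->alternate transition with K0 = kf0/kb0."""

    K0: float
    kf0: float
    kb0: float

    def __post_init__(self):
        if self.K0 <= 0 or self.kf0 <= 0 or self.kb0 <= 0:
            raise ValueError("K0, kf0, kb0 must all be positive")
        if abs(self.kf0 / self.kb0 - self.K0) > _REL_TOL * self.K0:
            raise ValueError("inconsistent transition: K0 != kf0/kb0")

    @classmethod
    def from_K(cls, K0: float, kf0: float = 1.0) -> "AllostericTransition":
        return cls(K0=K0, kf0=kf0, kb0=kf0 / K0)


@dataclass(frozen=True)
class ModifierEffect:
    """One active modifier: regulatory factor Gamma and its Phi value."""

    gamma: float
    phi: float = 0.5

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def effective_equilibrium(t: AllostericTransition, effects) -> float:
    """K0 multiplied by the regulatory factor of every active modifier."""
    K = t.K0
    for e in effects:
        if e.gamma <= 0:
            raise ValueError("gamma must be positive")
        K *= e.gamma
    return K


def effective_rates(t: AllostericTransition, effects) -> tuple[float, float]:
    """(kf, kb) of the modified transition.

    Modifiers act independently on the transition state, shifting the
    forward rate by Gamma**Phi and the backward rate by Gamma**(Phi-1); the
    ratio kf/kb therefore equals :func:`effective_equilibrium` exactly.
    """
    kf, kb = t.kf0, t.kb0
    for e in effects:
        if e.gamma <= 0:
            raise ValueError("gamma must be positive")
        kf *= e.gamma**e.phi
        kb *= e.gamma ** (e.phi - 1.0)
    return kf, kb


def gamma_from_affinities(K_ref: float, K_alt: float) -> float:
    """Regulatory factor of a ligand: ratio of its association constants to
    the alternate and reference conformations."""
    if K_ref <= 0 or K_alt <= 0:
        raise ValueError("affinities must be positive")
    return K_alt / K_ref


# ---------------------------------------------------------------------------
# Detailed-balance verification of compiled networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleResidual:
    """|log product of equilibrium constants| around one independent cycle.

    ``cycle`` lists the provenance strings of the reactions on the cycle
    (the closing reaction first).
    """

    cycle: tuple[str, ...]
    residual: float


def propagate_weights(network, seeds=None):
    """Assign a formation weight w to every species and collect cycle residuals.

    Weights satisfy ``w(products) = K * w(reactants)`` along a spanning set
    of the reversible reactions; every remaining (cycle-closing) reversible
    reaction yields a residual ``|log K + sum log w(react) - sum log w(prod)|``
    which is zero iff the network obeys detailed balance on that cycle.
    Irreversible reactions are excluded and reported via ``skipped``.

    Returns ``(logw, residuals, skipped)`` where ``logw`` maps species label
    to log formation weight.
    """
    reversible = [r for r in network.reactions if r.kb]
    skipped = [r for r in network.reactions if not r.kb]

    logw: dict[str, float] = {}
    if seeds is None:
        seeds = list(getattr(network, "seed_labels", lambda: [])())
    order = list(getattr(network, "species_order", lambda: sorted(network.species))())
    for s in seeds:
        logw[s] = 0.0

    assigned_by: dict[str, object] = {}
    residuals: list[CycleResidual] = []
    pending = list(reversible)
    done: list = []

    def try_round():
        progress = False
        remaining = []
        for rxn in pending:
            labels = list(rxn.reactants) + list(rxn.products)
            unknown = [l for l in labels if l not in logw]
            if not unknown:
                res = math.log(rxn.kf / rxn.kb)
                res += sum(logw[l] for l in rxn.reactants)
                res -= sum(logw[l] for l in rxn.products)
                residuals.append(
                    CycleResidual(cycle=_cycle_reactions(rxn, assigned_by), residual=abs(res))
                )
                done.append(rxn)
                progress = True
            elif len(set(unknown)) == 1 and len(unknown) == 1:
                target = unknown[0]
                base = math.log(rxn.kf / rxn.kb)
                base += sum(logw[l] for l in rxn.reactants if l != target)
                base -= sum(logw[l] for l in rxn.products if l != target)
                logw[target] = base if target in rxn.products else -base
                assigned_by[target] = rxn
                done.append(rxn)
                progress = True
            else:
                remaining.append(rxn)
        return progress, remaining

    while pending:
        progress, pending = try_round()
        if not progress:
            # underdetermined component: pick an extra seed (smallest species
            # first, deterministically) and continue.
            unknowns = [
                l
                for l in order
                if l not in logw
                and any(l in r.reactants or l in r.products for r in pending)
            ]
            if not unknowns:
                break
            unknowns.sort(key=lambda l: (network.species[l].size, l))
            logw[unknowns[0]] = 0.0

    return logw, residuals, skipped


def _cycle_reactions(closing, assigned_by) -> tuple[str, ...]:
    """Reactions forming the cycle closed by ``closing`` (approximate listing:
    the closing reaction plus the spanning-tree reactions that assigned its
    participants)."""
    names = [getattr(closing, "provenance", repr(closing))]
    seen = set()
    stack = list(closing.reactants) + list(closing.products)
    while stack:
        lbl = stack.pop()
        if lbl in seen:
            continue
        seen.add(lbl)
        rxn = assigned_by.get(lbl)
        if rxn is not None:
            name = getattr(rxn, "provenance", repr(rxn))
            if name not in names:
                names.append(name)
            stack.extend(list(rxn.reactants) + list(rxn.products))
    return tuple(names)


def detailed_balance_residuals(network) -> list[CycleResidual]:
    """Cycle residuals over a fundamental cycle basis of the species graph.

    All-zero residuals (< 1e-9) certify thermodynamic consistency for every
    cycle composed of conformational transitions and bimolecular binding
    steps.  Irreversible (catalytic) steps are excluded from the basis.
    """
    _, residuals, _ = propagate_weights(network)
    return residuals
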