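"""End-to-end protocols for the worked model family.

These functions run complete compile -> equilibrate -> analyse pipelines for
the library models: competing-ligand Hill-coefficient profiles of the
tetramer models, and functional-selectivity panels of the quartic ternary
complex receptor.  They exist so that scripted reproductions and tests
exercise exactly the same code path.
"""

from __future__ import annotations

import numpy as np

from . import library
from .analysis import hill_coefficient, hill_summary, rank_order, sweep_saturating
from .compiler import enumerate_network

__all__ = [
    "tetramer_network",
    "competitor_own_ec50",
    "hill_with_competitor",
    "max_hill_over_competitor_grid",
    "gpcr_selectivity_panel",
]

_VARIANTS = {
    "concerted": lambda ligands: library.concerted_tetramer(ligands=ligands),
    "sequential_tetrahedral": lambda ligands: library.sequential_tetramer(
        geometry="tetrahedral", ligands=ligands
    ),
    "sequential_square": lambda ligands: library.sequential_tetramer(
        geometry="square", ligands=ligands
    ),
}


def tetramer_network(variant: str, ligands: tuple[str, ...]):
    """Build and compile a tetramer model with the given ligand panel."""
    model = _VARIANTS[variant](tuple(ligands))
    return model, enumerate_network(model)


def competitor_own_ec50(variant: str, ligand: str, points_per_decade: int = 16) -> float:
    """EC50 of a ligand's own occupancy curve on the bare tetramer."""
    from .analysis import ec_point

    model, net = tetramer_network(variant, (ligand,))
    curve = sweep_saturating(
        net, ligand, model.probes[f"bound_{ligand}"], totals={"P": 1.0},
        points_per_decade=points_per_decade,
    )
    return ec_point(curve, 0.5)


def hill_with_competitor(
    variant: str,
    competitor: str | None = None,
    multiple: float | None = None,
    points_per_decade: int = 16,
) -> float:
    """Hill coefficient of L0 occupancy, optionally with a competitor fixed
    at ``multiple`` times the EC50 of its own occupancy curve."""
    ligands = ("L0",) if competitor is None else ("L0", competitor)
    model, net = tetramer_network(variant, ligands)
    clamped = {}
    if competitor is not None:
        ec50 = competitor_own_ec50(variant, competitor, points_per_decade)
        clamped[competitor] = multiple * ec50
    curve = sweep_saturating(
        net, "L0", model.probes["bound_L0"], totals={"P": 1.0}, clamped=clamped,
        points_per_decade=points_per_decade,
    )
    return hill_coefficient(curve)


def max_hill_over_competitor_grid(
    variant: str,
    competitor: str = "L3",
    multiples=None,
    points_per_decade: int = 16,
) -> float:
    """Maximum L0 Hill coefficient over a grid of fixed competitor levels
    (defaults: 0.01x to 100x the competitor's own-occupancy EC50)."""
    if multiples is None:
        multiples = np.logspace(-2, 2, 17)
    ec50 = competitor_own_ec50(variant, competitor, points_per_decade)
    model, net = tetramer_network(variant, ("L0", competitor))
    best = -np.inf
    for mult in multiples:
        curve = sweep_saturating(
            net, "L0", model.probes["bound_L0"], totals={"P": 1.0},
            clamped={competitor: float(mult) * ec50},
            points_per_decade=points_per_decade,
        )
        best = max(best, hill_coefficient(curve))
    return float(best)


def gpcr_selectivity_panel(
    ligands: tuple[str, ...] = ("L1", "L2", "L3"),
    gproteins: tuple[str, ...] = ("G1", "G2"),
    points_per_decade: int = 12,
):
    """Dose-response summaries of the quartic receptor for every
    ligand/G-protein pair, plus the per-pathway potency rank order."""
    summaries = {}
    for g in gproteins:
        for l in ligands:
            model = library.gpcr_quartic(ligands=(l,), gproteins=(g,))
            net = enumerate_network(model)
            curve = sweep_saturating(
                net, l, model.probes["signalling"], totals={"R": 1.0, g: 1.0},
                lo=1e-5, hi=1e4, points_per_decade=points_per_decade,
            )
            summaries[(l, g)] = hill_summary(curve)
    return summaries, rank_order(summaries)
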