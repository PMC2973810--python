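"""Mass-action simulation of compiled networks.

Two complementary equilibrium routes are provided:

* :func:`equilibrium_partition` — for closed binding-only systems, species
  concentrations follow from formation weights (products of equilibrium
  constants along any path from the reference monomers; path independence is
  guaranteed by detailed balance) and per-structure activity factors solved
  from the conservation totals.  This is exact, fast and serves as the
  independent oracle for the ODE route.
* :func:`steady_state` — stiff integration of the mass-action ODEs to large
  time followed by a root-finding polish; works for any network, including
  catalytic (driven) ones.

Ligands can be *clamped*: their free monomer concentration is held fixed
(the dilute-receptor convention for dose-response sweeps) instead of being
part of a conservation total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .compiler import ReactionNetwork
from .species import probe_weight
from .thermo import propagate_weights

__all__ = [
    "ODESystem",
    "DoseResponse",
    "equilibrium_partition",
    "steady_state",
    "dose_response",
    "probe_value",
    "conservation_matrix",
]


# ---------------------------------------------------------------------------
# Partition-function equilibrium (binding-only networks)
# ---------------------------------------------------------------------------

def equilibrium_partition(
    network: ReactionNetwork,
    totals: dict[str, float] | None = None,
    clamped: dict[str, float] | None = None,
    tol: float = 1e-12,
) -> dict[str, float]:
    """Equilibrium concentrations of a closed binding-only network.

    ``totals`` gives the conserved total concentration per structure;
    ``clamped`` fixes the free monomer concentration of selected structures
    instead.  Raises ``ValueError`` for networks with catalytic steps, whose
    steady states are not equilibria.
    """
    if not network.is_binding_only():
        raise ValueError(
            "equilibrium_partition applies only to reversible binding networks"
        )
    totals = dict(totals or {})
    clamped = dict(clamped or {})
    logw, _residuals, _ = propagate_weights(network)

    labels = network.species_order()
    structs = sorted(network.model.structures)
    comp = {lbl: network.species[lbl].composition for lbl in labels}

    free = [
        m
        for m in structs
        if m not in clamped and totals.get(m, 0.0) > 0.0
    ]
    # species containing a structure with no source have zero concentration
    dead = {
        m
        for m in structs
        if m not in clamped and totals.get(m, 0.0) <= 0.0
    } | {m for m, v in clamped.items() if v <= 0.0}
    live = [
        lbl for lbl in labels if lbl in logw and not (set(comp[lbl]) & dead)
    ]

    base = np.array(
        [
            logw[lbl]
            + sum(comp[lbl][m] * np.log(clamped[m]) for m in clamped if comp[lbl][m])
            for lbl in live
        ]
    )
    N = np.array([[comp[lbl][m] for m in free] for lbl in live], dtype=float)

    out = {lbl: 0.0 for lbl in labels}
    if free:
        target = np.log([totals[m] for m in free])
        u = target.copy()  # log activity factors
        for _ in range(400):
            logc = base + N @ u
            c = np.exp(logc)
            tot = N.T @ c
            F = np.log(tot) - target
            if np.max(np.abs(F)) < tol:
                break
            J = (N.T * c) @ N / tot[:, None]
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate
                step = -F
            step = np.clip(step, -4.0, 4.0)
            u = u + step
        else:  # pragma: no cover - fallback for hard cases
            sol = root(
                lambda v: np.log(N.T @ np.exp(base + N @ v)) - target, u, method="hybr"
            )
            u = sol.x
        c = np.exp(base + N @ u)
    else:
        c = np.exp(base)
    for lbl, ci in zip(live, c):
        out[lbl] = float(ci)
    return out


# ---------------------------------------------------------------------------
# ODE route
# ---------------------------------------------------------------------------

class ODESystem:
    """Mass-action ODEs over the full species vector.

    Clamped structures have their free-monomer derivative forced to zero
    (optionally driven by stimuli waveforms during trajectories).
    """

    def __init__(self, network: ReactionNetwork, clamped: dict[str, float] | None = None):
        self.network = network
        self.labels = network.species_order()
        self.index = {lbl: i for i, lbl in enumerate(self.labels)}
        self.clamped = dict(clamped or {})
        self.clamped_idx = {}
        for m, v in self.clamped.items():
            lbl = self._monomer_label(m)
            self.clamped_idx[self.index[lbl]] = v

        # directed reactions: (k, i_a, i_b or -1, stoich column)
        ks, ia, ib, cols = [], [], [], []
        n = len(self.labels)
        for r in network.reactions:
            directions = [(r.reactants, r.products, r.kf)]
            if r.kb:
                directions.append((r.products, r.reactants, r.kb))
            for reac, prod, k in directions:
                if not k:
                    continue
                idxs = [self.index[l] for l in reac]
                if len(idxs) > 2:
                    raise ValueError("mass action supports at most bimolecular steps")
                col = np.zeros(n)
                for l in reac:
                    col[self.index[l]] -= 1
                for l in prod:
                    col[self.index[l]] += 1
                ks.append(k)
                ia.append(idxs[0])
                ib.append(idxs[1] if len(idxs) > 1 else -1)
                cols.append(col)
        self.k = np.array(ks)
        self.ia = np.array(ia, dtype=int)
        self.ib = np.array(ib, dtype=int)
        self.S = np.array(cols).T if cols else np.zeros((n, 0))

    def _monomer_label(self, structure: str) -> str:
        from .species import make_monomer

        return self.network.canonicalizer.label(
            make_monomer(self.network.model, structure)
        )

    def fluxes(self, c: np.ndarray) -> np.ndarray:
        cb = np.where(self.ib >= 0, c[self.ib], 1.0)
        return self.k * c[self.ia] * cb

    def rhs(self, t: float, c: np.ndarray, drive=None) -> np.ndarray:
        c = np.maximum(c, 0.0)
        if drive is not None:
            c = c.copy()
            for i, fn in drive.items():
                c[i] = fn(t)
        dc = self.S @ self.fluxes(c)
        for i in self.clamped_idx:
            dc[i] = 0.0
        if drive is not None:
            for i in drive:
                dc[i] = 0.0
        return dc

    def initial_vector(self, initial: dict[str, float]) -> np.ndarray:
        c0 = np.zeros(len(self.labels))
        for lbl, v in initial.items():
            c0[self.index[lbl]] = v
        for i, v in self.clamped_idx.items():
            c0[i] = v
        return c0


def conservation_matrix(network: ReactionNetwork, exclude: set[str] | None = None):
    """Per-structure instance-count conservation laws (rows) over species
    (columns); structures in ``exclude`` (clamped sources) are omitted."""
    exclude = exclude or set()
    labels = network.species_order()
    structs = [m for m in sorted(network.model.structures) if m not in exclude]
    L = np.zeros((len(structs), len(labels)))
    for j, lbl in enumerate(labels):
        comp = network.species[lbl].composition
        for i, m in enumerate(structs):
            L[i, j] = comp.get(m, 0)
    return structs, L


def steady_state(
    network: ReactionNetwork,
    initial: dict[str, float],
    clamped: dict[str, float] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-13,
    t_max: float = 1e12,
) -> dict[str, float]:
    """Integrate to steady state and polish with damped root finding.

    The returned state satisfies ``||dc/dt|| < 1e-10 ||c|| + 1e-12`` and
    preserves the conservation totals of the initial state.
    """
    sys = ODESystem(network, clamped)
    c = sys.initial_vector(initial)
    t_end = 100.0
    f = sys.rhs(0.0, c)
    while np.linalg.norm(f) >= 1e-10 * np.linalg.norm(c) + 1e-12 and t_end <= t_max:
        sol = solve_ivp(
            sys.rhs,
            (0.0, t_end),
            c,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        c = np.maximum(sol.y[:, -1], 0.0)
        f = sys.rhs(0.0, c)
        t_end *= 10.0

    # polish on the free coordinates with conservation rows appended
    _, L = conservation_matrix(network, exclude=set(sys.clamped or ()))
    totals0 = L @ c
    free_idx = np.array(
        [i for i in range(len(c)) if i not in sys.clamped_idx], dtype=int
    )

    def F(x):
        full = c.copy()
        full[free_idx] = x
        dc = sys.rhs(0.0, full)
        return np.concatenate([dc[free_idx], (L @ full) - totals0])

    sol = root(F, c[free_idx], method="lm", options={"xtol": 1e-14, "ftol": 1e-14})
    if sol.success and np.all(sol.x > -1e-9):
        c[free_idx] = np.maximum(sol.x, 0.0)

    resid = np.linalg.norm(sys.rhs(0.0, c))
    if resid >= 1e-10 * np.linalg.norm(c) + 1e-12:
        raise RuntimeError(f"steady state not converged: residual {resid:.3e}")
    return dict(zip(sys.labels, map(float, c)))


def simulate_trajectory(
    network: ReactionNetwork,
    initial: dict[str, float],
    t_eval,
    stimuli=None,
    rtol: float = 1e-8,
    atol: float = 1e-11,
):
    """Time course with optional stimulus waveforms driving clamped species."""
    stimuli = stimuli if stimuli is not None else network.model.stimuli
    clamp0 = {s.target: s(0.0) for s in stimuli}
    sys = ODESystem(network, clamp0)
    drive = {}
    for s in stimuli:
        lbl = sys._monomer_label(s.target)
        drive[sys.index[lbl]] = s
    c0 = sys.initial_vector(initial)
    sol = solve_ivp(
        lambda t, c: sys.rhs(t, c, drive=drive),
        (float(t_eval[0]), float(t_eval[-1])),
        c0,
        t_eval=np.asarray(t_eval, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    y = sol.y.copy()
    for i, fn in drive.items():  # report the driven values, not the frozen state
        y[i, :] = [fn(t) for t in sol.t]
    return sys.labels, sol.t, y


# ---------------------------------------------------------------------------
# Probes and dose responses
# ---------------------------------------------------------------------------

def probe_value(network: ReactionNetwork, conc: dict[str, float], probe) -> float:
    model = network.model
    total = 0.0
    for lbl, c in conc.items():
        if c:
            w = probe_weight(model, network.species[lbl].raw, probe)
            if w:
                total += w * c
    return total


@dataclass
class DoseResponse:
    """Probe readout against an input concentration grid (log-spaced)."""

    input: str
    grid: np.ndarray
    values: np.ndarray
    probe: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("concentration grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose-response values must be finite")

    def normalized(self) -> np.ndarray:
        lo, hi = self.values[0], self.values[-1]
        if hi == lo:
            raise ValueError("flat curve cannot be normalized")
        return (self.values - lo) / (hi - lo)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({self.input: self.grid, self.probe or "probe": self.values})


def dose_response(
    network: ReactionNetwork,
    input_structure: str,
    grid,
    probe,
    totals: dict[str, float] | None = None,
    clamped: dict[str, float] | None = None,
    mode: str = "clamped",
) -> DoseResponse:
    """Sweep the input structure's concentration and read out a probe.

    ``mode="clamped"`` holds the free input concentration at each grid value
    (dilute-target convention); ``mode="total"`` treats the grid as total
    concentrations entering the conservation laws.
    """
    if input_structure not in network.model.structures:
        raise ValueError(f"unknown input structure {input_structure!r}")
    if isinstance(probe, str):
        probe = network.model.probes[probe]
    totals = dict(totals or {})
    clamped = dict(clamped or {})
    grid = np.asarray(grid, dtype=float)
    values = np.empty_like(grid)
    for i, g in enumerate(grid):
        tot, cl = dict(totals), dict(clamped)
        if mode == "clamped":
            cl[input_structure] = g
        elif mode == "total":
            tot[input_structure] = g
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if network.is_binding_only():
            conc = equilibrium_partition(network, totals=tot, clamped=cl)
        else:
            from .species import make_monomer

            init = {}
            for m, v in tot.items():
                lbl = network.canonicalizer.label(make_monomer(network.model, m))
                init[lbl] = v
            conc = steady_state(network, init, clamped=cl)
        values[i] = probe_value(network, conc, probe)
    return DoseResponse(input=input_structure, grid=grid, values=values, probe=probe.name)
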