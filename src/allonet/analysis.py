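"""Derived quantities: cooperativity, Hill coefficients, potency/efficacy,
assembly efficacy and rank-order comparisons.

The divalent allosteric adaptor (a two-state protein A with one site for X
and one for Y) can be coarse-grained by summing over its conformations.
The binding of X and Y is then coupled through a single cooperativity
parameter theta — the fold-change of A's apparent affinity for one ligand
caused by occupancy of the other site::

    theta = (1 + K_RT) (1 + K_RT G_X G_Y) / ((1 + K_RT G_X)(1 + K_RT G_Y))

with K_RT the unligated allosteric equilibrium constant and G_X, G_Y the
ligands' regulatory factors (affinity ratios between the two
conformations).  The same coarse-graining gives each ligand's apparent
association constant to unliganded A::

    K_app = (K_R + K_RT K_T) / (1 + K_RT)

Theta is maximal at K_RT = (G_X G_Y)^(-1/2): conformational bias is most
effective when the bare equilibrium sits at the geometric midpoint of the
shifts the two ligands can exert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar, root

from .simulate import DoseResponse, dose_response

__all__ = [
    "cooperativity_theta",
    "theta_optimum",
    "apparent_affinity",
    "hill_coefficient",
    "ec_point",
    "HillSummary",
    "hill_summary",
    "trimer_equilibrium",
    "assembly_metrics",
    "rank_order",
    "sweep_saturating",
]


# ---------------------------------------------------------------------------
# Coarse-grained adaptor cooperativity
# ---------------------------------------------------------------------------

def cooperativity_theta(K_RT: float, gamma_x: float, gamma_y: float) -> float:
    """Fold-change of A's apparent affinity for Y caused by X occupancy."""
    if min(K_RT, gamma_x, gamma_y) <= 0:
        raise ValueError("all arguments must be positive")
    return (
        (1.0 + K_RT)
        * (1.0 + K_RT * gamma_x * gamma_y)
        / ((1.0 + K_RT * gamma_x) * (1.0 + K_RT * gamma_y))
    )


def theta_optimum(gamma_x: float, gamma_y: float) -> float:
    """The allosteric constant maximizing theta: (G_X G_Y)^(-1/2)."""
    if gamma_x <= 0 or gamma_y <= 0:
        raise ValueError("regulatory factors must be positive")
    return 1.0 / math.sqrt(gamma_x * gamma_y)


def apparent_affinity(K_R: float, K_T: float, K_RT: float) -> float:
    """Conformation-summed association constant of a ligand to unliganded A."""
    if min(K_R, K_T, K_RT) <= 0:
        raise ValueError("all arguments must be positive")
    return (K_R + K_RT * K_T) / (1.0 + K_RT)


# ---------------------------------------------------------------------------
# Hill analysis
# ---------------------------------------------------------------------------

def ec_point(curve: DoseResponse, frac: float) -> float:
    """Input concentration at the given fraction of the normalized response.

    Interpolates log-concentration against the logit of the normalized
    response (exact for ideal Hill curves).  Raises when the grid does not
    bracket the requested point or the curve is not saturated at its ends
    (the EC point would then depend on the arbitrary grid limits).
    """
    y = curve.normalized()
    if np.any(np.diff(y) < -1e-6):
        raise ValueError("curve is not monotone after normalization")
    span_ok = abs(y[1] - y[0]) <= 0.05 and abs(y[-1] - y[-2]) <= 0.05
    if not span_ok:
        raise ValueError(
            f"grid does not bracket the EC{int(round(frac * 100))} point: "
            "response not saturated at the grid limits"
        )
    x = np.log(curve.grid)
    idx = np.nonzero((y[:-1] - frac) * (y[1:] - frac) <= 0)[0]
    if len(idx) == 0:
        raise ValueError(f"grid does not bracket the EC{int(round(frac * 100))} point")
    i = int(idx[0])
    if y[i + 1] == y[i]:
        return float(np.exp(x[i]))
    eps = 1e-15
    yi, yj = np.clip([y[i], y[i + 1]], eps, 1.0 - eps)
    li, lj = np.log(yi / (1 - yi)), np.log(yj / (1 - yj))
    lf = math.log(frac / (1.0 - frac))
    t = (lf - li) / (lj - li)
    return float(np.exp(x[i] + t * (x[i + 1] - x[i])))


def hill_coefficient(curve: DoseResponse, method: str = "midpoint") -> float:
    """Hill coefficient of a normalized sigmoidal dose response.

    ``method="midpoint"`` (default) is the classical definition: the slope
    of log(y / (1 - y)) against log(input) at half-maximal response,
    evaluated by a local quadratic fit of the logit around the EC50.  It
    equals n exactly for an ideal Hill curve and reproduces the published
    cooperativity indices of the tetramer models.  ``method="ec1090"`` is
    the coarser two-point estimator log(81) / log(EC90 / EC10), which
    systematically underestimates the midpoint slope for non-ideal curves.
    """
    if method == "ec1090":
        ec10 = ec_point(curve, 0.10)
        ec90 = ec_point(curve, 0.90)
        return math.log(81.0) / math.log(ec90 / ec10)
    if method != "midpoint":
        raise ValueError(f"unknown method {method!r}")
    from scipy.interpolate import PchipInterpolator

    y = curve.normalized()
    if np.any(np.diff(y) < -1e-6):
        raise ValueError("curve is not monotone after normalization")
    x0 = math.log(ec_point(curve, 0.5))
    x = np.log(curve.grid)
    ok = (y > 1e-12) & (y < 1.0 - 1e-12)
    if ok.sum() < 4:
        raise ValueError("too few interior points to estimate the midpoint slope")
    logit = np.log(y[ok] / (1.0 - y[ok]))
    spline = PchipInterpolator(x[ok], logit)
    return float(spline.derivative()(x0))


@dataclass(frozen=True)
class HillSummary:
    """Summary statistics of a sigmoidal dose response."""

    n_H: float
    ec50: float
    potency: float  # -log10(EC50)
    efficacy: float  # plateau response at saturating input
    basal: float  # response at the low end of the sweep

    @property
    def inverse(self) -> bool:
        return self.efficacy < self.basal


def hill_summary(curve: DoseResponse) -> HillSummary:
    ec50 = ec_point(curve, 0.5)
    return HillSummary(
        n_H=hill_coefficient(curve),
        ec50=ec50,
        potency=-math.log10(ec50),
        efficacy=float(curve.values[-1]),
        basal=float(curve.values[0]),
    )


def sweep_saturating(
    network,
    input_structure: str,
    probe,
    totals=None,
    clamped=None,
    lo: float = 1e-6,
    hi: float = 1e4,
    points_per_decade: int = 12,
    mode: str = "clamped",
    max_decades: int = 30,
) -> DoseResponse:
    """Dose response over a log grid automatically widened until the curve is
    flat (relative change < 1e-3) at both ends, so EC points are bracketed."""
    for _ in range(max_decades):
        n = int(round(points_per_decade * math.log10(hi / lo))) + 1
        grid = np.logspace(math.log10(lo), math.log10(hi), n)
        curve = dose_response(
            network, input_structure, grid, probe, totals=totals, clamped=clamped, mode=mode
        )
        y = curve.values
        span = abs(y[-1] - y[0])
        if span == 0:
            return curve
        k = points_per_decade
        low_flat = abs(y[k] - y[0]) < 1e-3 * span
        high_flat = abs(y[-1] - y[-1 - k]) < 1e-3 * span
        if low_flat and high_flat:
            return curve
        if not low_flat:
            lo /= 10.0
        if not high_flat:
            hi *= 10.0
    raise RuntimeError("dose response failed to saturate within the widened grid")


# ---------------------------------------------------------------------------
# Trimer assembly efficacy (coarse-grained adaptor)
# ---------------------------------------------------------------------------

def trimer_equilibrium(
    A_tot: float,
    X_tot: float = 1.0,
    Y_tot: float = 1.0,
    K_X: float = 1.0,
    K_Y: float = 1.0,
    theta: float = 1.0,
    guess=None,
):
    """Equilibrium of the coarse-grained 4-species assembly model
    A + X <-> XA, A + Y <-> AY, with the second binding scaled by theta.

    Returns (concentrations dict, free-log guess for warm starting).
    """

    from scipy.special import logsumexp

    lKX, lKY, lth = math.log(K_X), math.log(K_Y), math.log(theta)

    def F(u):
        la, lx, ly = u
        lxa = lKX + la + lx
        lay = lKY + la + ly
        lxay = lth + lKX + lKY + la + lx + ly
        return [
            logsumexp([lx, lxa, lxay]) - math.log(X_tot),
            logsumexp([ly, lay, lxay]) - math.log(Y_tot),
            logsumexp([la, lxa, lay, lxay]) - math.log(A_tot),
        ]

    u0 = guess if guess is not None else np.log([A_tot, X_tot, Y_tot])[[0, 1, 2]]
    sol = root(F, u0, method="hybr", options={"xtol": 1e-13})
    if not sol.success:
        sol = root(F, np.log([A_tot / 2, X_tot / 2, Y_tot / 2]), method="hybr")
    a, x, y = np.exp(sol.x)
    conc = {
        "A": a,
        "X": x,
        "Y": y,
        "XA": K_X * a * x,
        "AY": K_Y * a * y,
        "XAY": theta * K_X * K_Y * a * x * y,
    }
    return conc, sol.x


def assembly_metrics(
    thetas,
    X_tot: float = 1.0,
    Y_tot: float = 1.0,
    K_X: float = 1.0,
    K_Y: float = 1.0,
    log10_A_range: tuple[float, float] = (-4.0, 5.0),
    points_per_decade: int = 20,
) -> dict[float, dict[str, float]]:
    """Efficacious linker range and maximal complex per cooperativity value.

    For each theta, sweeps the total linker amount A_tot on a log grid,
    finds the maximal trimer concentration (refined by bounded
    optimization) and the width — in log10 units — of the A_tot interval
    where [XAY] >= 50% of that maximum, with bisection-refined crossings.
    """
    lo, hi = log10_A_range
    n = int(round((hi - lo) * points_per_decade)) + 1
    logA = np.linspace(lo, hi, n)
    out = {}
    for theta in thetas:
        xay = np.empty(n)
        guess = None
        for i, la in enumerate(logA):
            conc, guess = trimer_equilibrium(
                10.0**la, X_tot, Y_tot, K_X, K_Y, theta, guess=guess
            )
            xay[i] = conc["XAY"]
        i_max = int(np.argmax(xay))

        def neg_xay(la):
            return -trimer_equilibrium(10.0**la, X_tot, Y_tot, K_X, K_Y, theta)[0]["XAY"]

        res = minimize_scalar(
            neg_xay,
            bounds=(logA[max(i_max - 1, 0)], logA[min(i_max + 1, n - 1)]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        peak = -res.fun
        half = 0.5 * peak

        def excess(la):
            return trimer_equilibrium(10.0**la, X_tot, Y_tot, K_X, K_Y, theta)[0][
                "XAY"
            ] - half

        if xay[0] >= half or xay[-1] >= half:
            raise ValueError("efficacious region truncated by the A_tot grid")
        left_idx = np.nonzero(xay[: i_max + 1] >= half)[0][0]
        right_idx = i_max + np.nonzero(xay[i_max:] >= half)[0][-1]
        left = brentq(excess, logA[left_idx - 1], logA[left_idx], xtol=1e-12)
        right = brentq(excess, logA[right_idx], logA[right_idx + 1], xtol=1e-12)
        out[theta] = {
            "range_decades": right - left,
            "max_complex": peak,
            "left_log10": left,
            "right_log10": right,
        }
    return out


# ---------------------------------------------------------------------------
# Rank order of potency / functional selectivity
# ---------------------------------------------------------------------------

def rank_order(summaries: dict[tuple[str, str], HillSummary]) -> dict:
    """Order ligands by potency (ties by efficacy) for each pathway.

    Returns ``{"order": {pathway: [ligand, ...]}, "selective": bool,
    "inverse_agonists": set[(ligand, pathway)]}``; ``selective`` is set when
    the orderings differ between pathways (functional selectivity, which
    requires more than one active state of the receptor).
    """
    pathways = sorted({p for (_l, p) in summaries})
    order = {}
    for p in pathways:
        ligs = [l for (l, q) in summaries if q == p]
        ligs.sort(key=lambda l: (summaries[(l, p)].potency, summaries[(l, p)].efficacy), reverse=True)
        order[p] = ligs
    inverse = {(l, p) for (l, p), s in summaries.items() if s.inverse}
    selective = len({tuple(v) for v in order.values()}) > 1 or any(
        ((l, p) in inverse) != ((l, q) in inverse)
        for (l, p) in summaries
        for q in pathways
        if (l, q) in summaries
    )
    return {"order": order, "selective": selective, "inverse_agonists": inverse}
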