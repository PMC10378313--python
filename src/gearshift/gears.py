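"""Optimal gear selection: continuous ("variomatic") and discrete strategies.

At fixed coupling q and force ratio X the normalized ATP synthesis flux
``q*Z - Z**2*X`` is a downward parabola in the phenomenological
stoichiometry Z, maximised at Z = q/(2X) with value q**2/(4X).  A regulator
that tracks this optimum continuously ("variomatic" gear shifting)
dominates every fixed-Z pathway.

A cell restricted to a discrete set of gears (fixed stoichiometries n, each
a single fully coupled pathway with flux ``n*(1 - n*X)`` in normalized
units) should instead run only the gear with the highest flux at the
current X and switch at the crossing points: consecutive gears n < m give
equal flux at X = 1/(n+m).  Ties are broken toward the lower gear, which is
the safer boundary convention — the higher gear reverses into ATP
hydrolysis sooner, opening a futile cycle.

For a dual-pathway mosaic system the whole family of capacity splits shares
one intersection point: the total flux is affine in the split fraction phi,
and the phi-coefficient vanishes at X* = 1/(n1+n2), where every split
yields flux n1*n2/(n1+n2).  Beyond X* the flux ordering in phi inverts, so
an organism free to retune its capacities should jump straight from the
high gear to the low gear at X*.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .phenomenological import PhenomenologicalParams, phenomenological_fluxes

__all__ = [
    "GearSet",
    "GearSchedule",
    "NoCrossoverError",
    "variomatic_Z",
    "variomatic_flux",
    "best_discrete_gear",
    "gear_switch_points",
    "dual_pathway_intersection",
    "parallel_vs_best_single_crossover",
]


@dataclass(frozen=True)
class GearSet:
    """Candidate stoichiometries, strictly increasing, length >= 1."""

    gears: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gears", tuple(self.gears))
        if len(self.gears) < 1:
            raise ValueError("gear set must contain at least one gear")
        if any(g < 0 for g in self.gears):
            raise ValueError("gears must be non-negative")
        if any(b <= a for a, b in zip(self.gears, self.gears[1:])):
            raise ValueError("gears must be strictly increasing")


@dataclass(frozen=True)
class GearSchedule:
    """Partition of (0, x_max] into intervals with the optimal gear on each.

    ``breakpoints`` are the interior switch points (strictly increasing);
    ``selected_gears`` lists the optimal gear per interval, one more entry
    than breakpoints, ordered from X=0 upward (highest gear first).  At
    each breakpoint the two adjacent gears give equal flux,
    ``breakpoint_fluxes``; the lower gear owns the breakpoint itself.
    """

    breakpoints: tuple[float, ...]
    selected_gears: tuple[float, ...]
    breakpoint_fluxes: tuple[float, ...]
    x_max: float

    def intervals(self) -> list[tuple[float, float, float]]:
        """List of (start, end, gear) tuples tiling (0, x_max]."""
        edges = (0.0,) + self.breakpoints + (self.x_max,)
        return [
            (edges[k], edges[k + 1], g)
            for k, g in enumerate(self.selected_gears)
        ]

    def gear_at(self, x: float) -> float:
        """Optimal gear at force ratio x (lower gear at exact breakpoints)."""
        for b, g in zip(self.breakpoints, self.selected_gears):
            if x < b:
                return g
        return self.selected_gears[-1]


class NoCrossoverError(ValueError):
    """Parallel operation never loses to the best single pathway."""


def variomatic_Z(q: float, x: float) -> float:
    """Stoichiometry Z = q/(2X) maximising ATP synthesis at fixed q and X.

    Raises
    ------
    ValueError
        At X = 0, where the optimum is unbounded.
    """
    if not x > 0:
        raise ValueError(f"force ratio must be > 0 (unbounded optimum at 0), got {x}")
    return q / (2.0 * x)


def variomatic_flux(
    q: float, x: float, capacity: float = 1.0, gibbs_c: float = 1.0
) -> float:
    """ATP synthesis flux L*dGc*q**2/(4X) at the variomatic optimum Z.

    This is the upper envelope of the fixed-Z fluxes: it equals the
    phenomenological flux at Z = q/(2X) and exceeds it at every other Z.
    """
    if not x > 0:
        raise ValueError(f"force ratio must be > 0, got {x}")
    return capacity * gibbs_c * q * q / (4.0 * x)


def _gear_flux(n: float, x: float) -> float:
    # normalized single fully-coupled pathway: -Jp/(L*dGc) = n*(1 - n*X)
    return n * (1.0 - n * x)


def best_discrete_gear(gears: GearSet, x: float) -> tuple[float, float]:
    """Gear with the highest normalized ATP synthesis flux n*(1-n*X) at x.

    Returns ``(gear, flux)``.  Exact ties go to the lower gear.
    """
    best_n = gears.gears[0]
    best_f = _gear_flux(best_n, x)
    for n in gears.gears[1:]:
        f = _gear_flux(n, x)
        if f > best_f:
            best_n, best_f = n, f
    return best_n, best_f


def gear_switch_points(gears: GearSet, x_max: float = 1.0) -> GearSchedule:
    """Optimal discrete gear schedule over (0, x_max].

    Consecutive gears n < m exchange optimality at X = 1/(n+m) (closed
    form from n*(1-n*X) = m*(1-m*X)); since the pairwise crossing points
    of this family are ordered, the upper envelope visits every gear in
    descending order as X grows.
    """
    gs = gears.gears
    if len(gs) == 1:
        return GearSchedule(
            breakpoints=(),
            selected_gears=(gs[0],),
            breakpoint_fluxes=(),
            x_max=x_max,
        )
    descending = tuple(reversed(gs))
    breakpoints = []
    fluxes = []
    for hi, lo in zip(descending, descending[1:]):
        b = 1.0 / (hi + lo)
        breakpoints.append(b)
        fluxes.append(_gear_flux(lo, b))
    # drop gears whose interval starts at or beyond x_max
    keep = [k for k, b in enumerate(breakpoints) if b < x_max]
    breakpoints = [breakpoints[k] for k in keep]
    fluxes = [fluxes[k] for k in keep]
    selected = descending[: len(breakpoints) + 1]
    return GearSchedule(
        breakpoints=tuple(breakpoints),
        selected_gears=selected,
        breakpoint_fluxes=tuple(fluxes),
        x_max=x_max,
    )


def dual_pathway_intersection(n1: float, n2: float) -> tuple[float, float]:
    """Common intersection of the capacity-split family of flux curves.

    For two stoichiometries n1 != n2 (both > 0) the normalized total flux
    ``(1-phi)*n1*(1-n1*X) + phi*n2*(1-n2*X)`` is affine in phi; its
    phi-coefficient vanishes at X* = 1/(n1+n2), where the flux equals
    n1*n2/(n1+n2) for every phi.  Returns ``(X*, flux*)``.
    """
    if n1 == n2:
        raise ValueError("n1 = n2: the whole family coincides, no unique intersection")
    if not (n1 > 0 and n2 > 0):
        raise ValueError("stoichiometries must be > 0")
    x_star = 1.0 / (n1 + n2)
    return x_star, n1 * n2 / (n1 + n2)


def parallel_vs_best_single_crossover(
    params_list: list[PhenomenologicalParams],
    gibbs_c: float = 1.0,
    x_max: float = 2.0,
) -> float:
    """Force ratio at which parallel operation stops beating the best gear.

    The summed ATP synthesis flux of all pathways starts above the best
    individual flux (each extra pathway adds synthesis at low X) but
    decays faster, because high-stoichiometry pathways reverse into ATP
    hydrolysis and create a futile cycle.  Returns the smallest X > 0 at
    which the sum equals the pointwise maximum of the individual fluxes;
    below it the sum is strictly greater.

    Both the sum and the maximum are piecewise affine, so each segment of
    the upper envelope is solved exactly; no grid sampling is involved.

    Raises
    ------
    NoCrossoverError
        If the sum never meets the (still synthesising) best individual
        in (0, x_max] — e.g. identical pathways, where the sum is a fixed
        multiple of each individual flux.
    """
    if len(params_list) < 2:
        raise ValueError("need at least two pathways to compare parallel vs single")
    # individual fluxes: f_k(X) = a_k - b_k * X
    lines = []
    for p in params_list:
        scale = p.capacity * gibbs_c
        lines.append(
            (scale * p.coupling_q * p.stoichiometry_Z, scale * p.stoichiometry_Z**2)
        )
    sum_a = math.fsum(a for a, _ in lines)
    sum_b = math.fsum(b for _, b in lines)
    flux_scale = max(abs(a) for a, _ in lines) or 1.0

    # segment boundaries of the upper envelope: pairwise crossings in (0, x_max)
    cuts = {0.0, x_max}
    for (a1, b1), (a2, b2) in itertools.combinations(lines, 2):
        if b1 != b2:
            xc = (a1 - a2) / (b1 - b2)
            if 0.0 < xc < x_max:
                cuts.add(xc)
    edges = sorted(cuts)

    eps = 1e-12
    for lo, hi in zip(edges, edges[1:]):
        mid = 0.5 * (lo + hi)
        a, b = max(lines, key=lambda ab: ab[0] - ab[1] * mid)
        if sum_b == b:
            continue  # parallel: never meet on this segment
        x0 = (sum_a - a) / (sum_b - b)
        if lo - eps <= x0 <= hi + eps and x0 > eps:
            best_at_x0 = a - b * x0
            # require the best single pathway to still be synthesising:
            # a meeting where everything has already reversed (both sides
            # zero or negative) is not a meaningful crossover
            if best_at_x0 > 1e-9 * flux_scale:
                return x0
    raise NoCrossoverError(
        "parallel operation never crosses the best single pathway on (0, x_max]"
    )
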