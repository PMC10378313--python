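"""Black-box (phenomenological) description of the transducer.

Classical linear non-equilibrium thermodynamics describes a two-flux energy
transducer by three parameters: a catalytic capacity L, a phenomenological
stoichiometry Z, and a degree of coupling q in [0, 1]:

    Jc  = L * dGc * (1 - q*Z*X)
    -Jp = L * dGc * (q*Z - Z**2 * X)

A mosaic system with weighted pathway stoichiometries maps exactly onto this
form with

    Z = sqrt(sum_i w_i n_i**2 + leak),      q = nu / Z,

so q*Z equals the weighted-average stoichiometry nu.  The Cauchy-Schwarz
inequality gives 0 <= q <= 1, with q = 1 exactly when there is no leak and
all pathways carrying capacity share a single stoichiometry.  Incomplete
coupling (q < 1) therefore arises in two distinct ways: specific uncoupling
(leak > 0), or two gears operating at once (a futile cycle at high force
ratio, where the high-stoichiometry pathway reverses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import TransducerSystem

__all__ = [
    "PhenomenologicalParams",
    "weighted_stoichiometry",
    "to_phenomenological",
    "phenomenological_fluxes",
    "phenomenological_flux_ratio",
]


@dataclass(frozen=True)
class PhenomenologicalParams:
    """Phenomenological (black-box) transducer parameters.

    May be constructed directly — no mosaic origin is required; fixing q
    and varying Z across pathways is the standard way to compare gears at
    equal coupling.

    Attributes
    ----------
    stoichiometry_Z : float
        Phenomenological stoichiometry Z >= 0.
    coupling_q : float
        Degree of coupling, 0 <= q <= 1.
    capacity : float
        Catalytic capacity L > 0.
    """

    stoichiometry_Z: float
    coupling_q: float
    capacity: float = 1.0

    def __post_init__(self) -> None:
        if not self.stoichiometry_Z >= 0:
            raise ValueError(f"Z must be >= 0, got {self.stoichiometry_Z}")
        if not 0.0 <= self.coupling_q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.coupling_q}")
        if not self.capacity > 0:
            raise ValueError(f"capacity must be > 0, got {self.capacity}")

    @property
    def nu(self) -> float:
        """Weighted-average stoichiometry, nu = q * Z."""
        return self.coupling_q * self.stoichiometry_Z


def weighted_stoichiometry(system: TransducerSystem) -> float:
    """Capacity-weighted mean ATP stoichiometry nu = sum_i w_i n_i."""
    return system.nu


def to_phenomenological(system: TransducerSystem) -> PhenomenologicalParams:
    """Map a mosaic system to its equivalent (Z, q, L) description.

    The mapping is exact: the phenomenological flux equations evaluated at
    the returned parameters reproduce the mosaic totals for every force
    ratio.  Z is the root-mean-square stoichiometry (leak included under
    the root); q = nu/Z.

    Raises
    ------
    ValueError
        If the system is degenerate (all stoichiometries zero and no
        leak), where Z = 0 and q is undefined.
    """
    z_sq = system.second_moment
    if z_sq == 0.0:
        raise ValueError(
            "degenerate system: all stoichiometries zero with no leak (Z = 0)"
        )
    z = math.sqrt(z_sq)
    return PhenomenologicalParams(
        stoichiometry_Z=z,
        coupling_q=system.nu / z,
        capacity=system.capacity,
    )


def phenomenological_fluxes(
    params: PhenomenologicalParams, gibbs_c: float, x: float
) -> tuple[float, float]:
    """Catabolic and ATP-synthesis fluxes of the black-box transducer.

    Returns ``(jc, jp)`` with jp synthesis-positive:
    ``jc = L*dGc*(1 - q*Z*X)`` and ``jp = L*dGc*(q*Z - Z**2*X)``.
    """
    if not gibbs_c > 0:
        raise ValueError(f"gibbs_c must be > 0, got {gibbs_c}")
    scale = params.capacity * gibbs_c
    z = params.stoichiometry_Z
    q = params.coupling_q
    jc = scale * (1.0 - q * z * x)
    jp = scale * (q * z - z * z * x)
    return jc, jp


def phenomenological_flux_ratio(
    params: PhenomenologicalParams, x: float
) -> float | None:
    """Flux-ratio stoichiometry n(X) = Z*(q - Z*X) / (1 - q*Z*X).

    Equals jp/jc from :func:`phenomenological_fluxes`; starts at
    n(0) = q*Z = nu and decreases with X.  ``None`` at the singular point
    X = 1/(q*Z) where the catabolic flux vanishes.
    """
    z = params.stoichiometry_Z
    q = params.coupling_q
    denom = 1.0 - q * z * x
    if abs(denom) <= 1e-12:
        return None
    return z * (q - z * x) / denom
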