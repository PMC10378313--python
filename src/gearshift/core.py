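"""Mosaic non-equilibrium thermodynamic model of catabolic ATP synthesis.

The model describes a free-energy transducer in which K parallel catabolic
pathways, each fully coupled to ATP synthesis with its own stoichiometry
``n_i`` (ATP made per unit catabolic flux), share a total catalytic capacity
``L``.  Each pathway obeys a proportional flux–force relation: its catabolic
flux is ``w_i * L * dGc * (1 - n_i * X)`` where ``dGc > 0`` is the Gibbs
energy drop of catabolism, ``w_i`` the pathway's capacity fraction, and
``X = dGp / dGc`` the dimensionless force ratio of the counteracting Gibbs
energy of ATP synthesis to the driving Gibbs energy of catabolism.  An
optional catabolism-independent ATP leak (specific uncoupling, e.g. proton
leak or maintenance) hydrolyses ATP at rate ``leak * L * dGc * X``.

Because every relation is affine in X, all critical force ratios (stall of
ATP synthesis, reversal of catabolism) have closed forms, which this module
uses directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Pathway",
    "TransducerSystem",
    "FluxState",
    "force_ratio",
    "pathway_catabolic_flux",
    "pathway_atp_flux",
    "leak_flux",
    "total_fluxes",
    "flux_ratio_stoichiometry",
    "stall_force_ratio",
    "catabolic_reversal_force_ratio",
]

#: relative tolerance used to decide that a total catabolic flux is zero,
#: i.e. that the flux-ratio stoichiometry n(X) = -Jp/Jc is undefined.
_SINGULAR_RTOL = 1e-12


@dataclass(frozen=True)
class Pathway:
    """One coupled catabolic route.

    Parameters
    ----------
    stoichiometry : float
        ATP produced per unit catabolic flux (n_i >= 0). Real-valued;
        integer "gears" are a constraint imposed only by the discrete
        optimiser, not by the flux model.
    weight : float
        Fraction of the total catalytic capacity carried by this pathway,
        in [0, 1]. For the classic two-pathway system these are
        (1 - phi, phi).
    """

    stoichiometry: float
    weight: float

    def __post_init__(self) -> None:
        if not self.stoichiometry >= 0:
            raise ValueError(f"stoichiometry must be >= 0, got {self.stoichiometry}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class TransducerSystem:
    """A mosaic transducer: weighted parallel pathways plus an uncoupled leak.

    Parameters
    ----------
    pathways : tuple of Pathway
        Ordered, length K >= 1; weights must sum to 1 (tolerance 1e-12).
    capacity : float
        Total catabolic catalytic capacity L > 0.
    gibbs_catabolic : float
        Gibbs energy drop of catabolism dGc > 0 (substrates minus products).
    leak : float
        Dimensionless specific-uncoupling coefficient lambda = Lpl / L >= 0.
    """

    pathways: tuple[Pathway, ...]
    capacity: float = 1.0
    gibbs_catabolic: float = 1.0
    leak: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathways", tuple(self.pathways))
        if len(self.pathways) < 1:
            raise ValueError("at least one pathway is required")
        wsum = math.fsum(p.weight for p in self.pathways)
        if abs(wsum - 1.0) > 1e-12:
            raise ValueError(f"pathway weights sum to {wsum!r}, expected 1")
        if not self.capacity > 0:
            raise ValueError(f"capacity must be > 0, got {self.capacity}")
        if not self.gibbs_catabolic > 0:
            raise ValueError(
                f"gibbs_catabolic must be > 0, got {self.gibbs_catabolic}"
            )
        if not self.leak >= 0:
            raise ValueError(f"leak must be >= 0, got {self.leak}")

    @classmethod
    def two_pathway(
        cls,
        phi: float,
        n1: float,
        n2: float,
        capacity: float = 1.0,
        gibbs_catabolic: float = 1.0,
        leak: float = 0.0,
    ) -> "TransducerSystem":
        """Classic dual-pathway system: capacity split (1 - phi, phi).

        ``phi`` is the fraction of total capacity in the second pathway
        (stoichiometry ``n2``); the first pathway (``n1``) gets ``1 - phi``.
        """
        return cls(
            pathways=(Pathway(n1, 1.0 - phi), Pathway(n2, phi)),
            capacity=capacity,
            gibbs_catabolic=gibbs_catabolic,
            leak=leak,
        )

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(p.weight for p in self.pathways)

    @property
    def stoichiometries(self) -> tuple[float, ...]:
        return tuple(p.stoichiometry for p in self.pathways)

    @property
    def nu(self) -> float:
        """Capacity-weighted mean stoichiometry nu = sum_i w_i n_i."""
        return math.fsum(p.weight * p.stoichiometry for p in self.pathways)

    @property
    def second_moment(self) -> float:
        """sum_i w_i n_i**2 + leak — the slope coefficient of the total
        ATP synthesis flux in X (and the square of the phenomenological
        stoichiometry Z)."""
        return (
            math.fsum(p.weight * p.stoichiometry**2 for p in self.pathways)
            + self.leak
        )


@dataclass(frozen=True)
class FluxState:
    """All fluxes and derived quantities of a system at one force ratio.

    ATP fluxes are synthesis-positive (the negative of the thermodynamic
    ATP flux Jp, which counts hydrolysis as positive).  ``jp_leak`` is the
    ATP hydrolysed per unit time by the uncoupled leak; it is already
    subtracted from ``jp_total``.

    ``flux_ratio_stoichiometry`` (n = -Jp/Jc) and ``efficiency``
    (eta = n * X) are ``None`` at the singular force ratio X = 1/nu where
    the catabolic flux vanishes.  ``reverse_operation`` marks force ratios
    beyond catabolic reversal (X > 1/nu), where ATP hydrolysis would drive
    catabolism backwards.
    """

    force_ratio: float
    jc_per_pathway: tuple[float, ...]
    jc_total: float
    jp_per_pathway: tuple[float, ...]
    jp_leak: float
    jp_total: float
    flux_ratio_stoichiometry: float | None
    efficiency: float | None
    reverse_operation: bool = field(default=False)


def force_ratio(gibbs_p: float, gibbs_c: float) -> float:
    """Force ratio X = dGp / dGc of output to input Gibbs energy.

    Raises
    ------
    ValueError
        If ``gibbs_c`` is not strictly positive (the model's sign
        convention requires a positive catabolic driving force).
    """
    if not gibbs_c > 0:
        raise ValueError(f"gibbs_c must be > 0, got {gibbs_c}")
    return gibbs_p / gibbs_c


def _check_index(system: TransducerSystem, i: int) -> None:
    if not 0 <= i < len(system.pathways):
        raise IndexError(
            f"pathway index {i} out of range for {len(system.pathways)} pathways"
        )


def pathway_catabolic_flux(system: TransducerSystem, i: int, x: float) -> float:
    """Catabolic flux through pathway i: ``w_i * L * dGc * (1 - n_i * X)``.

    Negative values mean the pathway runs in reverse (driven backwards by
    the ATP potential).
    """
    _check_index(system, i)
    p = system.pathways[i]
    return (
        p.weight
        * system.capacity
        * system.gibbs_catabolic
        * (1.0 - p.stoichiometry * x)
    )


def pathway_atp_flux(system: TransducerSystem, i: int, x: float) -> float:
    """ATP synthesis flux of pathway i (synthesis-positive).

    Equals ``n_i`` times the pathway's catabolic flux; negative when the
    pathway has reversed into ATP hydrolysis.
    """
    _check_index(system, i)
    return system.pathways[i].stoichiometry * pathway_catabolic_flux(system, i, x)


def leak_flux(system: TransducerSystem, x: float) -> float:
    """ATP hydrolysed per unit time by the uncoupled leak: ``leak*L*dGc*X``."""
    return system.leak * system.capacity * system.gibbs_catabolic * x


def total_fluxes(system: TransducerSystem, x: float) -> FluxState:
    """Evaluate every flux of the system at force ratio ``x``.

    Totals use the closed affine forms
    ``Jc = L*dGc*(1 - nu*X)`` and
    ``-Jp = L*dGc*(nu - (sum_i w_i n_i^2 + leak)*X)``,
    which equal the sums of the per-pathway relations exactly.
    """
    if x < 0:
        raise ValueError(f"force ratio must be >= 0, got {x}")
    scale = system.capacity * system.gibbs_catabolic
    nu = system.nu
    jc_i = tuple(pathway_catabolic_flux(system, i, x) for i in range(len(system.pathways)))
    jp_i = tuple(pathway_atp_flux(system, i, x) for i in range(len(system.pathways)))
    jpl = leak_flux(system, x)
    jc_total = scale * (1.0 - nu * x)
    jp_total = scale * (nu - system.second_moment * x)
    if abs(jc_total) <= _SINGULAR_RTOL * scale:
        n = None
        eta = None
    else:
        n = jp_total / jc_total
        eta = n * x
    reverse = nu > 0 and x > 1.0 / nu and n is not None
    return FluxState(
        force_ratio=x,
        jc_per_pathway=jc_i,
        jc_total=jc_total,
        jp_per_pathway=jp_i,
        jp_leak=jpl,
        jp_total=jp_total,
        flux_ratio_stoichiometry=n,
        efficiency=eta,
        reverse_operation=reverse,
    )


def flux_ratio_stoichiometry(system: TransducerSystem, x: float) -> float | None:
    """Flux-ratio stoichiometry n(X) = -Jp/Jc, the realized "gear setting".

    At X = 0 this equals nu; it decreases with X (strictly, whenever the
    active stoichiometries differ or the leak is positive) and is ``None``
    at the singular point X = 1/nu where catabolism stalls.
    """
    return total_fluxes(system, x).flux_ratio_stoichiometry


def stall_force_ratio(system: TransducerSystem) -> float:
    """Force ratio at which total ATP synthesis stalls (crosses zero).

    Closed form ``nu / (sum_i w_i n_i^2 + leak)``.  Beyond this point the
    transducer wastes catabolic Gibbs energy while net-hydrolysing ATP.

    Raises
    ------
    ValueError
        If nu = 0 (no coupled synthesis, so no stall point).
    """
    nu = system.nu
    if nu <= 0:
        raise ValueError("system has nu = 0: no ATP synthesis, no stall point")
    return nu / system.second_moment


def catabolic_reversal_force_ratio(system: TransducerSystem) -> float:
    """Force ratio 1/nu at which the total catabolic flux crosses zero.

    At and beyond this point ATP hydrolysis would drive catabolism in
    reverse.  Always larger than the stall force ratio when two distinct
    stoichiometries are active or the leak is positive.

    Raises
    ------
    ValueError
        If nu = 0 (catabolism never reverses).
    """
    nu = system.nu
    if nu <= 0:
        raise ValueError("system has nu = 0: catabolism never reverses")
    return 1.0 / nu
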