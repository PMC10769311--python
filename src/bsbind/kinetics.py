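"""Reaction network and rate-constant algebra for bivalent antibody binding.

The model describes IgG-type bivalent antibodies — the monospecific
antibodies tocilizumab (anti-IL-6R, two identical arms) and 10H2
(anti-IL-8R), and the bispecific antibody BS1 (one anti-IL-6R arm, one
anti-IL-8R arm) — binding to receptors on the surface of cultured cells.
Binding proceeds in two steps: a solution-phase antibody arm first captures
a receptor (binary complex, Ab·R), after which the tethered antibody may
cross-link a second receptor on the same cell (ternary complex, R·Ab·R).

Units convention
----------------
Free antibody is tracked in nM (a solution concentration); receptors and
all cell-surface complexes are tracked in receptors/cell.  First-step
association rate constants therefore carry nM⁻¹s⁻¹, cross-linking rate
constants carry (receptors/cell)⁻¹s⁻¹, and the two unit systems are bridged
by the conversion factor

    alpha = cells_per_well * 1e9 / (N_A * well_volume)   [nM per (#/cell)]

so that depleting one surface complex per cell removes ``alpha`` nM of
antibody from the medium.

Thermodynamic cycle
-------------------
For a bispecific antibody the four reversible reactions

    Ab + R1 <-> Ab·R1        (kon_R1 / koff_R1)
    Ab + R2 <-> Ab·R2        (kon_R2 / koff_R2)
    Ab·R2 + R1 <-> R1·Ab·R2  (kon_R1* / koff_R1*)
    Ab·R1 + R2 <-> R1·Ab·R2  (kon_R2* / koff_R2*)

form a closed cycle, so detailed balance forces the product of equilibrium
constants around the cycle to one.  Together with the assumption that
dissociation is the same for the first and second binding step of a given
receptor (koff_R = koff_R*), this leaves five free parameters —
kon_6R, kon_8R, kon_6R*, koff_6R, koff_8R — and makes kon_8R* derived:

    chi = kon_6R* / (alpha * kon_6R) = kon_8R* / (alpha * kon_8R)

where chi is the dimensionless cross-arm binding efficiency (the fold
acceleration of the tethered second-arm association over the first-arm
association in common units).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AVOGADRO",
    "IL6R",
    "IL8R",
    "UnitContext",
    "ReceptorSpecies",
    "AntibodySpec",
    "RateConstantSet",
    "EquilibriumTable",
    "Reaction",
    "ReactionNetwork",
    "make_unit_context",
    "complete_rates",
    "detailed_balance_residual",
    "equilibrium_table",
    "restrict_monovalent",
    "build_network",
    "rhs",
    "REFERENCE_RATES",
    "DEFAULT_UNIT_CONTEXT",
    "HEK293T_LINES",
    "BS1",
    "TOCILIZUMAB",
    "ANTIBODY_10H2",
    "ANTIBODIES",
]

AVOGADRO = 6.022e23  # molecules per mole

IL6R = "IL6R"
IL8R = "IL8R"


class ValidationError(ValueError):
    """Raised for physically inadmissible model inputs."""


# ---------------------------------------------------------------------------
# Unit context
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitContext:
    """Conversion between solution (nM) and surface (receptors/cell) units.

    ``alpha`` is the nM concentration change in the well produced by one
    molecule per cell across ``cells_per_well`` cells in ``well_volume``
    litres of medium.
    """

    cells_per_well: float
    well_volume: float  # litres

    @property
    def alpha(self) -> float:
        """nM per (receptors/cell)."""
        return self.cells_per_well * 1e9 / (AVOGADRO * self.well_volume)


def make_unit_context(cells_per_well: float, well_volume: float) -> UnitContext:
    """Build a :class:`UnitContext`, validating positivity.

    With the assay defaults of 1e5 cells/well in 200 µL this yields
    alpha ≈ 8.3e-7 nM/(receptors/cell).
    """
    if not (cells_per_well > 0 and np.isfinite(cells_per_well)):
        raise ValidationError(f"cells_per_well must be positive, got {cells_per_well}")
    if not (well_volume > 0 and np.isfinite(well_volume)):
        raise ValidationError(f"well_volume must be positive, got {well_volume}")
    return UnitContext(cells_per_well=float(cells_per_well), well_volume=float(well_volume))


DEFAULT_UNIT_CONTEXT = UnitContext(cells_per_well=1e5, well_volume=2e-4)


# ---------------------------------------------------------------------------
# Species and antibody declarations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReceptorSpecies:
    """A cell-surface receptor type with its expression level."""

    name: str
    expression: float  # receptors/cell

    def __post_init__(self) -> None:
        if not (np.isfinite(self.expression) and self.expression >= 0):
            raise ValidationError(
                f"expression for {self.name!r} must be finite and >= 0, got {self.expression}"
            )


@dataclass(frozen=True)
class AntibodySpec:
    """A bivalent antibody identified by its two arm targets.

    Equal arm targets denote a homobivalent monospecific antibody; distinct
    targets denote a bispecific antibody.
    """

    name: str
    arm_targets: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.arm_targets) != 2:
            raise ValidationError("an antibody has exactly two arms")

    @property
    def is_bispecific(self) -> bool:
        return self.arm_targets[0] != self.arm_targets[1]


BS1 = AntibodySpec("BS1", (IL6R, IL8R))
TOCILIZUMAB = AntibodySpec("tocilizumab", (IL6R, IL6R))
ANTIBODY_10H2 = AntibodySpec("10H2", (IL8R, IL8R))
ANTIBODIES = {ab.name: ab for ab in (BS1, TOCILIZUMAB, ANTIBODY_10H2)}

#: Receptor quantification on transduced HEK 293T cell lines (receptors/cell).
HEK293T_LINES: dict[str, dict[str, float]] = {
    "IL6R+": {IL6R: 5.08e5},
    "IL8R+": {IL8R: 1.30e6},
    "IL6R+IL8R+": {IL6R: 3.16e5, IL8R: 6.18e5},
}


def cell_line_receptors(line: str | dict[str, float]) -> list[ReceptorSpecies]:
    """Resolve a named HEK 293T line or an explicit mapping to receptor specs."""
    if isinstance(line, str):
        try:
            line = HEK293T_LINES[line]
        except KeyError:
            raise ValidationError(f"unknown cell line {line!r}") from None
    return [ReceptorSpecies(name, expr) for name, expr in line.items()]


# ---------------------------------------------------------------------------
# Rate constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateConstantSet:
    """The six kinetic rate constants plus the cross-arm efficiency chi.

    ``kon_6R``/``kon_8R`` are first-step association rates (nM⁻¹s⁻¹);
    ``kon_6R_star``/``kon_8R_star`` are cross-linking rates
    ((receptors/cell)⁻¹s⁻¹); ``koff_6R``/``koff_8R`` apply to both the first
    and second dissociation step of their receptor.  Use
    :func:`complete_rates` to construct a thermodynamically consistent set.
    """

    kon_6R: float
    kon_8R: float
    kon_6R_star: float
    kon_8R_star: float
    koff_6R: float
    koff_8R: float
    chi: float
    monovalent_restricted: bool = field(default=False)

    def kon(self, receptor: str) -> float:
        return self.kon_6R if receptor == IL6R else self.kon_8R

    def kon_star(self, receptor: str) -> float:
        return self.kon_6R_star if receptor == IL6R else self.kon_8R_star

    def koff(self, receptor: str) -> float:
        return self.koff_6R if receptor == IL6R else self.koff_8R

    def as_dict(self) -> dict[str, float]:
        return {
            "kon_6R": self.kon_6R,
            "kon_8R": self.kon_8R,
            "kon_6R_star": self.kon_6R_star,
            "kon_8R_star": self.kon_8R_star,
            "koff_6R": self.koff_6R,
            "koff_8R": self.koff_8R,
            "chi": self.chi,
        }


FREE_PARAM_NAMES = ("kon_6R", "kon_8R", "kon_6R_star", "koff_6R", "koff_8R")


def complete_rates(
    kon_6R: float,
    kon_8R: float,
    kon_6R_star: float,
    koff_6R: float,
    koff_8R: float,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
) -> RateConstantSet:
    """Derive the dependent cross-link rate kon_8R* from the cycle constraint.

    chi = kon_6R*/(alpha*kon_6R) is the cross-arm binding efficiency; detailed
    balance around the binding cycle requires the same chi for both receptors,
    so kon_8R* = chi * alpha * kon_8R.
    """
    params = dict(kon_6R=kon_6R, kon_8R=kon_8R, kon_6R_star=kon_6R_star,
                  koff_6R=koff_6R, koff_8R=koff_8R)
    for name, value in params.items():
        if not (np.isfinite(value) and value > 0):
            raise ValidationError(f"{name} must be strictly positive, got {value}")
    chi = kon_6R_star / (ctx.alpha * kon_6R)
    kon_8R_star = chi * ctx.alpha * kon_8R
    return RateConstantSet(
        kon_6R=kon_6R,
        kon_8R=kon_8R,
        kon_6R_star=kon_6R_star,
        kon_8R_star=kon_8R_star,
        koff_6R=koff_6R,
        koff_8R=koff_8R,
        chi=chi,
    )


#: Rate constants calibrated against the HEK 293T flow-cytometry binding assay
#: (best multi-start fit under BS1-saturation normalization).
REFERENCE_RATES = complete_rates(
    kon_6R=5.92e-6,       # nM⁻¹s⁻¹
    kon_8R=9.03e-6,       # nM⁻¹s⁻¹
    kon_6R_star=8.11e-8,  # (receptors/cell)⁻¹s⁻¹
    koff_6R=5.61e-5,      # s⁻¹
    koff_8R=6.38e-5,      # s⁻¹
    ctx=DEFAULT_UNIT_CONTEXT,
)


def detailed_balance_residual(rates: RateConstantSet,
                              ctx: UnitContext = DEFAULT_UNIT_CONTEXT) -> float:
    """K1*K4/(K2*K3) - 1 with every rate expressed in nM units.

    Zero (to round-off) for any set produced by :func:`complete_rates`; the
    magnitude of the residual measures how far a hand-assembled set sits from
    thermodynamic consistency.
    """
    K1 = rates.koff_6R / rates.kon_6R                       # Ab + R1
    K2 = rates.koff_8R / rates.kon_8R                       # Ab + R2
    K3 = rates.koff_6R / (rates.kon_6R_star / ctx.alpha)    # Ab·R2 + R1
    K4 = rates.koff_8R / (rates.kon_8R_star / ctx.alpha)    # Ab·R1 + R2
    return K1 * K4 / (K2 * K3) - 1.0


@dataclass(frozen=True)
class EquilibriumTable:
    """Dissociation equilibrium constants (nM) and cross-arm efficiency."""

    KD_6R: float
    KD_8R: float
    KD_6R_star: float
    KD_8R_star: float
    chi: float

    def as_dict(self) -> dict[str, float]:
        return {"KD_6R": self.KD_6R, "KD_8R": self.KD_8R,
                "KD_6R_star": self.KD_6R_star, "KD_8R_star": self.KD_8R_star,
                "chi": self.chi}


def equilibrium_table(rates: RateConstantSet,
                      ctx: UnitContext = DEFAULT_UNIT_CONTEXT) -> EquilibriumTable:
    """KD = koff/kon per binding step, with cross-link on-rates in nM⁻¹s⁻¹."""
    return EquilibriumTable(
        KD_6R=rates.koff_6R / rates.kon_6R,
        KD_8R=rates.koff_8R / rates.kon_8R,
        KD_6R_star=rates.koff_6R / (rates.kon_6R_star / ctx.alpha),
        KD_8R_star=rates.koff_8R / (rates.kon_8R_star / ctx.alpha),
        chi=rates.chi,
    )


def restrict_monovalent(rates: RateConstantSet) -> RateConstantSet:
    """Copy of ``rates`` with both cross-linking on-rates forced to zero.

    Used to compare bivalent binding against a hypothetical antibody that can
    only form binary complexes; the cycle constraint does not apply to the
    restricted set.
    """
    return replace(rates, kon_6R_star=0.0, kon_8R_star=0.0, chi=0.0,
                   monovalent_restricted=True)


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One reversible mass-action reaction A (+ B) <-> C.

    ``first_association`` marks the solution-phase capture step whose forward
    flux couples nM antibody to receptors/cell (the antibody balance then
    carries the flux scaled by alpha).  ``stat_forward``/``stat_backward``
    are integer statistical factors: 2 on the first association of a
    homobivalent antibody (two equivalent free arms) and 2 on the
    dissociation of its homoternary complex (two equivalent bonds).
    """

    reactant_a: int          # antibody species (first assoc) or binary complex
    reactant_b: int          # receptor species
    product: int             # complex species
    receptor: str            # which receptor's rate constants apply
    first_association: bool
    stat_forward: int = 1
    stat_backward: int = 1


@dataclass(frozen=True)
class ReactionNetwork:
    """Species bookkeeping plus the reversible reaction list for one system.

    ``antibody_content[i]`` maps antibody name -> copies in species i (1 for
    the free antibody and every complex containing it); ``receptor_content``
    does the same per receptor type.  ``is_solution[i]`` is True for species
    tracked in nM (free antibodies), False for surface species.
    """

    species: tuple[str, ...]
    is_solution: tuple[bool, ...]
    antibody_content: tuple[dict[str, int], ...]
    receptor_content: tuple[dict[str, int], ...]
    reactions: tuple[Reaction, ...]
    antibodies: tuple[AntibodySpec, ...]
    receptors: tuple[ReceptorSpecies, ...]

    def index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_state(self, doses_nM: dict[str, float]) -> np.ndarray:
        """State vector at t=0: dosed free antibody + free receptors."""
        y0 = np.zeros(self.n_species)
        for ab in self.antibodies:
            y0[self.index(ab.name)] = float(doses_nM.get(ab.name, 0.0))
        for rec in self.receptors:
            y0[self.index(rec.name)] = rec.expression
        return y0

    def receptor_total(self, y: np.ndarray, receptor: str) -> float:
        """Receptors of one type summed over every species containing them."""
        return float(sum(content.get(receptor, 0) * y[i]
                         for i, content in enumerate(self.receptor_content)))

    def antibody_total_nM(self, y: np.ndarray, antibody: str, alpha: float) -> float:
        """Total antibody (nM equivalent): free + alpha * surface-bound."""
        total = 0.0
        for i, content in enumerate(self.antibody_content):
            n = content.get(antibody, 0)
            if n:
                total += n * y[i] * (1.0 if self.is_solution[i] else alpha)
        return total


def _binary_name(ab: str, rec: str) -> str:
    return f"{ab}.{rec}"


def _ternary_name(r1: str, ab: str, r2: str) -> str:
    return f"{r1}.{ab}.{r2}"


def build_network(
    antibodies: AntibodySpec | Sequence[AntibodySpec],
    cell_line: str | dict[str, float] | Sequence[ReceptorSpecies],
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
) -> ReactionNetwork:
    """Assemble the mass-action network for antibodies on a cell line.

    Arms whose target receptor is absent from the cell line simply never
    bind: the corresponding reactions and complex species are omitted, so a
    bispecific antibody on a single-positive line reduces to one reversible
    monovalent reaction.  A combination of antibodies shares the free
    receptor pools but keeps per-antibody complex species.
    """
    if isinstance(antibodies, AntibodySpec):
        antibodies = [antibodies]
    antibodies = list(antibodies)
    if isinstance(cell_line, (str, dict)):
        receptors = cell_line_receptors(cell_line)
    else:
        receptors = list(cell_line)
    declared = {r.name for r in receptors}
    known = {IL6R, IL8R}
    for ab in antibodies:
        for target in ab.arm_targets:
            if target not in known:
                raise ValidationError(f"unknown receptor {target!r} in antibody {ab.name!r}")
    for r in receptors:
        if r.name not in known:
            raise ValidationError(f"unknown receptor {r.name!r} in cell line")

    species: list[str] = []
    is_solution: list[bool] = []
    ab_content: list[dict[str, int]] = []
    rec_content: list[dict[str, int]] = []

    def add(name: str, solution: bool, abs_: dict[str, int], recs: dict[str, int]) -> int:
        species.append(name)
        is_solution.append(solution)
        ab_content.append(abs_)
        rec_content.append(recs)
        return len(species) - 1

    for ab in antibodies:
        add(ab.name, True, {ab.name: 1}, {})
    for rec in receptors:
        add(rec.name, False, {}, {rec.name: 1})

    reactions: list[Reaction] = []
    index = {name: i for i, name in enumerate(species)}

    for ab in antibodies:
        t1, t2 = ab.arm_targets
        if not ab.is_bispecific:
            rec = t1
            if rec not in declared:
                continue
            b = add(_binary_name(ab.name, rec), False, {ab.name: 1}, {rec: 1})
            t = add(_ternary_name(rec, ab.name, rec), False, {ab.name: 1}, {rec: 2})
            index = {name: i for i, name in enumerate(species)}
            # two equivalent free arms; two equivalent bonds in the homoternary
            reactions.append(Reaction(index[ab.name], index[rec], b, rec,
                                      first_association=True, stat_forward=2))
            reactions.append(Reaction(b, index[rec], t, rec,
                                      first_association=False, stat_backward=2))
        else:
            present = [r for r in (t1, t2) if r in declared]
            binaries: dict[str, int] = {}
            for rec in present:
                binaries[rec] = add(_binary_name(ab.name, rec), False,
                                    {ab.name: 1}, {rec: 1})
            if len(present) == 2:
                t = add(_ternary_name(t1, ab.name, t2), False,
                        {ab.name: 1}, {t1: 1, t2: 1})
            index = {name: i for i, name in enumerate(species)}
            for rec in present:
                reactions.append(Reaction(index[ab.name], index[rec], binaries[rec],
                                          rec, first_association=True))
            if len(present) == 2:
                # cross-linking: Ab·R_other + R -> ternary, governed by R's star rate
                reactions.append(Reaction(binaries[t2], index[t1], t, t1,
                                          first_association=False))
                reactions.append(Reaction(binaries[t1], index[t2], t, t2,
                                          first_association=False))

    return ReactionNetwork(
        species=tuple(species),
        is_solution=tuple(is_solution),
        antibody_content=tuple(ab_content),
        receptor_content=tuple(rec_content),
        reactions=tuple(reactions),
        antibodies=tuple(antibodies),
        receptors=tuple(receptors),
    )


def rhs(
    y: np.ndarray,
    rates: RateConstantSet,
    network: ReactionNetwork,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
    check: bool = False,
) -> np.ndarray:
    """Mass-action time derivative of the state vector.

    Fluxes are in receptors/cell/s; the free-antibody balance scales surface
    fluxes by alpha so total antibody (nM equivalent) is conserved exactly.
    With ``check=True`` a NaN or negative state raises ValidationError
    (integrators probe slightly negative states, so checking is opt-in).
    """
    if check:
        if np.any(~np.isfinite(y)) or np.any(y < 0):
            raise ValidationError("state must be finite and non-negative")
    alpha = ctx.alpha
    dy = np.zeros_like(y)
    for rx in network.reactions:
        if rx.first_association:
            kf = rates.kon(rx.receptor)
        else:
            kf = rates.kon_star(rx.receptor)
        kr = rates.koff(rx.receptor)
        flux = (rx.stat_forward * kf * y[rx.reactant_a] * y[rx.reactant_b]
                - rx.stat_backward * kr * y[rx.product])
        dy[rx.product] += flux
        dy[rx.reactant_b] -= flux
        if rx.first_association:
            dy[rx.reactant_a] -= alpha * flux
        else:
            dy[rx.reactant_a] -= flux
    return dy
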