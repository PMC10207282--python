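"""Physical constants, unit conventions and pKa/free-energy conversions.

All free energies are in kcal/mol. The central quantity is the
solution-phase deprotonation free energy ΔG_aq of

    HA  ->  A- + H+

which relates to the acid dissociation constant through

    ΔG_aq = -RT ln Ka = ln(10) * R * T * pKa

so that ``pKa = ΔG_aq / (ln(10)·R·T)``. At 298.15 K the conversion
factor ln(10)·R·T is about 1.364 kcal/mol per pKa unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE",
    "STANDARD_STATE_CORRECTION",
    "ThermoContext",
    "SpeciesEnergy",
    "ConformerSet",
    "free_energy_to_pka",
    "pka_to_free_energy",
    "pka_to_ka",
    "ka_to_pka",
    "select_conformer",
    "boltzmann_free_energy",
]

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Default absolute temperature (K) for all conversions.
STANDARD_TEMPERATURE = 298.15

#: Free-energy change of compressing an ideal gas from 1 atm to 1 M at
#: 298.15 K (RT ln 24.46), per mole of gas-phase species created.
STANDARD_STATE_CORRECTION = 1.894


class InvalidInputError(ValueError):
    """Raised when an operation receives a non-finite or empty input."""


def _require_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and unit conventions shared by every pKa scheme.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    gas_constant : float
        Gas constant in kcal mol^-1 K^-1.
    standard_state_correction : float
        Free-energy correction (kcal/mol) applied per net mole of
        gas-phase species created, converting the 1 atm gas standard
        state to the 1 M solution standard state. Only used when
        ``apply_standard_state`` is true.
    apply_standard_state : bool
        Whether cycle free energies include the standard-state term.
        Off by default; exposed so its effect can be studied.
    """

    temperature: float = STANDARD_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KCAL
    standard_state_correction: float = STANDARD_STATE_CORRECTION
    apply_standard_state: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise InvalidInputError(
                f"temperature must be positive and finite, got {self.temperature!r}"
            )
        _require_finite(self.gas_constant, "gas_constant")
        _require_finite(self.standard_state_correction, "standard_state_correction")

    @property
    def rt(self) -> float:
        """R·T in kcal/mol."""
        return self.gas_constant * self.temperature

    @property
    def log_conversion(self) -> float:
        """ln(10)·R·T — kcal/mol per pKa unit."""
        return math.log(10.0) * self.rt


@dataclass(frozen=True)
class SpeciesEnergy:
    """Free energies of one chemical species at one level of theory.

    ``g_gas`` is the gas-phase standard free energy and ``dg_solv`` the
    gas-to-solution transfer free energy, both in kcal/mol. ``method_tag``
    and ``solvent_tag`` are opaque labels (e.g. ``"M062X/6-31G**/SMD"``,
    ``"water"``); cycle operations refuse to mix species whose tags
    differ, since the level of theory is never interchangeable.
    """

    species_id: str
    charge_state: int
    g_gas: float
    dg_solv: float
    method_tag: str = "default"
    solvent_tag: str = "water"

    def __post_init__(self) -> None:
        _require_finite(self.g_gas, "g_gas")
        _require_finite(self.dg_solv, "dg_solv")

    @property
    def g_solution(self) -> float:
        """Solution-phase free energy: g_gas + dg_solv."""
        return self.g_gas + self.dg_solv

    def key(self) -> tuple[str, str, str]:
        return (self.species_id, self.method_tag, self.solvent_tag)


@dataclass(frozen=True)
class ConformerSet:
    """Conformers of one species at a single level of theory."""

    species_id: str
    members: tuple[SpeciesEnergy, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        members = tuple(self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise InvalidInputError("ConformerSet must contain at least one member")
        tags = {(m.method_tag, m.solvent_tag) for m in members}
        if len(tags) != 1:
            raise InvalidInputError(
                f"conformers of {self.species_id!r} mix method/solvent tags: {sorted(tags)}"
            )
        for m in members:
            if m.species_id != self.species_id:
                raise InvalidInputError(
                    f"member {m.species_id!r} does not belong to {self.species_id!r}"
                )


def free_energy_to_pka(dg_aq: float, ctx: ThermoContext | None = None) -> float:
    """Convert a solution deprotonation free energy (kcal/mol) to a pKa."""
    ctx = ctx or ThermoContext()
    return _require_finite(dg_aq, "dg_aq") / ctx.log_conversion


def pka_to_free_energy(pka: float, ctx: ThermoContext | None = None) -> float:
    """Inverse of :func:`free_energy_to_pka`."""
    ctx = ctx or ThermoContext()
    return _require_finite(pka, "pka") * ctx.log_conversion


def pka_to_ka(pka: float) -> float:
    """Equilibrium constant Ka = 10^(-pKa)."""
    return 10.0 ** (-_require_finite(pka, "pka"))


def ka_to_pka(ka: float) -> float:
    """pKa = -log10(Ka); requires Ka > 0."""
    ka = _require_finite(ka, "ka")
    if ka <= 0:
        raise InvalidInputError(f"ka must be positive, got {ka!r}")
    return -math.log10(ka)


def boltzmann_free_energy(
    energies: Sequence[float] | Iterable[float], ctx: ThermoContext | None = None
) -> float:
    """Effective free energy -RT·ln Σ exp(-G_i/RT) of a conformer ensemble.

    Always lies in [G_min - RT·ln n, G_min]. Computed with a shifted
    log-sum-exp so large energies do not overflow.
    """
    ctx = ctx or ThermoContext()
    values = [_require_finite(g, "energy") for g in energies]
    if not values:
        raise InvalidInputError("empty energy list")
    g_min = min(values)
    rt = ctx.rt
    acc = sum(math.exp(-(g - g_min) / rt) for g in values)
    return g_min - rt * math.log(acc)


def select_conformer(
    conformers: ConformerSet,
    mode: Literal["lowest", "boltzmann"] = "lowest",
    ctx: ThermoContext | None = None,
) -> SpeciesEnergy:
    """Reduce a conformer ensemble to a single representative species.

    ``lowest`` (default) keeps the member with the minimal total free
    energy g_gas + dg_solv, matching the usual practice of carrying only
    the most stable conformer forward. ``boltzmann`` returns a species
    carrying the ensemble effective free energy -RT·ln Σ exp(-G_i/RT),
    assigned to the gas term of the lowest member (dg_solv adjusted so
    the total equals the effective energy).
    """
    ctx = ctx or ThermoContext()
    best = min(conformers.members, key=lambda m: m.g_solution)
    if mode == "lowest":
        return best
    if mode == "boltzmann":
        g_eff = boltzmann_free_energy([m.g_solution for m in conformers.members], ctx)
        return SpeciesEnergy(
            species_id=best.species_id,
            charge_state=best.charge_state,
            g_gas=best.g_gas,
            dg_solv=g_eff - best.g_gas,
            method_tag=best.method_tag,
            solvent_tag=best.solvent_tag,
        )
    raise InvalidInputError(f"unknown conformer mode {mode!r}")
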