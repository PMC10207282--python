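"""The four pKa schemes: direct, TC1, TC2 and isodesmic.

All four express the solution deprotonation free energy of HA -> A + H+
(products minus reactants) and convert it with pKa = ΔG_aq / ln(10)RT.

* **direct** sums solution free energies, taking the proton's solution
  free energy as a single user-supplied number.
* **TC1** closes a thermodynamic cycle through the gas phase with a bare
  proton: ΔG_aq = ΔG_gas + ΔΔG_solv, where the proton contributes its
  gas-phase free energy and an empirical solvation free energy
  (conventionally between -265.9 and -270.3 kcal/mol — the dominant
  source of uncertainty in the scheme).
* **TC2** replaces the bare proton with the H2O/H3O+ pair, so the
  ill-defined proton terms drop out in favour of two computable species.
* **isodesmic** references a proton exchange HA + B -> A + HB against a
  molecule HB of known pKa; only solution free energies enter, so
  systematic errors shared by query and reference cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .core_thermo import (
    InvalidInputError,
    SpeciesEnergy,
    ThermoContext,
    _require_finite,
)

__all__ = [
    "PROTON_GAS_FREE_ENERGY",
    "PROTON_SOLVATION_PRESETS",
    "WATER_MOLARITY",
    "ProtonParameters",
    "AcidBasePair",
    "WaterPairParameters",
    "IsodesmicReference",
    "ConsistencyError",
    "InvalidPairError",
    "direct_pka",
    "tc1_pka",
    "tc2_pka",
    "isodesmic_pka",
]

#: Gas-phase free energy of the proton (kcal/mol) at 298.15 K, 1 atm,
#: from the Sackur-Tetrode translational partition function.
PROTON_GAS_FREE_ENERGY = -6.287

#: Named conventions for the proton solvation free energy (kcal/mol).
PROTON_SOLVATION_PRESETS: dict[str, float] = {
    "minus_265_9": -265.9,
    "minus_270_3": -270.3,
}

#: Molarity of pure water at 25 C, used by the optional TC2 correction.
WATER_MOLARITY = 55.34


class ConsistencyError(ValueError):
    """Species combined across different method or solvent tags."""


class InvalidPairError(ValueError):
    """Acid/base pair violating the charge-state contract."""


@dataclass(frozen=True)
class ProtonParameters:
    """Free-energy conventions for the bare proton used by TC1.

    ``preset_label`` pins ``dg_solv_proton`` to one of the two common
    literature conventions; ``custom`` leaves both fields free.
    """

    dg_solv_proton: float = PROTON_SOLVATION_PRESETS["minus_265_9"]
    g_gas_proton: float = PROTON_GAS_FREE_ENERGY
    preset_label: Literal["minus_265_9", "minus_270_3", "custom"] = "minus_265_9"

    def __post_init__(self) -> None:
        _require_finite(self.dg_solv_proton, "dg_solv_proton")
        _require_finite(self.g_gas_proton, "g_gas_proton")
        expected = PROTON_SOLVATION_PRESETS.get(self.preset_label)
        if expected is not None and self.dg_solv_proton != expected:
            raise InvalidInputError(
                f"preset {self.preset_label!r} fixes dg_solv_proton = {expected}, "
                f"got {self.dg_solv_proton}"
            )

    @classmethod
    def from_preset(cls, label: str, g_gas_proton: float = PROTON_GAS_FREE_ENERGY):
        if label not in PROTON_SOLVATION_PRESETS:
            raise InvalidInputError(
                f"unknown proton preset {label!r}; "
                f"choose from {sorted(PROTON_SOLVATION_PRESETS)}"
            )
        return cls(
            dg_solv_proton=PROTON_SOLVATION_PRESETS[label],
            g_gas_proton=g_gas_proton,
            preset_label=label,  # type: ignore[arg-type]
        )


def _check_tags(*species: SpeciesEnergy) -> None:
    tags = {(s.method_tag, s.solvent_tag) for s in species}
    if len(tags) != 1:
        raise ConsistencyError(
            f"species mix method/solvent tags: {sorted(tags)} "
            f"(ids: {[s.species_id for s in species]})"
        )


@dataclass(frozen=True)
class AcidBasePair:
    """A protonated species and its conjugate base.

    The acid must carry exactly one more positive charge than the base
    (HA/A- for neutral acids, HA+/A for cationic ones); both members
    must share level-of-theory and solvent tags.
    """

    acid: SpeciesEnergy
    base: SpeciesEnergy
    site_label: str = ""

    def __post_init__(self) -> None:
        if self.acid.charge_state != self.base.charge_state + 1:
            raise InvalidPairError(
                f"acid {self.acid.species_id!r} charge {self.acid.charge_state} must be "
                f"base {self.base.species_id!r} charge {self.base.charge_state} + 1"
            )
        _check_tags(self.acid, self.base)


@dataclass(frozen=True)
class WaterPairParameters:
    """H2O/H3O+ species for TC2, with the optional -log10[H2O] term.

    ``water_concentration_correction`` subtracts log10(55.34) from the
    raw pKa to move water from its pure-liquid to a 1 M standard state.
    Off by default, and never applied for non-aqueous solvents where the
    pair is treated as ordinary solutes.
    """

    water: SpeciesEnergy
    hydronium: SpeciesEnergy
    water_concentration_correction: bool = False

    def __post_init__(self) -> None:
        if self.hydronium.charge_state != self.water.charge_state + 1:
            raise InvalidPairError(
                "hydronium charge must exceed water charge by exactly 1"
            )
        _check_tags(self.water, self.hydronium)


@dataclass(frozen=True)
class IsodesmicReference:
    """A reference acid/base pair with a known pKa in the same solvent."""

    ref_acid: SpeciesEnergy
    ref_base: SpeciesEnergy
    ref_pka: float

    def __post_init__(self) -> None:
        if self.ref_acid.charge_state != self.ref_base.charge_state + 1:
            raise InvalidPairError(
                "reference acid charge must exceed reference base charge by 1"
            )
        _check_tags(self.ref_acid, self.ref_base)
        _require_finite(self.ref_pka, "ref_pka")


def direct_pka(
    pair: AcidBasePair,
    proton_solution_g: float,
    ctx: ThermoContext | None = None,
) -> float:
    """pKa from solution free energies alone.

    ΔG_soln = G_soln(A) + G_soln(H+) - G_soln(HA), with the proton's
    solution free energy supplied as one number. Sensitive to that
    choice; TC2 or the isodesmic route avoid it.
    """
    ctx = ctx or ThermoContext()
    _require_finite(proton_solution_g, "proton_solution_g")
    dg = pair.base.g_solution + proton_solution_g - pair.acid.g_solution
    return dg / ctx.log_conversion


def tc1_pka(
    pair: AcidBasePair,
    proton: ProtonParameters | None = None,
    ctx: ThermoContext | None = None,
) -> float:
    """pKa through thermodynamic cycle 1 (bare proton).

    ΔG_gas  = G_gas(A) + G_gas(H+) - G_gas(HA)
    ΔΔG_solv = ΔG_solv(A) + ΔG_solv(H+) - ΔG_solv(HA)
    ΔG_aq   = ΔG_gas + ΔΔG_solv  (+ standard-state term if enabled;
              deprotonation creates one mole of gas, so the term enters
              once with positive sign).
    """
    ctx = ctx or ThermoContext()
    proton = proton or ProtonParameters()
    dg_gas = pair.base.g_gas + proton.g_gas_proton - pair.acid.g_gas
    ddg_solv = pair.base.dg_solv + proton.dg_solv_proton - pair.acid.dg_solv
    dg_aq = dg_gas + ddg_solv
    if ctx.apply_standard_state:
        dg_aq += ctx.standard_state_correction
    return dg_aq / ctx.log_conversion


def tc2_pka(
    pair: AcidBasePair,
    water_pair: WaterPairParameters,
    ctx: ThermoContext | None = None,
) -> float:
    """pKa through thermodynamic cycle 2 (H2O/H3O+ pair).

    HA + H2O -> A + H3O+:

    ΔG_gas  = [G_gas(A) + G_gas(H3O+)] - [G_gas(HA) + G_gas(H2O)]
    ΔΔG_solv analogous with the solvation terms; ΔG_aq is their sum.
    The mole count of gas species is unchanged, so no standard-state
    term applies. If the H3O+/H2O free-energy differences equal the
    TC1 proton parameters, TC2 reduces to TC1 exactly.
    """
    ctx = ctx or ThermoContext()
    _check_tags(pair.acid, pair.base, water_pair.water, water_pair.hydronium)
    dg_gas = (pair.base.g_gas + water_pair.hydronium.g_gas) - (
        pair.acid.g_gas + water_pair.water.g_gas
    )
    ddg_solv = (pair.base.dg_solv + water_pair.hydronium.dg_solv) - (
        pair.acid.dg_solv + water_pair.water.dg_solv
    )
    pka = (dg_gas + ddg_solv) / ctx.log_conversion
    if water_pair.water_concentration_correction:
        pka -= math.log10(WATER_MOLARITY)
    return pka


def isodesmic_pka(
    query: AcidBasePair,
    reference: IsodesmicReference,
    ctx: ThermoContext | None = None,
) -> float:
    """pKa anchored to a reference acid through a proton exchange.

    For HA + B -> A + HB,

        ΔG_soln = [G_soln(A) + G_soln(HB)] - [G_soln(HA) + G_soln(B)]
        pKa(HA) = pKa(HB) + ΔG_soln / ln(10)RT

    Gas-phase and cavity errors common to both pairs cancel in the
    difference, which is what makes the scheme accurate when the
    reference resembles the query.
    """
    ctx = ctx or ThermoContext()
    _check_tags(query.acid, query.base, reference.ref_acid, reference.ref_base)
    dg = (query.base.g_solution + reference.ref_acid.g_solution) - (
        query.acid.g_solution + reference.ref_base.g_solution
    )
    return reference.ref_pka + dg / ctx.log_conversion
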