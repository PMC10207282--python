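"""Protonation-site selection from per-atom partial charges.

Basicity in azole and amidine heterocycles tracks the electron density
on nitrogen: the most electron-rich (most negatively charged) N is the
dominant protonation site. Partial charges come from population
analyses of a converged wavefunction — NPA, CM5 or Hirshfeld — and are
consumed here purely as data. The three schemes usually rank sites the
same way; when they disagree, NPA is taken as the primary analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core_thermo import InvalidInputError, _require_finite

__all__ = [
    "CHARGE_SCHEMES",
    "PRIMARY_SCHEME",
    "ChargeRecord",
    "SiteCall",
    "NoCandidateError",
    "select_site",
    "consensus_site",
]

CHARGE_SCHEMES = ("NPA", "CM5", "Hirshfeld")
PRIMARY_SCHEME = "NPA"


class NoCandidateError(ValueError):
    """No atom matches the requested element/scheme filter."""


@dataclass(frozen=True)
class ChargeRecord:
    """Partial charge of one atom under one population-analysis scheme."""

    molecule_id: str
    atom_index: int
    element: str
    scheme: str
    charge: float
    site_label: str = ""

    def __post_init__(self) -> None:
        if self.scheme not in CHARGE_SCHEMES:
            raise InvalidInputError(
                f"scheme must be one of {CHARGE_SCHEMES}, got {self.scheme!r}"
            )
        if self.atom_index < 1:
            raise InvalidInputError("atom_index must be a positive integer")
        _require_finite(self.charge, "charge")


@dataclass(frozen=True)
class SiteCall:
    """Chosen protonation site with per-scheme detail.

    ``consensus`` is true exactly when every scheme present picked the
    same atom.
    """

    molecule_id: str
    chosen_atom_index: int
    chosen_site_label: str
    per_scheme_choices: Mapping[str, int] = field(default_factory=dict)
    consensus: bool = True


def _matching(
    charges: Iterable[ChargeRecord], element_filter: str, scheme: str | None
) -> list[ChargeRecord]:
    return [
        r
        for r in charges
        if r.element == element_filter and (scheme is None or r.scheme == scheme)
    ]


def select_site(
    charges: Iterable[ChargeRecord],
    element_filter: str = "N",
    scheme: str = PRIMARY_SCHEME,
) -> int:
    """Atom index of the most electron-rich atom of the given element.

    Returns the atom with the most negative charge under ``scheme``;
    exact ties go to the lowest atom index. Selection depends only on
    the relative ordering of charges, so it is invariant both to input
    order and to any uniform shift of all charges.
    """
    candidates = _matching(charges, element_filter, scheme)
    if not candidates:
        raise NoCandidateError(
            f"no {element_filter!r} atoms with {scheme!r} charges in input"
        )
    best = min(candidates, key=lambda r: (r.charge, r.atom_index))
    return best.atom_index


def consensus_site(
    charges: Iterable[ChargeRecord], element_filter: str = "N"
) -> SiteCall:
    """Apply :func:`select_site` under every scheme present and reconcile.

    The chosen site is the NPA pick when NPA charges are available
    (NPA is treated as the primary analysis); otherwise the pick of the
    first available scheme in canonical order. ``consensus`` records
    whether all schemes agreed.
    """
    records = list(charges)
    schemes_present = [
        s for s in CHARGE_SCHEMES if _matching(records, element_filter, s)
    ]
    if not schemes_present:
        raise NoCandidateError(
            f"no {element_filter!r} atoms under any charge scheme in input"
        )
    choices = {s: select_site(records, element_filter, s) for s in schemes_present}
    primary = PRIMARY_SCHEME if PRIMARY_SCHEME in choices else schemes_present[0]
    chosen = choices[primary]
    labels = {
        r.atom_index: r.site_label
        for r in _matching(records, element_filter, None)
        if r.site_label
    }
    molecule_ids = {r.molecule_id for r in records}
    return SiteCall(
        molecule_id=molecule_ids.pop() if len(molecule_ids) == 1 else "",
        chosen_atom_index=chosen,
        chosen_site_label=labels.get(chosen, ""),
        per_scheme_choices=choices,
        consensus=len(set(choices.values())) == 1,
    )
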