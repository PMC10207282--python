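"""Synthetic free-energy datasets emulating a quantum-chemistry backend.

Electronic-structure output enters the pKa pipeline only as per-species
free energies, so a statistical emulator suffices for end-to-end and
error-propagation testing: each molecule gets a "true" pKa, and its
species free energies are constructed so that thermodynamic-cycle
evaluation returns

    true pKa + method bias + molecule noise

exactly. The bias term models the systematic error a level of theory
imposes on every molecule alike (the component an isodesmic reference
cancels); the Gaussian noise models molecule-specific error (which the
isodesmic difference doubles in variance rather than cancels).

The module also ships transcriptions of the published benchmark tables
(level-of-theory scans, the 17-heterocycle test set, nitrogen charges)
as packaged CSV fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .core_thermo import InvalidInputError, SpeciesEnergy, ThermoContext
from .cycles import AcidBasePair, IsodesmicReference, ProtonParameters, WaterPairParameters

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "fixture_tables",
    "load_fixture",
]

_FIXTURE_FILES = {
    "tc1_level_scan": "tc1_level_scan.csv",
    "tc2_level_scan": "tc2_level_scan.csv",
    "heterocycle_test_set": "heterocycle_test_set.csv",
    "thiazolimine_nitrogen_charges": "thiazolimine_nitrogen_charges.csv",
    "reference_molecule_charges": "reference_molecule_charges.csv",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``true_pka_range`` defaults to (10, 25), the span the acetonitrile
    test compounds cover; ``method_bias`` and ``noise_sd`` are in pKa
    units so their effect on recovered values is direct. The 50/50
    ``gas_split`` of each constructed ΔG between gas-phase and solvation
    components is arbitrary — every cycle scheme is invariant to it.
    """

    n_molecules: int = 50
    true_pka_range: tuple[float, float] = (10.0, 25.0)
    method_bias: float = 0.0
    noise_sd: float = 0.0
    solvent_tag: str = "mecn"
    method_tag: str = "synthetic"
    proton: ProtonParameters = field(default_factory=ProtonParameters)
    gas_split: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise InvalidInputError("n_molecules must be >= 1")
        low, high = self.true_pka_range
        if not low < high:
            raise InvalidInputError("true_pka_range must satisfy low < high")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not 0.0 <= self.gas_split <= 1.0:
            raise InvalidInputError("gas_split must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated species with the ground truth that produced them."""

    species: tuple[SpeciesEnergy, ...]
    pairs: tuple[AcidBasePair, ...]
    reference_pair: AcidBasePair
    water_pair: WaterPairParameters
    truth: Mapping[str, float]
    noise: Mapping[str, float]
    reference_true_pka: float
    reference_noise: float
    config: SyntheticConfig

    def isodesmic_reference(self) -> IsodesmicReference:
        """Reference anchored at its own true pKa (the experimental analogue)."""
        return IsodesmicReference(
            ref_acid=self.reference_pair.acid,
            ref_base=self.reference_pair.base,
            ref_pka=self.reference_true_pka,
        )

    def energies_frame(self) -> pd.DataFrame:
        """Species energies in the standard tabular layout."""
        return pd.DataFrame(
            {
                "species_id": [s.species_id for s in self.species],
                "charge_state": [s.charge_state for s in self.species],
                "g_gas_kcal": [s.g_gas for s in self.species],
                "dg_solv_kcal": [s.dg_solv for s in self.species],
                "method_tag": [s.method_tag for s in self.species],
                "solvent_tag": [s.solvent_tag for s in self.species],
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"molecule_id": mid, "true_pka": pka, "noise": self.noise[mid]}
            for mid, pka in self.truth.items()
        ]
        rows.append(
            {
                "molecule_id": "reference",
                "true_pka": self.reference_true_pka,
                "noise": self.reference_noise,
            }
        )
        return pd.DataFrame(rows)


def _build_pair(
    molecule_id: str,
    target_pka: float,
    cfg: SyntheticConfig,
    ctx: ThermoContext,
) -> AcidBasePair:
    # TC1 on the pair must return target_pka exactly: put the whole
    # reaction free energy on the base species, acid pinned at zero.
    dg_total = target_pka * ctx.log_conversion - (
        cfg.proton.g_gas_proton + cfg.proton.dg_solv_proton
    )
    acid = SpeciesEnergy(
        species_id=f"{molecule_id}_acid",
        charge_state=1,
        g_gas=0.0,
        dg_solv=0.0,
        method_tag=cfg.method_tag,
        solvent_tag=cfg.solvent_tag,
    )
    base = SpeciesEnergy(
        species_id=f"{molecule_id}_base",
        charge_state=0,
        g_gas=cfg.gas_split * dg_total,
        dg_solv=(1.0 - cfg.gas_split) * dg_total,
        method_tag=cfg.method_tag,
        solvent_tag=cfg.solvent_tag,
    )
    return AcidBasePair(acid=acid, base=base, site_label="imine-N")


def generate(
    config: SyntheticConfig, ctx: ThermoContext | None = None
) -> SyntheticDataset:
    """Draw a dataset of acid/base pairs plus reference and water species.

    For molecule i with true pKa t_i and noise draw e_i, the pair is
    constructed so tc1_pka gives t_i + bias + e_i identically. The
    reference pair shares the same bias with its own noise draw, so an
    isodesmic evaluation against it returns t_i + e_i - e_ref — bias
    gone. The H2O/H3O+ species satisfy the TC2-reduction condition
    (their free-energy differences equal the proton parameters), so TC2
    and TC1 coincide on every generated pair.
    """
    ctx = ctx or ThermoContext()
    rng = np.random.default_rng(config.seed)
    low, high = config.true_pka_range
    n = config.n_molecules

    true_pkas = rng.uniform(low, high, size=n)
    noises = (
        rng.normal(0.0, config.noise_sd, size=n)
        if config.noise_sd > 0
        else np.zeros(n)
    )
    ref_true = float(rng.uniform(low, high))
    ref_noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0

    pairs = []
    truth: dict[str, float] = {}
    noise: dict[str, float] = {}
    for i in range(n):
        mid = f"mol{i + 1:04d}"
        truth[mid] = float(true_pkas[i])
        noise[mid] = float(noises[i])
        pairs.append(
            _build_pair(mid, truth[mid] + config.method_bias + noise[mid], config, ctx)
        )
    reference_pair = _build_pair(
        "reference", ref_true + config.method_bias + ref_noise, config, ctx
    )

    water = SpeciesEnergy(
        species_id="water",
        charge_state=0,
        g_gas=0.0,
        dg_solv=0.0,
        method_tag=config.method_tag,
        solvent_tag=config.solvent_tag,
    )
    hydronium = SpeciesEnergy(
        species_id="hydronium",
        charge_state=1,
        g_gas=config.proton.g_gas_proton,
        dg_solv=config.proton.dg_solv_proton,
        method_tag=config.method_tag,
        solvent_tag=config.solvent_tag,
    )
    species = tuple(
        s
        for p in [*pairs, reference_pair]
        for s in (p.acid, p.base)
    ) + (water, hydronium)

    return SyntheticDataset(
        species=species,
        pairs=tuple(pairs),
        reference_pair=reference_pair,
        water_pair=WaterPairParameters(water=water, hydronium=hydronium),
        truth=truth,
        noise=noise,
        reference_true_pka=ref_true,
        reference_noise=ref_noise,
        config=config,
    )


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged benchmark table by name."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    path = resources.files("pkacycles.data").joinpath(_FIXTURE_FILES[name])
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def fixture_tables() -> dict:
    """All packaged benchmark fixtures plus the scalar reference constants.

    Keys: the five table names (pandas DataFrames) and ``constants``
    (dict with the reference molecule's experimental water pKa, its
    calculated acetonitrile pKa, and the winning level of theory).
    """
    tables: dict = {name: load_fixture(name) for name in _FIXTURE_FILES}
    constants = resources.files("pkacycles.data").joinpath("reference_constants.json")
    tables["constants"] = json.loads(constants.read_text())
    return tables
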