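"""Tabular readers/writers and the end-to-end pKa pipeline.

Ingestion contract (CSV, header mandatory, decimal point):

* energies:   species_id, charge_state, g_gas_kcal, dg_solv_kcal,
              method_tag, solvent_tag
* pairs:      acid_id, base_id [, molecule_id, site_label]
* experimental: molecule_id, experimental_pka

Direct parsing of quantum-chemistry program output is deliberately out
of scope; the energies CSV is the single ingestion format, and
:func:`read_energies` is the extension point for future format readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

from .benchmark_stats import BenchmarkReport, BenchmarkRow, aggregate
from .core_thermo import InvalidInputError, SpeciesEnergy, ThermoContext
from .cycles import (
    AcidBasePair,
    IsodesmicReference,
    ProtonParameters,
    WaterPairParameters,
    direct_pka,
    isodesmic_pka,
    tc1_pka,
    tc2_pka,
)

__all__ = [
    "ENERGY_COLUMNS",
    "EnergiesTable",
    "RunConfig",
    "ParseError",
    "IntegrityError",
    "ConfigError",
    "EmptyPipelineError",
    "read_energies",
    "write_energies",
    "read_pairs",
    "read_experimental",
    "run_pipeline",
]

ENERGY_COLUMNS = (
    "species_id",
    "charge_state",
    "g_gas_kcal",
    "dg_solv_kcal",
    "method_tag",
    "solvent_tag",
)


class ParseError(ValueError):
    """Malformed table content (reported with the offending line)."""


class IntegrityError(ValueError):
    """Structurally valid table violating a dataset invariant."""


class ConfigError(ValueError):
    """Run configuration missing fields the chosen scheme requires."""


class EmptyPipelineError(ValueError):
    """Pipeline invoked with no pairs or no usable rows."""


@dataclass
class EnergiesTable:
    """Validated species-energy records plus acid->base pairing."""

    records: dict[tuple[str, str, str], SpeciesEnergy] = field(default_factory=dict)
    # acid species_id -> (base species_id, molecule_id, site_label)
    pairing: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def lookup(self, species_id: str) -> SpeciesEnergy:
        hits = [s for s in self.records.values() if s.species_id == species_id]
        if not hits:
            raise IntegrityError(f"species {species_id!r} not found in energies table")
        if len(hits) > 1:
            tags = [(s.method_tag, s.solvent_tag) for s in hits]
            raise IntegrityError(
                f"species {species_id!r} is ambiguous across tags {tags}"
            )
        return hits[0]

    def add(self, species: SpeciesEnergy) -> None:
        key = species.key()
        if key in self.records:
            raise IntegrityError(f"duplicate species key {key}")
        self.records[key] = species

    def set_pairing(
        self, acid_id: str, base_id: str, molecule_id: str = "", site_label: str = ""
    ) -> None:
        acid = self.lookup(acid_id)
        base = self.lookup(base_id)
        if acid.charge_state != base.charge_state + 1:
            raise IntegrityError(
                f"pair {acid_id!r}/{base_id!r}: acid charge {acid.charge_state} "
                f"must be base charge {base.charge_state} + 1"
            )
        self.pairing[acid_id] = (base_id, molecule_id or acid_id, site_label)

    def pairs(self) -> list[tuple[str, AcidBasePair]]:
        out = []
        for acid_id, (base_id, molecule_id, site_label) in self.pairing.items():
            out.append(
                (
                    molecule_id,
                    AcidBasePair(
                        acid=self.lookup(acid_id),
                        base=self.lookup(base_id),
                        site_label=site_label,
                    ),
                )
            )
        return out


def read_energies(path, pairs_path=None) -> EnergiesTable:
    """Read and validate an energies CSV (and optional pairs CSV)."""
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in ENERGY_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    table = EnergiesTable()
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            species = SpeciesEnergy(
                species_id=str(row["species_id"]),
                charge_state=int(row["charge_state"]),
                g_gas=float(row["g_gas_kcal"]),
                dg_solv=float(row["dg_solv_kcal"]),
                method_tag=str(row["method_tag"]),
                solvent_tag=str(row["solvent_tag"]),
            )
        except (ValueError, TypeError, InvalidInputError) as exc:
            raise ParseError(f"{path}: malformed row at line {line}: {exc}") from exc
        table.add(species)
    if pairs_path is not None:
        for acid_id, base_id, molecule_id, site_label in read_pairs(pairs_path):
            table.set_pairing(acid_id, base_id, molecule_id, site_label)
    return table


def write_energies(table: EnergiesTable, path) -> None:
    records = list(table.records.values())
    pd.DataFrame(
        {
            "species_id": [s.species_id for s in records],
            "charge_state": [s.charge_state for s in records],
            "g_gas_kcal": [s.g_gas for s in records],
            "dg_solv_kcal": [s.dg_solv for s in records],
            "method_tag": [s.method_tag for s in records],
            "solvent_tag": [s.solvent_tag for s in records],
        }
    ).to_csv(path, index=False)


def read_pairs(path) -> list[tuple[str, str, str, str]]:
    """Pairs CSV -> list of (acid_id, base_id, molecule_id, site_label)."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    for col in ("acid_id", "base_id"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            (
                row["acid_id"],
                row["base_id"],
                row.get("molecule_id", "") or row["acid_id"],
                row.get("site_label", "") or "",
            )
        )
    return out


def read_experimental(path) -> dict[str, float]:
    """Experimental pKa CSV -> molecule_id -> value mapping."""
    frame = pd.read_csv(path)
    for col in ("molecule_id", "experimental_pka"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out: dict[str, float] = {}
    for _, row in frame.iterrows():
        value = row["experimental_pka"]
        if pd.isna(value):
            continue
        out[str(row["molecule_id"])] = float(value)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline invocation needs besides the tables.

    ``scheme`` picks the pKa route. The isodesmic scheme requires the
    reference species ids and ``ref_pka``; TC2 requires the water and
    hydronium species ids; TC1/direct use the proton preset (direct may
    override the proton's solution free energy with one number).
    """

    scheme: Literal["direct", "tc1", "tc2", "isodesmic"]
    proton_preset: str = "minus_265_9"
    proton_solution_g: float | None = None
    ref_acid_id: str | None = None
    ref_base_id: str | None = None
    ref_pka: float | None = None
    water_id: str | None = None
    hydronium_id: str | None = None
    water_concentration_correction: bool = False
    apply_standard_state: bool = False
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("direct", "tc1", "tc2", "isodesmic"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "isodesmic":
            if not (self.ref_acid_id and self.ref_base_id and self.ref_pka is not None):
                raise ConfigError(
                    "isodesmic scheme requires ref_acid_id, ref_base_id and ref_pka"
                )
        if self.scheme == "tc2" and not (self.water_id and self.hydronium_id):
            raise ConfigError("tc2 scheme requires water_id and hydronium_id")

    def context(self) -> ThermoContext:
        return ThermoContext(
            temperature=self.temperature,
            apply_standard_state=self.apply_standard_state,
        )

    def proton(self) -> ProtonParameters:
        if self.proton_preset == "custom":
            raise ConfigError("custom proton parameters must be passed explicitly")
        return ProtonParameters.from_preset(self.proton_preset)


def run_pipeline(
    config: RunConfig,
    energies: EnergiesTable,
    experimental: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, BenchmarkReport | None]:
    """Compute pKa for every paired acid under the configured scheme.

    Returns per-molecule predictions (one row per pair, with the
    experimental value and deviation joined when available) and a
    :class:`~pkacycles.benchmark_stats.BenchmarkReport` when at least
    one experimental value matched, else ``None``.
    """
    ctx = config.context()
    molecule_pairs = energies.pairs()
    if not molecule_pairs:
        raise EmptyPipelineError("energies table defines no acid/base pairs")

    if config.scheme == "tc2":
        water_pair = WaterPairParameters(
            water=energies.lookup(config.water_id),
            hydronium=energies.lookup(config.hydronium_id),
            water_concentration_correction=config.water_concentration_correction,
        )
    elif config.scheme == "isodesmic":
        reference = IsodesmicReference(
            ref_acid=energies.lookup(config.ref_acid_id),
            ref_base=energies.lookup(config.ref_base_id),
            ref_pka=float(config.ref_pka),
        )

    rows = []
    bench_rows = []
    for molecule_id, pair in molecule_pairs:
        if config.scheme == "tc1":
            pka = tc1_pka(pair, config.proton(), ctx)
        elif config.scheme == "tc2":
            pka = tc2_pka(pair, water_pair, ctx)
        elif config.scheme == "isodesmic":
            pka = isodesmic_pka(pair, reference, ctx)
        else:
            proton = config.proton()
            g_h = (
                config.proton_solution_g
                if config.proton_solution_g is not None
                else proton.g_gas_proton + proton.dg_solv_proton
            )
            pka = direct_pka(pair, g_h, ctx)
        exp = None if experimental is None else experimental.get(molecule_id)
        rows.append(
            {
                "molecule_id": molecule_id,
                "acid_id": pair.acid.species_id,
                "base_id": pair.base.species_id,
                "site_label": pair.site_label,
                "scheme": config.scheme,
                "solvent_tag": pair.acid.solvent_tag,
                "method_tag": pair.acid.method_tag,
                "calculated_pka": pka,
                "experimental_pka": exp,
                "delta": None if exp is None else pka - exp,
            }
        )
        bench_rows.append(
            BenchmarkRow(
                molecule_id=molecule_id,
                calculated_pka=pka,
                experimental_pka=exp,
                solvent_tag=pair.acid.solvent_tag,
                method_tag=pair.acid.method_tag,
            )
        )

    predictions = pd.DataFrame(rows)
    report = None
    if any(r.experimental_pka is not None for r in bench_rows):
        report = aggregate(bench_rows)
    return predictions, report
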