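"""Deviation statistics for calculated-vs-experimental pKa benchmarks.

The deviation convention is fixed throughout:

    Δ = calculated - experimental

and the aggregates are the usual ones: RMSE = sqrt(mean Δ²),
MAD = mean |Δ|, MD = mean Δ (signed), plus the maximum |Δ| and an
ordinary least-squares regression of calculated on experimental with
R² equal to the squared Pearson correlation. Rows without an
experimental value are carried through but excluded from every
statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from .core_thermo import InvalidInputError, _require_finite

__all__ = [
    "BenchmarkRow",
    "RegressionResult",
    "BenchmarkReport",
    "MissingDataError",
    "EmptyReportError",
    "delta_pka",
    "aggregate",
    "flag_inconsistent_deltas",
]

#: Tolerance beyond which a supplied deviation column is flagged as
#: inconsistent with its own calculated/experimental columns.
DELTA_CONSISTENCY_TOL = 0.01


class MissingDataError(ValueError):
    """Experimental value required but absent."""


class EmptyReportError(ValueError):
    """No rows carry experimental values; nothing to aggregate."""


@dataclass(frozen=True)
class BenchmarkRow:
    """One molecule's experimental and calculated pKa in one solvent."""

    molecule_id: str
    calculated_pka: float
    experimental_pka: float | None = None
    solvent_tag: str = ""
    method_tag: str = ""

    def __post_init__(self) -> None:
        _require_finite(self.calculated_pka, "calculated_pka")
        if self.experimental_pka is not None and not math.isfinite(
            float(self.experimental_pka)
        ):
            raise InvalidInputError("experimental_pka must be finite when present")

    @property
    def delta(self) -> float | None:
        if self.experimental_pka is None:
            return None
        return self.calculated_pka - self.experimental_pka


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of calculated on experimental pKa."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class BenchmarkReport:
    rows: tuple[BenchmarkRow, ...]
    rmse: float
    mad: float
    md: float
    max_abs_delta: float
    n_evaluated: int
    regression: RegressionResult | None = None

    def to_dict(self) -> dict:
        """JSON-ready report (schema v1); pKa values at full precision."""
        return {
            "schema_version": 1,
            "n_rows": len(self.rows),
            "n_evaluated": self.n_evaluated,
            "rmse": self.rmse,
            "mad": self.mad,
            "md": self.md,
            "md_experimental_minus_calculated": -self.md,
            "max_abs_delta": self.max_abs_delta,
            "delta_convention": "calculated - experimental",
            "regression": (
                None
                if self.regression is None
                else {
                    "slope": self.regression.slope,
                    "intercept": self.regression.intercept,
                    "r_squared": self.regression.r_squared,
                }
            ),
            "rows": [
                {
                    "molecule_id": r.molecule_id,
                    "solvent": r.solvent_tag,
                    "method": r.method_tag,
                    "experimental_pka": r.experimental_pka,
                    "calculated_pka": r.calculated_pka,
                    "delta": r.delta,
                }
                for r in self.rows
            ],
        }


def delta_pka(row: BenchmarkRow) -> float:
    """Signed deviation Δ = calculated - experimental for one row."""
    if row.experimental_pka is None:
        raise MissingDataError(
            f"molecule {row.molecule_id!r} has no experimental pKa"
        )
    return row.calculated_pka - row.experimental_pka


def aggregate(rows: Iterable[BenchmarkRow]) -> BenchmarkReport:
    """Aggregate per-molecule deviations into a benchmark report.

    Requires at least one row with an experimental value; the OLS
    regression additionally needs two such rows and a non-degenerate
    experimental axis (otherwise ``regression`` is None).
    """
    rows = tuple(rows)
    evaluated = [r for r in rows if r.experimental_pka is not None]
    if not evaluated:
        raise EmptyReportError("no rows with experimental pKa values")
    deltas = [delta_pka(r) for r in evaluated]
    n = len(deltas)
    rmse = math.sqrt(sum(d * d for d in deltas) / n)
    mad = sum(abs(d) for d in deltas) / n
    md = sum(deltas) / n

    regression: RegressionResult | None = None
    exp = [r.experimental_pka for r in evaluated]
    calc = [r.calculated_pka for r in evaluated]
    if n >= 2 and len(set(exp)) > 1:
        fit = stats.linregress(exp, calc)
        regression = RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue) ** 2,
        )
    return BenchmarkReport(
        rows=rows,
        rmse=rmse,
        mad=mad,
        md=md,
        max_abs_delta=max(abs(d) for d in deltas),
        n_evaluated=n,
        regression=regression,
    )


def flag_inconsistent_deltas(
    rows: Sequence[BenchmarkRow],
    reported_deltas: Sequence[float | None],
    tol: float = DELTA_CONSISTENCY_TOL,
) -> list[str]:
    """Molecule ids whose externally reported Δ disagrees with calc - exp.

    Published benchmark tables occasionally print deviation cells that
    do not match their own calculated/experimental columns; this check
    recomputes Δ from the primary columns and flags any row where the
    supplied value differs by more than ``tol``.
    """
    if len(reported_deltas) != len(rows):
        raise InvalidInputError("reported_deltas length must match rows")
    flagged = []
    for row, reported in zip(rows, reported_deltas):
        if reported is None or row.experimental_pka is None:
            continue
        if abs(delta_pka(row) - reported) > tol:
            flagged.append(row.molecule_id)
    return flagged
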