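"""Theoretical EIC targeting and metabolite profile scaling.

Negative-mode LC-MS work on secoiridoids is driven off two adducts: the
deprotonated molecule [M-H]- and the formate cluster [M+formate]-.
Given a molecular formula this module computes the monoisotopic adduct
m/z (4 decimal places, the precision instruments print) and the +/- m/z
window used to pull an extracted ion chromatogram. It also implements
the per-species percent-of-maximum scaling used to summarize metabolite
AUC time-courses across species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .tables_io import MetaboliteTable

# Most-abundant-isotope masses (Da). Extensible: pass extra symbols via
# Formula(masses=...).
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "P": 30.97376163,
    "S": 31.97207100,
}

# Charge -1 adduct mass deltas. [M-H]-: loss of a proton. [M+formate]-:
# gain of HCOOH (46.005479) minus a proton; the electron mass is
# neglected, consistent with 4-dp instrument output.
ADDUCT_DELTAS: dict[str, float] = {
    "M-H": -1.007276,
    "M+formate": +44.998203,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed molecular formulas."""


@dataclass(frozen=True)
class Formula:
    """Element symbol -> positive integer count."""

    counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass(frozen=True)
class EicWindow:
    """m/z window (center +/- tolerance) for chromatogram extraction."""

    center: float
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("EIC tolerance must be > 0")

    @property
    def low(self) -> float:
        return self.center - self.tolerance

    @property
    def high(self) -> float:
        return self.center + self.tolerance

    def contains(self, mz: float) -> bool:
        return self.low <= mz <= self.high


def parse_formula(text: str, masses: dict[str, float] | None = None) -> Formula:
    """Parse a Hill-style molecular formula such as ``C25H32O13``."""
    table = masses or MONOISOTOPIC_MASSES
    if not text:
        raise FormulaError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos or not match.group(0):
            break
        symbol, digits = match.groups()
        if symbol not in table:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"malformed formula {text!r}")
    return Formula(tuple(counts.items()))


def monoisotopic_mass(formula: Formula | str, masses: dict[str, float] | None = None) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da."""
    table = masses or MONOISOTOPIC_MASSES
    if isinstance(formula, str):
        formula = parse_formula(formula, table)
    return sum(table[el] * n for el, n in formula.counts)


def adduct_mz(formula: Formula | str, adduct: str) -> float:
    """Theoretical adduct m/z, round-half-up to 4 decimal places."""
    if adduct not in ADDUCT_DELTAS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_DELTAS)}")
    raw = monoisotopic_mass(formula) + ADDUCT_DELTAS[adduct]
    return float(Decimal(repr(raw)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def eic_window(formula: Formula | str, adduct: str, tolerance: float = 0.05) -> EicWindow:
    return EicWindow(adduct_mz(formula, adduct), tolerance)


@dataclass
class ScaledProfile:
    """Percent-of-species-maximum AUC trajectories and cross-species summary.

    ``per_species``: species, compound, timepoint_order, pct (in [0, 100];
    each species/compound maximum is exactly 100).
    ``summary``: compound, timepoint_order, mean_pct, sd_pct, n_species.
    """

    per_species: pd.DataFrame
    summary: pd.DataFrame = field(repr=False)


def scale_metabolite_profiles(table: MetaboliteTable) -> ScaledProfile:
    """Scale each (species, compound) AUC series to percent of its maximum,
    then average the percentages across species per compound/timepoint."""
    df = table.table.copy()
    rows = []
    for (sp, cp), grp in df.groupby(["species", "compound"], sort=True):
        peak = grp["auc"].max()
        if peak <= 0:
            raise ValueError(f"compound {cp!r} has all-zero AUC in species {sp!r}")
        for r in grp.itertuples(index=False):
            rows.append({
                "species": sp, "compound": cp,
                "timepoint_order": r.timepoint_order,
                # ratio first, then percent: a/peak is exact (1.0) at
                # the species maximum, so that row is exactly 100
                "pct": min(100.0 * (r.auc / peak), 100.0),
            })
    per_species = pd.DataFrame(rows).sort_values(
        ["compound", "species", "timepoint_order"]).reset_index(drop=True)
    summary = (
        per_species.groupby(["compound", "timepoint_order"], sort=True)["pct"]
        .agg(mean_pct="mean", sd_pct=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
             n_species="size")
        .reset_index()
    )
    return ScaledProfile(per_species, summary)
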