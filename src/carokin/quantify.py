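"""HPLC-UV quantification and carotene pattern summaries.

Absorbances convert to concentrations through Beer-Lambert with molar
extinction coefficients.  Two carotenes have no reported coefficient and
borrow from their closest structural relative: tetradehydrolycopene uses
didehydrolycopene's coefficient, dehydro-beta-carotene uses
beta-zeacarotene's.  The shipped coefficient table holds editable
literature placeholders; analyses should supply vetted values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pathway import CaroteneSpecies, species_registry

__all__ = [
    "ExtinctionEntry",
    "PatternSummary",
    "SURROGATE_RULES",
    "load_extinction_table",
    "default_extinction_table",
    "resolve_epsilon",
    "concentration_from_absorbance",
    "pattern_summary",
]

#: Closest-molecule substitutions for species without reported coefficients.
SURROGATE_RULES: dict[str, str] = {
    "tetradehydrolycopene": "didehydrolycopene",
    "dehydro-beta-carotene": "beta-zeacarotene",
}

GRID_SHAPE = (7, 3)  # desaturation_index 0..6 x cycle_count 0..2


@dataclass(frozen=True)
class ExtinctionEntry:
    """One molar extinction coefficient, M^-1 cm^-1 at a given wavelength."""

    species: str
    epsilon: float
    wavelength: float  # nm
    surrogate_of: str | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def load_extinction_table(path: str | Path) -> list[ExtinctionEntry]:
    """Read a coefficient CSV: species,epsilon_M_cm,wavelength_nm,surrogate_of."""
    df = pd.read_csv(path)
    required = {"species", "epsilon_M_cm", "wavelength_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coefficient table missing column(s): {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        surrogate = getattr(row, "surrogate_of", None)
        if pd.isna(surrogate) or surrogate == "":
            surrogate = None
        entries.append(
            ExtinctionEntry(row.species, float(row.epsilon_M_cm),
                            float(row.wavelength_nm), surrogate)
        )
    return entries


def save_extinction_table(entries: Sequence[ExtinctionEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "species": [e.species for e in entries],
            "epsilon_M_cm": [e.epsilon for e in entries],
            "wavelength_nm": [e.wavelength for e in entries],
            "surrogate_of": [e.surrogate_of or "" for e in entries],
        }
    ).to_csv(path, index=False)


def default_extinction_table() -> list[ExtinctionEntry]:
    """Shipped placeholder table (see data/extinction_coefficients.csv)."""
    ref = resources.files("carokin.data").joinpath("extinction_coefficients.csv")
    with resources.as_file(ref) as path:
        return load_extinction_table(path)


def resolve_epsilon(
    species: str, table: Sequence[ExtinctionEntry]
) -> ExtinctionEntry:
    """Find the coefficient for a species, applying the surrogate rules.

    Surrogate resolution never chains: the borrowed entry must be the
    surrogate's own coefficient.
    """
    by_name = {e.species: e for e in table}
    if species in by_name and species not in SURROGATE_RULES:
        return by_name[species]
    if species in SURROGATE_RULES:
        source = SURROGATE_RULES[species]
        entry = by_name.get(source)
        if entry is None or entry.surrogate_of is not None:
            raise KeyError(
                f"no own coefficient for surrogate source {source!r} "
                f"(needed by {species!r})"
            )
        return replace(entry, species=species, surrogate_of=source)
    raise KeyError(f"no extinction coefficient for species {species!r}")


def concentration_from_absorbance(
    absorbance: float, entry: ExtinctionEntry, path_length: float = 1.0
) -> float:
    """Beer-Lambert: c = A/(epsilon*l), returned in µM."""
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    molar = absorbance / (entry.epsilon * path_length)
    return molar * 1e6


@dataclass
class PatternSummary:
    """Fractional composition of a carotene mixture.

    ``fractions_total`` covers all detected carotenes and sums to 1;
    ``fractions_desaturated`` covers detected species with at least one
    added double bond (phytoene excluded).  ``grid`` is concentration (µM)
    indexed by (desaturation_index, cycle_count).
    """

    fractions_total: dict[str, float]
    fractions_desaturated: dict[str, float]
    grid: np.ndarray
    total_carotene: float

    @property
    def empty(self) -> bool:
        return not self.fractions_total

    def grid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.grid,
            index=pd.Index(range(GRID_SHAPE[0]), name="desaturations"),
            columns=pd.Index(range(GRID_SHAPE[1]), name="cycles"),
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"species": name, "fraction_total": f,
             "fraction_desaturated": self.fractions_desaturated.get(name, np.nan)}
            for name, f in self.fractions_total.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")

    def grid_to_csv(self, path: str | Path) -> None:
        self.grid_frame().to_csv(path, float_format="%.10g")


def pattern_summary(
    concentrations: Mapping[str, float],
    detection_limit: float = 0.0,
    registry: Mapping[str, CaroteneSpecies] | None = None,
) -> PatternSummary:
    """Summarise a concentration map as fractions and a desaturation x cycle grid.

    Species below ``detection_limit`` are excluded before any fraction is
    computed, mirroring HPLC reporting.  If everything is below the limit
    an empty summary is returned (``summary.empty`` is true).
    """
    reg = dict(registry) if registry is not None else species_registry()
    detected: dict[str, float] = {}
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if name not in reg:
            raise KeyError(f"unknown carotene species {name!r}")
        if conc >= detection_limit and conc > 0:
            detected[name] = float(conc)

    grid = np.zeros(GRID_SHAPE)
    total = sum(detected.values())
    if not detected:
        return PatternSummary({}, {}, grid, 0.0)

    fractions_total = {n: c / total for n, c in detected.items()}
    desat = {n: c for n, c in detected.items() if reg[n].desaturation_index >= 1}
    desat_total = sum(desat.values())
    fractions_desat = (
        {n: c / desat_total for n, c in desat.items()} if desat_total > 0 else {}
    )
    for name, conc in detected.items():
        sp = reg[name]
        grid[sp.desaturation_index, sp.cycle_count] += conc
    return PatternSummary(fractions_total, fractions_desat, grid, total)
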