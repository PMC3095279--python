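"""Molecular-clock dating of duplication events: T = Ks / (2 * lambda).

Lambda is a per-species clock-like synonymous substitution rate in
substitutions per synonymous site per year; ages are reported in Ma
(millions of years), rounded half-up to two decimals for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

__all__ = [
    "DEFAULT_RATES",
    "ClockRate",
    "DatedDuplication",
    "date_duplication",
    "date_duplication_ma",
    "species_rate",
]

#: Default clock-like synonymous substitution rates (per site per year).
DEFAULT_RATES: dict[str, float] = {
    "Arabidopsis": 1.5e-8,
    "Rice": 6.5e-9,
    "Poplar": 9.1e-9,
    "Grape": 6.5e-9,
}

SATURATION_CUTOFF = 2.0


@dataclass(frozen=True)
class ClockRate:
    species: str
    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"{self.species}: lambda must be positive")


@dataclass(frozen=True)
class DatedDuplication:
    pair: tuple[str, str]
    mean_ks: float
    t_years: float

    @property
    def t_ma(self) -> float:
        """Age in Ma, rounded half-up to 2 decimals (display precision)."""
        return round_ma(self.t_years / 1e6)


def round_ma(value_ma: float) -> float:
    return float(Decimal(repr(value_ma)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def date_duplication(mean_ks: float, lam: float) -> float:
    """Duplication age in years, T = Ks / (2 * lambda)."""
    if mean_ks < 0:
        raise ValueError("mean Ks must be non-negative")
    if not lam > 0:
        raise ValueError("lambda must be positive")
    if mean_ks > SATURATION_CUTOFF:
        warnings.warn(
            f"mean Ks {mean_ks} exceeds the saturation cutoff {SATURATION_CUTOFF}; "
            "the resulting date is unreliable",
            stacklevel=2,
        )
    return mean_ks / (2.0 * lam)


def date_duplication_ma(mean_ks: float, lam: float) -> float:
    """Duplication age in Ma, rounded half-up to two decimals."""
    return round_ma(date_duplication(mean_ks, lam) / 1e6)


def species_rate(species: str, rates: Mapping[str, float] | None = None) -> ClockRate:
    """Look up the clock rate for a species; the four defaults ship built in."""
    table = dict(DEFAULT_RATES)
    if rates:
        table.update(rates)
    if species not in table:
        raise KeyError(
            f"no synonymous substitution rate configured for species {species!r}; "
            "supply one explicitly"
        )
    return ClockRate(species=species, lam=table[species])
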