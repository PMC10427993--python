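"""Hybridization opportunity: congener encounters at naturalization events.

A naturalization event is one (neophyte, botanical country) pair. The event
offers a hybridization opportunity when a native member of the same genus is
present in the invaded country; a neophyte species has encountered a
congener when at least one of its events did. The projection combines the
species-level encounter fraction with a literature range for the fraction of
plant species that hybridize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError


@dataclass(frozen=True)
class EncounterSummary:
    n_events: int
    n_events_with_congener: int
    event_fraction: float
    n_species: int
    n_species_with_congener: int
    species_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_events_with_congener": self.n_events_with_congener,
            "event_fraction": self.event_fraction,
            "n_species": self.n_species,
            "n_species_with_congener": self.n_species_with_congener,
            "species_fraction": self.species_fraction,
        }


def encounter_summary(
    neophyte_events: pd.DataFrame, native_presence: pd.DataFrame
) -> EncounterSummary:
    """Count events and species with a native congener in the invaded region.

    Parameters
    ----------
    neophyte_events
        Columns ``taxon_name``, ``genus``, ``region_code`` (one row per
        naturalization event; duplicates collapsed).
    native_presence
        Columns ``genus``, ``region_code`` — native genus presences; the
        caller is responsible for excluding the neophyte taxon itself.
    """
    events = neophyte_events[["taxon_name", "genus", "region_code"]].drop_duplicates()
    pres = native_presence[["genus", "region_code"]].drop_duplicates()
    joined = events.merge(pres, on=["genus", "region_code"], how="left", indicator=True)
    joined["_with"] = joined["_merge"] == "both"
    n_events = len(joined)
    n_with = int(joined["_with"].sum())
    per_species = joined.groupby("taxon_name")["_with"].any()
    n_species = len(per_species)
    n_species_with = int(per_species.sum())
    return EncounterSummary(
        n_events=n_events,
        n_events_with_congener=n_with,
        event_fraction=(n_with / n_events) if n_events else 0.0,
        n_species=n_species,
        n_species_with_congener=n_species_with,
        species_fraction=(n_species_with / n_species) if n_species else 0.0,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def projected_hybridizations(
    n_neophytes: int,
    encounter_fraction: float,
    rate_low: float,
    rate_high: float,
) -> tuple[int, int]:
    """Project how many hybridization events may follow from introductions.

    ``n_neophytes × encounter_fraction × rate`` for a hybridization-rate
    range [rate_low, rate_high]; rounding is half-away-from-zero to whole
    events.
    """
    if n_neophytes < 0:
        raise DomainError("n_neophytes must be nonnegative")
    for name, val in (
        ("encounter_fraction", encounter_fraction),
        ("rate_low", rate_low),
        ("rate_high", rate_high),
    ):
        if not 0.0 <= val <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {val}")
    if rate_low > rate_high:
        raise DomainError("rate_low must not exceed rate_high")
    low = _round_half_away(n_neophytes * encounter_fraction * rate_low)
    high = _round_half_away(n_neophytes * encounter_fraction * rate_high)
    return low, high
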