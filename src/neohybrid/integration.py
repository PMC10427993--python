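"""Inclusion/exclusion filters and per-country / per-genus tallies.

The filters encode the checklist rules of the analysis: hybrids are accepted
interspecific hybrids excluding artificial ones; neophytes are accepted,
naturalized, non-hybrid taxa (aliens of unclear establishment removed;
infraspecific neophytes retained because their naturalizations equally
present hybridization opportunities). Tallies count *distinct* normalized
taxon names per unit, since source tables repeat names across region rows.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxa_io import TaxonRecord

COUNTRY_TALLY_COLUMNS = [
    "region_code",
    "n_hybrids",
    "n_neophytes",
    "n_natives",
    "hybrid_ratio",
    "neophyte_ratio",
]

GENUS_TALLY_COLUMNS = [
    "genus",
    "n_species_accepted",
    "n_hybrids",
    "n_neophytes",
    "hybrid_ratio",
    "neophyte_ratio",
    "ratios_defined",
]


def filter_hybrids(records: Iterable[TaxonRecord]) -> list[TaxonRecord]:
    """Keep accepted natural interspecific hybrids; drop artificial hybrids."""
    return [
        r
        for r in records
        if r.is_hybrid and not r.is_artificial_hybrid and r.name_status == "accepted"
    ]


def filter_neophytes(records: Iterable[TaxonRecord]) -> list[TaxonRecord]:
    """Keep accepted, naturalized, non-hybrid taxa (any rank, varieties included).

    Aliens — taxa whose establishment is unclear — are excluded, as are
    hybrid-flagged neophytes (so hybrids are never regressed on hybrids).
    """
    return [
        r
        for r in records
        if r.name_status == "accepted"
        and r.naturalization_status == "naturalized"
        and not r.is_hybrid
    ]


def filter_natives(records: Iterable[TaxonRecord]) -> list[TaxonRecord]:
    """Accepted species-rank taxa recorded as native (the ratio denominator)."""
    return [
        r
        for r in records
        if r.name_status == "accepted"
        and r.naturalization_status == "native"
        and not r.is_hybrid
        and r.rank == "species"
    ]


def _distinct_by_region(records: Sequence[TaxonRecord]) -> pd.Series:
    """Distinct taxon names per region code."""
    if not records:
        return pd.Series(dtype=int)
    df = pd.DataFrame(
        {"region_code": [r.region_code for r in records], "name": [r.taxon_name for r in records]}
    )
    return df.drop_duplicates().groupby("region_code").size()


def tally_by_country(
    hybrids: Sequence[TaxonRecord],
    neophytes: Sequence[TaxonRecord],
    natives: Sequence[TaxonRecord],
) -> pd.DataFrame:
    """Per-region counts and ratios of hybrids, neophytes and natives.

    Regions with neither hybrid nor neophyte records are dropped: absence of
    both more likely reflects a data-mobilization gap than a true absence.
    Ratios are NaN where the native denominator is zero.
    """
    h = _distinct_by_region(hybrids)
    n = _distinct_by_region(neophytes)
    m = _distinct_by_region(natives)
    regions = sorted(set(h.index) | set(n.index) | set(m.index))
    df = pd.DataFrame(
        {
            "region_code": regions,
            "n_hybrids": [int(h.get(r, 0)) for r in regions],
            "n_neophytes": [int(n.get(r, 0)) for r in regions],
            "n_natives": [int(m.get(r, 0)) for r in regions],
        }
    )
    df = df[(df["n_hybrids"] > 0) | (df["n_neophytes"] > 0)].reset_index(drop=True)
    denom = df["n_natives"].where(df["n_natives"] > 0, np.nan)
    df["hybrid_ratio"] = df["n_hybrids"] / denom
    df["neophyte_ratio"] = df["n_neophytes"] / denom
    return df[COUNTRY_TALLY_COLUMNS]


def _distinct_by_genus(records: Sequence[TaxonRecord]) -> pd.Series:
    if not records:
        return pd.Series(dtype=int)
    df = pd.DataFrame(
        {"genus": [r.genus for r in records], "name": [r.taxon_name for r in records]}
    )
    return df.drop_duplicates().groupby("genus").size()


def tally_by_genus(
    hybrids: Sequence[TaxonRecord],
    neophytes: Sequence[TaxonRecord],
    accepted_species: Sequence[TaxonRecord],
) -> pd.DataFrame:
    """Per-genus counts: accepted species (rank = species only), hybrids, neophytes.

    Ratios use the accepted-species count as denominator and may exceed 1
    (e.g. a genus with 18 accepted species and 26 hybrids has hybrid_ratio
    ~1.44); they are flagged undefined, not clamped, when the denominator is
    zero.
    """
    species = [
        r for r in accepted_species if r.rank == "species" and r.name_status == "accepted"
    ]
    s = _distinct_by_genus(species)
    h = _distinct_by_genus(hybrids)
    n = _distinct_by_genus(neophytes)
    genera = sorted(set(s.index) | set(h.index) | set(n.index))
    df = pd.DataFrame(
        {
            "genus": genera,
            "n_species_accepted": [int(s.get(g, 0)) for g in genera],
            "n_hybrids": [int(h.get(g, 0)) for g in genera],
            "n_neophytes": [int(n.get(g, 0)) for g in genera],
        }
    )
    denom = df["n_species_accepted"].where(df["n_species_accepted"] > 0, np.nan)
    df["hybrid_ratio"] = df["n_hybrids"] / denom
    df["neophyte_ratio"] = df["n_neophytes"] / denom
    df["ratios_defined"] = df["n_species_accepted"] > 0
    return df[GENUS_TALLY_COLUMNS]


def restrict_to_both(genus_tally: pd.DataFrame) -> pd.DataFrame:
    """Genera containing both hybrids and neophytes (the regression subset)."""
    mask = (genus_tally["n_hybrids"] > 0) & (genus_tally["n_neophytes"] > 0)
    return genus_tally[mask].reset_index(drop=True)


def write_tally(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_tally(path) -> pd.DataFrame:
    return pd.read_csv(path)
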