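"""Taxonomic-effort covariates: GDP crosswalk and range-weighted author counts.

GDP per capita is recorded per *political* country and year; botanical
countries (the analysis unit) are crosswalked by first averaging each
political country's series over years, then copying the value to every
botanical country inside it, and averaging (unweighted) where several
political countries share one botanical country.

Taxonomist effort follows the describer-count approach with a spillage
correction: an author is credited to a region if at least one taxon they
described occurs there, and the credit is the reciprocal of the mean range
size (number of occupied regions) of their described taxa occurring in that
region — so describers of widespread species are down-weighted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def gdp_crosswalk(gdp_table: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Crosswalk yearly political-country GDP onto botanical regions.

    Parameters
    ----------
    gdp_table
        Columns ``political_code``, ``year``, ``gdp``; gaps (NaN) allowed.
    mapping
        Columns ``political_code``, ``region_code`` (many-to-many pairs).

    Returns
    -------
    DataFrame with ``region_code`` and ``gdp_per_capita``; regions with no
    mapped political country (or no GDP data) carry NaN — missing is
    flagged, never zero-filled.
    """
    gdp = gdp_table.copy()
    gdp["gdp"] = pd.to_numeric(gdp["gdp"], errors="coerce")
    per_political = gdp.groupby("political_code")["gdp"].mean()  # skips NaN years
    merged = mapping.merge(
        per_political.rename("gdp_per_capita"),
        left_on="political_code",
        right_index=True,
        how="left",
    )
    out = (
        merged.groupby("region_code")["gdp_per_capita"]
        .mean()
        .reset_index()
        .sort_values("region_code", ignore_index=True)
    )
    return out


def taxonomist_effort(
    descriptions: pd.DataFrame,
    presence: pd.DataFrame,
    ranges: pd.Series | None = None,
) -> pd.DataFrame:
    """Range-weighted describer counts per region.

    Parameters
    ----------
    descriptions
        Columns ``author``, ``taxon_name`` — who first described what.
    presence
        Columns ``taxon_name``, ``region_code`` — where described taxa occur.
    ranges
        Optional taxon -> range size (occupied-region count) override;
        computed from ``presence`` when omitted. Every described taxon must
        have range size >= 1.

    Returns
    -------
    DataFrame ``region_code``, ``taxonomist_effort`` where the region score
    is the sum over credited authors of 1 / mean(range sizes of that
    author's described taxa occurring in the region). Each author's
    contribution therefore lies in (0, 1].
    """
    desc = descriptions[["author", "taxon_name"]].drop_duplicates()
    pres = presence[["taxon_name", "region_code"]].drop_duplicates()
    if ranges is None:
        ranges = pres.groupby("taxon_name")["region_code"].nunique()
    ranges = pd.Series(ranges, dtype=float)
    described = desc["taxon_name"].unique()
    missing = [t for t in described if ranges.get(t, 0) < 1]
    if missing:
        raise ValidationError(
            f"described taxa with range size 0 (absent from presence): {missing[:5]}"
        )
    triples = desc.merge(pres, on="taxon_name")
    triples["range_size"] = triples["taxon_name"].map(ranges)
    per_author_region = (
        triples.drop_duplicates(["author", "taxon_name", "region_code"])
        .groupby(["author", "region_code"])["range_size"]
        .mean()
    )
    contrib = 1.0 / per_author_region
    out = (
        contrib.groupby("region_code")
        .sum()
        .rename("taxonomist_effort")
        .reset_index()
        .sort_values("region_code", ignore_index=True)
    )
    return out


def effort_covariates(
    gdp: pd.DataFrame, effort: pd.DataFrame, areas: pd.DataFrame
) -> pd.DataFrame:
    """Merge GDP, taxonomist effort and area into one covariate table.

    ``areas`` has columns ``region_code``, ``area_km2``. Regions missing a
    covariate keep NaN (flagged for the caller to drop or impute explicitly);
    a region with no describer credit at all scores 0 effort.
    """
    out = areas[["region_code", "area_km2"]].copy()
    out["area_km2"] = pd.to_numeric(out["area_km2"], errors="coerce")
    out = out.merge(gdp, on="region_code", how="left")
    out = out.merge(effort, on="region_code", how="left")
    out["taxonomist_effort"] = out["taxonomist_effort"].fillna(0.0)
    if not np.isfinite(out["area_km2"]).all():
        raise ValidationError("non-finite area values")
    return out.sort_values("region_code", ignore_index=True)
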