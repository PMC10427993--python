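"""Zonal footprint statistics and hybrid/native/neophyte triplet comparisons.

The human-footprint raster (~1 km cells, values 0-50) is summarised per
hectad (10 × 10 km recording cell) as the mean over all raster cells whose
*center* falls inside the hectad rectangle (half-open on the max edges so no
cell is counted twice). Hectad means are then joined to taxon occupancy to
give one footprint observation per (taxon, occupied hectad). A triplet —
a hybrid with its native and neophyte parent — enters the comparison only
when the hybrid occupies strictly more than 10 hectads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .taxa_io import FootprintGrid

TAXON_TYPES = ("hybrid", "native", "neophyte")

#: "more than 10 hectads" inclusion rule
MIN_HECTADS_DEFAULT = 11


def hectad_mean_hfi(grid: FootprintGrid, polygons: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Mean footprint per hectad rectangle (cell-center containment).

    ``polygons`` columns: ``hectad_code, xmin, ymin, xmax, ymax`` in the
    grid's planar coordinate system; a CRS tag mismatch is an error.
    Hectads with no contributing non-missing cell are omitted and reported.
    """
    poly_crs = polygons.attrs.get("crs_tag", "unspecified")
    if (
        poly_crs != "unspecified"
        and grid.crs_tag != "unspecified"
        and poly_crs != grid.crs_tag
    ):
        raise ValidationError(
            f"CRS mismatch: raster {grid.crs_tag!r} vs hectads {poly_crs!r}"
        )
    xs, ys = grid.cell_centers()
    rows = []
    empty = []
    for rec in polygons.itertuples(index=False):
        # half-open on max edges: [xmin, xmax) x [ymin, ymax)
        col_mask = (xs >= rec.xmin) & (xs < rec.xmax)
        row_mask = (ys >= rec.ymin) & (ys < rec.ymax)
        block = grid.values[np.ix_(row_mask, col_mask)]
        vals = block[~np.isnan(block)]
        if vals.size == 0:
            empty.append(rec.hectad_code)
            continue
        rows.append(
            {
                "hectad_code": rec.hectad_code,
                "mean_hfi": float(vals.mean()),
                "n_cells": int(vals.size),
            }
        )
    report = {"n_hectads_in": len(polygons), "n_omitted_no_cells": len(empty), "omitted": empty}
    return pd.DataFrame(rows, columns=["hectad_code", "mean_hfi", "n_cells"]), report


def apply_occupancy_rule(
    occurrences: pd.DataFrame,
    triplets: pd.DataFrame,
    min_hectads: int = MIN_HECTADS_DEFAULT,
) -> pd.DataFrame:
    """Flag triplets whose hybrid occupies at least ``min_hectads`` hectads.

    The default of 11 realises the "strictly more than 10 hectads" rule; a
    hybrid seen in exactly 10 hectads is excluded.
    """
    counts = occurrences.groupby("taxon_name")["hectad_code"].nunique()
    out = triplets.copy()
    out["included"] = [
        int(counts.get(name, 0)) >= min_hectads for name in out["hybrid_name"]
    ]
    return out


def triplet_observations(
    occurrences: pd.DataFrame,
    hectad_footprints: pd.DataFrame,
    triplets: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """One footprint observation per (taxon, occupied hectad with coverage).

    Only triplets flagged ``included`` contribute. Taxa whose occupied
    hectads have no footprint coverage at all are excluded and reported.
    """
    if "included" not in triplets.columns:
        raise DataError("triplets must carry the 'included' flag; apply the occupancy rule first")
    inc = triplets[triplets["included"].astype(bool)]
    long = inc.melt(
        id_vars=["triplet_id"],
        value_vars=["hybrid_name", "native_name", "neophyte_name"],
        var_name="taxon_type",
        value_name="taxon_name",
    )
    long["taxon_type"] = long["taxon_type"].str.replace("_name", "", regex=False)
    obs = long.merge(occurrences, on="taxon_name")
    obs = obs.merge(hectad_footprints[["hectad_code", "mean_hfi"]], on="hectad_code")
    obs = obs.rename(columns={"mean_hfi": "hfi"})
    joined_taxa = set(obs["taxon_name"])
    unjoined = sorted(set(long["taxon_name"]) - joined_taxa)
    report = {"n_taxa_no_joinable_hectads": len(unjoined), "unjoined_taxa": unjoined}
    obs = obs[["triplet_id", "taxon_type", "taxon_name", "hectad_code", "hfi"]]
    return obs.reset_index(drop=True), report


def range_coverage_stats(observations: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-triplet range-extreme comparisons of footprint values.

    ``hybrid_min_above_native_min``: the hybrid's range omits the most
    natural habitat its native parent reaches (min hybrid HFI strictly above
    min native HFI). ``hybrid_max_above_both_parents``: the hybrid pushes
    into more disturbed areas than either parent (max hybrid HFI strictly
    above both parents' maxima). Triplets missing a type are skipped and
    reported.
    """
    rows = []
    skipped = []
    for tid, sub in observations.groupby("triplet_id"):
        by_type = {t: g["hfi"].to_numpy(float) for t, g in sub.groupby("taxon_type")}
        if any(t not in by_type for t in TAXON_TYPES):
            skipped.append(tid)
            continue
        h, nat, neo = (by_type[t] for t in TAXON_TYPES)
        rows.append(
            {
                "triplet_id": tid,
                "hybrid_min_above_native_min": bool(h.min() > nat.min()),
                "hybrid_max_above_both_parents": bool(
                    h.max() > nat.max() and h.max() > neo.max()
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["triplet_id", "hybrid_min_above_native_min", "hybrid_max_above_both_parents"],
    )
    counts = {
        "n_triplets_evaluated": len(df),
        "n_hybrid_min_above_native_min": int(df["hybrid_min_above_native_min"].sum())
        if len(df)
        else 0,
        "n_hybrid_max_above_both_parents": int(df["hybrid_max_above_both_parents"].sum())
        if len(df)
        else 0,
        "n_skipped_missing_type": len(skipped),
        "skipped": skipped,
    }
    return df, counts
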