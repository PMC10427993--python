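"""Readers, writers and validated in-memory types for every input format.

Checklists arrive as delimited text in two dialects: the world-checklist
("wcvp") layout used for accepted names, ranks and hybrid markers, and the
naturalized-alien-flora ("glonaf") layout used for naturalization status.
Both are mapped onto the unified :class:`TaxonRecord`. Trees are Newick
(via dendropy), human-footprint rasters are ESRI ASCII grids with values on
the 0-50 scale, occupancy is a taxon-by-hectad CSV, and hectad geometry is a
CSV of axis-aligned rectangles in the same planar coordinate system as the
raster.

Every reader returns a :class:`ReadResult` carrying the parsed object plus a
:class:`ReadReport` so that dropped rows are always accounted for
(``drop counts + retained rows == input rows``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

RANKS = {
    "species",
    "variety",
    "subvariety",
    "convariety",
    "form",
    "subform",
    "subspecies",
    "hybrid_species",
    "other",
}

NAME_STATUSES = {"accepted", "not_accepted"}
NATURALIZATION_STATUSES = {"naturalized", "alien", "native", "not_applicable"}

#: columns each checklist dialect must provide (optional extras in comments)
DIALECT_COLUMNS = {
    # optional: occurrence_status, artificial_hybrid
    "wcvp": ["taxon_name", "genus", "rank", "species_hybrid", "taxon_status", "region_code"],
    # optional: rank
    "glonaf": ["taxon_name", "genus", "name_status", "status", "hybrid", "region_code"],
}

_FALSY = {"", "0", "false", "no", "nan", "none"}

_WS_RUN = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Deterministic name normalization used for every join and tally key.

    Trims, collapses internal whitespace runs and removes the hybrid sign
    "×" (and a leading "x " marker); comparisons stay case-sensitive.
    """
    s = str(name).replace("×", " ")
    s = _WS_RUN.sub(" ", s).strip()
    if s.startswith("x ") or s.startswith("X "):
        s = s[2:]
    return s


@dataclass(frozen=True)
class TaxonRecord:
    """One checklist row after dialect mapping and normalization."""

    taxon_name: str
    genus: str
    rank: str = "species"
    is_hybrid: bool = False
    is_artificial_hybrid: bool = False
    name_status: str = "accepted"
    naturalization_status: str = "not_applicable"
    region_code: str = ""

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ValidationError(f"unknown rank {self.rank!r}")
        if self.name_status not in NAME_STATUSES:
            raise ValidationError(f"unknown name_status {self.name_status!r}")
        if self.naturalization_status not in NATURALIZATION_STATUSES:
            raise ValidationError(
                f"unknown naturalization_status {self.naturalization_status!r}"
            )
        if self.is_artificial_hybrid and not self.is_hybrid:
            raise ValidationError("is_artificial_hybrid implies is_hybrid")


@dataclass
class ReadReport:
    """Bookkeeping for one read: every input row is retained or counted here."""

    n_rows: int = 0
    n_retained: int = 0
    n_dropped_numeric_region: int = 0
    n_dropped_empty_region: int = 0
    n_dropped_duplicate: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            self.n_dropped_numeric_region
            + self.n_dropped_empty_region
            + self.n_dropped_duplicate
        )


@dataclass
class ReadResult:
    records: object
    report: ReadReport


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    return "\t" if "\t" in first else ","


def _truthy(value) -> bool:
    return str(value).strip().lower() not in _FALSY


def _norm_rank(value) -> str:
    v = str(value).strip().lower().replace(" ", "_")
    if v in {"", "nan"}:
        return "species"
    return v if v in RANKS else "other"


def read_checklist(path, dialect: str) -> ReadResult:
    """Read a checklist file into :class:`TaxonRecord` rows.

    Rows whose region code is purely numeric (a known mis-coding of
    botanical-country identifiers) or empty are dropped and counted in the
    report, never silently discarded.
    """
    if dialect not in DIALECT_COLUMNS:
        raise FormatError(f"unknown checklist dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    required = DIALECT_COLUMNS[dialect]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    report = ReadReport(n_rows=len(df))
    records: list[TaxonRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        region = str(d["region_code"]).strip()
        if region == "":
            report.n_dropped_empty_region += 1
            continue
        if region.isdigit():
            report.n_dropped_numeric_region += 1
            continue
        if dialect == "wcvp":
            rec = TaxonRecord(
                taxon_name=normalize_name(d["taxon_name"]),
                genus=normalize_name(d["genus"]),
                rank=_norm_rank(d["rank"]),
                is_hybrid=_truthy(d["species_hybrid"]),
                is_artificial_hybrid=_truthy(d.get("artificial_hybrid", "")),
                name_status=(
                    "accepted"
                    if str(d["taxon_status"]).strip().lower() == "accepted"
                    else "not_accepted"
                ),
                naturalization_status=_status_wcvp(d.get("occurrence_status", "native")),
                region_code=region,
            )
        else:
            rec = TaxonRecord(
                taxon_name=normalize_name(d["taxon_name"]),
                genus=normalize_name(d["genus"]),
                rank=_norm_rank(d.get("rank", "species")),
                is_hybrid=_truthy(d["hybrid"]),
                is_artificial_hybrid=False,
                name_status=(
                    "accepted"
                    if str(d["name_status"]).strip().lower() == "accepted"
                    else "not_accepted"
                ),
                naturalization_status=_status_glonaf(d["status"]),
                region_code=region,
            )
        records.append(rec)
    report.n_retained = len(records)
    return ReadResult(records=records, report=report)


def _status_wcvp(value) -> str:
    v = str(value).strip().lower()
    if v in {"", "nan", "native"}:
        return "native"
    if v in {"introduced", "alien"}:
        return "alien"
    if v == "naturalized":
        return "naturalized"
    return "not_applicable"


def _status_glonaf(value) -> str:
    v = str(value).strip().lower()
    if v == "naturalized":
        return "naturalized"
    if v == "alien":
        return "alien"
    if v == "native":
        return "native"
    return "not_applicable"


def write_checklist(records: Iterable[TaxonRecord], path, dialect: str) -> None:
    """Write records back out in the named dialect (round-trip partner)."""
    rows = []
    for r in records:
        if dialect == "wcvp":
            rows.append(
                {
                    "taxon_name": r.taxon_name,
                    "genus": r.genus,
                    "rank": r.rank,
                    "species_hybrid": "×" if r.is_hybrid else "",
                    "artificial_hybrid": "1" if r.is_artificial_hybrid else "",
                    "taxon_status": "Accepted" if r.name_status == "accepted" else "Synonym",
                    "occurrence_status": r.naturalization_status,
                    "region_code": r.region_code,
                }
            )
        elif dialect == "glonaf":
            rows.append(
                {
                    "taxon_name": r.taxon_name,
                    "genus": r.genus,
                    "rank": r.rank,
                    "name_status": "accepted" if r.name_status == "accepted" else "unresolved",
                    "status": r.naturalization_status,
                    "hybrid": "1" if r.is_hybrid else "0",
                    "region_code": r.region_code,
                }
            )
        else:
            raise FormatError(f"unknown checklist dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in Myr; tip labels unique."""

    tree: dendropy.Tree
    tip_labels: list[str]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def total_branch_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.edges() if e.head_node.parent_node)


def read_tree(path) -> ReadResult:
    """Read a single rooted Newick tree; duplicate tip labels are rejected."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:
        if "uplicate taxon" in str(exc):
            raise ValidationError(f"{path}: duplicate tip labels") from exc
        raise FormatError(f"{path}: unparsable Newick ({exc})") from exc
    labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
    seen, dupes = set(), set()
    for lab in labels:
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
    if dupes:
        raise ValidationError(f"{path}: duplicate tip labels {sorted(dupes)}")
    report = ReadReport(n_rows=len(labels), n_retained=len(labels))
    n_zero = sum(
        1 for leaf in tree.leaf_node_iter() if (leaf.edge.length or 0.0) == 0.0
    )
    if n_zero:
        report.notes.append(f"{n_zero} zero-length terminal branch(es)")
    return ReadResult(records=Phylogeny(tree=tree, tip_labels=labels), report=report)


# ---------------------------------------------------------------------------
# Rasters (human footprint index, ESRI ASCII grid dialect)

HFI_MIN, HFI_MAX = 0.0, 50.0


@dataclass
class FootprintGrid:
    """Regular planar grid of footprint values; missing cells are NaN."""

    values: np.ndarray  # 2-D float array, row 0 = northernmost row
    cell_size: float
    origin: tuple[float, float]  # (x, y) of the lower-left corner
    crs_tag: str = "unspecified"
    nodata: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x-centers per column, y-centers per row), row 0 on top."""
        nrows, ncols = self.values.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.origin[1] + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return xs, ys


def read_raster(path) -> ReadResult:
    """Read an ESRI ASCII grid; values must lie in [0, 50] or be the sentinel."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    header: dict[str, float] = {}
    data_start = 0
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        toks = line.split()
        if not toks:
            continue
        if toks[0][0].isalpha():
            if len(toks) != 2:
                raise FormatError(f"{path}: malformed header line {line!r}")
            try:
                header[toks[0].lower()] = float(toks[1])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric header value in {line!r}") from exc
        else:
            data_start = i
            break
    else:
        raise FormatError(f"{path}: no data rows")
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing header field {key!r}")
    try:
        values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: grid shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", -9999.0)
    mask = values == nodata
    vals = np.where(mask, np.nan, values)
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < HFI_MIN or finite.max() > HFI_MAX):
        raise ValidationError(
            f"{path}: footprint values outside [{HFI_MIN}, {HFI_MAX}]"
        )
    prj = path.with_suffix(".prj")
    crs_tag = prj.read_text(encoding="utf-8").strip() if prj.exists() else "unspecified"
    grid = FootprintGrid(
        values=vals,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        crs_tag=crs_tag,
        nodata=nodata,
    )
    report = ReadReport(n_rows=vals.size, n_retained=int(np.sum(~np.isnan(vals))))
    report.n_dropped_empty_region = int(np.sum(np.isnan(vals)))  # missing cells
    return ReadResult(records=grid, report=report)


def write_raster(grid: FootprintGrid, path) -> None:
    path = Path(path)
    nrows, ncols = grid.values.shape
    out = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(grid.origin[0])!r}\n")
        fh.write(f"yllcorner {float(grid.origin[1])!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"nodata_value {float(grid.nodata)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    if grid.crs_tag != "unspecified":
        path.with_suffix(".prj").write_text(grid.crs_tag + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Occupancy, hectad polygons, stem ages


def read_occurrences(path) -> ReadResult:
    """CSV of (taxon_name, hectad_code); duplicate pairs collapsed and counted."""
    df = _read_table(path, ["taxon_name", "hectad_code"])
    df["taxon_name"] = df["taxon_name"].map(normalize_name)
    df["hectad_code"] = df["hectad_code"].astype(str).str.strip()
    n = len(df)
    out = df.drop_duplicates(ignore_index=True)
    report = ReadReport(n_rows=n, n_retained=len(out))
    report.n_dropped_duplicate = n - len(out)
    return ReadResult(records=out, report=report)


def read_hectad_polygons(path) -> ReadResult:
    """CSV of hectad_code + rectangle corners (xmin, ymin, xmax, ymax)."""
    df = _read_table(path, ["hectad_code", "xmin", "ymin", "xmax", "ymax"])
    for col in ("xmin", "ymin", "xmax", "ymax"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["xmax"] <= df["xmin"]).any() or (df["ymax"] <= df["ymin"]).any():
        raise ValidationError(f"{path}: degenerate hectad rectangle")
    prj = Path(path).with_suffix(".prj")
    df.attrs["crs_tag"] = (
        prj.read_text(encoding="utf-8").strip() if prj.exists() else "unspecified"
    )
    return ReadResult(records=df, report=ReadReport(n_rows=len(df), n_retained=len(df)))


def read_stem_ages(path) -> ReadResult:
    """Stem-age table: genus + positive age in Myr (column `rn.bl` or `stem_age`)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if "genus" not in df.columns:
        raise FormatError(f"{path}: missing required column 'genus'")
    age_col = "rn.bl" if "rn.bl" in df.columns else "stem_age"
    if age_col not in df.columns:
        raise FormatError(f"{path}: missing required column 'rn.bl' (or 'stem_age')")
    out = pd.DataFrame(
        {
            "genus": df["genus"].map(normalize_name),
            "stem_age": pd.to_numeric(df[age_col], errors="raise"),
        }
    )
    if (out["stem_age"] <= 0).any():
        raise ValidationError(f"{path}: stem ages must be positive")
    return ReadResult(records=out, report=ReadReport(n_rows=len(out), n_retained=len(out)))


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    return df
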