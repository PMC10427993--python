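"""Synthetic worlds with planted ground truth for every pipeline stage.

Three generators emulate the shapes of the real inputs without any
download, each fully deterministic under the configured seed:

* :func:`gen_checklists` — a country-stage pair of checklist files (world-
  checklist dialect + naturalized-flora dialect) whose per-country hybrid
  counts follow the Gaussian-on-log10 regression with a known slope, plus
  raw-material files for the effort covariates, and a separate genus-stage
  checklist pair whose hybrid/neophyte *ratios* follow a known slope.
  Filter-rule violators (artificial hybrids, aliens, hybrid neophytes,
  numeric region codes, non-accepted names) are planted in known numbers.
* :func:`gen_phylogeny` — a pure-birth genus tree; stem ages are the
  terminal branch lengths, and each genus' richness is chosen by inverting
  the stem-age method-of-moments estimator so that its rate equals a known
  group multiplier times a base rate (up to lognormal noise and randomized
  integer rounding). Also provides Brownian-motion traits simulated by
  walking the tree edges (independent of the covariance-matrix code that
  the signal statistic uses).
* :func:`gen_footprint_world` — a footprint raster with a west-east
  gradient, hectad rectangles, taxon occupancy and a triplet table whose
  per-type footprint means sit at a base level plus known type offsets.

Counts are lognormal on the latent scale (matching the Gaussian-on-log10
models, so recovery is exact in expectation) and every generator writes a
``ground_truth.json`` consumed by the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigError
from .taxa_io import FootprintGrid, write_raster


@dataclass
class WorldConfig:
    """Study conditions for the synthetic worlds.

    Effect sizes default to the planted-recovery targets of the analysis:
    country slope 0.26, genus ratio slope 0.64, group rate multipliers
    (1, 1.6, 2.5, 2.91) on a base rate of 0.05 species/Myr, and footprint
    type offsets (native 0, neophyte +2.0, hybrid +5.9) on a base mean of
    22.6. Scales (200 regions, 800 genera, 30 triplets) keep a full
    pipeline run within a few minutes on one CPU.
    """

    n_regions: int = 200
    n_genera: int = 800
    n_triplets: int = 30
    seed: int = 20230816

    # --- country world
    true_country_slope: float = 0.26
    country_covariate_slopes: tuple[float, float, float] = (0.10, 0.15, 0.10)
    country_intercept: float = -0.26
    country_noise_sd: float = 0.15

    # --- genus world (ratio regression)
    n_genera_checklist: int = 600
    true_genus_slope: float = 0.64
    genus_intercept: float = -0.23
    genus_noise_sd: float = 0.20

    # --- diversification world
    base_rate: float = 0.05
    group_rate_multipliers: tuple[float, float, float, float] = (1.0, 1.6, 2.5, 2.91)
    rate_noise_sd: float = 0.12  # sd on the log10 rate scale
    extinction_fraction: float = 0.9

    # --- footprint world
    hfi_base: float = 22.6
    hfi_type_offsets: tuple[float, float, float] = (0.0, 2.0, 5.9)  # native, neophyte, hybrid
    hfi_noise_sd: float = 4.0
    hfi_triplet_sd: float = 1.5
    hfi_slope_sd: float = 0.8
    n_hectads_side: int = 20  # 20 x 20 hectads of 10 x 10 cells
    occupancy_per_type: tuple[int, int, int] = (120, 80, 34)  # native, neophyte, hybrid
    n_small_range_hybrids: int = 2  # planted at <= 10 hectads -> excluded

    # --- planted filter violators (country files)
    n_artificial_hybrids: int = 10
    n_alien_rows: int = 10
    n_neophyte_hybrids: int = 5
    n_numeric_region_rows: int = 7
    n_nonaccepted_rows: int = 6

    def __post_init__(self):
        if self.n_regions < 5:
            raise ConfigError("n_regions must be at least 5")
        if any(m <= 0 for m in self.group_rate_multipliers):
            raise ConfigError("group rate multipliers must be positive")
        if self.n_genera < 8 or self.n_genera_checklist < 8:
            raise ConfigError("too few genera to populate all groups")


def _region_codes(n: int) -> list[str]:
    codes = []
    i = 0
    while len(codes) < n:
        a, b, c = i // 676, (i // 26) % 26, i % 26
        codes.append(chr(65 + a) + chr(65 + b) + chr(65 + c))
        i += 1
    return codes


def _round_pos(rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
    """Randomized rounding to a positive integer (unbiased given the latent)."""
    lo = np.floor(x)
    out = lo + (rng.random(np.shape(x)) < (x - lo))
    return np.maximum(1, out).astype(int)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# Country + genus checklist world


def gen_checklists(cfg: WorldConfig, outdir) -> dict:
    """Write the checklist, effort and congener inputs; return ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    truth: dict = {"config": asdict(cfg)}
    truth.update(_gen_country_world(cfg, outdir, np.random.default_rng(ss[0])))
    truth.update(_gen_genus_checklists(cfg, outdir, np.random.default_rng(ss[1])))
    _write_json(truth, outdir / "ground_truth_checklists.json")
    return truth


def _gen_country_world(cfg: WorldConfig, outdir: Path, rng: np.random.Generator) -> dict:
    R = cfg.n_regions
    regions = _region_codes(R)
    genus_pool = [f"Genus{j:03d}" for j in range(60)]
    shared = genus_pool[:30]  # genera where neophytes can meet native congeners

    log_n = rng.normal(1.3, 0.35, R)
    n_neo = _round_pos(rng, 10.0**log_n)
    gdp = 10.0 ** rng.normal(4.0, 0.4, R)
    effort = _round_pos(rng, 10.0 ** rng.normal(0.8, 0.35, R))
    area = 10.0 ** rng.normal(5.0, 0.5, R)
    be, bt, ba = cfg.country_covariate_slopes
    eta = (
        cfg.country_intercept
        + cfg.true_country_slope * np.log10(n_neo)
        + be * np.log10(gdp)
        + bt * np.log10(effort)
        + ba * np.log10(area)
        + rng.normal(0.0, cfg.country_noise_sd, R)
    )
    n_hyb = _round_pos(rng, 10.0**eta)
    n_nat = _round_pos(rng, 10.0 ** rng.normal(1.7, 0.3, R))

    wcvp_rows: list[dict] = []
    glonaf_rows: list[dict] = []

    def wcvp(name, genus, region, rank="species", hybrid="", artificial="",
             status="Accepted", occ="native"):
        wcvp_rows.append(
            {
                "taxon_name": name,
                "genus": genus,
                "rank": rank,
                "species_hybrid": hybrid,
                "artificial_hybrid": artificial,
                "taxon_status": status,
                "occurrence_status": occ,
                "region_code": region,
            }
        )

    def glonaf(name, genus, region, status="naturalized", hybrid="0",
               name_status="accepted", rank="species"):
        glonaf_rows.append(
            {
                "taxon_name": name,
                "genus": genus,
                "rank": rank,
                "name_status": name_status,
                "status": status,
                "hybrid": hybrid,
                "region_code": region,
            }
        )

    # neophyte species pool shared across regions: naturalization events are
    # (species, region) pairs and one species can naturalize in many regions
    pool_size = max(300, 6 * R)
    neo_pool = [
        (
            f"Neophyte species {j}",
            shared[int(rng.integers(30))]
            if rng.random() < 0.75
            else genus_pool[30 + int(rng.integers(30))],
        )
        for j in range(pool_size)
    ]

    native_pairs: set[tuple[str, str]] = set()
    event_rows: list[tuple[str, str, str]] = []
    for i, r in enumerate(regions):
        for k in range(n_hyb[i]):
            wcvp(f"Hybrid {r} {k}", genus_pool[int(rng.integers(60))], r, hybrid="×")
        for k in range(n_nat[i]):
            g = shared[int(rng.integers(30))] if rng.random() < 0.8 else genus_pool[30 + int(rng.integers(30))]
            wcvp(f"Native {r} {k}", g, r)
            native_pairs.add((g, r))
        for j in rng.choice(pool_size, size=min(int(n_neo[i]), pool_size), replace=False):
            name, g = neo_pool[int(j)]
            glonaf(name, g, r)
            event_rows.append((name, g, r))

    # one duplicated native row per first region (distinctness exercise)
    wcvp("Native " + regions[0] + " 0", wcvp_rows[n_hyb[0]]["genus"], regions[0])

    # planted violators, all in the first few regions
    for k in range(cfg.n_artificial_hybrids):
        wcvp(f"Artificial hybrid {k}", genus_pool[0], regions[k % R], hybrid="×", artificial="1")
    for k in range(cfg.n_nonaccepted_rows):
        wcvp(f"Synonym hybrid {k}", genus_pool[1], regions[k % R], hybrid="×", status="Synonym")
    for k in range(cfg.n_alien_rows):
        glonaf(f"Alien {k}", genus_pool[2], regions[k % R], status="alien")
    for k in range(cfg.n_neophyte_hybrids):
        glonaf(f"Neophyte hybrid {k}", genus_pool[3], regions[k % R], hybrid="1")
    for k in range(cfg.n_numeric_region_rows):
        glonaf(f"Miscoded {k}", genus_pool[4], str(2 + 3 * k))

    pd.DataFrame(wcvp_rows).to_csv(outdir / "wcvp_country.csv", index=False)
    pd.DataFrame(glonaf_rows).to_csv(outdir / "glonaf_country.csv", index=False)

    # effort raw material: per-region political country with constant GDP,
    # and `effort[i]` authors each describing one single-region taxon
    gdp_rows, map_rows, author_rows, pres_rows, area_rows = [], [], [], [], []
    for i, r in enumerate(regions):
        pol = f"P{r}"
        map_rows.append({"political_code": pol, "region_code": r})
        for year in range(2016, 2021):
            gdp_rows.append({"political_code": pol, "year": year, "gdp": gdp[i]})
        for k in range(effort[i]):
            taxon = f"Described taxon {r} {k}"
            author_rows.append({"author": f"Author {r} {k}", "taxon_name": taxon})
            pres_rows.append({"taxon_name": taxon, "region_code": r})
        area_rows.append({"region_code": r, "area_km2": area[i]})
    pd.DataFrame(gdp_rows).to_csv(outdir / "gdp.csv", index=False)
    pd.DataFrame(map_rows).to_csv(outdir / "gdp_mapping.csv", index=False)
    pd.DataFrame(author_rows).to_csv(outdir / "authors.csv", index=False)
    pd.DataFrame(pres_rows).to_csv(outdir / "effort_presence.csv", index=False)
    pd.DataFrame(area_rows).to_csv(outdir / "areas.csv", index=False)

    # congener truth by direct set counting on the generated events
    n_events = len(event_rows)
    with_con = [(g, r) in native_pairs for (_, g, r) in event_rows]
    species = {}
    for (name, g, r), w in zip(event_rows, with_con):
        species[name] = species.get(name, False) or w
    return {
        "country": {
            "true_slope": cfg.true_country_slope,
            "covariate_slopes": list(cfg.country_covariate_slopes),
            "intercept": cfg.country_intercept,
            "noise_sd": cfg.country_noise_sd,
            "n_regions": R,
            "per_region_hybrids": {r: int(h) for r, h in zip(regions, n_hyb)},
            "per_region_neophytes": {r: int(v) for r, v in zip(regions, n_neo)},
            "per_region_natives": {r: int(v) for r, v in zip(regions, n_nat)},
            "taxonomist_effort": {r: int(v) for r, v in zip(regions, effort)},
            "gdp": {r: float(v) for r, v in zip(regions, gdp)},
        },
        "planted": {
            "artificial_hybrids": cfg.n_artificial_hybrids,
            "nonaccepted_hybrids": cfg.n_nonaccepted_rows,
            "aliens": cfg.n_alien_rows,
            "neophyte_hybrids": cfg.n_neophyte_hybrids,
            "numeric_region_rows": cfg.n_numeric_region_rows,
        },
        "congeners": {
            "n_events": n_events,
            "n_events_with_congener": int(sum(with_con)),
            "n_species": len(species),
            "n_species_with_congener": int(sum(species.values())),
        },
    }


def _gen_genus_checklists(cfg: WorldConfig, outdir: Path, rng: np.random.Generator) -> dict:
    G = cfg.n_genera_checklist
    n_both = int(round(G * 2 / 3))
    n_neo_only = n_hyb_only = int(round(G / 9))
    n_neither = G - n_both - n_neo_only - n_hyb_only
    genera = [f"Checkgenus{j:04d}" for j in range(G)]
    kinds = (["both"] * n_both + ["neo"] * n_neo_only + ["hyb"] * n_hyb_only
             + ["neither"] * n_neither)

    wcvp_rows, glonaf_rows = [], []
    truth_rows = []
    for g, kind in zip(genera, kinds):
        richness = int(_round_pos(rng, 10.0 ** rng.normal(1.45, 0.25, 1))[0])  # ~30
        n_h = n_n = 0
        if kind in ("both", "hyb"):
            if kind == "both":
                # draw the neophyte count first, then condition the hybrid
                # count on the *realized* ratio so the planted slope is the
                # regression truth (no errors-in-variables from rounding)
                n_n = int(_round_pos(rng, np.array([richness * 10.0 ** rng.normal(-0.5, 0.35)]))[0])
                log_rn = np.log10(n_n / richness)
                log_rh = (
                    cfg.genus_intercept
                    + cfg.true_genus_slope * log_rn
                    + rng.normal(0.0, cfg.genus_noise_sd)
                )
                n_h = int(_round_pos(rng, np.array([richness * 10.0**log_rh]))[0])
            else:
                n_h = int(_round_pos(rng, np.array([rng.uniform(1, 6)]))[0])
        elif kind == "neo":
            n_n = int(_round_pos(rng, np.array([rng.uniform(1, 6)]))[0])
        for k in range(richness):
            wcvp_rows.append(
                {
                    "taxon_name": f"{g} species{k}",
                    "genus": g,
                    "rank": "species",
                    "species_hybrid": "",
                    "taxon_status": "Accepted",
                    "region_code": "GEN",
                }
            )
        for k in range(n_h):
            wcvp_rows.append(
                {
                    "taxon_name": f"{g} hybrid{k}",
                    "genus": g,
                    "rank": "hybrid_species",
                    "species_hybrid": "×",
                    "taxon_status": "Accepted",
                    "region_code": "GEN",
                }
            )
        for k in range(n_n):
            glonaf_rows.append(
                {
                    "taxon_name": f"{g} neophyte{k}",
                    "genus": g,
                    "rank": "variety" if (k == 0 and kind == "both" and rng.random() < 0.1) else "species",
                    "name_status": "accepted",
                    "status": "naturalized",
                    "hybrid": "0",
                    "region_code": "GEN",
                }
            )
        truth_rows.append({"genus": g, "richness": richness, "n_hybrids": n_h, "n_neophytes": n_n})
    pd.DataFrame(wcvp_rows).to_csv(outdir / "wcvp_genus.csv", index=False)
    pd.DataFrame(glonaf_rows).to_csv(outdir / "glonaf_genus.csv", index=False)
    return {
        "genus": {
            "true_slope": cfg.true_genus_slope,
            "intercept": cfg.genus_intercept,
            "noise_sd": cfg.genus_noise_sd,
            "n_genera": G,
            "n_both": n_both,
            "per_genus": truth_rows,
        }
    }


# ---------------------------------------------------------------------------
# Phylogeny + diversification world


def gen_phylogeny(cfg: WorldConfig, outdir) -> dict:
    """Pure-birth genus tree, stem ages, group-structured tallies, BM traits."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed + 1).spawn(3)
    rng = np.random.default_rng(ss[0])

    tree = _yule_tree(cfg.n_genera, rng)
    # scale so the median terminal edge is ~25 Myr
    term = np.array([leaf.edge.length for leaf in tree.leaf_node_iter()])
    scale = 25.0 / np.median(term)
    for e in tree.edges():
        if e.length is not None:
            e.length *= scale
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    stem_age = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
    tree.write(path=str(outdir / "genus_tree.nwk"), schema="newick",
               suppress_rooting=True)

    rng = np.random.default_rng(ss[1])
    groups = rng.choice([1, 2, 3, 4], size=cfg.n_genera, p=[0.40, 0.25, 0.15, 0.20])
    mult = np.array(cfg.group_rate_multipliers)
    rate = cfg.base_rate * mult[groups - 1] * 10.0 ** rng.normal(0, cfg.rate_noise_sd, cfg.n_genera)
    e = cfg.extinction_fraction
    ages = np.array([stem_age[lab] for lab in labels])
    # cap the exponent so deep-stem outliers stay finite (they get flagged
    # extreme downstream either way)
    latent_richness = (np.exp(np.minimum(rate * ages, 25.0)) - e) / (1.0 - e)
    richness = _round_pos(rng, latent_richness)
    # monotypic genera occur only in the no-hybrid groups; give groups 3/4 a sister
    richness[(richness == 1) & np.isin(groups, (3, 4))] = 2

    n_h = np.where(np.isin(groups, (3, 4)), rng.poisson(2.0, cfg.n_genera) + 1, 0)
    n_n = np.where(np.isin(groups, (2, 4)), rng.poisson(2.0, cfg.n_genera) + 1, 0)
    tallies = pd.DataFrame(
        {
            "genus": labels,
            "n_species_accepted": richness,
            "n_hybrids": n_h,
            "n_neophytes": n_n,
            "hybrid_ratio": n_h / richness,
            "neophyte_ratio": n_n / richness,
            "ratios_defined": True,
        }
    )
    tallies.to_csv(outdir / "genus_tallies.csv", index=False)
    pd.DataFrame({"genus": labels, "rn.bl": ages}).to_csv(outdir / "stem_ages.csv", index=False)

    truth = {
        "diversification": {
            "base_rate": cfg.base_rate,
            "group_rate_multipliers": list(cfg.group_rate_multipliers),
            "rate_noise_sd": cfg.rate_noise_sd,
            "extinction_fraction": e,
            "group_sizes": np.bincount(groups, minlength=5)[1:].tolist(),
        }
    }
    _write_json(truth, outdir / "ground_truth_phylogeny.json")
    return truth


def _yule_tree(n_tips: int, rng: np.random.Generator, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth tree grown tip by tip (exponential waiting times)."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    tips = [tree.seed_node]
    heights = {id(tree.seed_node): 0.0}
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        node.edge.length = t - heights[id(node)]
        for _ in range(2):
            child = node.new_child()
            child.edge.length = 0.0
            heights[id(child)] = t
            tips.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    for node in tips:
        node.edge.length = t_end - heights[id(node)]
    for k, node in enumerate(tree.leaf_node_iter()):
        node.taxon = taxa.new_taxon(label=f"Treegenus{k:04d}")
    return tree


def brownian_traits(
    tree: dendropy.Tree, n_traits: int, rng: np.random.Generator, sigma: float = 1.0
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion traits simulated by walking the tree edges.

    Returns an (n_tips, n_traits) array in leaf-iteration order. Pure
    edge-walk simulation: shares no code with the covariance-matrix route
    used by the signal statistic, so the two can cross-check each other.
    """
    values = {id(tree.seed_node): np.zeros(n_traits)}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        values[id(node)] = values[id(node.parent_node)] + rng.normal(
            0.0, sigma * np.sqrt(bl), n_traits
        )
    labels = []
    rows = []
    for leaf in tree.leaf_node_iter():
        labels.append(leaf.taxon.label if leaf.taxon else "")
        rows.append(values[id(leaf)])
    return np.asarray(rows), labels


# ---------------------------------------------------------------------------
# Footprint world


def gen_footprint_world(cfg: WorldConfig, outdir) -> dict:
    """Raster + hectads + occupancy + triplets with planted type offsets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed + 2))

    side = cfg.n_hectads_side
    ncells = side * 10
    # west-east gradient spanning most of the 0-50 scale, plus cell noise
    xfrac = (np.arange(ncells) + 0.5) / ncells
    base = 3.0 + 44.0 * xfrac
    values = np.clip(base[None, :] + rng.normal(0, 2.0, (ncells, ncells)), 0.0, 50.0)
    # ~1% missing cells
    miss = rng.random((ncells, ncells)) < 0.01
    values[miss] = np.nan
    grid = FootprintGrid(
        values=values, cell_size=1.0, origin=(0.0, 0.0), crs_tag="synthetic-planar", nodata=-9999.0
    )
    write_raster(grid, outdir / "hfi.asc")

    codes, rects = [], []
    for hx in range(side):
        for hy in range(side):
            code = f"{chr(65 + hx)}{chr(65 + hy)}{hx % 10}{hy % 10}"
            codes.append(code)
            rects.append(
                {
                    "hectad_code": code,
                    "xmin": hx * 10.0,
                    "ymin": hy * 10.0,
                    "xmax": (hx + 1) * 10.0,
                    "ymax": (hy + 1) * 10.0,
                }
            )
    poly = pd.DataFrame(rects)
    poly.to_csv(outdir / "hectad_polygons.csv", index=False)
    (outdir / "hectad_polygons.prj").write_text("synthetic-planar\n", encoding="utf-8")

    # hectad means for placement (cell-center rule on this aligned layout is
    # a plain 10x10 block mean)
    means = np.full(len(codes), np.nan)
    for i, rec in enumerate(rects):
        block = values[
            int(ncells - rec["ymax"]) : int(ncells - rec["ymin"]),
            int(rec["xmin"]) : int(rec["xmax"]),
        ]
        v = block[~np.isnan(block)]
        if v.size:
            means[i] = v.mean()
    order = np.argsort(means)
    sorted_means = means[order]

    off_native, off_neo, off_hyb = cfg.hfi_type_offsets
    offsets = {"native": off_native, "neophyte": off_neo, "hybrid": off_hyb}
    n_occ = {"native": cfg.occupancy_per_type[0], "neophyte": cfg.occupancy_per_type[1],
             "hybrid": cfg.occupancy_per_type[2]}

    trip_rows, occ_rows = [], []
    small_hybrids = []
    for t in range(cfg.n_triplets):
        tid = f"T{t:02d}"
        alpha = rng.normal(0.0, cfg.hfi_triplet_sd)
        names = {
            "hybrid": f"Hybrid taxon {t}",
            "native": f"Native taxon {t}",
            "neophyte": f"Neophyte taxon {t}",
        }
        trip_rows.append(
            {
                "triplet_id": tid,
                "hybrid_name": names["hybrid"],
                "native_name": names["native"],
                "neophyte_name": names["neophyte"],
            }
        )
        for typ in ("native", "neophyte", "hybrid"):
            b = rng.normal(0.0, cfg.hfi_slope_sd)
            k = n_occ[typ]
            if typ == "hybrid" and t < cfg.n_small_range_hybrids:
                k = 10  # planted at the exclusion boundary
                small_hybrids.append(names["hybrid"])
            targets = cfg.hfi_base + offsets[typ] + alpha + b + rng.normal(
                0.0, cfg.hfi_noise_sd, k
            )
            chosen = _match_hectads(targets, sorted_means, order, rng)
            for idx in chosen:
                occ_rows.append({"taxon_name": names[typ], "hectad_code": codes[idx]})
    pd.DataFrame(trip_rows).to_csv(outdir / "triplets.csv", index=False)
    pd.DataFrame(occ_rows).to_csv(outdir / "occurrences.csv", index=False)

    truth = {
        "footprint": {
            "hfi_base": cfg.hfi_base,
            "type_offsets": offsets,
            "type_means": {t: cfg.hfi_base + offsets[t] for t in offsets},
            "noise_sd": cfg.hfi_noise_sd,
            "triplet_sd": cfg.hfi_triplet_sd,
            "n_triplets": cfg.n_triplets,
            "small_range_hybrids": small_hybrids,
        }
    }
    _write_json(truth, outdir / "ground_truth_footprint.json")
    return truth


def _match_hectads(
    targets: np.ndarray, sorted_means: np.ndarray, order: np.ndarray, rng: np.random.Generator
) -> list[int]:
    """Nearest-mean hectad per target value, without replacement per taxon.

    ``sorted_means`` is ascending with NaNs (coverage-free hectads) at the
    end; ``order`` maps sorted position back to the hectad index. In a
    sorted array the nearest unused value is the closer of the first unused
    neighbour on each side of the insertion point.
    """
    n_finite = int(np.sum(np.isfinite(sorted_means)))
    if len(targets) > n_finite:
        raise ConfigError("more occupancy targets than hectads with coverage")
    used: set[int] = set()
    chosen: list[int] = []
    for y in targets:
        j = int(np.searchsorted(sorted_means[:n_finite], y))
        lo, hi = j - 1, j
        while lo >= 0 and lo in used:
            lo -= 1
        while hi < n_finite and hi in used:
            hi += 1
        d_lo = y - sorted_means[lo] if lo >= 0 else np.inf
        d_hi = sorted_means[hi] - y if hi < n_finite else np.inf
        pos = lo if d_lo <= d_hi else hi
        used.add(pos)
        chosen.append(int(order[pos]))
    return chosen


# ---------------------------------------------------------------------------


def simulate(cfg: WorldConfig, outdir) -> dict:
    """Run all three generators and merge their ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = {}
    truth.update(gen_checklists(cfg, outdir))
    truth.update(gen_phylogeny(cfg, outdir))
    truth.update(gen_footprint_world(cfg, outdir))
    _write_json(truth, outdir / "ground_truth.json")
    return truth
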