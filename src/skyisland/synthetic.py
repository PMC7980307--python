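"""Synthetic sky-island study systems with known ground truth.

Builds a complete small world emulating the study design: five mountain
populations on a raster landscape split 2 vs 3 by a single deep low-altitude
"rift" barrier, with altitude, ecoregion-class, human-footprint,
arable-fraction and suitability-score rasters; genotypes and mtDNA sequences
simulated under a chosen demographic scenario; and per-population land-use
covariates with a configurable regression structure. Every file the pipeline
reads can be written from one of these worlds, so each stage is testable
without any field data.

The generator aims at the statistical shape of the study system (sample
sizes, barrier geometry, altitude-stratified ecoregions, anti-correlated
arable cover), not at realistic geomorphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import MutationModel, SimulatedDataset, simulate_dataset
from .landscape import CostScheme, NodeSet, RasterGrid
from .popgen import GenotypeMatrix, PopulationMap, SequenceAlignment

__all__ = ["WorldConfig", "SyntheticWorld", "make_world",
           "simulate_truth_genetics", "inject_covariate_effect"]

SITE_NAMES = ("BaleD", "BaleS", "Guassa", "Simien", "Abune")
SITE_SIZES = (7, 9, 7, 12, 11)  # diploid samples per site, as in the study
SOUTH_SITES = ("BaleD", "BaleS")  # south-east of the rift (2 vs 3 split)

# altitude strata (m): montane woodland vs alpine moorland, emulating the
# 2,795-3,492 m and 3,773-4,224 m capture strata
ALT_LOWLAND_MAX = 2795.0
ALT_MONTANE_MAX = 3600.0


@dataclass
class WorldConfig:
    nrows: int = 100
    ncols: int = 100
    cellsize: float = 1000.0  # metres
    n_mountains: int = 5
    base_altitude: float = 1800.0
    peak_altitude: float = 4200.0
    rift_altitude: float = 1200.0
    rift_halfwidth: float = 6.0  # cells
    noise_sd: float = 40.0  # altitude noise, m


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    rasters: dict[str, RasterGrid]
    sites: pd.DataFrame  # site, row, col, x, y
    true_cost_scheme: CostScheme
    manifest: dict[str, object] = field(default_factory=dict)

    @property
    def nodes(self) -> NodeSet:
        return NodeSet(
            {r.site: (int(r.row), int(r.col)) for r in self.sites.itertuples()}
        )

    @property
    def site_coords(self) -> dict[str, tuple[float, float]]:
        return {r.site: (float(r.x), float(r.y)) for r in self.sites.itertuples()}


def _rift_distance(rr: np.ndarray, cc: np.ndarray, nrows: int, ncols: int
                   ) -> np.ndarray:
    """Signed distance (cells) to the rift line, a diagonal band through the
    grid centre running south-west to north-east."""
    # line: r + c = (nrows + ncols) / 2  -> distance along its normal
    return (rr + cc - (nrows + ncols) / 2.0) / np.sqrt(2.0)


def make_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate the raster stack and the five population sites.

    The altitude field is a smooth sum of Gaussian peaks (2 south-east of the
    rift, 3 north-west) carved by a low-altitude rift band; ecoregion classes
    are altitude strata (0 lowland, 1 montane, 2 alpine); human footprint and
    arable fraction decrease with altitude; the suitability score increases
    with it. Identical (config, seed) pairs regenerate the world bit for bit.
    """
    cfg = config or WorldConfig()
    if cfg.n_mountains != 5:
        raise ValueError("the study design uses exactly 5 mountain sites")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(101,)))
    nr, nc = cfg.nrows, cfg.ncols
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rift_d = _rift_distance(rr, cc, nr, nc)

    # peak centres: 2 on the south-east side (rift_d > 0), 3 north-west
    def _place(side: int, count: int) -> list[tuple[float, float]]:
        pts: list[tuple[float, float]] = []
        tries = 0
        while len(pts) < count:
            tries += 1
            if tries > 10_000:
                raise RuntimeError("could not place the requested mountain peaks")
            r = rng.uniform(0.15 * nr, 0.85 * nr)
            c = rng.uniform(0.15 * nc, 0.85 * nc)
            d = float(_rift_distance(np.array(r), np.array(c), nr, nc))
            if side * d < cfg.rift_halfwidth + 5:
                continue
            if all((r - pr) ** 2 + (c - pc) ** 2 > (0.16 * min(nr, nc)) ** 2
                   for pr, pc in pts):
                pts.append((r, c))
        return pts

    centers = _place(+1, len(SOUTH_SITES)) + _place(-1, 5 - len(SOUTH_SITES))
    alt = np.full((nr, nc), cfg.base_altitude)
    width = 0.10 * min(nr, nc)
    for pr, pc in centers:
        bump = np.exp(-(((rr - pr) ** 2 + (cc - pc) ** 2) / (2 * width**2)))
        alt += (cfg.peak_altitude - cfg.base_altitude) * bump
    alt = np.maximum(alt, cfg.base_altitude)
    # carve the rift: inside the band altitude drops to the rift floor
    in_rift = np.abs(rift_d) <= cfg.rift_halfwidth
    alt = np.where(in_rift, cfg.rift_altitude, alt)
    alt = alt + rng.normal(0.0, cfg.noise_sd, size=alt.shape)

    sites = []
    used: set[tuple[int, int]] = set()
    for name, (pr, pc) in zip(SITE_NAMES, centers):
        # site = highest cell near the peak centre (unique per site; peaks
        # are kept well separated so the rounded centre breaks any tie)
        r0, r1 = int(max(0, pr - 3)), int(min(nr, pr + 4))
        c0, c1 = int(max(0, pc - 3)), int(min(nc, pc + 4))
        local = alt[r0:r1, c0:c1]
        dr, dc = np.unravel_index(np.argmax(local), local.shape)
        cell = (r0 + dr, c0 + dc)
        if cell in used:
            cell = (int(round(pr)), int(round(pc)))
        used.add(cell)
        sites.append((name, cell[0], cell[1]))

    grid0 = RasterGrid(alt, cellsize=cfg.cellsize)
    site_rows = []
    for name, r, c in sites:
        x, y = grid0.cell_center(r, c)
        site_rows.append({"site": name, "row": r, "col": c, "x": x, "y": y})
    sites_df = pd.DataFrame(site_rows)
    if sites_df[["row", "col"]].duplicated().any():
        raise RuntimeError("site cells collide; use a larger grid")

    eco = np.digitize(alt, [ALT_LOWLAND_MAX, ALT_MONTANE_MAX]).astype(float)
    rel = np.clip((alt - cfg.rift_altitude) /
                  (cfg.peak_altitude - cfg.rift_altitude), 0, 1)
    footprint = np.clip(100 * (1 - rel) * rng.uniform(0.6, 1.0, size=alt.shape), 0, 100)
    arable = np.clip((1 - rel) * rng.uniform(0.5, 1.0, size=alt.shape), 0, 1)
    suit = np.clip(rel ** 1.5 + rng.normal(0, 0.03, size=alt.shape), 0, 1)

    def grid(v: np.ndarray) -> RasterGrid:
        return RasterGrid(v, cellsize=cfg.cellsize)

    true_scheme = CostScheme(
        variable="ecoregion", label="Ecoregions true",
        categories={0.0: 100.0, 1.0: 20.0, 2.0: 1.0},
    )
    return SyntheticWorld(
        config=cfg,
        seed=seed,
        rasters={
            "altitude": grid(alt),
            "ecoregion": grid(eco),
            "footprint": grid(footprint),
            "arable": grid(arable),
            "suitability": grid(suit),
        },
        sites=sites_df,
        true_cost_scheme=true_scheme,
        manifest={"seed": seed, "nrows": cfg.nrows, "ncols": cfg.ncols,
                  "cellsize": cfg.cellsize,
                  "sites": ",".join(SITE_NAMES)},
    )


def simulate_truth_genetics(
    world: SyntheticWorld,
    scenario: int,
    params: dict[str, float],
    seed: int = 0,
    site_sizes: tuple[int, ...] = SITE_SIZES,
    mutation: MutationModel | None = None,
) -> tuple[GenotypeMatrix, SequenceAlignment, PopulationMap, dict]:
    """Genotypes + sequences for the five sites under a known scenario.

    The coalescent runs on the two sides of the rift (southern deme = the 2
    south-eastern sites, northern deme = the other 3, panmictic within a
    side); simulated individuals are then assigned to sites with the study's
    per-site sample sizes. A manifest records the ground truth.
    """
    sizes = dict(zip(SITE_NAMES, site_sizes))
    n_s = sum(sizes[s] for s in SOUTH_SITES)
    n_n = sum(v for k, v in sizes.items() if k not in SOUTH_SITES)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(202,)))
    ds: SimulatedDataset = simulate_dataset(
        scenario, params, n_s=n_s, n_n=n_n, mutation=mutation, seed=rng
    )
    # relabel individuals site by site, preserving the S/N assignment
    new_ids: list[str] = []
    popmap = PopulationMap()
    s_iter = iter([i for i in ds.genotypes.ids if i.startswith("S")])
    n_iter = iter([i for i in ds.genotypes.ids if i.startswith("N")])
    mapping: dict[str, str] = {}
    for site in SITE_NAMES:
        src = s_iter if site in SOUTH_SITES else n_iter
        for k in range(sizes[site]):
            old = next(src)
            new = f"{site}_{k + 1:02d}"
            mapping[old] = new
            popmap[new] = site
    new_ids = [mapping[i] for i in ds.genotypes.ids]
    gt = GenotypeMatrix(new_ids, ds.genotypes.loci, ds.genotypes.calls)
    aln = SequenceAlignment(new_ids, ds.alignment.seqs, ds.alignment.partitions)
    manifest = {
        "scenario": scenario,
        "seed": seed,
        "site_sizes": ",".join(f"{k}:{v}" for k, v in sizes.items()),
        **{f"true_{k}": v for k, v in params.items()},
    }
    return gt, aln, popmap, manifest


def inject_covariate_effect(
    world: SyntheticWorld,
    slope: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 6.0,
    buffer_cells: int = 5,
) -> pd.DataFrame:
    """Per-site arable-land cover and a diversity response with known slope.

    The covariate is the mean arable fraction in a square buffer around each
    site; the response emulates rarefied allelic richness, generated as
    ``intercept + slope * arable + N(0, noise_sd)`` so the expected
    regression of diversity on arable cover has exactly the configured
    slope. With ``noise_sd=0`` an OLS fit recovers the slope exactly.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(303,)))
    arable = world.rasters["arable"].values
    nr, nc = arable.shape
    rows = []
    for r in world.sites.itertuples():
        r0, r1 = max(0, r.row - buffer_cells), min(nr, r.row + buffer_cells + 1)
        c0, c1 = max(0, r.col - buffer_cells), min(nc, r.col + buffer_cells + 1)
        cov = float(np.nanmean(arable[r0:r1, c0:c1]))
        rows.append({"site": r.site, "arable": cov})
    df = pd.DataFrame(rows).set_index("site")
    df["response"] = intercept + slope * df["arable"] + rng.normal(
        0.0, noise_sd, size=len(df)
    )
    return df


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture bundle (rasters, sites, manifest) to a directory."""
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, grid in world.rasters.items():
        p = out / f"{name}.asc"
        pio.write_ascii_grid(grid, p)
        paths[name] = p
    sites_path = out / "sites.csv"
    world.sites.to_csv(sites_path, index=False)
    paths["sites"] = sites_path
    manifest_path = out / "world_manifest.txt"
    pio.write_config(world.manifest, manifest_path)
    paths["manifest"] = manifest_path
    return paths
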