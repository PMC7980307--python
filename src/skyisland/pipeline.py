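"""Orchestration of the full analysis over a (synthetic or on-disk) bundle.

``run_pipeline`` chains the stages of the study workflow — synthetic-world
generation, population-genetic summaries, landscape-genetic model comparison,
ABC demographic inference and range-change accounting — exchanging data only
through declared file artifacts in the output directory, with one child seed
per stage derived from the master seed. Re-running with the same
configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc as abc_mod
from . import io as pio
from . import landscape as lsc
from . import popgen
from . import range_dynamics as rng_dyn
from . import synthetic
from .demography import MutationModel, PriorSpec, sample_priors

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "popgen", "landscape", "abc", "range")


@dataclass
class RunConfig:
    """All pipeline parameters; every stochastic stage has an explicit seed
    derived from ``seed`` unless overridden."""

    out_dir: str = "skyisland_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # synthetic world / truth
    scenario: int = 4
    decline_ratio: float = 6.0
    world_nrows: int = 60
    world_ncols: int = 60
    # popgen
    n_perm_hwe: int = 200
    # landscape
    n_perm_mrdm: int = 999
    connectivity: int = 8
    # abc
    abc_rows_per_scenario: int = 250
    abc_tolerance: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        raw = pio.read_config(path, known_keys=known)
        kwargs: dict[str, object] = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "stages":
                kwargs[f.name] = tuple(s.strip() for s in str(v).split(",") if s.strip())
            elif f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        cfg = cls(**kwargs)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=master,
                                spawn_key=(STAGES.index(stage) + 1,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _truth_params(cfg: RunConfig, spec: PriorSpec) -> dict[str, float]:
    rng = np.random.default_rng(_stage_seed(cfg.seed, "simulate") + 1)
    params = sample_priors(spec, cfg.scenario, rng)
    if "N_S0" in params:
        params["N_S0"] = params["N_S"] * cfg.decline_ratio
    return params


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the toggled stages; returns the paths of the report artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines: list[str] = [f"seed = {cfg.seed}", f"stages = {','.join(cfg.stages)}"]
    spec = PriorSpec()
    mut = MutationModel()

    try:
        if "simulate" in cfg.stages:
            seed = _stage_seed(cfg.seed, "simulate")
            log_lines.append(f"simulate.seed = {seed}")
            world = synthetic.make_world(
                synthetic.WorldConfig(nrows=cfg.world_nrows, ncols=cfg.world_ncols),
                seed=seed,
            )
            synthetic.write_world(world, out / "world")
            params = _truth_params(cfg, spec)
            gt, aln, popmap, manifest = synthetic.simulate_truth_genetics(
                world, cfg.scenario, params, seed=seed, mutation=mut
            )
            pio.write_genepop(gt, popmap, out / "world" / "genotypes.gen")
            pio.write_fasta(aln, out / "world" / "mtdna.fasta")
            pio.write_popmap(popmap, out / "world" / "popmap.csv")
            pio.write_config(manifest, out / "world" / "truth_manifest.txt")
            artifacts["world"] = out / "world"

        world_dir = out / "world"
        if not world_dir.exists():
            raise FileNotFoundError(
                f"no input bundle at {world_dir}; run the simulate stage first"
            )
        gt, popmap = pio.read_genepop(world_dir / "genotypes.gen")
        popmap = pio.read_popmap(world_dir / "popmap.csv")
        aln = pio.read_fasta(world_dir / "mtdna.fasta",
                             partitions={"cytb": (1, mut.cytb_len),
                                         "hv1": (mut.cytb_len + 1, mut.seq_length)})
        sites = pd.read_csv(world_dir / "sites.csv")
        coords = {r.site: (float(r.x), float(r.y)) for r in sites.itertuples()}
        nodes = lsc.NodeSet({r.site: (int(r.row), int(r.col))
                             for r in sites.itertuples()})

        if "popgen" in cfg.stages:
            seed = _stage_seed(cfg.seed, "popgen")
            log_lines.append(f"popgen.seed = {seed}")
            div = popgen.microsat_summaries(gt, popmap)
            fml = popgen.inbreeding_ml(gt, popmap)
            div["F_ind"] = pd.Series(
                {p: fml[[i for i in gt.ids if popmap[i] == p]].mean()
                 for p in popmap.populations}
            )
            mt_rows = {}
            for p in popmap.populations:
                ids = [i for i in aln.ids if popmap[i] == p]
                hap, hd, pi = popgen.mtdna_diversity(aln.subset(ids))
                mt_rows[p] = {"Hap": hap, "Hd": hd, "Pi": pi}
            div = div.join(pd.DataFrame(mt_rows).T)
            div.to_csv(out / "diversity_table.csv")
            artifacts["diversity_table"] = out / "diversity_table.csv"

            qc = popgen.marker_qc(gt, popmap, n_perm=cfg.n_perm_hwe, seed=seed)
            qc.to_csv(out / "marker_qc.csv", index=False)
            artifacts["marker_qc"] = out / "marker_qc.csv"

            theta, jd = popgen.pairwise_differentiation(gt, popmap)
            pio.write_matrix_csv(theta, out / "fst_matrix.csv")
            pio.write_matrix_csv(jd, out / "jostd_matrix.csv")
            artifacts["fst_matrix"] = out / "fst_matrix.csv"
            artifacts["jostd_matrix"] = out / "jostd_matrix.csv"

            cov = synthetic.inject_covariate_effect(
                synthetic.make_world(
                    synthetic.WorldConfig(nrows=cfg.world_nrows,
                                          ncols=cfg.world_ncols),
                    seed=_stage_seed(cfg.seed, "simulate"),
                ),
                slope=-2.0, noise_sd=0.2, seed=seed,
            )
            reg = popgen.diversity_landuse_regression(
                div["Ar"], cov["arable"].reindex(div.index)
            )
            pd.DataFrame([reg]).to_csv(out / "diversity_landuse.csv", index=False)
            artifacts["diversity_landuse"] = out / "diversity_landuse.csv"

        if "landscape" in cfg.stages:
            seed = _stage_seed(cfg.seed, "landscape")
            log_lines.append(f"landscape.seed = {seed}")
            eco = pio.read_ascii_grid(world_dir / "ecoregion.asc")
            alt = pio.read_ascii_grid(world_dir / "altitude.asc")
            foot = pio.read_ascii_grid(world_dir / "footprint.asc")
            theta = pio.read_matrix_csv(out / "fst_matrix.csv")
            euclid = lsc.euclidean_distances(coords)
            y = lsc.normalize_genetic_distance(theta, euclid)

            eco_scheme = synthetic.make_world(
                synthetic.WorldConfig(nrows=cfg.world_nrows, ncols=cfg.world_ncols),
                seed=_stage_seed(cfg.seed, "simulate"),
            ).true_cost_scheme
            alt_scheme = lsc.CostScheme(
                variable="altitude", label="Altitude 3",
                ranges=[(-1e9, 2500.0, 100.0), (2500.0, 3200.0, 30.0),
                        (3200.0, 1e9, 1.0)],
            )
            foot_scheme = lsc.CostScheme(
                variable="footprint", label="Footprint 2",
                ranges=[(-1e9, 50.0, 1.0), (50.0, 1e9, 50.0)],
            )
            hypotheses = {
                "Ecoregions": (eco, eco_scheme),
                "Topography": (alt, alt_scheme),
                "Anthropogenic": (foot, foot_scheme),
            }
            fits = []
            for name, (grid, scheme) in hypotheses.items():
                surface = lsc.reclassify(grid, scheme)
                rd = lsc.resistance_distances(surface, nodes, cfg.connectivity)
                rd = popgen.PairwiseMatrix(
                    y.labels,
                    np.array([[rd.pair(a, b) if a != b else 0.0
                               for b in y.labels] for a in y.labels]),
                    name,
                )
                fits.append(lsc.mlpe_fit(y, [rd], name=name))
            comp = lsc.model_compare(fits)
            comp.to_frame().to_csv(out / "mlpe_comparison.csv", index=False)
            artifacts["mlpe_comparison"] = out / "mlpe_comparison.csv"

        if "abc" in cfg.stages:
            seed = _stage_seed(cfg.seed, "abc")
            log_lines.append(f"abc.seed = {seed}")
            sizes = dict(zip(synthetic.SITE_NAMES, synthetic.SITE_SIZES))
            side = {i: ("S" if popmap[i] in synthetic.SOUTH_SITES else "N")
                    for i in gt.ids}
            order = ([i for i in gt.ids if side[i] == "S"]
                     + [i for i in gt.ids if side[i] == "N"])
            n_s = sum(1 for i in order if side[i] == "S")
            n_n = len(order) - n_s
            from .demography import SimulatedDataset

            obs_ds = SimulatedDataset(
                gt.subset(order), aln.subset(order),
                popgen.PopulationMap({i: side[i] for i in order}), 0, {},
            )
            obs = abc_mod.summarize(obs_ds, lo=mut.allele_lo, hi=mut.allele_hi)
            table = abc_mod.build_reference_table(
                spec, n_per_scenario=cfg.abc_rows_per_scenario, seed=seed,
                n_s=n_s, n_n=n_n, mutation=mut,
            )
            table.to_csv(out / "reference_table.csv")
            artifacts["reference_table"] = out / "reference_table.csv"
            choice = abc_mod.model_choice(obs, table, tolerance=cfg.abc_tolerance)
            pd.DataFrame({
                "scenario": choice.scenarios,
                "p_direct": choice.direct,
                "p_logistic": choice.logistic,
            }).to_csv(out / "scenario_choice.csv", index=False)
            artifacts["scenario_choice"] = out / "scenario_choice.csv"
            post = abc_mod.estimate_parameters(
                obs, table.restrict(choice.selected), spec,
                tolerance=max(cfg.abc_tolerance, 0.1),
            )
            post.summary.to_csv(out / "posterior_summary.csv")
            artifacts["posterior_summary"] = out / "posterior_summary.csv"

        if "range" in cfg.stages:
            seed = _stage_seed(cfg.seed, "range")
            log_lines.append(f"range.seed = {seed}")
            suit = pio.read_ascii_grid(world_dir / "suitability.asc")
            rng = np.random.default_rng(seed)
            pres = np.array([suit.values[r, c] for r, c in nodes.values()])
            back = rng.choice(suit.values[~np.isnan(suit.values)].ravel(),
                              size=200, replace=False)
            thr = rng_dyn.max_sss_threshold(np.clip(pres, 0, 1),
                                           np.clip(back, 0, 1))
            # emulate cooler (larger suitable area) and warmer (smaller) slices
            slices = {
                "present": suit,
                "past_cool": suit.like(np.clip(suit.values * 1.6, 0, 1)),
                "future_warm": suit.like(np.clip(suit.values * 0.5, 0, 1)),
            }
            maps = {k: rng_dyn.binarize(v, thr) for k, v in slices.items()}
            report = rng_dyn.range_report(maps, present="present")
            report.to_csv(out / "range_report.csv")
            artifacts["range_report"] = out / "range_report.csv"
    except Exception as err:
        log_lines.append(f"FAILED: {type(err).__name__}: {err}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = out / "run_log.txt"
    return artifacts
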