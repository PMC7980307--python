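"""Approximate Bayesian computation over the demographic scenarios.

The pipeline follows the classic rejection + regression ABC recipe: simulate
large reference tables of (scenario, parameters, summary statistics), retain
the simulations whose statistics are nearest the observed vector, then

* estimate scenario posterior probabilities both by direct rejection
  (scenario frequencies among retained rows) and by a distance-weighted
  polychotomous logistic regression evaluated at the observed point;
* estimate parameter posteriors by local-linear regression adjustment
  (Beaumont) on logit-transformed parameters, with Epanechnikov weights;
* calibrate the machinery with pseudo-observed datasets (pods): scenario
  confusion matrices and type-1/type-2 error rates, posterior-predictive
  model checking through PCA, and estimator bias (relative mean bias and
  relative median absolute deviation, RMedAD).

Eighteen summary statistics are computed per dataset (fixed order, see
``STAT_NAMES``): microsatellites — mean alleles/locus, mean unbiased expected
heterozygosity and mean allele-size variance for each population, pairwise
Weir-Cockerham F_ST and Goldstein's (delta-mu)^2 distance; mtDNA — haplotype
count, segregating sites, mean pairwise differences and Tajima's D for each
population, pairwise Hudson F_ST and the mean between-population pairwise
difference count. Statistics undefined on degenerate (monomorphic) data are
set to 0 and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .demography import (
    ALL_PARAMS,
    GENERATION_TIME_YEARS,
    SCENARIO_PARAMS,
    MutationModel,
    PriorSpec,
    SimulatedDataset,
    sample_priors,
    simulate_dataset,
)
from .popgen import MISSING

__all__ = [
    "STAT_NAMES",
    "ReferenceTable",
    "ModelChoiceResult",
    "ParameterPosterior",
    "ConfidenceReport",
    "BiasReport",
    "summarize",
    "build_reference_table",
    "model_choice",
    "estimate_parameters",
    "confidence_analysis",
    "posterior_predictive_check",
    "bias_precision",
    "bias_from_estimates",
]

STAT_NAMES = (
    "msat_na_s", "msat_na_n",
    "msat_he_s", "msat_he_n",
    "msat_var_s", "msat_var_n",
    "msat_fst", "msat_dmu2",
    "mt_hap_s", "mt_hap_n",
    "mt_segsites_s", "mt_segsites_n",
    "mt_pairdiff_s", "mt_pairdiff_n",
    "mt_tajd_s", "mt_tajd_n",
    "mt_fst", "mt_dxy",
)


# ---------------------------------------------------------------------------
# Summary statistics (vectorized fast paths; equivalence with the popgen
# module's generic implementations is asserted in the test suite)
# ---------------------------------------------------------------------------


def _msat_counts(calls: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """(n_loci, n_allele_states) allele copy counts; missing ignored."""
    n, L, _ = calls.shape
    span = hi - lo + 1
    counts = np.zeros((L, span), dtype=np.int64)
    flat = calls.reshape(n, L * 2)
    locus_idx = np.repeat(np.arange(L), 2)
    for row in flat:
        ok = row != MISSING
        np.add.at(counts, (locus_idx[ok], row[ok] - lo), 1)
    return counts


def _msat_pop_stats(counts: np.ndarray, het_freq: np.ndarray, lo: int
                    ) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """(Na, He, size variance, per-locus freqs, per-locus mean size)."""
    genes = counts.sum(axis=1, keepdims=True).astype(float)
    genes[genes == 0] = np.nan
    p = counts / genes
    na = float(np.nanmean((counts > 0).sum(axis=1)))
    g = genes.ravel()
    he_loc = np.where(g > 1, g / np.maximum(g - 1, 1) * (1 - np.sum(p**2, axis=1)), 0.0)
    he = float(np.nanmean(he_loc))
    sizes = lo + np.arange(counts.shape[1], dtype=float)
    mean_size = np.sum(p * sizes, axis=1)
    var_size = np.sum(p * sizes**2, axis=1) - mean_size**2
    return na, he, float(np.nanmean(var_size)), p, mean_size


def _wc_theta_from_counts(
    counts_s: np.ndarray, counts_n: np.ndarray,
    het_s: np.ndarray, het_n: np.ndarray,
) -> float:
    """Weir-Cockerham theta for two populations, vectorized over loci x alleles.

    ``het_*`` are (n_loci, n_states) frequencies of individuals heterozygous
    for each allele.
    """
    n1 = counts_s.sum(axis=1) / 2.0  # diploid sample sizes per locus
    n2 = counts_n.sum(axis=1) / 2.0
    ok = (n1 > 1) & (n2 > 1)
    if not ok.any():
        return 0.0
    n1, n2 = n1[ok], n2[ok]
    r = 2.0
    nbar = (n1 + n2) / 2.0
    nsum = n1 + n2
    nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1)
    p1 = counts_s[ok] / (2 * n1)[:, None]
    p2 = counts_n[ok] / (2 * n2)[:, None]
    pbar = (n1[:, None] * p1 + n2[:, None] * p2) / nsum[:, None]
    s2 = (n1[:, None] * (p1 - pbar) ** 2 + n2[:, None] * (p2 - pbar) ** 2) / (
        (r - 1) * nbar[:, None]
    )
    hbar = (n1[:, None] * het_s[ok] + n2[:, None] * het_n[ok]) / nsum[:, None]
    nb = nbar[:, None]
    a = (nb / nc[:, None]) * (
        s2 - (1.0 / (nb - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
    )
    b = (nb / (nb - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nb - 1) / (4 * nb) * hbar
    )
    c = hbar / 2.0
    den = float(np.sum(a + b + c))
    return float(np.sum(a)) / den if den != 0 else 0.0


def _het_freqs(calls: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """(n_loci, n_states) frequency of individuals heterozygous per allele."""
    n, L, _ = calls.shape
    span = hi - lo + 1
    a0 = calls[:, :, 0]
    a1 = calls[:, :, 1]
    out = np.zeros((L, span))
    het = (a0 != a1) & (a0 != MISSING)
    scored = (a0 != MISSING).sum(axis=0).astype(float)
    scored[scored == 0] = np.nan
    for s in range(2):
        al = calls[:, :, s]
        sel = het & (al != MISSING)
        locus_idx = np.where(sel)[1]
        np.add.at(out, (locus_idx, al[sel] - lo), 1)
    return out / scored[:, None]


def _seq_to_int(aln_rows: np.ndarray) -> np.ndarray:
    """Byte array (n, L) -> ACGT indices; gaps/N mapped to -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[aln_rows.view(np.uint8)]


def _site_base_counts(seq_idx: np.ndarray) -> np.ndarray:
    """(L, 4) base counts per site (negative codes ignored)."""
    n, L = seq_idx.shape
    counts = np.zeros((L, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = np.sum(seq_idx == b, axis=0)
    return counts


def _tajimas_d(n: int, s: int, kbar: float) -> float:
    if s == 0 or n < 4:
        return 0.0
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return 0.0
    return (kbar - s / a1) / math.sqrt(var)


def _mt_pop_stats(seq_idx: np.ndarray) -> tuple[int, int, float]:
    """(haplotype count, segregating sites, mean pairwise differences)."""
    n, L = seq_idx.shape
    counts = _site_base_counts(seq_idx)
    seg = int(np.sum((counts > 0).sum(axis=1) > 1))
    npairs = n * (n - 1) / 2.0
    same = np.sum(counts * (counts - 1) / 2.0, axis=1)
    kbar = float(np.sum(npairs - same) / npairs) if npairs > 0 else 0.0
    hap = len({row.tobytes() for row in np.ascontiguousarray(seq_idx)})
    return hap, seg, kbar


def summarize(ds: SimulatedDataset, lo: int | None = None, hi: int | None = None
              ) -> np.ndarray:
    """The 18-statistic summary vector for a combined dataset (fixed order).

    Allele-state bounds default to the observed range of the genotype matrix.
    """
    gt, aln, popmap = ds.genotypes, ds.alignment, ds.popmap
    s_ids = [i for i in gt.ids if popmap[i] == "S"]
    n_ids = [i for i in gt.ids if popmap[i] == "N"]
    idx = {ind: k for k, ind in enumerate(gt.ids)}
    s_rows = [idx[i] for i in s_ids]
    n_rows = [idx[i] for i in n_ids]
    calls = gt.calls
    scored = calls[calls != MISSING]
    if lo is None:
        lo = int(scored.min()) if scored.size else 1
    if hi is None:
        hi = int(scored.max()) if scored.size else 1

    out = np.zeros(len(STAT_NAMES))
    cs = _msat_counts(calls[s_rows], lo, hi)
    cn = _msat_counts(calls[n_rows], lo, hi)
    hs = _het_freqs(calls[s_rows], lo, hi)
    hn = _het_freqs(calls[n_rows], lo, hi)
    na_s, he_s, var_s, _, mean_s = _msat_pop_stats(cs, hs, lo)
    na_n, he_n, var_n, _, mean_n = _msat_pop_stats(cn, hn, lo)
    out[0:2] = na_s, na_n
    out[2:4] = he_s, he_n
    out[4:6] = var_s, var_n
    out[6] = _wc_theta_from_counts(cs, cn, hs, hn)
    out[7] = float(np.nanmean((mean_s - mean_n) ** 2))

    arr = _seq_to_int(aln.to_array())
    seq_s = arr[s_rows]
    seq_n = arr[n_rows]
    hap_s, seg_s, k_s = _mt_pop_stats(seq_s)
    hap_n, seg_n, k_n = _mt_pop_stats(seq_n)
    out[8:10] = hap_s, hap_n
    out[10:12] = seg_s, seg_n
    out[12:14] = k_s, k_n
    out[14] = _tajimas_d(len(s_rows), seg_s, k_s)
    out[15] = _tajimas_d(len(n_rows), seg_n, k_n)
    c1 = _site_base_counts(seq_s).astype(float)
    c2 = _site_base_counts(seq_n).astype(float)
    n1, n2 = seq_s.shape[0], seq_n.shape[0]
    between = float(np.sum(1.0 - (c1 * c2).sum(axis=1) / (n1 * n2)))
    out[17] = between
    L = arr.shape[1]
    if between > 0:
        pi_b = between / L
        pi_w = 0.5 * (k_s + k_n) / L
        out[16] = 1.0 - pi_w / pi_b
    return out


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameter draw, summary statistics) rows.

    ``params`` has one column per entry of ``ALL_PARAMS`` (NaN where a
    scenario does not use a parameter); ``stats`` columns follow
    ``STAT_NAMES``. ``manifest`` records the generating configuration.
    """

    scenario: np.ndarray
    params: pd.DataFrame
    stats: pd.DataFrame
    manifest: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scenario)

    def restrict(self, scenario: int) -> "ReferenceTable":
        mask = self.scenario == scenario
        return ReferenceTable(
            self.scenario[mask],
            self.params[mask].reset_index(drop=True),
            self.stats[mask].reset_index(drop=True),
            dict(self.manifest),
        )

    def concat(self, other: "ReferenceTable") -> "ReferenceTable":
        return ReferenceTable(
            np.concatenate([self.scenario, other.scenario]),
            pd.concat([self.params, other.params], ignore_index=True),
            pd.concat([self.stats, other.stats], ignore_index=True),
            dict(self.manifest),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.concat(
            [pd.Series(self.scenario, name="scenario"), self.params, self.stats],
            axis=1,
        )
        with open(path, "w") as fh:
            for k, v in self.manifest.items():
                fh.write(f"# {k} = {v}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        manifest: dict[str, object] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                pos = fh.tell()
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                k, v = line[1:].split("=", 1)
                manifest[k.strip()] = v.strip()
            df = pd.read_csv(fh)
        params = df[list(ALL_PARAMS)]
        stats = df[list(STAT_NAMES)]
        return cls(df["scenario"].to_numpy(int), params, stats, manifest)


def _row_rng(seed: int, scenario: int, row: int) -> np.random.Generator:
    """Counter-based per-row RNG: reproducible and chunk-parallelizable."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(scenario, row))
    return np.random.default_rng(ss)


def simulate_row(
    spec: PriorSpec, scenario: int, seed: int, row: int,
    n_s: int = 22, n_n: int = 28,
    mutation: MutationModel | None = None,
) -> tuple[dict[str, float], np.ndarray]:
    """One reference-table row: prior draw, dataset, summary vector."""
    rng = _row_rng(seed, scenario, row)
    params = sample_priors(spec, scenario, rng)
    mut = mutation or MutationModel()
    ds = simulate_dataset(scenario, params, n_s=n_s, n_n=n_n,
                          mutation=mut, seed=rng)
    return params, summarize(ds, lo=mut.allele_lo, hi=mut.allele_hi)


def build_reference_table(
    spec: PriorSpec,
    scenarios: tuple[int, ...] = (1, 2, 3, 4),
    n_per_scenario: int = 1000,
    seed: int = 0,
    n_s: int = 22,
    n_n: int = 28,
    mutation: MutationModel | None = None,
    row_range: tuple[int, int] | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` rows per scenario.

    Rows are seeded individually from ``(seed, scenario, row)``, so partial
    builds over ``row_range`` (for chunked/parallel construction) concatenate
    to the same table as one serial build.
    """
    lo_row, hi_row = row_range or (0, n_per_scenario)
    scen_col, par_rows, stat_rows = [], [], []
    for scenario in scenarios:
        for row in range(lo_row, hi_row):
            params, stats = simulate_row(spec, scenario, seed, row,
                                         n_s=n_s, n_n=n_n, mutation=mutation)
            scen_col.append(scenario)
            par_rows.append([params.get(k, np.nan) for k in ALL_PARAMS])
            stat_rows.append(stats)
    return ReferenceTable(
        np.array(scen_col, dtype=int),
        pd.DataFrame(par_rows, columns=list(ALL_PARAMS)),
        pd.DataFrame(np.array(stat_rows), columns=list(STAT_NAMES)),
        manifest={
            "seed": seed,
            "scenarios": ",".join(map(str, scenarios)),
            "n_per_scenario": n_per_scenario,
            "n_s": n_s,
            "n_n": n_n,
            "priors": ";".join(
                f"{k}:{kind}[{lo},{hi}]" for k, (kind, lo, hi) in spec.priors.items()
            ),
        },
    )


# ---------------------------------------------------------------------------
# Rejection machinery
# ---------------------------------------------------------------------------


def _standardize(stats: np.ndarray, obs: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sd = stats.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return stats / sd, obs / sd, sd


def _retain(stats_std: np.ndarray, obs_std: np.ndarray, tolerance: float
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Indices of the tolerance-fraction nearest rows, their distances and
    the kernel bandwidth (max retained distance)."""
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    d = np.sqrt(np.sum((stats_std - obs_std) ** 2, axis=1))
    n_keep = max(2, int(math.ceil(tolerance * len(d))))
    order = np.argsort(d, kind="stable")[:n_keep]
    bw = float(d[order].max())
    return order, d[order], bw


def _epanechnikov(d: np.ndarray, bw: float) -> np.ndarray:
    if bw <= 0:
        return np.ones_like(d)
    u = np.clip(d / bw, 0.0, 1.0)
    w = 1.0 - u**2
    w[w <= 0] = 1e-12
    return w


@dataclass
class ModelChoiceResult:
    scenarios: list[int]
    direct: np.ndarray
    logistic: np.ndarray
    tolerance: float
    n_retained: int

    @property
    def selected(self) -> int:
        return int(self.scenarios[int(np.argmax(self.logistic))])


def model_choice(
    obs: np.ndarray, table: ReferenceTable, tolerance: float = 0.01
) -> ModelChoiceResult:
    """Scenario posterior probabilities by rejection and weighted
    polychotomous logistic regression.

    Statistics are standardized by the table's SD; the nearest
    ``tolerance`` fraction of rows (Euclidean distance) is retained. The
    direct estimate is the scenario frequency among retained rows; the
    regression estimate fits a multinomial logistic model of scenario on the
    centred statistics with Epanechnikov distance weights and evaluates it at
    the observed point.
    """
    scenarios = sorted(set(int(s) for s in np.unique(table.scenario)))
    stats = table.stats.to_numpy(float)
    stats_std, obs_std, _ = _standardize(stats, np.asarray(obs, float))
    keep, d, bw = _retain(stats_std, obs_std, tolerance)
    labels = table.scenario[keep]
    direct = np.array([np.mean(labels == s) for s in scenarios])
    missing = [s for s in scenarios if s not in labels]
    if missing:
        warnings.warn(f"scenarios {missing} absent from retained set; probability 0")
    present = sorted(set(int(s) for s in np.unique(labels)))
    if len(present) == 1:
        logistic = np.array([1.0 if s == present[0] else 0.0 for s in scenarios])
    else:
        X = stats_std[keep] - obs_std
        w = _epanechnikov(d, bw)
        # near-unpenalized fit; the weak ridge keeps the solver stable when
        # scenarios separate perfectly in the retained cloud. C scales with
        # the total weight so the per-observation penalty is constant (and
        # the result invariant to duplicating reference rows).
        clf = LogisticRegression(C=1e6 / float(w.sum()), max_iter=1000,
                                 tol=1e-8, solver="newton-cg")
        clf.fit(X, labels, sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        logistic = np.zeros(len(scenarios))
        for cls, p in zip(clf.classes_, probs):
            logistic[scenarios.index(int(cls))] = p
    return ModelChoiceResult(scenarios, direct, logistic / logistic.sum(),
                             tolerance, len(keep))


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------


def _to_latent(x: np.ndarray, kind: str, lo: float, hi: float) -> np.ndarray:
    if kind == "loguniform":
        x, lo, hi = np.log(x), math.log(lo), math.log(hi)
    u = np.clip((x - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(u / (1 - u))


def _from_latent(z: np.ndarray, kind: str, lo: float, hi: float) -> np.ndarray:
    u = 1.0 / (1.0 + np.exp(-z))
    if kind == "loguniform":
        return np.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
    return lo + u * (hi - lo)


def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    return np.interp(qs, cdf, x)


@dataclass
class ParameterPosterior:
    """Adjusted posterior sample per parameter (scenario-restricted).

    ``accepted``/``adjusted`` map parameter name -> draws; ``summary`` holds
    median and the 2.5/97.5% quantiles (weighted); time parameters appear
    additionally in years. ``decline_ratio`` = N_S0 / N_S when defined.
    """

    scenario: int
    accepted: dict[str, np.ndarray]
    adjusted: dict[str, np.ndarray]
    weights: np.ndarray
    summary: pd.DataFrame
    regression_ok: bool

    def median(self, name: str) -> float:
        return float(self.summary.loc[name, "median"])

    def ci(self, name: str) -> tuple[float, float]:
        return (float(self.summary.loc[name, "q2.5"]),
                float(self.summary.loc[name, "q97.5"]))


def estimate_parameters(
    obs: np.ndarray,
    table: ReferenceTable,
    spec: PriorSpec,
    tolerance: float = 0.05,
    regression: bool = True,
) -> ParameterPosterior:
    """Local-linear regression-adjusted posterior for one scenario's table.

    Each parameter is mapped to an unconstrained latent scale (logit of its
    position within the prior support, on log scale for log-uniform priors),
    regressed on the standardized retained statistics with Epanechnikov
    weights, adjusted to the observed point (Beaumont local-linear ABC) and
    mapped back, which keeps every adjusted draw inside the prior support.
    """
    scen = set(int(s) for s in np.unique(table.scenario))
    if len(scen) != 1:
        raise ValueError("estimate_parameters needs a single-scenario table")
    scenario = scen.pop()
    names = [p for p in SCENARIO_PARAMS[scenario]] + ["mu_ms", "gsm_p", "mu_mt"]
    stats = table.stats.to_numpy(float)
    stats_std, obs_std, _ = _standardize(stats, np.asarray(obs, float))
    keep, d, bw = _retain(stats_std, obs_std, tolerance)
    w = _epanechnikov(d, bw)
    X = stats_std[keep] - obs_std
    Xd = np.column_stack([np.ones(len(keep)), X])
    sw = np.sqrt(w)
    accepted: dict[str, np.ndarray] = {}
    adjusted: dict[str, np.ndarray] = {}
    regression_ok = True
    for name in names:
        vals = table.params[name].to_numpy(float)[keep]
        accepted[name] = vals
        kind, lo, hi = spec.bounds(name)
        if lo == hi:
            adjusted[name] = vals
            continue
        z = _to_latent(vals, kind, lo, hi)
        if regression:
            try:
                beta, *_ = np.linalg.lstsq(Xd * sw[:, None], z * sw, rcond=None)
                z_adj = z - X @ beta[1:]
            except np.linalg.LinAlgError:
                warnings.warn(f"singular local-linear system for {name}; "
                              "falling back to rejection")
                regression_ok = False
                z_adj = z
        else:
            z_adj = z
        adjusted[name] = _from_latent(z_adj, kind, lo, hi)

    if "N_S0" in adjusted and "N_S" in adjusted:
        adjusted["decline_ratio"] = adjusted["N_S0"] / adjusted["N_S"]
        accepted["decline_ratio"] = accepted["N_S0"] / accepted["N_S"]

    qs = (0.025, 0.5, 0.975)
    rows = {}
    for name, vals in adjusted.items():
        lo_q, med, hi_q = _weighted_quantiles(vals, w, qs)
        rows[name] = {"median": med, "q2.5": lo_q, "q97.5": hi_q}
        if name in ("t_split", "t_dec"):
            rows[name + "_years"] = {
                "median": med * spec.generation_time,
                "q2.5": lo_q * spec.generation_time,
                "q97.5": hi_q * spec.generation_time,
            }
    summary = pd.DataFrame(rows).T
    return ParameterPosterior(scenario, accepted, adjusted, w, summary,
                              regression_ok)


# ---------------------------------------------------------------------------
# Calibration with pseudo-observed datasets
# ---------------------------------------------------------------------------


def _simulate_pod(
    spec: PriorSpec, scenario: int, rng: np.random.Generator,
    n_s: int, n_n: int, mutation: MutationModel | None,
    params: dict[str, float] | None = None,
) -> tuple[dict[str, float], np.ndarray]:
    mut = mutation or MutationModel()
    p = params or sample_priors(spec, scenario, rng)
    ds = simulate_dataset(scenario, p, n_s=n_s, n_n=n_n, mutation=mut, seed=rng)
    return p, summarize(ds, lo=mut.allele_lo, hi=mut.allele_hi)


@dataclass
class ConfidenceReport:
    scenarios: list[int]
    confusion: pd.DataFrame  # rows: simulated scenario, cols: assigned
    selected: int
    type1: float
    type2_mean: float
    type2_sd: float


def confidence_analysis(
    table: ReferenceTable,
    spec: PriorSpec,
    selected_scenario: int,
    n_pods: int = 100,
    seed: int = 0,
    tolerance: float = 0.01,
    n_s: int = 22,
    n_n: int = 28,
    mutation: MutationModel | None = None,
) -> ConfidenceReport:
    """False-allocation rates from pods simulated under every scenario.

    Type-1 error: fraction of pods simulated under the selected scenario that
    are assigned elsewhere. Type-2 error: per other scenario, the fraction of
    its pods assigned to the selected scenario (mean +/- sd reported).
    """
    if n_pods < 50:
        raise ValueError("n_pods must be >= 50")
    rng = np.random.default_rng(seed)
    scenarios = sorted(set(int(s) for s in np.unique(table.scenario)))
    conf = np.zeros((len(scenarios), len(scenarios)))
    for i, scen in enumerate(scenarios):
        for _ in range(n_pods):
            _, stats = _simulate_pod(spec, scen, rng, n_s, n_n, mutation)
            res = model_choice(stats, table, tolerance)
            conf[i, scenarios.index(res.selected)] += 1
    conf /= n_pods
    sel_idx = scenarios.index(selected_scenario)
    type1 = 1.0 - conf[sel_idx, sel_idx]
    others = [conf[i, sel_idx] for i in range(len(scenarios)) if i != sel_idx]
    return ConfidenceReport(
        scenarios,
        pd.DataFrame(conf, index=scenarios, columns=scenarios),
        selected_scenario,
        float(type1),
        float(np.mean(others)),
        float(np.std(others, ddof=1)) if len(others) > 1 else 0.0,
    )


@dataclass
class PPCResult:
    scores: np.ndarray       # simulated datasets in PC space
    obs_scores: np.ndarray   # observed dataset
    explained: np.ndarray
    inside_99: bool


def posterior_predictive_check(
    posterior: ParameterPosterior,
    obs: np.ndarray,
    spec: PriorSpec,
    n_sim: int = 1000,
    seed: int = 0,
    n_s: int = 22,
    n_n: int = 28,
    mutation: MutationModel | None = None,
) -> PPCResult:
    """PCA model check: simulate from the posterior, project the observation.

    Datasets are simulated at parameter draws resampled from the adjusted
    posterior (weighted); a PCA is fitted on their standardized summary
    vectors and the observed vector is projected. ``inside_99`` reports
    whether the observation falls inside the 99% ellipsoid of the first two
    components (Mahalanobis / chi-square criterion).
    """
    if n_sim < 10:
        raise ValueError("n_sim must be >= 10")
    rng = np.random.default_rng(seed)
    names = [n for n in posterior.adjusted if n != "decline_ratio"]
    w = posterior.weights / posterior.weights.sum()
    n_draws = len(next(iter(posterior.adjusted.values())))
    sims = np.empty((n_sim, len(STAT_NAMES)))
    for k in range(n_sim):
        row = rng.choice(n_draws, p=w)
        params = {n: float(posterior.adjusted[n][row]) for n in names}
        _, sims[k] = _simulate_pod(spec, posterior.scenario, rng, n_s, n_n,
                                   mutation, params=params)
    mu = sims.mean(axis=0)
    sd = sims.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=min(5, sims.shape[1]))
    scores = pca.fit_transform((sims - mu) / sd)
    obs_scores = pca.transform(((np.asarray(obs, float) - mu) / sd)[None, :])[0]
    s2 = scores[:, :2]
    cov = np.cov(s2, rowvar=False)
    center = s2.mean(axis=0)
    dev = obs_scores[:2] - center
    m2 = float(dev @ np.linalg.solve(cov, dev))
    from scipy.stats import chi2

    inside = m2 <= chi2.ppf(0.99, df=2)
    return PPCResult(scores, obs_scores, pca.explained_variance_ratio_, bool(inside))


@dataclass
class BiasReport:
    per_parameter: pd.DataFrame  # relative mean bias and RMedAD


def bias_from_estimates(est: dict[str, np.ndarray], truth: dict[str, np.ndarray]
                        ) -> BiasReport:
    """Relative mean bias = mean((est-true)/true); RMedAD = median(|est-true|/true)."""
    rows = {}
    for name in est:
        e = np.asarray(est[name], float)
        t = np.asarray(truth[name], float)
        rel = (e - t) / t
        rows[name] = {
            "rel_mean_bias": float(np.mean(rel)),
            "rmedad": float(np.median(np.abs(rel))),
        }
    return BiasReport(pd.DataFrame(rows).T)


def bias_precision(
    spec: PriorSpec,
    table: ReferenceTable,
    n_pods: int = 100,
    seed: int = 0,
    tolerance: float = 0.05,
    n_s: int = 22,
    n_n: int = 28,
    mutation: MutationModel | None = None,
) -> BiasReport:
    """Estimator bias/precision over pods from the table's (single) scenario.

    Each pod is simulated at a fresh prior draw; its parameters are estimated
    with the regression-adjusted posterior median against ``table``.
    """
    scen = set(int(s) for s in np.unique(table.scenario))
    if len(scen) != 1:
        raise ValueError("bias_precision needs a single-scenario table")
    scenario = scen.pop()
    rng = np.random.default_rng(seed)
    names = [p for p in SCENARIO_PARAMS[scenario]] + ["mu_ms", "gsm_p", "mu_mt"]
    est: dict[str, list[float]] = {n: [] for n in names}
    truth: dict[str, list[float]] = {n: [] for n in names}
    for _ in range(n_pods):
        params, stats = _simulate_pod(spec, scenario, rng, n_s, n_n, mutation)
        post = estimate_parameters(stats, table, spec, tolerance)
        for n in names:
            est[n].append(post.median(n))
            truth[n].append(params[n])
    return bias_from_estimates(
        {n: np.array(v) for n, v in est.items()},
        {n: np.array(v) for n, v in truth.items()},
    )
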