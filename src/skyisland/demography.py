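"""Coalescent simulation of mixed microsatellite + mtDNA data under competing
two-population demographic scenarios.

Two sampled populations, S (south-east of the barrier) and N (north-west),
merge backwards in time into an ancestor A at ``t_split`` generations. Four
competing histories are modelled:

1. a large ancient population split into two smaller ones, no later change
   (N_A >= max(N_S, N_N));
2. expansion after the split (ancestor smaller than both current sizes);
3. recent decline in both populations at ``t_dec`` (pre-decline sizes
   N_S0 > N_S and N_N0 > N_N);
4. recent decline in the southern population only (N_S0 > N_S).

Sizes are diploid effective numbers of individuals; times are generations
(reported in years with a 2-year generation time). The mitochondrial genome
is maternally inherited and haploid, so its effective size is N/4 on the
diploid scale (a haploid pool of N/2 gene copies; E[T_MRCA] for two
sequences is 2*(N/4) = N/2 generations).

Genealogies are drawn by a structured coalescent specialized to this
scenario family (piecewise-constant sizes, one population merge): an ABC
reference table needs tens of thousands of independent single-locus
genealogies per analysis, and this dedicated simulator generates one in tens
of microseconds. Its distributional behaviour is cross-checked against
msprime in the test suite.

Mutations: microsatellites follow the generalized stepwise model (GSM) —
allele size steps up/down with equal probability by a geometrically
distributed number of repeat units (parameter P; P=0 is the strict stepwise
model) — with allele sizes reflected into the bounds [lo, hi]. The mtDNA
fragment evolves under HKY (normalized jump chain: every event substitutes
the base, with transition/transversion ratio kappa and equilibrium
frequencies pi), with a proportion of invariant sites on the protein-coding
partition (cytb) and gamma-distributed rate heterogeneity on the
hyper-variable partition (HV1). The fully linked mtDNA partitions share one
genealogy; the 19 microsatellite loci are independent.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass, field

import numpy as np

from .popgen import GenotypeMatrix, PopulationMap, SequenceAlignment

__all__ = [
    "SCENARIO_PARAMS",
    "PriorSpec",
    "MutationModel",
    "SimulatedDataset",
    "Genealogy",
    "sample_priors",
    "simulate_genealogy",
    "simulate_dataset",
    "GENERATION_TIME_YEARS",
]

GENERATION_TIME_YEARS = 2.0

# parameters sampled per scenario (all scenarios share N_S, N_N, N_A, t_split)
SCENARIO_PARAMS: dict[int, tuple[str, ...]] = {
    1: ("N_S", "N_N", "N_A", "t_split"),
    2: ("N_S", "N_N", "N_A", "t_split"),
    3: ("N_S", "N_N", "N_A", "N_S0", "N_N0", "t_split", "t_dec"),
    4: ("N_S", "N_N", "N_A", "N_S0", "t_split", "t_dec"),
}

ALL_PARAMS = ("N_S", "N_N", "N_A", "N_S0", "N_N0", "t_split", "t_dec",
              "mu_ms", "gsm_p", "mu_mt")

TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T in ACGT coding
BASES = np.array(["A", "C", "G", "T"])


@dataclass
class PriorSpec:
    """Prior distributions for demographic and mutation parameters.

    Each entry maps a parameter name to ``(kind, low, high)`` with kind
    ``"uniform"`` or ``"loguniform"``. Defaults follow the study design:
    split times span pre/post-LGM (100-100,000 generations = 200-200,000
    years at 2 y/generation), decline times 10-500 generations (20-1,000
    years), population sizes 100-100,000 diploids, mean microsatellite rate
    log-uniform 1e-4..1e-3, GSM P uniform 0..0.3, mtDNA rate log-uniform
    1e-8..1e-7 per site per generation.
    """

    priors: dict[str, tuple[str, float, float]] = field(default_factory=lambda: {
        "N_S": ("uniform", 100.0, 100_000.0),
        "N_N": ("uniform", 100.0, 100_000.0),
        "N_A": ("uniform", 100.0, 100_000.0),
        "N_S0": ("uniform", 100.0, 100_000.0),
        "N_N0": ("uniform", 100.0, 100_000.0),
        "t_split": ("uniform", 100.0, 100_000.0),
        "t_dec": ("uniform", 10.0, 500.0),
        "mu_ms": ("loguniform", 1e-4, 1e-3),
        "gsm_p": ("uniform", 0.0, 0.3),
        "mu_mt": ("loguniform", 1e-8, 1e-7),
    })
    generation_time: float = GENERATION_TIME_YEARS

    def __post_init__(self) -> None:
        for name, (kind, lo, hi) in self.priors.items():
            if kind not in ("uniform", "loguniform"):
                raise ValueError(f"{name}: unknown prior kind {kind!r}")
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError(f"{name}: bad bounds ({lo}, {hi})")
            if kind == "loguniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform needs positive bounds")

    def draw(self, name: str, rng: np.random.Generator) -> float:
        kind, lo, hi = self.priors[name]
        if lo == hi:
            return float(lo)
        if kind == "uniform":
            return float(rng.uniform(lo, hi))
        return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))

    def bounds(self, name: str) -> tuple[str, float, float]:
        return self.priors[name]


def _scenario_ok(scenario: int, p: dict[str, float]) -> bool:
    if scenario == 1:
        return p["N_A"] >= max(p["N_S"], p["N_N"])
    if scenario == 2:
        return p["N_A"] < min(p["N_S"], p["N_N"])
    if scenario == 3:
        return (p["t_dec"] < p["t_split"] and p["N_S0"] > p["N_S"]
                and p["N_N0"] > p["N_N"])
    if scenario == 4:
        return p["t_dec"] < p["t_split"] and p["N_S0"] > p["N_S"]
    raise ValueError(f"unknown scenario {scenario}")


def sample_priors(
    spec: PriorSpec, scenario: int, rng: np.random.Generator | int,
    max_tries: int = 100_000,
) -> dict[str, float]:
    """Draw one parameter set satisfying the scenario's ordering constraints.

    Constraints (t_dec < t_split, pre-decline > current size, ancestor
    larger/smaller than both daughters for scenarios 1/2) are enforced by
    rejection-resampling the full vector.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    names = SCENARIO_PARAMS[scenario] + ("mu_ms", "gsm_p", "mu_mt")
    for _ in range(max_tries):
        p = {name: spec.draw(name, rng) for name in names}
        if _scenario_ok(scenario, p):
            return p
    raise RuntimeError(
        f"scenario {scenario}: could not satisfy ordering constraints in "
        f"{max_tries} draws; priors may be infeasible"
    )


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------


@dataclass
class Genealogy:
    """Binary coalescent tree over ``n`` sampled lineages.

    Nodes 0..n-1 are samples; internal nodes are numbered in coalescence
    order, so a parent id always exceeds its children's ids. ``parent[i]`` is
    -1 for the root; ``time`` is in generations.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray

    @property
    def branch_lengths(self) -> np.ndarray:
        """Length of the edge above each non-root node (0 for the root)."""
        bl = np.zeros(len(self.parent))
        nz = self.parent >= 0
        bl[nz] = self.time[self.parent[nz]] - self.time[nz]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])


def _epoch_sizes(scenario: int, p: dict[str, float]) -> tuple[list, list]:
    """Piecewise-constant diploid sizes for S and N: lists of (end_time, N)."""
    t_split = p["t_split"]
    if scenario in (3, 4):
        t_dec = p["t_dec"]
        s_epochs = [(t_dec, p["N_S"]), (t_split, p["N_S0"])]
    else:
        s_epochs = [(t_split, p["N_S"])]
    if scenario == 3:
        n_epochs = [(p["t_dec"], p["N_N"]), (t_split, p["N_N0"])]
    else:
        n_epochs = [(t_split, p["N_N"])]
    return s_epochs, n_epochs


def simulate_genealogy(
    scenario: int,
    params: dict[str, float],
    n_s: int,
    n_n: int,
    rand: _pyrandom.Random,
    copies_per_diploid: float = 2.0,
) -> Genealogy:
    """Draw one genealogy under the scenario's structured coalescent.

    ``copies_per_diploid`` converts diploid population sizes to gene-copy
    pool sizes: 2 for autosomal loci, 0.5 for the maternally inherited
    haploid mitochondrial genome (N/2 gene copies).
    """
    s_epochs, n_epochs = _epoch_sizes(scenario, params)
    t_split = params["t_split"]
    n_total = n_s + n_n
    n_nodes = 2 * n_total - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    pools: list[list[int]] = [list(range(n_s)), list(range(n_s, n_total))]
    epoch_idx = [0, 0]
    epochs = [s_epochs, n_epochs]
    next_node = n_total
    t = 0.0
    merged = False
    anc_pool = params["N_A"] * copies_per_diploid

    while next_node < 2 * n_total - 1:
        if not merged:
            rates = []
            for d in (0, 1):
                k = len(pools[d])
                size = epochs[d][epoch_idx[d]][1] * copies_per_diploid
                rates.append(k * (k - 1) / 2.0 / size)
            total = rates[0] + rates[1]
            # nearest upcoming epoch boundary (size change or the split)
            boundary = min(
                epochs[0][epoch_idx[0]][0], epochs[1][epoch_idx[1]][0]
            )
            wait = math.inf if total == 0 else -math.log(rand.random()) / total
            if t + wait >= boundary:
                t = boundary
                for d in (0, 1):
                    while (epoch_idx[d] < len(epochs[d]) - 1
                           and epochs[d][epoch_idx[d]][0] <= t):
                        epoch_idx[d] += 1
                if t >= t_split:
                    pools = [pools[0] + pools[1]]
                    merged = True
                continue
            t += wait
            d = 0 if rand.random() * total < rates[0] else 1
            pool = pools[d]
        else:
            k = len(pools[0])
            rate = k * (k - 1) / 2.0 / anc_pool
            t += -math.log(rand.random()) / rate
            pool = pools[0]
        k = len(pool)
        i = rand.randrange(k)
        j = rand.randrange(k - 1)
        if j >= i:
            j += 1
        a, b = pool[i], pool[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        # replace the two children by the new node
        if i > j:
            i, j = j, i
        pool[i] = next_node
        pool.pop(j)
        next_node += 1
    return Genealogy(n_total, parent, time)


# ---------------------------------------------------------------------------
# Mutation models
# ---------------------------------------------------------------------------


@dataclass
class MutationModel:
    """Mutation model for both marker classes.

    Microsatellites: per-locus rate ``mu_ms`` and GSM geometric parameter
    ``gsm_p`` in [0, 1); allele sizes (repeat numbers) reflected into
    [allele_lo, allele_hi]. mtDNA: rate ``mu_mt``/site/generation, HKY kappa
    and equilibrium base frequencies; proportion of invariant sites
    ``prop_invariant`` on cytb and gamma shape ``gamma_alpha`` on HV1, both
    scaled to preserve the partition-mean rate at ``mu_mt``.
    """

    mu_ms: float = 5e-4
    gsm_p: float = 0.22
    allele_lo: int = 5
    allele_hi: int = 50
    mu_mt: float = 3e-8
    kappa: float = 10.0
    prop_invariant: float = 0.8
    gamma_alpha: float = 0.3
    cytb_len: int = 650
    hv1_len: int = 460
    base_freqs: tuple[float, float, float, float] = (0.30, 0.25, 0.15, 0.30)

    def __post_init__(self) -> None:
        if not (0 <= self.gsm_p < 1):
            raise ValueError("gsm_p must be in [0, 1)")
        if not (0 <= self.prop_invariant < 1):
            raise ValueError("prop_invariant must be in [0, 1)")
        if self.gamma_alpha <= 0 or self.kappa <= 0:
            raise ValueError("kappa and gamma_alpha must be positive")
        if self.mu_ms <= 0 or self.mu_mt <= 0:
            raise ValueError("mutation rates must be positive")
        if self.allele_lo >= self.allele_hi:
            raise ValueError("allele bounds must satisfy lo < hi")

    @property
    def seq_length(self) -> int:
        return self.cytb_len + self.hv1_len

    def with_params(self, params: dict[str, float]) -> "MutationModel":
        """Copy with any mutation parameters from a prior draw applied."""
        return MutationModel(
            mu_ms=params.get("mu_ms", self.mu_ms),
            gsm_p=params.get("gsm_p", self.gsm_p),
            allele_lo=self.allele_lo, allele_hi=self.allele_hi,
            mu_mt=params.get("mu_mt", self.mu_mt),
            kappa=self.kappa, prop_invariant=self.prop_invariant,
            gamma_alpha=self.gamma_alpha,
            cytb_len=self.cytb_len, hv1_len=self.hv1_len,
            base_freqs=self.base_freqs,
        )

    def site_rates(self, rng: np.random.Generator) -> np.ndarray:
        """Per-site mtDNA rates: cytb HKY+I, HV1 HKY+Gamma."""
        rates = np.empty(self.seq_length)
        inv = rng.random(self.cytb_len) < self.prop_invariant
        rates[: self.cytb_len] = np.where(
            inv, 0.0, self.mu_mt / (1.0 - self.prop_invariant)
        )
        g = rng.gamma(self.gamma_alpha, 1.0 / self.gamma_alpha, size=self.hv1_len)
        rates[self.cytb_len:] = self.mu_mt * g
        return rates

    def hky_jump_rows(self) -> np.ndarray:
        """4x4 row-normalized jump probabilities (diagonal zero)."""
        pi = np.array(self.base_freqs)
        P = np.tile(pi, (4, 1))
        for i in range(4):
            P[i, TRANSITION[i]] *= self.kappa
            P[i, i] = 0.0
            P[i] /= P[i].sum()
        return P


def _reflect(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Fold an unconstrained walk into [lo, hi] (triangle-wave reflection)."""
    span = hi - lo
    m = np.mod(values - lo, 2 * span)
    return lo + np.minimum(m, 2 * span - m)


def drop_microsat_mutations(
    tree: Genealogy, mu: float, gsm_p: float, lo: int, hi: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele sizes at the leaves after a GSM walk down the genealogy.

    Each branch receives Poisson(mu * length) mutation events; each event
    shifts repeat number by a geometric(1 - P) magnitude with random sign.
    Leaf values are reflected into [lo, hi].
    """
    bl = tree.branch_lengths
    counts = rng.poisson(mu * bl)
    total = int(counts.sum())
    if total:
        mags = rng.geometric(1.0 - gsm_p, size=total)
        signs = rng.integers(0, 2, size=total) * 2 - 1
        node_of_step = np.repeat(np.arange(len(bl)), counts)
        disp = np.bincount(node_of_step, weights=mags * signs, minlength=len(bl))
    else:
        disp = np.zeros(len(bl))
    values = np.empty(len(bl))
    root = len(bl) - 1
    values[root] = (lo + hi) // 2
    for node in range(root - 1, -1, -1):  # parents precede children
        values[node] = values[tree.parent[node]] + disp[node]
    return _reflect(values[: tree.n], lo, hi).astype(np.int64)


def drop_sequence_mutations(
    tree: Genealogy, site_rates: np.ndarray, jump_rows: np.ndarray,
    base_freqs: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Leaf sequences (n, L) as ACGT indices after HKY evolution on the tree.

    The root sequence is drawn from the equilibrium frequencies; every
    mutation event substitutes the current base using the normalized HKY
    jump chain, so the realized substitution rate per site equals its entry
    in ``site_rates``.
    """
    L = len(site_rates)
    total_rate = float(site_rates.sum())
    bl = tree.branch_lengths
    counts = rng.poisson(total_rate * bl)
    n_nodes = len(bl)
    root_seq = rng.choice(4, size=L, p=base_freqs)
    n_mut = int(counts.sum())
    if n_mut == 0:
        return np.tile(root_seq, (tree.n, 1))
    sites = rng.choice(L, size=n_mut, p=site_rates / total_rate)
    node_of_mut = np.repeat(np.arange(n_nodes), counts)
    # per mutated site, walk the tree applying that site's mutations
    seqs = np.tile(root_seq, (tree.n, 1))
    for s in np.unique(sites):
        on_edge = node_of_mut[sites == s]
        edge_counts = np.bincount(on_edge, minlength=n_nodes)
        state = np.empty(n_nodes, dtype=np.int64)
        root = n_nodes - 1
        state[root] = root_seq[s]
        for node in range(root - 1, -1, -1):
            b = state[tree.parent[node]]
            for _ in range(edge_counts[node]):
                b = rng.choice(4, p=jump_rows[b])
            state[node] = b
        seqs[:, s] = state[: tree.n]
    return seqs


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    alignment: SequenceAlignment
    popmap: PopulationMap
    scenario: int
    params: dict[str, float]


def simulate_dataset(
    scenario: int,
    params: dict[str, float],
    n_s: int = 22,
    n_n: int = 28,
    mutation: MutationModel | None = None,
    seed: int | np.random.Generator = 0,
    n_loci: int = 19,
) -> SimulatedDataset:
    """Simulate one combined microsatellite + mtDNA dataset.

    ``n_s``/``n_n`` are diploid sample sizes for the southern and northern
    populations (study design defaults 22 and 28). Mutation parameters
    present in ``params`` (``mu_ms``, ``gsm_p``, ``mu_mt``) override the
    ``mutation`` defaults, so prior draws flow through. Each of the
    ``n_loci`` microsatellite loci gets an independent genealogy with 2
    lineages per diploid; the mtDNA alignment uses one lineage per individual
    on a haploid pool of N/2 copies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rand = _pyrandom.Random(int(rng.integers(0, 2**63 - 1)))
    mut = (mutation or MutationModel()).with_params(params)

    n_ind = n_s + n_n
    calls = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for locus in range(n_loci):
        tree = simulate_genealogy(scenario, params, 2 * n_s, 2 * n_n, rand,
                                  copies_per_diploid=2.0)
        alleles = drop_microsat_mutations(
            tree, mut.mu_ms, mut.gsm_p, mut.allele_lo, mut.allele_hi, rng
        )
        calls[:, locus, :] = alleles.reshape(n_ind, 2)

    tree_mt = simulate_genealogy(scenario, params, n_s, n_n, rand,
                                 copies_per_diploid=0.5)
    seq_idx = drop_sequence_mutations(
        tree_mt, mut.site_rates(rng), mut.hky_jump_rows(),
        np.array(mut.base_freqs), rng,
    )
    ids = [f"S{i:03d}" for i in range(n_s)] + [f"N{i:03d}" for i in range(n_n)]
    loci = [f"locus{j + 1:02d}" for j in range(n_loci)]
    gt = GenotypeMatrix(ids, loci, calls)
    byte_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = [row.tobytes().decode("ascii") for row in byte_lut[seq_idx]]
    aln = SequenceAlignment(
        list(ids), seqs,
        partitions={"cytb": (1, mut.cytb_len),
                    "hv1": (mut.cytb_len + 1, mut.seq_length)},
    )
    popmap = PopulationMap({i: ("S" if i.startswith("S") else "N") for i in ids})
    return SimulatedDataset(gt, aln, popmap, scenario, dict(params))
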