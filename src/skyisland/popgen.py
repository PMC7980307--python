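"""Sequence and microsatellite summary statistics for sky-island populations.

Implements the marker-level analyses of the monitoring pipeline: haplotype
collapsing and mitochondrial diversity/divergence, microsatellite diversity
(rarefied allelic richness, private alleles, observed/expected heterozygosity),
an individual maximum-likelihood inbreeding coefficient, marker quality control
(Hardy-Weinberg Monte-Carlo exact tests, null-allele frequencies), pairwise
differentiation (Weir-Cockerham theta and Jost's D_est) and the simple linear
models relating per-population diversity to land-use covariates.

Conventions
-----------
* Missing microsatellite calls are coded as ``-1`` in the genotype array and
  excluded from per-locus gene counts.
* Gap (``-``) and ambiguous (``N``) sequence positions are handled by pairwise
  deletion in nucleotide-diversity statistics; haplotype collapsing treats
  ``N`` as an ordinary mismatching state unless ``ambiguous_merge`` is set.
* Expected heterozygosity uses Nei's unbiased estimator ``2n/(2n-1)(1-sum p^2)``
  (gene counts ``2n``); haplotype diversity is the same estimator on haploid
  counts, ``n/(n-1)(1-sum p^2)``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

MISSING = -1

__all__ = [
    "MISSING",
    "SequenceAlignment",
    "GenotypeMatrix",
    "PopulationMap",
    "PairwiseMatrix",
    "HaplotypeTable",
    "collapse_haplotypes",
    "mtdna_diversity",
    "mtdna_divergence",
    "microsat_summaries",
    "inbreeding_ml",
    "marker_qc",
    "pairwise_differentiation",
    "weir_cockerham_theta",
    "jost_d",
    "diversity_landuse_regression",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceAlignment:
    """Aligned haploid sequences with optional named partitions.

    Partitions are 1-based inclusive ranges into the concatenated alignment,
    e.g. ``{"cytb": (1, 650), "hv1": (651, 1110)}``.
    """

    ids: list[str]
    seqs: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        L = self.length
        seen: list[tuple[int, int]] = []
        for name, (lo, hi) in self.partitions.items():
            if not (1 <= lo <= hi <= L):
                raise ValueError(f"partition {name!r} range ({lo},{hi}) out of bounds 1..{L}")
            for plo, phi in seen:
                if lo <= phi and plo <= hi:
                    raise ValueError(f"partition {name!r} overlaps another partition")
            seen.append((lo, hi))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def slice_partition(self, name: str) -> "SequenceAlignment":
        lo, hi = self.partitions[name]
        return SequenceAlignment(list(self.ids), [s[lo - 1 : hi] for s in self.seqs])

    def subset(self, ids: list[str]) -> "SequenceAlignment":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return SequenceAlignment(list(ids), [self.seqs[r] for r in rows], dict(self.partitions))

    def to_array(self) -> np.ndarray:
        """(n, L) byte array view of the alignment."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(self.n, self.length)


@dataclass
class GenotypeMatrix:
    """Diploid microsatellite calls: (n individuals, L loci, 2) allele sizes.

    Allele sizes are positive integers; missing calls are ``MISSING`` (-1) in
    both slots of the pair. The pair is unordered.
    """

    ids: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({len(self.ids)}, {len(self.loci)}, 2)"
            )
        bad = (self.calls != MISSING) & (self.calls <= 0)
        if bad.any():
            raise ValueError("allele sizes must be positive integers (missing = -1)")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), list(self.loci), self.calls[rows])


class PopulationMap(dict):
    """Individual label -> population label."""

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.values():
            seen.setdefault(p, None)
        return list(seen)

    def members(self, pop: str) -> list[str]:
        return [i for i, p in self.items() if p == pop]

    def require_complete(self, ids: list[str]) -> None:
        missing = [i for i in ids if i not in self]
        if missing:
            raise ValueError(f"individuals not in population map: {missing[:5]}")


@dataclass
class PairwiseMatrix:
    """Symmetric labelled matrix of a named pairwise statistic."""

    labels: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("matrix is not symmetric")

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def lower_triangle(self) -> np.ndarray:
        iu = np.tril_indices(len(self.labels), k=-1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class HaplotypeTable:
    """haplotype id -> representative sequence and member individuals."""

    sequences: list[str]
    members: list[list[str]]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])


# ---------------------------------------------------------------------------
# mtDNA operations
# ---------------------------------------------------------------------------


def collapse_haplotypes(
    aln: SequenceAlignment,
    scope: str | None = None,
    ambiguous_merge: bool = False,
) -> HaplotypeTable:
    """Group identical sequences into haplotypes.

    ``scope`` restricts the comparison to a named partition; by default the
    full concatenated sequence is used. With ``ambiguous_merge`` a sequence
    whose only differences from an existing haplotype fall on ``N``/``-``
    positions is merged into it (first-match, in input order); by default
    ambiguity codes are ordinary mismatching states.
    """
    if scope is not None:
        aln = aln.slice_partition(scope)
    table_seqs: list[str] = []
    members: list[list[str]] = []
    if not ambiguous_merge:
        index: dict[str, int] = {}
        for ind, seq in zip(aln.ids, aln.seqs):
            h = index.get(seq)
            if h is None:
                index[seq] = len(table_seqs)
                table_seqs.append(seq)
                members.append([ind])
            else:
                members[h].append(ind)
    else:
        for ind, seq in zip(aln.ids, aln.seqs):
            for h, ref in enumerate(table_seqs):
                if _compatible(seq, ref):
                    members[h].append(ind)
                    # keep the more resolved state at ambiguous positions
                    table_seqs[h] = "".join(
                        r if r not in "N-" else s for s, r in zip(seq, ref)
                    )
                    break
            else:
                table_seqs.append(seq)
                members.append([ind])
    return HaplotypeTable(table_seqs, members)


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x in "N-" or y in "N-" for x, y in zip(a, b))


def _pairwise_diff_stats(arr: np.ndarray) -> tuple[float, float]:
    """Mean pairwise (raw count, per-site proportion) with pairwise deletion."""
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    valid = ~np.isin(arr, [b"N", b"-"])
    tot_d = 0.0
    tot_p = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        ok = valid[i] & valid[j]
        L = int(ok.sum())
        if L == 0:
            continue
        d = int(((arr[i] != arr[j]) & ok).sum())
        tot_d += d
        tot_p += d / L
        npairs += 1
    if npairs == 0:
        return 0.0, 0.0
    return tot_d / npairs, tot_p / npairs


def mtdna_diversity(aln: SequenceAlignment) -> tuple[int, float, float]:
    """(haplotype count, haplotype diversity Hd, nucleotide diversity Pi).

    Hd is Nei's unbiased gene diversity on haplotype frequencies,
    ``n (1 - sum p_i^2) / (n - 1)``; Pi is the mean pairwise proportion of
    differing sites with pairwise deletion of gaps and Ns.
    """
    if aln.n < 2:
        raise ValueError("haplotype diversity is undefined for n < 2 sequences")
    table = collapse_haplotypes(aln)
    n = aln.n
    p = table.counts / n
    hd = n * (1.0 - float(np.sum(p**2))) / (n - 1)
    _, pi = _pairwise_diff_stats(aln.to_array())
    return table.n_haplotypes, hd, pi


def _between_diffs(arr_a: np.ndarray, arr_b: np.ndarray) -> tuple[float, float]:
    """Mean between-group pairwise (count, per-site proportion), pairwise deletion."""
    valid_a = ~np.isin(arr_a, [b"N", b"-"])
    valid_b = ~np.isin(arr_b, [b"N", b"-"])
    tot_d = tot_p = 0.0
    npairs = 0
    for i in range(arr_a.shape[0]):
        for j in range(arr_b.shape[0]):
            ok = valid_a[i] & valid_b[j]
            L = int(ok.sum())
            if L == 0:
                continue
            d = int(((arr_a[i] != arr_b[j]) & ok).sum())
            tot_d += d
            tot_p += d / L
            npairs += 1
    if npairs == 0:
        return 0.0, 0.0
    return tot_d / npairs, tot_p / npairs


def mtdna_divergence(
    aln: SequenceAlignment, popmap: PopulationMap
) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Per-population-pair Dxy and Hudson F_ST matrices.

    Dxy is the mean between-population pairwise difference per site; Hudson's
    F_ST is ``1 - mean(pi_S, pi_N) / pi_between``. Populations with fewer than
    two sequences are excluded with a warning.
    """
    popmap.require_complete(aln.ids)
    pops = []
    for p in popmap.populations:
        ids = [i for i in aln.ids if popmap[i] == p]
        if len(ids) < 2:
            warnings.warn(f"population {p!r} has <2 sequences; excluded from divergence")
            continue
        pops.append(p)
    if len(pops) < 2:
        raise ValueError("need >=2 populations with >=2 sequences")
    arrays = {p: aln.subset([i for i in aln.ids if popmap[i] == p]).to_array() for p in pops}
    k = len(pops)
    dxy = np.zeros((k, k))
    fst = np.zeros((k, k))
    pi_within = {p: _pairwise_diff_stats(arrays[p])[1] for p in pops}
    for a, b in itertools.combinations(range(k), 2):
        _, pb = _between_diffs(arrays[pops[a]], arrays[pops[b]])
        dxy[a, b] = dxy[b, a] = pb
        if pb > 0:
            f = 1.0 - 0.5 * (pi_within[pops[a]] + pi_within[pops[b]]) / pb
        else:
            f = 0.0
        fst[a, b] = fst[b, a] = f
    return (
        PairwiseMatrix(pops, dxy, "Dxy"),
        PairwiseMatrix(pops, fst, "Hudson_FST"),
    )


# ---------------------------------------------------------------------------
# Microsatellite helpers
# ---------------------------------------------------------------------------


def _allele_counts(calls: np.ndarray) -> dict[int, int]:
    """Non-missing allele copy counts for a (n, 2) locus slice."""
    flat = calls.reshape(-1)
    flat = flat[flat != MISSING]
    alleles, counts = np.unique(flat, return_counts=True)
    return dict(zip(alleles.tolist(), counts.tolist()))


def _lncomb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_richness(counts: dict[int, int], g: int) -> float:
    """Expected distinct alleles in a random subsample of g gene copies."""
    N = sum(counts.values())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene count N={N}")
    ar = 0.0
    for ni in counts.values():
        if N - ni < g:
            ar += 1.0
        else:
            ar += 1.0 - math.exp(_lncomb(N - ni, g) - _lncomb(N, g))
    return ar


def _unbiased_he(counts: dict[int, int]) -> float:
    N = sum(counts.values())
    if N < 2:
        return 0.0
    p = np.array(list(counts.values())) / N
    return N / (N - 1) * (1.0 - float(np.sum(p**2)))


def microsat_summaries(
    gt: GenotypeMatrix,
    popmap: PopulationMap,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Per-population diversity table: N, Na, Ar, Pa, Ho, He.

    Na is the mean observed number of alleles per locus; Ar the allelic
    richness rarefied to ``rarefaction_g`` gene copies (default: the smallest
    per-locus non-missing gene count over populations); Pa counts alleles
    observed in exactly one population (summed over loci); He is Nei's
    unbiased expected heterozygosity averaged over loci.
    """
    popmap.require_complete(gt.ids)
    pops = popmap.populations
    sub = {p: gt.subset([i for i in gt.ids if popmap[i] == p]) for p in pops}

    counts: dict[str, list[dict[int, int]]] = {
        p: [_allele_counts(sub[p].calls[:, l]) for l in range(gt.n_loci)] for p in pops
    }
    if rarefaction_g is None:
        gene_counts = [
            sum(counts[p][l].values()) for p in pops for l in range(gt.n_loci)
        ]
        rarefaction_g = max(2, min(gene_counts))
    g = int(rarefaction_g)

    # private alleles: allele x locus seen in exactly one population
    rows = []
    for p in pops:
        na, ar, ho, he = [], [], [], []
        pa = 0
        ar_dropped = 0
        for l in range(gt.n_loci):
            c = counts[p][l]
            if not c:
                continue
            na.append(len(c))
            he.append(_unbiased_he(c))
            N = sum(c.values())
            if N >= g:
                ar.append(_rarefied_richness(c, g))
            else:
                ar_dropped += 1
            calls = sub[p].calls[:, l]
            scored = calls[:, 0] != MISSING
            if scored.any():
                ho.append(float(np.mean(calls[scored, 0] != calls[scored, 1])))
            for allele in c:
                if not any(allele in counts[q][l] for q in pops if q != p):
                    pa += 1
        if ar_dropped:
            warnings.warn(
                f"population {p!r}: {ar_dropped} loci dropped from Ar (gene count < g={g})"
            )
        rows.append(
            {
                "population": p,
                "N": len(sub[p].ids),
                "Na": float(np.mean(na)),
                "Ar": float(np.mean(ar)) if ar else np.nan,
                "Pa": pa,
                "Ho": float(np.mean(ho)),
                "He": float(np.mean(he)),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def inbreeding_ml(gt: GenotypeMatrix, popmap: PopulationMap) -> pd.Series:
    """Per-individual maximum-likelihood inbreeding coefficient on [0, 1].

    Maximizes the product over loci of ``P(genotype | F)`` with
    ``P(A_iA_i) = p_i^2 + F p_i (1-p_i)`` and ``P(A_iA_j) = 2 p_i p_j (1-F)``
    using the individual's population allele frequencies. Individuals with no
    scored loci get NaN.
    """
    popmap.require_complete(gt.ids)
    pops = popmap.populations
    freqs: dict[str, list[dict[int, float]]] = {}
    for p in pops:
        sub = gt.subset([i for i in gt.ids if popmap[i] == p])
        freqs[p] = []
        for l in range(gt.n_loci):
            c = _allele_counts(sub.calls[:, l])
            N = sum(c.values())
            freqs[p].append({a: k / N for a, k in c.items()} if N else {})

    out = {}
    for idx, ind in enumerate(gt.ids):
        f = freqs[popmap[ind]]
        terms: list[tuple[float, float]] = []  # (hom part, het/base part) per locus
        for l in range(gt.n_loci):
            a, b = gt.calls[idx, l]
            if a == MISSING or not f[l]:
                continue
            pa = f[l].get(int(a), 0.0)
            pb = f[l].get(int(b), 0.0)
            if pa == 0 or pb == 0:
                continue
            if a == b:
                # p^2 + F p (1-p) = p^2 (1-F) + p F
                terms.append((pa * pa, pa))
            else:
                terms.append((2 * pa * pb, 0.0))
        if not terms:
            out[ind] = np.nan
            continue
        base = np.array([t[0] for t in terms])
        homf = np.array([t[1] for t in terms])

        def nll(F: float) -> float:
            probs = base * (1 - F) + homf * F
            if np.any(probs <= 0):
                return np.inf
            return -float(np.sum(np.log(probs)))

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-8})
        cand = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
        out[ind] = min(cand)[1]
    return pd.Series(out, name="F_ml")


def marker_qc(
    gt: GenotypeMatrix,
    popmap: PopulationMap,
    n_perm: int = 1000,
    seed: int | None = None,
    hwe_alpha: float = 0.01,
    null_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per locus x population HWE Monte-Carlo p, null-allele frequency, flags.

    The HWE test permutes gene copies within the population into random
    diploid genotypes and compares the observed heterozygote count to its
    permutation distribution (two-sided). The null-allele frequency is
    Chakraborty's ``r = (He - Ho) / (He + Ho)`` floored at 0. A locus is
    flagged ``drop`` if HWE is rejected at ``hwe_alpha`` or the null-allele
    frequency exceeds ``null_threshold`` in more than half of the populations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for the HWE Monte-Carlo test")
    rng = np.random.default_rng(seed)
    popmap.require_complete(gt.ids)
    pops = popmap.populations
    rows = []
    for l, locus in enumerate(gt.loci):
        for p in pops:
            sub = gt.subset([i for i in gt.ids if popmap[i] == p])
            calls = sub.calls[:, l]
            calls = calls[calls[:, 0] != MISSING]
            n = calls.shape[0]
            c = _allele_counts(calls)
            if len(c) <= 1 or n < 2:
                rows.append({"locus": locus, "population": p, "hwe_p": 1.0,
                             "null_freq": 0.0})
                continue
            he = _unbiased_he(c)
            ho = float(np.mean(calls[:, 0] != calls[:, 1]))
            r = max(0.0, (he - ho) / (he + ho)) if (he + ho) > 0 else 0.0
            genes = calls.reshape(-1).copy()
            obs_het = int(np.sum(calls[:, 0] != calls[:, 1]))
            het_perm = np.empty(n_perm, dtype=int)
            for b in range(n_perm):
                rng.shuffle(genes)
                pairs = genes.reshape(n, 2)
                het_perm[b] = int(np.sum(pairs[:, 0] != pairs[:, 1]))
            center = het_perm.mean()
            extreme = np.abs(het_perm - center) >= abs(obs_het - center) - 1e-12
            pval = (1 + int(extreme.sum())) / (n_perm + 1)
            rows.append({"locus": locus, "population": p, "hwe_p": pval,
                         "null_freq": r})
    df = pd.DataFrame(rows)
    flags = []
    for locus in gt.loci:
        d = df[df.locus == locus]
        bad = ((d.hwe_p < hwe_alpha) | (d.null_freq > null_threshold)).mean()
        flags.append({"locus": locus, "retain": bool(bad <= 0.5)})
    return df.merge(pd.DataFrame(flags), on="locus")


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------


def weir_cockerham_theta(
    gt: GenotypeMatrix, popmap: PopulationMap, pops: list[str] | None = None
) -> float:
    """Multilocus Weir-Cockerham (1984) theta = sum(a) / sum(a+b+c).

    Computed over the given populations (default: all in the map), summing
    variance components over alleles and loci. May be negative; reported raw.
    """
    popmap.require_complete(gt.ids)
    if pops is None:
        pops = popmap.populations
    subs = [gt.subset([i for i in gt.ids if popmap[i] == p]) for p in pops]
    r = len(pops)
    num = den = 0.0
    for l in range(gt.n_loci):
        slices = []
        for s in subs:
            calls = s.calls[:, l]
            calls = calls[calls[:, 0] != MISSING]
            if calls.shape[0] == 0:
                continue
            slices.append(calls)
        if len(slices) < 2:
            continue
        ns = np.array([c.shape[0] for c in slices], dtype=float)
        nbar = ns.mean()
        rr = len(slices)
        nc = (ns.sum() - np.sum(ns**2) / ns.sum()) / (rr - 1)
        alleles = sorted({int(a) for c in slices for a in np.unique(c)})
        for allele in alleles:
            p_i = np.array([np.mean(c == allele) for c in slices])
            h_i = np.array(
                [np.mean((c[:, 0] == allele) != (c[:, 1] == allele)) for c in slices]
            )
            pbar = float(np.sum(ns * p_i) / ns.sum())
            s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((rr - 1) * nbar))
            hbar = float(np.sum(ns * h_i) / ns.sum())
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - (rr - 1) / rr * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (rr - 1) / rr * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            num += a
            den += a + b + c
    if den == 0:
        return 0.0
    return num / den


def _nei_chesser(counts_by_pop: list[dict[int, int]]) -> tuple[float, float]:
    """Bias-corrected (Hs, Ht) of Nei & Chesser (1983) for one locus."""
    r = len(counts_by_pop)
    Ns = np.array([sum(c.values()) for c in counts_by_pop], dtype=float)
    n_harm = r / np.sum(2.0 / Ns)  # harmonic mean sample size (individuals)
    alleles = sorted({a for c in counts_by_pop for a in c})
    p = np.array(
        [[c.get(a, 0) / Ns[k] for a in alleles] for k, c in enumerate(counts_by_pop)]
    )
    hs_tilde = 1.0 - float(np.mean(np.sum(p**2, axis=1)))
    pbar = p.mean(axis=0)
    ht_tilde = 1.0 - float(np.sum(pbar**2))
    hs = (2 * n_harm / (2 * n_harm - 1)) * hs_tilde
    ht = ht_tilde + hs / (2 * n_harm * r)
    return hs, ht


def jost_d(
    gt: GenotypeMatrix, popmap: PopulationMap, pops: list[str] | None = None
) -> float:
    """Multilocus Jost's D_est with Nei-Chesser corrected Hs/Ht.

    Per locus ``D = (Ht - Hs)/(1 - Hs) * r/(r - 1)``; the multilocus value is
    the harmonic mean over loci with per-locus D floored at 0 (a zero-D locus
    yields a multilocus D of 0, matching the behaviour on identical tables).
    """
    popmap.require_complete(gt.ids)
    if pops is None:
        pops = popmap.populations
    subs = [gt.subset([i for i in gt.ids if popmap[i] == p]) for p in pops]
    r = len(pops)
    ds = []
    for l in range(gt.n_loci):
        counts = []
        for s in subs:
            c = _allele_counts(s.calls[:, l])
            if c:
                counts.append(c)
        if len(counts) < 2:
            continue
        hs, ht = _nei_chesser(counts)
        if 1.0 - hs <= 0:
            continue
        d = (ht - hs) / (1.0 - hs) * len(counts) / (len(counts) - 1)
        ds.append(max(0.0, d))
    if not ds:
        return 0.0
    ds_arr = np.array(ds)
    if np.any(ds_arr == 0):
        return 0.0
    return float(len(ds_arr) / np.sum(1.0 / ds_arr))


def pairwise_differentiation(
    gt: GenotypeMatrix, popmap: PopulationMap
) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Pairwise Weir-Cockerham theta and Jost's D matrices over populations."""
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need >=2 populations")
    k = len(pops)
    theta = np.zeros((k, k))
    d = np.zeros((k, k))
    for a, b in itertools.combinations(range(k), 2):
        pair = [pops[a], pops[b]]
        theta[a, b] = theta[b, a] = weir_cockerham_theta(gt, popmap, pair)
        d[a, b] = d[b, a] = jost_d(gt, popmap, pair)
    return (
        PairwiseMatrix(pops, theta, "WC_theta"),
        PairwiseMatrix(pops, d, "Jost_D"),
    )


# ---------------------------------------------------------------------------
# Diversity ~ land-use models
# ---------------------------------------------------------------------------


def diversity_landuse_regression(
    response: pd.Series, covariate: pd.Series
) -> dict[str, float]:
    """OLS of a per-population diversity measure on one land-use covariate.

    Returns slope, intercept, F statistic of the slope, (df1, df2), p-value
    and R^2. Requires >=3 populations and a non-degenerate covariate.
    """
    df = pd.concat([response, covariate], axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError("need >=3 populations for the regression")
    y = df.iloc[:, 0].to_numpy(float)
    x = df.iloc[:, 1].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "F": 0.0, "df1": 1,
                "df2": int(len(y) - 2), "p": 1.0, "r2": 0.0, "n": int(len(y))}
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "F": float(model.fvalue),
        "df1": 1,
        "df2": int(model.df_resid),
        "p": float(model.f_pvalue),
        "r2": float(model.rsquared),
        "n": int(len(df)),
    }
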