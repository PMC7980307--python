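"""Circuit-theory landscape genetics.

The landscape is a raster of per-cell movement resistance. Treating each cell
as a node and each neighbour adjacency as a resistor (edge conductance = the
reciprocal of the mean of the two cell resistances; diagonal neighbours under
8-connectivity get their conductance divided by sqrt(2) to account for the
longer step), the effective resistance between two population nodes summarizes
movement across all pathways simultaneously — the circuit-theory analogue of
gene-flow connectivity.

Hypothesis testing follows the standard landscape-genetics workflow: candidate
cost schemes are ranked by multiple regression on distance matrices (MRDM)
against genetic distance; competing landscape hypotheses are compared with the
maximum-likelihood population-effects (MLPE) mixed model, ranked by AICc/BIC
evidence weights. Genetic distances are normalized for geography by dividing
log genetic distance by log Euclidean distance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .popgen import PairwiseMatrix

__all__ = [
    "RasterGrid",
    "CostScheme",
    "NodeSet",
    "MLPEFit",
    "ModelComparison",
    "reclassify",
    "resistance_distances",
    "current_density_map",
    "mrdm",
    "select_cost_scheme",
    "normalize_genetic_distance",
    "mlpe_fit",
    "model_compare",
    "euclidean_distances",
]

SQRT2 = math.sqrt(2.0)
FST_FLOOR = 1e-6  # clamp for non-positive differentiation before log


@dataclass
class RasterGrid:
    """Single-band row-major grid; row 0 is the northern edge.

    ``values`` holds floats with NaN for nodata; ``nodata_value`` is the
    sentinel used on disk.
    """

    values: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def like(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(values, self.cellsize, self.xllcorner, self.yllcorner,
                          self.nodata_value)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of a cell centre."""
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return x, y


@dataclass
class CostScheme:
    """Mapping from a landscape variable to resistance costs in [1, 100].

    ``categories`` maps exact cell values (e.g. ecoregion class codes) to
    costs; ``ranges`` is a list of (low, high, cost) half-open [low, high)
    bins for continuous variables. A cell must be covered by exactly one rule.
    """

    variable: str
    label: str
    categories: dict[float, float] = field(default_factory=dict)
    ranges: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        costs = list(self.categories.values()) + [c for *_, c in self.ranges]
        for c in costs:
            if not (1.0 <= c <= 100.0):
                raise ValueError(f"resistance cost {c} outside [1, 100]")

    def cost(self, value: float) -> float:
        if value in self.categories:
            return self.categories[value]
        for lo, hi, c in self.ranges:
            if lo <= value < hi:
                return c
        raise KeyError(f"scheme {self.label!r}: unmapped value {value!r}")


class NodeSet(dict):
    """Population label -> (row, col) raster cell."""

    def validate(self, grid: RasterGrid) -> None:
        seen = set()
        for label, (r, c) in self.items():
            if not (0 <= r < grid.nrows and 0 <= c < grid.ncols):
                raise ValueError(f"node {label!r} outside grid")
            if np.isnan(grid.values[r, c]):
                raise ValueError(f"node {label!r} on a nodata cell")
            if (r, c) in seen:
                raise ValueError(f"node {label!r} duplicates a cell")
            seen.add((r, c))


def reclassify(raster: RasterGrid, scheme: CostScheme) -> RasterGrid:
    """Apply a cost scheme cell-by-cell; nodata propagates."""
    out = np.full_like(raster.values, np.nan)
    vals = raster.values
    finite = ~np.isnan(vals)
    uniq = np.unique(vals[finite])
    lut = {v: scheme.cost(float(v)) for v in uniq}
    for v, c in lut.items():
        out[finite & (vals == v)] = c
    return raster.like(out)


# ---------------------------------------------------------------------------
# Circuit theory
# ---------------------------------------------------------------------------


def _build_laplacian(resist: RasterGrid, connectivity: int = 8
                     ) -> tuple[sparse.csc_matrix, np.ndarray]:
    """Graph Laplacian over non-nodata cells.

    Returns (L, node_index) where node_index maps flat cell index -> graph
    node id (-1 for nodata).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    vals = resist.values
    nr, nc = vals.shape
    finite = ~np.isnan(vals)
    node_index = -np.ones(nr * nc, dtype=np.int64)
    node_index[finite.ravel()] = np.arange(int(finite.sum()))
    rows, cols, conds = [], [], []
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        a = vals[r0, c0]
        b = vals[r1, c1]
        ok = ~np.isnan(a) & ~np.isnan(b)
        ia = (np.arange(nr)[r0, None] * nc + np.arange(nc)[None, c0])[ok]
        ib = (np.arange(nr)[r1, None] * nc + np.arange(nc)[None, c1])[ok]
        g = 1.0 / (0.5 * (a[ok] + b[ok]))
        if dr != 0 and dc != 0:
            g = g / SQRT2
        rows.append(node_index[ia])
        cols.append(node_index[ib])
        conds.append(g)
    i = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
    j = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
    g = np.concatenate(conds) if conds else np.array([])
    n = int(finite.sum())
    A = sparse.coo_matrix((np.r_[g, g], (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    L = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    return L.tocsc(), node_index


def _node_ids(resist: RasterGrid, nodes: NodeSet, node_index: np.ndarray
              ) -> tuple[list[str], np.ndarray]:
    nodes.validate(resist)
    labels = list(nodes)
    ids = np.array([node_index[r * resist.ncols + c] for r, c in nodes.values()])
    return labels, ids


def _solve_pair_potentials(lu, ground: int, n: int, src: int, dst: int) -> np.ndarray:
    """Potentials for unit current src -> dst with one grounded node.

    The Laplacian row/column of ``ground`` is removed before factorization;
    ``lu`` solves the reduced system.
    """
    b = np.zeros(n)
    b[src] += 1.0
    b[dst] -= 1.0
    b_red = np.delete(b, ground)
    v_red = lu.solve(b_red)
    v = np.insert(v_red, ground, 0.0)
    return v


def resistance_distances(
    resist: RasterGrid, nodes: NodeSet, connectivity: int = 8
) -> PairwiseMatrix:
    """Pairwise effective resistance between node cells.

    Disconnected pairs get ``inf`` with a warning. Solved exactly by sparse LU
    factorization of the grounded Laplacian, one factorization per surface.
    """
    L, node_index = _build_laplacian(resist, connectivity)
    labels, ids = _node_ids(resist, nodes, node_index)
    ncomp, comp = connected_components(L != 0, directed=False)
    k = len(labels)
    out = np.zeros((k, k))
    lu_cache: dict[int, tuple] = {}

    def component_solver(cid: int):
        if cid not in lu_cache:
            sel = np.where(comp == cid)[0]
            sub = L[np.ix_(sel, sel)].tocsc()
            remap = {g: i for i, g in enumerate(sel)}
            lu_cache[cid] = (splu(sub[1:, 1:]), remap, len(sel))
        return lu_cache[cid]

    for a, b in itertools.combinations(range(k), 2):
        if comp[ids[a]] != comp[ids[b]]:
            warnings.warn(f"nodes {labels[a]!r} and {labels[b]!r} are disconnected")
            out[a, b] = out[b, a] = np.inf
            continue
        lu, remap, n_sub = component_solver(int(comp[ids[a]]))
        v = _solve_pair_potentials(lu, 0, n_sub, remap[ids[a]], remap[ids[b]])
        out[a, b] = out[b, a] = v[remap[ids[a]]] - v[remap[ids[b]]]
    return PairwiseMatrix(labels, out, "resistance")


def current_density_map(
    resist: RasterGrid,
    nodes: NodeSet,
    pairs: list[tuple[str, str]] | None = None,
    connectivity: int = 8,
) -> RasterGrid:
    """Per-cell current magnitude summed over unit-current node pairs.

    For each pair a unit current is injected/extracted and each cell receives
    half the sum of absolute currents on its incident edges (so a cell on a
    single series path carries current 1). Disconnected pairs are skipped with
    a warning.
    """
    L, node_index = _build_laplacian(resist, connectivity)
    labels, ids = _node_ids(resist, nodes, node_index)
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    n = L.shape[0]
    ncomp, comp = connected_components(L != 0, directed=False)
    lu_cache: dict[int, tuple] = {}

    def component_solver(cid: int):
        if cid not in lu_cache:
            sel = np.where(comp == cid)[0]
            sub = L[np.ix_(sel, sel)].tocsc()
            remap = np.full(n, -1, dtype=np.int64)
            remap[sel] = np.arange(len(sel))
            lu_cache[cid] = (splu(sub[1:, 1:]), remap, sel)
        return lu_cache[cid]

    A = -L.copy()
    A.setdiag(0)
    A.eliminate_zeros()
    A = A.tocoo()
    total = np.zeros(n)
    idx = {lab: i for i, lab in enumerate(labels)}
    for a_lab, b_lab in pairs:
        a, b = ids[idx[a_lab]], ids[idx[b_lab]]
        if comp[a] != comp[b]:
            warnings.warn(f"pair ({a_lab}, {b_lab}) is disconnected; skipped")
            continue
        lu, remap, sel = component_solver(int(comp[a]))
        v_sub = _solve_pair_potentials(lu, 0, len(sel), remap[a], remap[b])
        v = np.zeros(n)
        v[sel] = v_sub
        # A holds each undirected edge in both orientations; summing half the
        # absolute directed currents at each node gives 0.5 * sum |I_edge|.
        edge_cur = np.abs(A.data * (v[A.row] - v[A.col]))
        same_comp = comp[A.row] == comp[a]
        np.add.at(total, A.row[same_comp], 0.5 * edge_cur[same_comp])
    out = np.full(resist.values.size, np.nan)
    out[node_index >= 0] = total[node_index[node_index >= 0]]
    return resist.like(out.reshape(resist.values.shape))


def euclidean_distances(sites: dict[str, tuple[float, float]]) -> PairwiseMatrix:
    """Pairwise Euclidean distances from projected (x, y) coordinates."""
    labels = list(sites)
    xy = np.array([sites[k] for k in labels], dtype=float)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    return PairwiseMatrix(labels, d, "euclidean")


# ---------------------------------------------------------------------------
# MRDM
# ---------------------------------------------------------------------------


def _aligned_lower(Y: PairwiseMatrix, X: list[PairwiseMatrix]) -> tuple[np.ndarray, np.ndarray]:
    labels = Y.labels
    for x in X:
        if x.labels != labels:
            raise ValueError("predictor matrix labels do not match response")
    iu = np.tril_indices(len(labels), k=-1)
    y = Y.values[iu]
    xs = np.column_stack([x.values[iu] for x in X])
    return y, xs


def _ols_stats(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """R^2, coefficients (incl. intercept) and |t| statistics."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = max(n - Xd.shape[1], 1)
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(Xd.T @ Xd)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
    return r2, beta, np.abs(beta / se)


def mrdm(
    Y: PairwiseMatrix,
    X: list[PairwiseMatrix],
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Multiple regression on distance matrices with permutation tests.

    OLS on the vectorized lower triangles; significance by simultaneous
    row/column permutation of the response matrix (Legendre). Returns R^2,
    its permutation p-value, coefficients and per-coefficient p-values
    (permutation distribution of |t|).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("a permutation seed is required")
    y, xs = _aligned_lower(Y, X)
    if np.ptp(y) == 0:
        raise ValueError("constant response matrix")
    r2_obs, beta_obs, t_obs = _ols_stats(y, xs)
    rng = np.random.default_rng(seed)
    k = len(Y.labels)
    iu = np.tril_indices(k, k=-1)
    ge_r2 = 0
    ge_t = np.zeros_like(t_obs)
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yp = Y.values[np.ix_(perm, perm)][iu]
        r2p, _, tp = _ols_stats(yp, xs)
        if r2p >= r2_obs - 1e-12:
            ge_r2 += 1
        ge_t += tp >= t_obs - 1e-12
    return {
        "r2": r2_obs,
        "p": (ge_r2 + 1) / (n_perm + 1),
        "coefficients": beta_obs,
        "coef_p": (ge_t + 1) / (n_perm + 1),
        "n_perm": n_perm,
    }


def select_cost_scheme(
    raster: RasterGrid,
    candidates: list[CostScheme],
    genetic: PairwiseMatrix,
    nodes: NodeSet,
    connectivity: int = 8,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[CostScheme, list[dict]]:
    """Rank candidate cost schemes by MRDM R^2 against genetic distance.

    Ties break toward the lexicographically lowest scheme label.
    """
    if not candidates:
        raise ValueError("no candidate schemes")
    results = []
    for scheme in candidates:
        surface = reclassify(raster, scheme)
        rd = resistance_distances(surface, nodes, connectivity)
        rd_aligned = PairwiseMatrix(
            genetic.labels,
            np.array([[rd.pair(a, b) if a != b else 0.0 for b in genetic.labels]
                      for a in genetic.labels]),
            rd.name,
        )
        fit = mrdm(genetic, [rd_aligned], n_perm=n_perm, seed=seed)
        results.append({"label": scheme.label, "scheme": scheme,
                        "r2": fit["r2"], "p": fit["p"]})
    results.sort(key=lambda r: (-r["r2"], r["label"]))
    return results[0]["scheme"], results


def normalize_genetic_distance(
    G: PairwiseMatrix, E: PairwiseMatrix, clamp: float = FST_FLOOR
) -> PairwiseMatrix:
    """ln(G_ij) / ln(E_ij) per pair; non-positive G clamped to ``clamp``.

    Euclidean distances must exceed 1 (log positive) — use metre-scale
    projected coordinates.
    """
    if G.labels != E.labels:
        raise ValueError("matrix labels do not match")
    k = len(G.labels)
    out = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        e = E.values[i, j]
        if e <= 1.0:
            raise ValueError(
                f"Euclidean distance {e} <= 1 between {G.labels[i]} and {G.labels[j]}; "
                "log-normalization needs distances in units > 1 (use metres)"
            )
        g = max(G.values[i, j], clamp)
        out[i, j] = out[j, i] = math.log(g) / math.log(e)
    return PairwiseMatrix(G.labels, out, f"log_{G.name}_over_log_euclid")


# ---------------------------------------------------------------------------
# MLPE
# ---------------------------------------------------------------------------


@dataclass
class MLPEFit:
    """ML fit of the population-effects mixed model on pairwise data.

    y_ij = b0 + sum_k b_k x_k,ij + u_i + u_j + e_ij with iid population
    effects u ~ N(0, sigma_u^2) shared by every pair containing the
    population, fitted by full maximum likelihood (not REML) so that
    likelihoods are comparable across fixed-effect structures.
    """

    name: str
    predictors: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sigma2_u: float
    sigma2_e: float
    loglik: float
    k: int
    n: int
    dropped: list[str] = field(default_factory=list)


def _pair_design(labels: list[str]) -> np.ndarray:
    """Z matrix: pairs x populations incidence (1 if pop in pair)."""
    npop = len(labels)
    pairs = list(itertools.combinations(range(npop), 2))
    Z = np.zeros((len(pairs), npop))
    for r, (i, j) in enumerate(pairs):
        Z[r, i] = Z[r, j] = 1.0
    return Z


def mlpe_loglik(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray,
    beta: np.ndarray, sigma2_u: float, sigma2_e: float,
) -> float:
    """Exact multivariate-normal log-likelihood with cov = s2e I + s2u Z Z'."""
    n = len(y)
    V = sigma2_e * np.eye(n) + sigma2_u * (Z @ Z.T)
    resid = y - X @ beta
    sign, logdet = np.linalg.slogdet(V)
    return float(
        -0.5 * (n * math.log(2 * math.pi) + logdet + resid @ np.linalg.solve(V, resid))
    )


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors for the columns of X (no intercept)."""
    n, p = X.shape
    out = np.ones(p)
    if p < 2:
        return out
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
        out[j] = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
    return out


def mlpe_fit(
    y: PairwiseMatrix,
    X: list[PairwiseMatrix],
    name: str = "",
    log_predictors: bool = True,
    vif_threshold: float = 4.0,
) -> MLPEFit:
    """Fit the MLPE mixed model to a pairwise response.

    Predictors are log-transformed by default (distances must be positive;
    non-positive values are clamped to the F_ST floor). When two or more
    predictors are supplied, variables with VIF >= ``vif_threshold`` are
    dropped (highest first, recomputed after each drop). The variance ratio
    sigma_u^2 / sigma_e^2 is profiled out with generalized least squares and
    optimized in one dimension; 95% CIs are Wald intervals from the GLS
    covariance.
    """
    yv, xs = _aligned_lower(y, X)
    names = [x.name or f"x{i}" for i, x in enumerate(X)]
    if log_predictors:
        xs = np.log(np.maximum(xs, FST_FLOOR))
    dropped: list[str] = []
    while xs.shape[1] >= 2:
        v = _vif(xs)
        worst = int(np.argmax(v))
        if v[worst] < vif_threshold:
            break
        dropped.append(names.pop(worst))
        xs = np.delete(xs, worst, axis=1)
    if dropped:
        warnings.warn(f"dropped collinear predictors (VIF >= {vif_threshold}): {dropped}")
    Z = _pair_design(y.labels)
    n = len(yv)
    Xd = np.column_stack([np.ones(n), xs])
    ZZt = Z @ Z.T
    I = np.eye(n)

    def profile_nll(log_lam: float) -> tuple[float, np.ndarray, float, float]:
        lam = math.exp(log_lam)
        V0 = I + lam * ZZt
        V0_inv = np.linalg.inv(V0)
        XtVX = Xd.T @ V0_inv @ Xd
        beta = np.linalg.solve(XtVX, Xd.T @ V0_inv @ yv)
        resid = yv - Xd @ beta
        rss = float(resid @ V0_inv @ resid)
        s2e = rss / n  # ML estimate
        sign, logdet = np.linalg.slogdet(V0)
        nll = 0.5 * (n * math.log(2 * math.pi * s2e) + logdet + n)
        return nll, beta, s2e, lam

    # boundary (lambda -> 0, i.e. no population effect) vs interior optimum
    res = minimize_scalar(lambda t: profile_nll(t)[0], bounds=(-12.0, 12.0),
                          method="bounded", options={"xatol": 1e-10})
    cands = [profile_nll(res.x), profile_nll(-30.0)]
    nll, beta, s2e, lam = min(cands, key=lambda c: c[0])
    if lam < 1e-10:
        lam = 0.0
    s2u = lam * s2e
    V0_inv = np.linalg.inv(I + lam * ZZt)
    cov_beta = s2e * np.linalg.inv(Xd.T @ V0_inv @ Xd)
    se = np.sqrt(np.diag(cov_beta))
    z = norm.ppf(0.975)
    k = Xd.shape[1] + 2  # intercept + slopes + two variance components
    return MLPEFit(
        name=name,
        predictors=names,
        beta=beta,
        beta_se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        sigma2_u=s2u,
        sigma2_e=s2e,
        loglik=-nll,
        k=k,
        n=n,
        dropped=dropped,
    )


@dataclass
class ModelComparison:
    """AICc/BIC ranking of competing MLPE hypotheses."""

    names: list[str]
    aicc: np.ndarray
    bic: np.ndarray
    aicc_weight: np.ndarray
    bic_weight: np.ndarray
    rank: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "hypothesis": self.names,
                "AICc": self.aicc,
                "BIC": self.bic,
                "AICc_weight": self.aicc_weight,
                "BIC_weight": self.bic_weight,
                "rank": self.rank,
            }
        ).sort_values("rank")


def model_compare(fits: list[MLPEFit]) -> ModelComparison:
    """AICc = -2LL + 2k + 2k(k+1)/(n-k-1); BIC = -2LL + k ln n; Akaike weights."""
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError("fits are not on an identical response")
    n = ns.pop()
    aicc, bic = [], []
    for f in fits:
        if n <= f.k + 1:
            raise ValueError(f"AICc undefined for {f.name!r}: n={n} <= k+1={f.k + 1}")
        aicc.append(-2 * f.loglik + 2 * f.k + 2 * f.k * (f.k + 1) / (n - f.k - 1))
        bic.append(-2 * f.loglik + f.k * math.log(n))
    aicc = np.array(aicc)
    bic = np.array(bic)

    def weights(crit: np.ndarray) -> np.ndarray:
        d = crit - crit.min()
        w = np.exp(-d / 2)
        return w / w.sum()

    order = np.argsort(aicc, kind="stable")
    rank = np.empty(len(fits), dtype=int)
    rank[order] = np.arange(1, len(fits) + 1)
    return ModelComparison(
        [f.name for f in fits], aicc, bic, weights(aicc), weights(bic), rank
    )
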