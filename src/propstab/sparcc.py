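"""Compositional co-abundance networks: SparCC-style correlation inference
with permutation pseudo-P values and per-network edge thresholds.

Relative-abundance (compositional) data induce spurious negative
correlations; the basis-correlation approach estimates correlations of the
unobserved absolute abundances from pairwise log-ratio variances
T_ij = Var log(x_i/x_j) under a sparsity assumption.  Each inner iteration
resamples fractions from a Dirichlet posterior (counts + 1 pseudocount),
solves the linear system t_i = Σ_j T_ij ≈ (D−2)ω_i + Σ_k ω_k for the basis
variances ω, forms ρ_ij = (ω_i + ω_j − T_ij) / (2√(ω_i ω_j)), and
iteratively excludes the most strongly correlated pair (violating the
sparsity assumption) from the system; the reported ρ is the component-wise
median over iterations.

Edge calling combines two permutation-null devices computed from shuffled
abundance tables (each taxon's counts independently permuted across
samples, i.e. without replacement): a per-pair pseudo-P value and a
network-specific magnitude threshold taken as a high quantile of the
pooled null |ρ|, so thresholds represent equal levels of confidence across
networks with different abundance distributions.  Retained edges satisfy
both pseudo-P < cutoff and |ρ| ≥ threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import AbundanceTable

_V_MIN = 1e-4  # floor for basis variances, as in the reference workflow


@dataclass
class BasisEstimate:
    """SparCC basis-variance solution for one abundance table."""

    taxon_ids: list[str]
    variation: np.ndarray        #: median pairwise log-ratio variance matrix T
    basis_variance: np.ndarray   #: median basis variances ω
    correlation: np.ndarray      #: median basis correlation matrix ρ
    excluded_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


def _counts_matrix(table: AbundanceTable | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, AbundanceTable):
        return table.counts.astype(float), list(table.taxon_ids)
    arr = np.asarray(table, dtype=float)
    return arr, [f"t{i}" for i in range(arr.shape[0])]


def _dirichlet_fractions(rng: np.random.Generator, counts: np.ndarray) -> np.ndarray:
    """Posterior fractions per sample: Dirichlet(counts + 1), columns sum to 1."""
    g = rng.standard_gamma(counts + 1.0)
    return g / g.sum(axis=0, keepdims=True)


def _variation_matrix(fracs: np.ndarray) -> np.ndarray:
    """T_ij = Var over samples of log(x_i / x_j), via the log covariance."""
    L = np.log(fracs)
    C = np.cov(L)
    v = np.diag(C)
    T = v[:, None] + v[None, :] - 2.0 * C
    np.fill_diagonal(T, 0.0)
    return T


def _basis_iteration(
    T: np.ndarray, n_exclusion_rounds: int, exclusion_threshold: float
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Solve for basis variances with iterative strong-pair exclusion."""
    D = T.shape[0]
    M = np.ones((D, D)) + (D - 2) * np.eye(D)
    T_work = T.copy()
    excluded: list[tuple[int, int]] = []
    excl_count = np.zeros(D, dtype=int)

    def solve() -> tuple[np.ndarray, np.ndarray]:
        t = T_work.sum(axis=1)
        try:
            omega = np.linalg.solve(M, t)
        except np.linalg.LinAlgError:
            omega = np.linalg.lstsq(M, t, rcond=None)[0]
        omega = np.where(omega <= 0, _V_MIN, omega)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - T) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return omega, rho

    omega, rho = solve()
    for _ in range(n_exclusion_rounds):
        mag = np.abs(rho)
        np.fill_diagonal(mag, 0.0)
        for i, j in excluded:
            mag[i, j] = mag[j, i] = 0.0
        # a taxon in too many excluded pairs would make the system singular
        saturated = excl_count >= D - 3
        mag[saturated, :] = 0.0
        mag[:, saturated] = 0.0
        i, j = np.unravel_index(int(np.argmax(mag)), mag.shape)
        if mag[i, j] <= exclusion_threshold:
            break
        excluded.append((int(i), int(j)))
        excl_count[i] += 1
        excl_count[j] += 1
        M[i, j] -= 1
        M[j, i] -= 1
        M[i, i] -= 1
        M[j, j] -= 1
        T_work[i, j] = T_work[j, i] = 0.0
        omega, rho = solve()
    return omega, rho, excluded


def sparcc_correlations(
    table: AbundanceTable | np.ndarray,
    n_inner_iterations: int = 20,
    n_exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> BasisEstimate:
    """Infer basis correlations for a taxa × samples count table.

    Requires at least 4 taxa (the sparsity linear system is
    underdetermined below that).  Deterministic given *seed*.
    """
    counts, taxon_ids = _counts_matrix(table)
    D = counts.shape[0]
    if D < 4:
        raise ValueError(f"sparcc requires >= 4 taxa, got {D}")
    rng = np.random.default_rng(seed)
    rhos, omegas, Ts = [], [], []
    excluded_union: set[tuple[int, int]] = set()
    for _ in range(n_inner_iterations):
        fracs = _dirichlet_fractions(rng, counts)
        T = _variation_matrix(fracs)
        omega, rho, excl = _basis_iteration(
            T, n_exclusion_rounds, exclusion_threshold
        )
        rhos.append(rho)
        omegas.append(omega)
        Ts.append(T)
        excluded_union.update(excl)
    return BasisEstimate(
        taxon_ids=taxon_ids,
        variation=np.median(Ts, axis=0),
        basis_variance=np.median(omegas, axis=0),
        correlation=np.median(rhos, axis=0),
        excluded_pairs=sorted(excluded_union),
    )


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """SparCC correlations from shuffled tables: per-pair null distributions
    (``rhos``: n_tables × D × D) and the pooled off-diagonal values."""

    rhos: np.ndarray
    n_tables: int

    @property
    def pooled(self) -> np.ndarray:
        D = self.rhos.shape[1]
        iu = np.triu_indices(D, k=1)
        return self.rhos[:, iu[0], iu[1]].ravel()


def shuffle_table(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each taxon's counts across samples
    (without replacement: every row keeps its count multiset)."""
    out = np.empty_like(counts)
    n = counts.shape[1]
    for i in range(counts.shape[0]):
        out[i] = counts[i, rng.permutation(n)]
    return out


def shuffle_null(
    table: AbundanceTable | np.ndarray,
    n_tables: int,
    seed: int = 0,
    n_inner_iterations: int = 5,
    n_exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
) -> NullEnsemble:
    """Null correlation ensemble from independently shuffled tables.

    Each of ``n_tables`` null tables permutes every taxon's counts across
    samples independently, then runs the same SparCC inference (with a
    reduced inner-iteration count by default, since the null is an
    ensemble).  Deterministic given *seed*.
    """
    if n_tables < 1:
        raise ValueError("n_tables must be >= 1")
    counts, _ = _counts_matrix(table)
    rng = np.random.default_rng(seed)
    rhos = np.empty((n_tables, counts.shape[0], counts.shape[0]))
    for k in range(n_tables):
        shuffled = shuffle_table(counts, rng)
        est = sparcc_correlations(
            shuffled.astype(np.int64),
            n_inner_iterations=n_inner_iterations,
            n_exclusion_rounds=n_exclusion_rounds,
            exclusion_threshold=exclusion_threshold,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        rhos[k] = est.correlation
    return NullEnsemble(rhos=rhos, n_tables=n_tables)


def edge_threshold(null_pool: np.ndarray, confidence: float = 0.99) -> float:
    """Magnitude threshold: the ``confidence`` quantile of pooled |null ρ|."""
    null_pool = np.asarray(null_pool, dtype=float)
    if null_pool.size == 0:
        raise ValueError("null pool is empty")
    return float(np.quantile(np.abs(null_pool), confidence))


def pseudo_p_values(
    rho_obs: np.ndarray,
    null: NullEnsemble | np.ndarray,
    two_sided: bool = True,
) -> np.ndarray:
    """Per-pair pseudo-P, (1 + #{|ρ_null| ≥ |ρ_obs|}) / (1 + n_tables).

    One-sided mode counts null values at least as extreme in the sign of
    the observed correlation.
    """
    null_rhos = null.rhos if isinstance(null, NullEnsemble) else np.asarray(null)
    n = null_rhos.shape[0]
    if two_sided:
        exceed = (np.abs(null_rhos) >= np.abs(rho_obs)[None, :, :]).sum(axis=0)
    else:
        pos = (null_rhos >= rho_obs[None, :, :]).sum(axis=0)
        neg = (null_rhos <= rho_obs[None, :, :]).sum(axis=0)
        exceed = np.where(rho_obs >= 0, pos, neg)
    p = (1.0 + exceed) / (1.0 + n)
    np.fill_diagonal(p, 1.0)
    return p


# ---------------------------------------------------------------------------
# Network construction and metrics
# ---------------------------------------------------------------------------

@dataclass
class CoabundanceNetwork:
    """Taxa nodes with signed, thresholded co-abundance edges."""

    node_ids: list[str]
    edges: pd.DataFrame  #: columns taxon_a, taxon_b, rho, pseudo_p, sign
    threshold_meta: dict

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for _, e in self.edges.iterrows():
            g.add_edge(e["taxon_a"], e["taxon_b"], rho=float(e["rho"]),
                       pseudo_p=float(e["pseudo_p"]), sign=e["sign"])
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(
    estimate: BasisEstimate,
    pseudo_p: np.ndarray,
    threshold: float,
    p_cutoff: float = 0.01,
    threshold_meta: dict | None = None,
) -> CoabundanceNetwork:
    """Retain edges with pseudo-P < ``p_cutoff`` and |ρ| ≥ ``threshold``.

    Edge sign follows ρ (positive/negative co-abundance).
    """
    D = estimate.n_taxa
    rows = []
    for i in range(D):
        for j in range(i + 1, D):
            rho = estimate.correlation[i, j]
            p = pseudo_p[i, j]
            if np.isnan(rho):
                continue
            if p < p_cutoff and abs(rho) >= threshold:
                rows.append({
                    "taxon_a": estimate.taxon_ids[i],
                    "taxon_b": estimate.taxon_ids[j],
                    "rho": float(rho),
                    "pseudo_p": float(p),
                    "sign": "positive" if rho >= 0 else "negative",
                })
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho",
                                        "pseudo_p", "sign"])
    meta = {"p_cutoff": p_cutoff, "magnitude_threshold": float(threshold)}
    if threshold_meta:
        meta.update(threshold_meta)
    return CoabundanceNetwork(list(estimate.taxon_ids), edges, meta)


def degree_distribution(net: CoabundanceNetwork) -> pd.Series:
    """Histogram of per-node edge counts, zero-degree nodes included."""
    g = net.to_graph()
    degrees = pd.Series(dict(g.degree()), dtype=int)
    return degrees.value_counts().sort_index()


def connected_components(net: CoabundanceNetwork) -> tuple[int, list[int]]:
    """Component count and sizes (descending) over the undirected edge set."""
    comps = sorted((len(c) for c in nx.connected_components(net.to_graph())),
                   reverse=True)
    return len(comps), comps


def network_summary(net: CoabundanceNetwork) -> dict:
    """Structure metrics: edges, mean degree, fragmentation."""
    g = net.to_graph()
    n = g.number_of_nodes()
    n_comp, sizes = connected_components(net)
    return {
        "n_nodes": n,
        "n_edges": g.number_of_edges(),
        "mean_degree": (2.0 * g.number_of_edges() / n) if n else 0.0,
        "n_components": n_comp,
        "largest_component_fraction": (sizes[0] / n) if sizes else 0.0,
    }


def infer_network(
    table: AbundanceTable,
    n_boot: int = 1000,
    n_shuffled_tables: int | None = None,
    confidence: float = 0.99,
    p_cutoff: float = 0.01,
    n_inner_iterations: int = 20,
    null_inner_iterations: int = 5,
    seed: int = 0,
    two_sided: bool = True,
) -> tuple[CoabundanceNetwork, BasisEstimate]:
    """End-to-end inference: SparCC, shuffled-table nulls, edge calling.

    ``n_boot`` shuffled tables feed the per-pair pseudo-P values; the
    pooled null from the same ensemble (or a separate one of
    ``n_shuffled_tables``) sets this network's magnitude threshold at the
    ``confidence`` quantile of |null ρ|.
    """
    est = sparcc_correlations(
        table, n_inner_iterations=n_inner_iterations, seed=seed
    )
    null = shuffle_null(
        table, n_tables=n_boot, seed=seed + 1,
        n_inner_iterations=null_inner_iterations,
    )
    if n_shuffled_tables is not None and n_shuffled_tables != n_boot:
        pool_null = shuffle_null(
            table, n_tables=n_shuffled_tables, seed=seed + 2,
            n_inner_iterations=null_inner_iterations,
        )
    else:
        pool_null = null
    thr = edge_threshold(pool_null.pooled, confidence)
    pp = pseudo_p_values(est.correlation, null, two_sided=two_sided)
    meta = {
        "n_bootstraps": n_boot,
        "n_shuffled_tables": pool_null.n_tables,
        "confidence": confidence,
        "seed": seed,
    }
    net = build_network(est, pp, thr, p_cutoff=p_cutoff, threshold_meta=meta)
    return net, est


def write_edge_list(net: CoabundanceNetwork, path: str | Path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def write_graphml(net: CoabundanceNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_graph(), str(path))
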