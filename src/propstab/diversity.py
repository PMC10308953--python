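"""Community-structure statistics: alpha diversity, Bray–Curtis,
beta-dispersion, and permutational MANOVA.

Alpha diversity uses observed richness, Shannon entropy (natural log), and
Pielou's evenness.  Beta diversity is Bray–Curtis dissimilarity on
(rarefied) counts.  Beta-dispersion embeds the dissimilarity matrix by
principal coordinates, keeping negative-eigenvalue axes as imaginary
coordinates, and measures each sample's distance to its group centroid —
the standard multivariate dispersion construction for non-Euclidean
dissimilarities.  PERMANOVA partitions the Gower-centered inner-product
matrix by sequential (order-of-entry) sums of squares over one or more
crossed factors, with free permutation of sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .tables import AbundanceTable

__all__ = [
    "richness", "shannon", "pielou_evenness", "alpha_diversity_table",
    "bray_curtis_matrix", "beta_dispersion", "permanova", "PermanovaResult",
    "DistanceMatrix",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def richness(counts: np.ndarray) -> int:
    """Number of taxa with count > 0."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return int((counts > 0).sum())


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = −Σ p_i ln p_i over positive fractions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("shannon requires at least one positive count")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou_evenness(counts: np.ndarray) -> float:
    """Evenness H / ln(richness); defined as 1 for single-taxon samples."""
    s = richness(counts)
    if s == 0:
        raise ValueError("evenness requires at least one positive count")
    if s == 1:
        return 1.0
    return shannon(counts) / np.log(s)


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Richness, Shannon and evenness per sample."""
    rows = {}
    for j, s in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows[s] = {
            "richness": richness(col),
            "shannon": shannon(col),
            "evenness": pielou_evenness(col),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Bray–Curtis
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities d(u,v) = Σ|u−v| / Σ(u+v)."""
    sums = table.sample_sums()
    if (sums == 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Beta-dispersion
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = −½ J (d∘d) J."""
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary axes."""
    G = _gower_center(d)
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def beta_dispersion(dist: DistanceMatrix, groups: dict[str, str]) -> pd.Series:
    """Distance of each sample to its group centroid in PCoA space.

    Negative-eigenvalue (imaginary) axes contribute negatively:
    z = sqrt(max(d_real² − d_imag², 0)), matching the standard correction
    for non-Euclidean dissimilarities.
    """
    ids = list(dist.ids)
    labels = np.array([groups[s] for s in ids])
    for g in np.unique(labels):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    real, imag = _pcoa_coords(dist.data)
    out = np.empty(len(ids))
    for g in np.unique(labels):
        m = labels == g
        cr = real[m].mean(axis=0)
        ci = imag[m].mean(axis=0) if imag.size else np.zeros(0)
        d2r = ((real[m] - cr) ** 2).sum(axis=1)
        d2i = ((imag[m] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        out[m] = np.sqrt(np.clip(d2r - d2i, 0.0, None))
    return pd.Series(out, index=ids, name="dispersion")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential-SS decomposition of a distance matrix.

    ``table`` has one row per model term plus ``Residual`` and ``Total``,
    with columns df, SS, R2, F, p; permutation p-values carry the +1
    correction in numerator and denominator.
    """

    table: pd.DataFrame
    n_permutations: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n_permutations={self.n_permutations})\n{self.table}"


def _projector(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank, via SVD."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * max(X.shape) * np.finfo(float).eps).sum()) if s.size else 0
    u = u[:, :rank]
    return u @ u.T, rank


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def permanova(
    dist: DistanceMatrix,
    factors: pd.DataFrame | dict[str, dict[str, str]],
    include_interaction: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    ``factors`` maps each sample id to a label per factor; columns enter
    the model in the given order, optionally followed by the full
    interaction of all listed factors.  Pseudo-F for each term uses the
    residual mean square of the full model; p-values come from freely
    permuting sample labels, p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm).
    """
    ids = list(dist.ids)
    n = len(ids)
    if isinstance(factors, dict):
        factors = pd.DataFrame(factors)
    factors = factors.loc[ids]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for c in factors.columns:
        if factors[c].nunique() < 2:
            raise ValueError(f"factor {c!r} is constant")

    label_arrays = {c: factors[c].to_numpy() for c in factors.columns}
    terms = list(factors.columns)
    blocks = [_dummies(label_arrays[c]) for c in terms]
    if include_interaction:
        combo = factors[terms[0]].astype(str)
        for c in terms[1:]:
            combo = combo + ":" + factors[c].astype(str)
        terms.append(":".join(factors.columns))
        blocks.append(_dummies(combo.to_numpy()))

    # cumulative projectors: intercept, then each term in order
    ones = np.ones((n, 1))
    projectors, ranks = [], []
    X = ones
    P_prev, r_prev = _projector(X)
    for B in blocks:
        X = np.hstack([X, B])
        P, r = _projector(X)
        projectors.append((P - P_prev, r - r_prev))
        P_prev, r_prev = P, r
    resid_proj = np.eye(n) - P_prev
    df_resid = n - r_prev
    if df_resid <= 0:
        raise ValueError("model is saturated; no residual degrees of freedom")

    G = _gower_center(dist.data)
    ss_total = float(np.trace(G))

    def decompose(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(P * Gm)) for P, _ in projectors])
        ss_res = float(np.sum(resid_proj * Gm))
        return ss, ss_res

    ss_obs, ss_res_obs = decompose(G)
    dfs = np.array([df for _, df in projectors], dtype=float)
    f_obs = (ss_obs / dfs) / (ss_res_obs / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = decompose(Gp)
        f_p = (ss_p / dfs) / (ss_res_p / df_resid)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, t in enumerate(terms):
        rows.append({
            "term": t, "df": int(dfs[i]), "SS": ss_obs[i],
            "R2": ss_obs[i] / ss_total, "F": f_obs[i], "p": pvals[i],
        })
    rows.append({"term": "Residual", "df": df_resid, "SS": ss_res_obs,
                 "R2": ss_res_obs / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm)
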