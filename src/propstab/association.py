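"""Stability-stratified correlation analyses and Mantel tests.

Links community traits, taxa abundances and ecosystem-function readouts
within stability groups: all-pairs Pearson correlations with
Benjamini–Hochberg FDR control, taxa~function correlation screens behind a
prevalence filter, function dissimilarity matrices (single-variable and
combined DOC/CO₂), and Mantel tests between composition and function
dissimilarities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, MetadataTable, prevalence_filter

__all__ = [
    "pearson_bh_matrix", "taxa_function_correlations",
    "function_dissimilarity", "mantel_test", "MantelResult",
    "trait_correlation_network",
]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def pearson_bh_matrix(features: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """All-pairs Pearson correlations with BH-adjusted p-values.

    ``features`` is samples × features; rows with a missing value in
    either member of a pair are dropped pairwise.  Zero-variance features
    yield NA rows that are excluded from the BH family.  Returns a tidy
    frame with columns feature_a, feature_b, r, n, p, p_adj, significant
    (``p_adj < 0.05``, the display threshold) and reject_fdr
    (BH rejection at level ``fdr``).
    """
    cols = list(features.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        sub = features[[a, b]].dropna()
        n = len(sub)
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append({"feature_a": a, "feature_b": b, "r": np.nan,
                         "n": n, "p": np.nan})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"feature_a": a, "feature_b": b, "r": float(r),
                     "n": n, "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    df["reject_fdr"] = False
    ok = df["p"].notna()
    if ok.any():
        adj = _bh_adjust(df.loc[ok, "p"].to_numpy())
        df.loc[ok, "p_adj"] = adj
        rej = multipletests(df.loc[ok, "p"].to_numpy(), alpha=fdr,
                            method="fdr_bh")[0]
        df.loc[ok, "reject_fdr"] = rej
    df["significant"] = df["p_adj"] < 0.05
    return df


def taxa_function_correlations(
    table: AbundanceTable,
    metadata: MetadataTable,
    variables: Sequence[str],
    group_assignments: Mapping[str, str],
    extra_features: pd.DataFrame | None = None,
    min_prevalence: float = 0.8,
    strict: bool = True,
) -> dict[str, pd.DataFrame]:
    """Taxon~variable Pearson screens within each stability group.

    Within each group separately: restrict the table to the group's
    samples, prevalence-filter taxa (present in > ``min_prevalence`` of the
    group's samples when ``strict``), correlate each retained taxon's
    abundance with each variable, and BH-adjust within the group's full
    family of tests.  ``variables`` name metadata fields (DOC, CO2, TN);
    ``extra_features`` may add per-sample columns (e.g. ΔDOC).
    """
    meta_df = metadata.to_dataframe()
    groups: dict[str, list[str]] = {}
    for s, g in group_assignments.items():
        groups.setdefault(g, []).append(s)
    results = {}
    for g, samples in groups.items():
        samples = [s for s in samples if s in table.sample_ids]
        if not samples:
            raise ValueError(f"stability group {g!r} has no samples in the table")
        sub = prevalence_filter(
            table.subset_samples(samples), min_prevalence, strict=strict
        )
        rows = []
        for i, taxon in enumerate(sub.taxon_ids):
            abund = sub.counts[i].astype(float)
            for var in variables:
                if extra_features is not None and var in extra_features.columns:
                    vals = extra_features[var].reindex(samples).to_numpy(float)
                else:
                    vals = meta_df.loc[samples, var].to_numpy(float)
                mask = ~np.isnan(vals)
                x, y = abund[mask], vals[mask]
                if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                    continue
                r, p = stats.pearsonr(x, y)
                rows.append({"taxon": taxon, "variable": var, "r": float(r),
                             "n": int(len(x)), "p": float(p)})
        df = pd.DataFrame(rows)
        if len(df):
            df["p_adj"] = _bh_adjust(df["p"].to_numpy())
            df["significant"] = df["p_adj"] < 0.05
        results[g] = df
    return results


def function_dissimilarity(
    metadata: MetadataTable | pd.DataFrame,
    variables: Sequence[str] = ("DOC",),
    sample_ids: Sequence[str] | None = None,
    combined_mode: str = "euclidean",
) -> DistanceMatrix:
    """Pairwise dissimilarity of functional readouts.

    A single variable gives |x_i − x_j|.  ``variables=("DOC", "CO2")``
    gives the combined dissimilarity: by default the Euclidean distance
    over z-scored (DOC, CO₂) pairs; ``combined_mode="product"`` instead
    uses |DOC_i·CO2_i − DOC_j·CO2_j|.  Constant variables z-score to zero
    and so contribute nothing to the combined distance.
    """
    df = metadata.to_dataframe() if isinstance(metadata, MetadataTable) else metadata
    if sample_ids is not None:
        df = df.loc[list(sample_ids)]
    ids = list(df.index)
    X = df[list(variables)].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("missing functional values")
    if len(variables) == 1:
        v = X[:, 0]
        d = np.abs(v[:, None] - v[None, :])
    elif combined_mode == "euclidean":
        sd = X.std(axis=0, ddof=1)
        Z = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
        diff = Z[:, None, :] - Z[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1))
    elif combined_mode == "product":
        v = X.prod(axis=1)
        d = np.abs(v[:, None] - v[None, :])
    else:
        raise ValueError(f"unknown combined_mode {combined_mode!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, ids=ids)


@dataclass
class MantelResult:
    """Matrix correlation r with its permutation p-value."""

    r: float
    p: float
    n_perm: int
    n_samples: int


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test between two distance matrices over matched samples.

    r is the Pearson correlation of the lower triangles; significance
    comes from jointly permuting rows and columns of ``d2``,
    p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm) for the default one-sided
    positive alternative (``alternative="two-sided"`` uses |r|).  With
    ``exact=True`` all n! relabelings are enumerated (n ≤ 8) and
    p is the exact fraction of relabelings at least as extreme, identity
    included.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different sample sets")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("mantel test requires at least 4 samples")
    ids = list(d1.ids)
    m1 = d1.data
    m2 = d2.filter(ids).data
    il = np.tril_indices(n, k=-1)
    x = m1[il]

    def corr(mat: np.ndarray) -> float:
        y = mat[il]
        xs, ys = x - x.mean(), y - y.mean()
        denom = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
        if denom == 0:
            raise ValueError("zero-variance distance matrix")
        return float((xs * ys).sum() / denom)

    def stat(r: float) -> float:
        return abs(r) if alternative == "two-sided" else r

    r_obs = corr(m2)
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            total += 1
            if stat(corr(m2[np.ix_(p, p)])) >= stat(r_obs) - 1e-12:
                count += 1
        return MantelResult(r_obs, count / total, total, n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if stat(corr(m2[np.ix_(p, p)])) >= stat(r_obs):
            exceed += 1
    return MantelResult(r_obs, (1 + exceed) / (1 + n_perm), n_perm, n)


def trait_correlation_network(
    results: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Edge list of significant trait pairs from a correlation table.

    Keeps rows of a :func:`pearson_bh_matrix` result with
    ``p_adj < alpha``; edges carry r and its sign.
    """
    if "p_adj" not in results.columns:
        raise ValueError("results must carry a p_adj column")
    edges = results[results["p_adj"] < alpha].copy()
    edges["sign"] = np.where(edges["r"] >= 0, "positive", "negative")
    cols = [c for c in ("feature_a", "feature_b", "r", "p", "p_adj", "sign")
            if c in edges.columns]
    return edges[cols].reset_index(drop=True)
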