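"""Simulation experiments that validate calibration and parameter recovery.

Each function runs a self-contained Monte-Carlo experiment against known
ground truth: type-I error calibration for the permutation tests, false
edge control for the co-abundance networks, and recovery of planted
generator parameters (drift regime, basis correlations, DOC-effect taxa,
composition→function coupling).  They are used by the test suite and by
the reproduction script; all are deterministic given their seed.

Experiment designs follow standard parameter-recovery practice: the
quantity being recovered is varied while nuisance noise sources (assay
noise, transfer bottlenecks, interaction terms) are held low or off, and
paired cohorts share a seed so they differ only in the manipulated
parameter.  Problem sizes are chosen so every experiment runs in seconds
to minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .association import function_dissimilarity, mantel_test, taxa_function_correlations
from .diversity import bray_curtis_matrix, permanova
from .sparcc import infer_network, shuffle_table, sparcc_correlations
from .stability import delta_function, pair_lineages, stratify_stability, MOST_STABLE
from .synth import SyntheticConfig, generate_experiment
from .tables import AbundanceTable


# ---------------------------------------------------------------------------
# Calibration (type-I error under the null)
# ---------------------------------------------------------------------------

def mantel_type1_error(
    n_sims: int = 200, n_samples: int = 15, n_perm: int = 199,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of the Mantel test on independent distance matrices."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n_samples)]
    rejections = 0
    for k in range(n_sims):
        X = rng.normal(size=(n_samples, 3))
        Y = rng.normal(size=(n_samples, 3))
        d1 = DistanceMatrix(squareform(pdist(X)), ids=ids)
        d2 = DistanceMatrix(squareform(pdist(Y)), ids=ids)
        m = mantel_test(d1, d2, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rejections += m.p <= alpha
    return rejections / n_sims


def permanova_type1_error(
    n_sims: int = 200, n_samples: int = 20, n_perm: int = 99,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of PERMANOVA with random labels on random data."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n_samples)]
    half = n_samples // 2
    factors = pd.DataFrame({"g": ["A"] * half + ["B"] * (n_samples - half)},
                           index=ids)
    rejections = 0
    for k in range(n_sims):
        X = rng.normal(size=(n_samples, 3))
        dm = DistanceMatrix(squareform(pdist(X)), ids=ids)
        res = permanova(dm, factors, n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31))).table
        rejections += res.loc["g", "p"] <= alpha
    return rejections / n_sims


def _lognormal_counts(rng: np.random.Generator, n_taxa: int, n_samples: int,
                      rho: float = 0.0, pair: tuple[int, int] = (0, 1),
                      depth: int = 5000) -> np.ndarray:
    """Compositional counts from a log-normal basis, optionally with one
    correlated taxon pair."""
    mu = rng.normal(0, 1, n_taxa)
    Z = rng.normal(size=(n_samples, n_taxa))
    i, j = pair
    Z[:, j] = rho * Z[:, i] + np.sqrt(1 - rho ** 2) * Z[:, j]
    ab = np.exp(mu + Z)
    frac = ab / ab.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, f) for f in frac]).T


def network_false_edge_rate(
    n_runs: int = 5, n_taxa: int = 20, n_samples: int = 50,
    n_boot: int = 199, p_cutoff: float = 0.01, seed: int = 0,
) -> float:
    """Mean edge fraction called on fully shuffled (null) tables."""
    rng = np.random.default_rng(seed)
    possible = n_taxa * (n_taxa - 1) // 2
    rates = []
    for k in range(n_runs):
        counts = _lognormal_counts(rng, n_taxa, n_samples)
        shuffled = shuffle_table(counts, rng)
        tab = AbundanceTable([f"t{i}" for i in range(n_taxa)],
                             [f"s{j}" for j in range(n_samples)], shuffled)
        net, _ = infer_network(tab, n_boot=n_boot, p_cutoff=p_cutoff,
                               seed=int(rng.integers(2 ** 31)))
        rates.append(net.n_edges / possible)
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def _recovery_config(drift_sd: float, seed: int) -> SyntheticConfig:
    """Paired-cohort config for the drift-recovery experiment: 25 origins ×
    4 lineages (100 lineages), three generations, exhaustive transfer, no
    interactions, dense positive-baseline DOC mapping, low assay noise —
    the cohorts differ only in drift_sd."""
    return SyntheticConfig(
        n_origins=25, n_generations=3, n_taxa_bacteria=60, n_taxa_fungi=20,
        seq_depth_bacteria=1000, seq_depth_fungi=1000,
        transfer_depth=None, interaction_connectance=0.0,
        legacy_sd=0.3, doc_effect_fraction=1.0, doc_baseline=10.0,
        doc_noise_sd=0.05, drift_sd=drift_sd, seed=seed,
    )


def drift_stratification_recovery(
    seed: int = 0, drift_low: float = 0.05, drift_high: float = 0.5,
) -> float:
    """Fraction of most-stable labels falling on the low-drift cohort.

    Two cohorts of 100 lineages sharing one seed (identical communities
    and DOC mapping) are propagated under low vs high drift; ΔDOC values
    are pooled and stratified.  With ΔDOC tracking compositional drift,
    the most-stable quartile should come almost entirely from the
    low-drift cohort.
    """
    deltas = {}
    for tag, drift in (("low", drift_low), ("high", drift_high)):
        _, _, meta, _ = generate_experiment(_recovery_config(drift, seed))
        dd = delta_function(pair_lineages(meta), meta, "DOC")
        dd.index = [f"{tag}:{s}" for s in dd.index]
        deltas[tag] = dd
    pooled = pd.concat(deltas.values())
    labels, _ = stratify_stability(pooled)
    most = labels[labels == MOST_STABLE]
    if len(most) == 0:
        return 0.0
    return float(most.index.str.startswith("low:").mean())


def sparcc_planted_recovery(
    n_runs: int = 20, rho: float = 0.8, n_taxa: int = 30,
    n_samples: int = 100, n_boot: int = 199, seed: int = 0,
) -> tuple[float, float]:
    """(median estimated ρ for a planted pair, fraction of runs detecting
    the edge) across seeded simulations."""
    rng = np.random.default_rng(seed)
    estimates = []
    detected = 0
    for k in range(n_runs):
        counts = _lognormal_counts(rng, n_taxa, n_samples, rho=rho)
        tab = AbundanceTable([f"t{i:03d}" for i in range(n_taxa)],
                             [f"s{j}" for j in range(n_samples)], counts)
        run_seed = int(rng.integers(2 ** 31))
        est = sparcc_correlations(tab, seed=run_seed)
        estimates.append(est.correlation[0, 1])
        net, _ = infer_network(tab, n_boot=n_boot, seed=run_seed)
        pairs = {frozenset(e) for e in
                 net.edges[["taxon_a", "taxon_b"]].to_numpy()}
        detected += frozenset(("t000", "t001")) in pairs
    return float(np.median(estimates)), detected / n_runs


def doc_taxon_recovery(n_sims: int = 50, seed: int = 0) -> float:
    """Fraction of simulations where a single planted abundant positive
    DOC-effect taxon is significantly positively correlated with DOC."""
    hits = 0
    for k in range(n_sims):
        cfg = SyntheticConfig(
            n_origins=5, n_generations=3, n_taxa_bacteria=60, n_taxa_fungi=20,
            seq_depth_bacteria=2000, seq_depth_fungi=500, transfer_depth=2000,
            doc_effect_fraction=1 / 60, doc_effect_positive=True,
            doc_effect_abundant=True, doc_baseline=10.0, doc_noise_sd=0.1,
            seed=seed * 1000 + k,
        )
        bact, _, meta, truth = generate_experiment(cfg)
        taxon = max(truth.doc_effect_taxa, key=truth.doc_effect_taxa.get)
        res = taxa_function_correlations(
            bact, meta, ("DOC",), {s: "all" for s in bact.sample_ids},
            min_prevalence=0.8,
        )["all"]
        row = res[(res["taxon"] == taxon) & (res["variable"] == "DOC")]
        if len(row) == 1 and row["r"].iloc[0] > 0 and row["p_adj"].iloc[0] < 0.05:
            hits += 1
    return hits / n_sims


def mantel_mechanism_rates(
    n_sims: int = 50, n_perm: int = 999, alpha: float = 0.05, seed: int = 0,
) -> tuple[float, float]:
    """Significance rates of the composition~DOC Mantel test when DOC is a
    near-noiseless function of composition vs when noise dominates.

    Each simulation takes the 20 first-generation microcosms of a
    five-origin experiment; the low-noise condition maps DOC densely from
    composition with zero assay noise, the noise-dominated condition
    shrinks the mapping to a small fraction of the noise SD.  Returns the
    (low-noise, noise-dominated) rates of p ≤ alpha.
    """
    rates = []
    for noise_sd, scale in ((0.0, 20.0), (4.0, 1.0)):
        sig = 0
        for k in range(n_sims):
            cfg = SyntheticConfig(
                n_origins=5, n_generations=2, n_taxa_bacteria=60,
                n_taxa_fungi=20, seq_depth_bacteria=5457, seq_depth_fungi=500,
                transfer_depth=2000, doc_baseline=10.0,
                doc_effect_fraction=1.0, doc_effect_scale=scale,
                doc_noise_sd=noise_sd, seed=seed * 1000 + k,
            )
            bact, _, meta, _ = generate_experiment(cfg)
            g1 = [r.sample_id for r in meta.records if r.generation == 1]
            dm = bray_curtis_matrix(bact.subset_samples(g1))
            fd = function_dissimilarity(meta, ("DOC",), sample_ids=g1)
            m = mantel_test(dm, fd, n_perm=n_perm, seed=seed * 1000 + k)
            sig += m.p <= alpha
        rates.append(sig / n_sims)
    return rates[0], rates[1]


# ---------------------------------------------------------------------------
# Descriptive summary of a default-design cohort
# ---------------------------------------------------------------------------

def default_cohort_summary(seed: int = 0) -> dict[str, float]:
    """Headline statistics of one default-design synthetic experiment:
    pooled ΔDOC median and quartile cutoffs, per-generation DOC CV, and
    the origin/generation PERMANOVA decomposition of bacterial
    composition."""
    from .stability import generation_cv

    cfg = SyntheticConfig(seed=seed)
    bact, fungi, meta, _ = generate_experiment(cfg)
    dd = delta_function(pair_lineages(meta), meta, "DOC")
    _, cutoffs = stratify_stability(dd)
    cv = generation_cv(meta, "DOC")
    dm = bray_curtis_matrix(bact)
    meta_df = meta.to_dataframe()
    factors = meta_df.loc[list(dm.ids), ["origin_id", "generation"]].astype(str)
    res = permanova(dm, factors, include_interaction=True, n_perm=199,
                    seed=seed).table
    return {
        "n_samples": float(len(meta)),
        "delta_doc_median": cutoffs.median,
        "delta_doc_q25": cutoffs.q25,
        "delta_doc_q75": cutoffs.q75,
        "doc_cv_g0": float(cv[0]),
        "doc_cv_g4": float(cv[4]),
        "permanova_r2_origin": float(res.loc["origin_id", "R2"]),
        "permanova_r2_generation": float(res.loc["generation", "R2"]),
        "permanova_r2_interaction": float(
            res.loc["origin_id:generation", "R2"]),
    }
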