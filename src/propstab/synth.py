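"""Synthetic serial-propagation experiments with known ground truth.

Emulates a community "evolution" experiment: soil-derived communities from
several origins are inoculated into sterile litter microcosms (generation
G0, two replicate microcosms per origin), then serially propagated — each
G0 replicate inoculates two G1 microcosms, after which propagation is 1:1 —
for a configurable number of 28-day generations.  Composition evolves by
origin legacy effects, per-generation log-abundance drift, a sparse
pairwise interaction term, and a multinomial transfer bottleneck; samples
are then "sequenced" by multinomial draws at a fixed read depth.  Each
microcosm also carries a composition-dependent functional readout:
dissolved organic carbon (DOC), with CO₂ negatively coupled to DOC and
total nitrogen (TN) drawn independently.

Because composition, interactions and the composition→DOC mapping are all
known, every downstream statistic (stability stratification, Mantel
coupling, co-abundance networks) can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .tables import RANKS, AbundanceTable, MetadataTable, SampleRecord


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic serial-propagation experiment.

    Defaults mirror the emulated study design: 10 origins × 2 G0
    replicates, each G0 replicate inoculating two G1 microcosms (four
    lineages per origin), five generations G0–G4, and sequencing depths
    equal to the study's per-domain rarefaction depths.
    """

    n_origins: int = 10
    n_g0_replicates: int = 2
    n_lineages_per_origin: int = 4
    n_generations: int = 5
    n_taxa_bacteria: int = 150
    n_taxa_fungi: int = 50
    #: SD of origin-level log-abundance offsets (legacy effect size).
    legacy_sd: float = 1.0
    #: SD of per-generation multiplicative log-abundance drift.
    drift_sd: float = 0.3
    #: Fraction of ordered taxon pairs with a nonzero interaction.
    interaction_connectance: float = 0.05
    #: SD of nonzero interaction coefficients.
    interaction_strength_sd: float = 0.5
    #: Cells transferred at inoculation; ``None`` = exhaustive transfer.
    transfer_depth: Optional[int] = 1000
    seq_depth_bacteria: int = 5457
    seq_depth_fungi: int = 6670
    #: DOC mapping (mg C per g litter): baseline + scale·(effects · rel.ab.) + noise.
    doc_baseline: float = 3.0
    doc_effect_scale: float = 20.0
    doc_noise_sd: float = 0.3
    #: Fraction of bacterial taxa carrying a nonzero DOC effect weight.
    doc_effect_fraction: float = 0.2
    #: Force planted effect weights to be positive (|N(0,1)|) — useful for
    #: recovery experiments that plant known DOC-producer taxa.
    doc_effect_positive: bool = False
    #: Plant effects on the most abundant taxa (by expected abundance)
    #: instead of at random — emulates dominant DOC-producer taxa.
    doc_effect_abundant: bool = False
    #: CO₂ (mg per g litter, 28-day total) = intercept + tradeoff·DOC + noise.
    co2_intercept: float = 45.0
    co2_tradeoff: float = -2.0
    co2_noise_sd: float = 3.0
    tn_mean: float = 0.6
    tn_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_origins", "n_g0_replicates", "n_lineages_per_origin",
            "n_generations", "n_taxa_bacteria", "n_taxa_fungi",
            "seq_depth_bacteria", "seq_depth_fungi",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("legacy_sd", "drift_sd", "interaction_strength_sd",
                     "doc_noise_sd", "co2_noise_sd", "tn_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.interaction_connectance <= 1.0:
            raise ValueError("interaction_connectance must lie in [0, 1]")
        if not 0.0 <= self.doc_effect_fraction <= 1.0:
            raise ValueError("doc_effect_fraction must lie in [0, 1]")
        if self.transfer_depth is not None and self.transfer_depth < 1:
            raise ValueError("transfer_depth must be >= 1 or None")
        if self.n_lineages_per_origin % self.n_g0_replicates != 0:
            raise ValueError(
                "n_lineages_per_origin must be a multiple of n_g0_replicates"
            )


@dataclass
class GroundTruth:
    """Latent quantities behind one generated experiment.

    ``latent_compositions`` maps ``(domain, sample_id)`` to the relative
    abundance vector before sequencing noise; DOC is computed from the
    bacterial latent composition.
    """

    origin_profiles: dict[str, dict[str, np.ndarray]]
    interaction_matrix: dict[str, np.ndarray]
    doc_effect_taxa: dict[str, float]
    latent_compositions: dict[tuple[str, str], np.ndarray]


def _softmax(w: np.ndarray) -> np.ndarray:
    w = w - w.max()
    e = np.exp(w)
    return e / e.sum()


def _make_taxonomy(prefix: str, kingdom: str, n: int) -> tuple[list[str], dict]:
    """Synthetic ranked taxonomy: ~5 ASVs per family, nested labels."""
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    tax = {}
    for i, tid in enumerate(ids):
        fam = i // 5
        order = fam // 3
        phylum = order // 4
        tax[tid] = (
            kingdom,
            f"{prefix}p{phylum:02d}",
            f"{prefix}c{phylum:02d}",
            f"{prefix}o{order:02d}",
            f"{prefix}f{fam:02d}",
            f"{prefix}g{i // 2:03d}",
            None,
        )
    return ids, tax


def _sparse_interactions(rng: np.random.Generator, n: int,
                         connectance: float, strength_sd: float) -> np.ndarray:
    A = np.zeros((n, n))
    if connectance > 0 and strength_sd > 0:
        mask = rng.random((n, n)) < connectance
        np.fill_diagonal(mask, False)
        A[mask] = rng.normal(0.0, strength_sd, size=mask.sum())
    return A


def _propagate(rng: np.random.Generator, parent_frac: np.ndarray,
               A: np.ndarray, drift_sd: float,
               transfer_depth: Optional[int]) -> np.ndarray:
    """One generation of latent dynamics: drift + interactions + bottleneck."""
    alive = parent_frac > 0
    w = np.full(parent_frac.shape, -np.inf)
    w[alive] = np.log(parent_frac[alive])
    w[alive] += A[alive] @ parent_frac
    if drift_sd > 0:
        w[alive] += rng.normal(0.0, drift_sd, size=int(alive.sum()))
    frac = np.zeros_like(parent_frac)
    frac[alive] = _softmax(w[alive])
    if transfer_depth is not None:
        cells = rng.multinomial(transfer_depth, frac)
        frac = cells / transfer_depth
    return frac


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[AbundanceTable, AbundanceTable, MetadataTable, GroundTruth]:
    """Generate bacterial and fungal count tables, metadata, and ground truth.

    The lineage graph mirrors the emulated design: ``n_g0_replicates`` G0
    microcosms per origin, each inoculating
    ``n_lineages_per_origin / n_g0_replicates`` G1 microcosms, then 1:1
    propagation through generation ``n_generations − 1``.  Emitted count
    columns sum exactly to the per-domain sequencing depth.  Fully
    reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    domains = {
        "bacteria": (config.n_taxa_bacteria, "B", "Bacteria",
                     config.seq_depth_bacteria),
        "fungi": (config.n_taxa_fungi, "F", "Fungi", config.seq_depth_fungi),
    }
    taxon_ids: dict[str, list[str]] = {}
    taxonomies: dict[str, dict] = {}
    base_logmean: dict[str, np.ndarray] = {}
    A: dict[str, np.ndarray] = {}
    origin_profiles: dict[str, dict[str, np.ndarray]] = {d: {} for d in domains}
    for d, (n, prefix, kingdom, _) in domains.items():
        taxon_ids[d], taxonomies[d] = _make_taxonomy(prefix, kingdom, n)
        base_logmean[d] = rng.normal(0.0, 1.0, n)
        A[d] = _sparse_interactions(
            rng, n, config.interaction_connectance, config.interaction_strength_sd
        )

    # DOC effect weights on bacterial taxa
    nb = config.n_taxa_bacteria
    n_eff = max(1, int(round(config.doc_effect_fraction * nb)))
    if config.doc_effect_abundant:
        eff_idx = np.argsort(base_logmean["bacteria"])[::-1][:n_eff]
    else:
        eff_idx = rng.choice(nb, size=n_eff, replace=False)
    effects = np.zeros(nb)
    weights = rng.normal(0.0, 1.0, n_eff)
    if config.doc_effect_positive:
        weights = np.abs(weights)
    effects[eff_idx] = weights
    doc_effect_taxa = {
        taxon_ids["bacteria"][i]: float(effects[i]) for i in eff_idx
    }

    origins = [f"O{i + 1:02d}" for i in range(config.n_origins)]
    for d in domains:
        for o in origins:
            origin_profiles[d][o] = base_logmean[d] + rng.normal(
                0.0, config.legacy_sd, len(base_logmean[d])
            )

    records: list[SampleRecord] = []
    latent: dict[tuple[str, str], np.ndarray] = {}
    columns: dict[str, dict[str, np.ndarray]] = {d: {} for d in domains}

    def measure(sample_id: str, frac_bact: np.ndarray) -> tuple[float, float, float]:
        doc = (config.doc_baseline
               + config.doc_effect_scale * float(effects @ frac_bact))
        if config.doc_noise_sd > 0:
            doc += rng.normal(0.0, config.doc_noise_sd)
        doc = max(doc, 0.0)
        co2 = config.co2_intercept + config.co2_tradeoff * doc
        if config.co2_noise_sd > 0:
            co2 += rng.normal(0.0, config.co2_noise_sd)
        co2 = max(co2, 0.0)
        tn = max(rng.normal(config.tn_mean, config.tn_sd), 0.0)
        return doc, co2, tn

    def sequence(sample_id: str) -> None:
        for d, (_, _, _, depth) in domains.items():
            columns[d][sample_id] = rng.multinomial(depth, latent[(d, sample_id)])

    children_per_rep = config.n_lineages_per_origin // config.n_g0_replicates
    for o in origins:
        g0_fracs: dict[str, dict[str, np.ndarray]] = {}
        g0_ids: list[str] = []
        for r in range(config.n_g0_replicates):
            sid = f"{o}.R{r + 1}.G0"
            g0_ids.append(sid)
            fracs = {}
            for d in domains:
                w = origin_profiles[d][o] + (
                    rng.normal(0.0, config.drift_sd, len(base_logmean[d]))
                    if config.drift_sd > 0 else 0.0
                )
                frac = _softmax(w)
                if config.transfer_depth is not None:
                    cells = rng.multinomial(config.transfer_depth, frac)
                    frac = cells / config.transfer_depth
                fracs[d] = frac
                latent[(d, sid)] = frac
            g0_fracs[sid] = fracs
            doc, co2, tn = measure(sid, fracs["bacteria"])
            records.append(SampleRecord(sid, o, 0, f"{o}.R{r + 1}", None,
                                        f"R{r + 1}", doc, co2, tn))
            sequence(sid)
        # lineages: G0 replicate r spawns children_per_rep G1 lineages
        lineage_no = 0
        for r, g0_sid in enumerate(g0_ids):
            for _ in range(children_per_rep):
                lineage_no += 1
                lin = f"{o}.L{lineage_no}"
                parent_sid = g0_sid
                parent_fracs = g0_fracs[g0_sid]
                for g in range(1, config.n_generations):
                    sid = f"{lin}.G{g}"
                    fracs = {}
                    for d in domains:
                        fracs[d] = _propagate(
                            rng, parent_fracs[d], A[d],
                            config.drift_sd, config.transfer_depth,
                        )
                        latent[(d, sid)] = fracs[d]
                    doc, co2, tn = measure(sid, fracs["bacteria"])
                    records.append(SampleRecord(sid, o, g, lin, parent_sid,
                                                f"L{lineage_no}", doc, co2, tn))
                    sequence(sid)
                    parent_sid, parent_fracs = sid, fracs

    metadata = MetadataTable(records)
    sample_ids = metadata.sample_ids
    tables = {}
    for d in domains:
        counts = np.column_stack([columns[d][s] for s in sample_ids])
        tables[d] = AbundanceTable(list(taxon_ids[d]), list(sample_ids),
                                   counts, dict(taxonomies[d]))
    truth = GroundTruth(
        origin_profiles=origin_profiles,
        interaction_matrix=A,
        doc_effect_taxa=doc_effect_taxa,
        latent_compositions=latent,
    )
    return tables["bacteria"], tables["fungi"], metadata, truth


def design_summary(metadata: MetadataTable) -> pd.DataFrame:
    """Sample counts per origin × generation (empty metadata → empty table)."""
    if len(metadata) == 0:
        return pd.DataFrame()
    df = metadata.to_dataframe()
    return (
        df.groupby(["origin_id", "generation"]).size().unstack(fill_value=0)
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SyntheticConfig:
    cfg = SyntheticConfig(**d)
    cfg.validate()
    return cfg
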