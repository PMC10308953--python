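"""End-to-end analysis pipeline with config, provenance and seeding.

Stages run in a fixed order — simulate (or load) → prep → diversity →
stability → associate → network — each writing tidy TSV/JSON artifacts to
the output directory.  A run manifest records the full configuration,
master seed, per-stage parameters and SHA-256 hashes of the input tables,
so a run can be reproduced from the manifest alone.  Stages derive their
RNG seeds from the master seed, making reruns with the same config
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from skbio.stats.distance import DistanceMatrix

from . import association, diversity, sparcc, stability, synth, tables

logger = logging.getLogger(__name__)

DOMAINS = ("bacteria", "fungi")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-loadable)."""

    output_dir: str = "propstab_out"
    seed: int = 0
    #: either a synthetic block ...
    simulate: Optional[dict] = None
    #: ... or paths to existing tables
    bacteria_path: Optional[str] = None
    fungi_path: Optional[str] = None
    metadata_path: Optional[str] = None
    #: rarefaction depth per domain; None = minimum sample sum
    rarefaction_depth: dict = field(
        default_factory=lambda: {"bacteria": None, "fungi": None}
    )
    q_low: float = 0.25
    q_high: float = 0.75
    fdr: float = 0.1
    mantel_permutations: int = 999
    permanova_permutations: int = 999
    prevalence: float = 0.8
    network: dict = field(default_factory=lambda: {
        "n_boot": 1000,
        "confidence": 0.99,
        "p_cutoff": 0.01,
        "n_inner_iterations": 20,
        "null_inner_iterations": 5,
        "max_taxa": 60,
    })

    def validate(self) -> None:
        if self.simulate is None:
            for p in (self.bacteria_path, self.fungi_path, self.metadata_path):
                if p is None:
                    raise ValueError(
                        "config needs either a 'simulate' block or all three "
                        "input paths (bacteria_path, fungi_path, metadata_path)"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_dm(dm: DistanceMatrix, path: Path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t")


def _read_dm(path: Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(c) for c in df.columns])


class PipelineState:
    """In-memory state passed between stages; loadable from an output dir."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.tables: dict[str, tables.AbundanceTable] = {}
        self.rarefied: dict[str, tables.AbundanceTable] = {}
        self.metadata: Optional[tables.MetadataTable] = None
        self.distances: dict[str, DistanceMatrix] = {}
        self.assignments: Optional[pd.DataFrame] = None
        self.cutoffs: Optional[stability.StabilityCutoffs] = None
        self.manifest: dict = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "stages": [],
        }

    # -- persistence -----------------------------------------------------
    def load_inputs(self) -> None:
        self.metadata = tables.read_metadata(self.outdir / "metadata.tsv")
        for d in DOMAINS:
            self.tables[d] = tables.read_abundance_table(self.outdir / f"{d}.tsv")

    def load_rarefied(self) -> None:
        for d in DOMAINS:
            self.rarefied[d] = tables.read_abundance_table(
                self.outdir / f"{d}_rarefied.tsv"
            )

    def load_distances(self) -> None:
        for d in DOMAINS:
            self.distances[d] = _read_dm(self.outdir / f"bray_curtis_{d}.tsv")

    def load_assignments(self) -> None:
        df = pd.read_csv(self.outdir / "stability_assignments.tsv", sep="\t",
                         index_col="sample_id")
        df["sample_id"] = df.index
        self.assignments = df

    def record(self, stage: str, **params) -> None:
        self.manifest["stages"].append({
            "stage": stage,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "params": params,
        })

    def write_manifest(self, status: str = "ok") -> None:
        self.manifest["status"] = status
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(state: PipelineState) -> None:
    cfg = state.config
    state.outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        sim_cfg = synth.config_from_dict({**cfg.simulate, "seed": cfg.seed})
        bact, fungi, meta, truth = synth.generate_experiment(sim_cfg)
        state.tables = {"bacteria": bact, "fungi": fungi}
        state.metadata = meta
        with open(state.outdir / "ground_truth.json", "w") as fh:
            json.dump({
                "config": synth.config_to_dict(sim_cfg),
                "doc_effect_taxa": truth.doc_effect_taxa,
            }, fh, indent=2)
        state.record("simulate", **synth.config_to_dict(sim_cfg))
    else:
        state.metadata = tables.read_metadata(cfg.metadata_path)
        state.tables["bacteria"] = tables.read_abundance_table(cfg.bacteria_path)
        state.tables["fungi"] = tables.read_abundance_table(cfg.fungi_path)
        state.record(
            "load",
            bacteria_sha256=_sha256(Path(cfg.bacteria_path)),
            fungi_sha256=_sha256(Path(cfg.fungi_path)),
            metadata_sha256=_sha256(Path(cfg.metadata_path)),
        )
    for d in DOMAINS:
        tables.write_table(state.tables[d], state.outdir / f"{d}.tsv")
    tables.write_metadata(state.metadata, state.outdir / "metadata.tsv")


def stage_prep(state: PipelineState) -> None:
    cfg = state.config
    depths = {}
    for i, d in enumerate(DOMAINS):
        depth = cfg.rarefaction_depth.get(d)
        if depth is None:
            depth = int(state.tables[d].sample_sums().min())
        depths[d] = depth
        state.rarefied[d] = tables.rarefy(
            state.tables[d], depth, seed=cfg.seed + 100 + i
        )
        tables.write_table(state.rarefied[d], state.outdir / f"{d}_rarefied.tsv")
    state.record("prep", depths=depths)


def stage_diversity(state: PipelineState) -> None:
    cfg = state.config
    meta_df = state.metadata.to_dataframe()
    for d in DOMAINS:
        tab = state.rarefied[d]
        alpha = diversity.alpha_diversity_table(tab)
        alpha.to_csv(state.outdir / f"alpha_{d}.tsv", sep="\t",
                     index_label="sample_id")
        dm = diversity.bray_curtis_matrix(tab)
        state.distances[d] = dm
        _write_dm(dm, state.outdir / f"bray_curtis_{d}.tsv")
        ids = list(dm.ids)
        factors = meta_df.loc[ids, ["origin_id", "generation"]].astype(str)
        res = diversity.permanova(
            dm, factors, include_interaction=True,
            n_perm=cfg.permanova_permutations, seed=cfg.seed + 200,
        )
        res.table.to_csv(state.outdir / f"permanova_{d}.tsv", sep="\t")
        disp = diversity.beta_dispersion(
            dm, meta_df.loc[ids, "origin_id"].to_dict()
        )
        disp.to_frame().to_csv(state.outdir / f"beta_dispersion_{d}.tsv",
                               sep="\t", index_label="sample_id")
    state.record("diversity", n_perm=cfg.permanova_permutations)


def stage_stability(state: PipelineState) -> None:
    cfg = state.config
    df, cutoffs = stability.stability_assignments(
        state.metadata,
        dist_bacterial=state.distances.get("bacteria"),
        dist_fungal=state.distances.get("fungi"),
        q_low=cfg.q_low, q_high=cfg.q_high,
    )
    state.assignments = df
    state.cutoffs = cutoffs
    df.to_csv(state.outdir / "stability_assignments.tsv", sep="\t", index=False)
    with open(state.outdir / "stability_cutoffs.json", "w") as fh:
        json.dump(dataclasses.asdict(cutoffs), fh, indent=2)
    cv = pd.DataFrame({
        "cv_doc": stability.generation_cv(state.metadata, "DOC"),
        "cv_co2": stability.generation_cv(state.metadata, "CO2"),
    })
    cv.to_csv(state.outdir / "generation_cv.tsv", sep="\t",
              index_label="generation")
    state.record("stability", q_low=cfg.q_low, q_high=cfg.q_high)


def _trait_features(state: PipelineState) -> pd.DataFrame:
    """Per-child-sample trait table: deltas, diversity metrics, readouts."""
    meta_df = state.metadata.to_dataframe()
    df = state.assignments
    feats = pd.DataFrame(index=df.index)
    feats["delta_doc"] = df["delta_doc"]
    feats["delta_comp_bacterial"] = df["delta_comp_bact"]
    feats["delta_comp_fungal"] = df["delta_comp_fungi"]
    for d in DOMAINS:
        alpha = diversity.alpha_diversity_table(state.rarefied[d])
        for col in alpha.columns:
            feats[f"{d}_{col}"] = alpha[col].reindex(feats.index)
    for var in ("DOC", "CO2", "TN"):
        feats[var] = meta_df[var].reindex(feats.index)
    return feats


def stage_associate(state: PipelineState) -> None:
    cfg = state.config
    feats = _trait_features(state)
    # Pooled trait correlations (all child samples)
    pooled = association.pearson_bh_matrix(feats, fdr=cfg.fdr)
    pooled.to_csv(state.outdir / "trait_correlations_all.tsv", sep="\t",
                  index=False)
    groups = state.assignments["group"]
    mantel_rows = []
    for g in (stability.MOST_STABLE, stability.LEAST_STABLE):
        samples = groups.index[groups == g].tolist()
        if len(samples) < 4:
            logger.warning("group %s too small for group-wise analyses", g)
            continue
        res = association.pearson_bh_matrix(feats.loc[samples], fdr=cfg.fdr)
        res.to_csv(state.outdir / f"trait_correlations_{g}.tsv", sep="\t",
                   index=False)
        net = association.trait_correlation_network(res)
        net.to_csv(state.outdir / f"trait_network_{g}.tsv", sep="\t",
                   index=False)
        # Mantel: composition vs DOC / CO2 / combined, per domain
        for d in DOMAINS:
            dm = state.distances[d]
            keep = [s for s in samples if s in set(dm.ids)]
            sub = dm.filter(keep)
            for label, variables in (("DOC", ("DOC",)), ("CO2", ("CO2",)),
                                     ("DOCxCO2", ("DOC", "CO2"))):
                fd = association.function_dissimilarity(
                    state.metadata, variables, sample_ids=keep
                )
                m = association.mantel_test(
                    sub, fd, n_perm=cfg.mantel_permutations,
                    seed=cfg.seed + 300,
                )
                mantel_rows.append({
                    "group": g, "domain": d, "function": label,
                    "r": m.r, "p": m.p, "n_perm": m.n_perm,
                    "n_samples": m.n_samples,
                })
        # Taxa ~ function screens (bacteria at family level, fungi at ASV)
        for d in DOMAINS:
            tab = state.rarefied[d]
            if d == "bacteria":
                tab = tables.aggregate_by_rank(tab, "family")
            assign = {s: g for s in samples}
            res = association.taxa_function_correlations(
                tab, state.metadata, ("DOC", "CO2", "TN"), assign,
                extra_features=feats[["delta_doc"]].rename(
                    columns={"delta_doc": "delta_doc"}),
                min_prevalence=cfg.prevalence,
            )[g]
            res.to_csv(state.outdir / f"taxa_correlations_{d}_{g}.tsv",
                       sep="\t", index=False)
    pd.DataFrame(mantel_rows).to_csv(state.outdir / "mantel_results.tsv",
                                     sep="\t", index=False)
    state.record("associate", fdr=cfg.fdr, n_perm=cfg.mantel_permutations)


def stage_network(state: PipelineState) -> None:
    cfg = state.config
    net_cfg = dict(cfg.network)
    max_taxa = net_cfg.pop("max_taxa", None)
    groups = state.assignments["group"]
    summaries = {}
    for g in (stability.MOST_STABLE, stability.LEAST_STABLE):
        samples = groups.index[groups == g].tolist()
        for i, d in enumerate(DOMAINS):
            tab = state.rarefied[d]
            keep = [s for s in samples if s in tab.sample_ids]
            if len(keep) < 10:
                logger.warning("skipping network %s/%s: too few samples", d, g)
                continue
            tab = tab.subset_samples(keep)
            if d == "bacteria":
                tab = tables.aggregate_by_rank(tab, "family")
            tab = tab.drop_empty_taxa()
            if max_taxa is not None and tab.n_taxa > max_taxa:
                # keep the most abundant taxa so the system stays well-posed
                order = np.argsort(tab.counts.sum(axis=1))[::-1][:max_taxa]
                keep_taxa = [tab.taxon_ids[k] for k in sorted(order)]
                mask = [t in set(keep_taxa) for t in tab.taxon_ids]
                tab = tables.AbundanceTable(
                    [t for t, m in zip(tab.taxon_ids, mask) if m],
                    list(tab.sample_ids),
                    tab.counts[np.array(mask)], dict(tab.taxonomy),
                )
            net, est = sparcc.infer_network(
                tab, seed=cfg.seed + 400 + 10 * i, **net_cfg
            )
            name = f"network_{d}_{g}"
            sparcc.write_edge_list(net, state.outdir / f"{name}_edges.tsv")
            sparcc.write_graphml(net, state.outdir / f"{name}.graphml")
            summaries[name] = {
                **sparcc.network_summary(net),
                "threshold_meta": net.threshold_meta,
            }
    with open(state.outdir / "network_summaries.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    state.record("network", **cfg.network)


STAGES = [
    ("simulate", stage_simulate),
    ("prep", stage_prep),
    ("diversity", stage_diversity),
    ("stability", stage_stability),
    ("associate", stage_associate),
    ("network", stage_network),
]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages in order; write a manifest; return the output dir.

    On stage failure, partial outputs are retained, the manifest records
    the failed stage, and the exception propagates.
    """
    config.validate()
    state = PipelineState(config)
    state.outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        logger.info("stage %s", name)
        try:
            fn(state)
        except Exception:
            state.write_manifest(status=f"failed at stage {name}")
            (state.outdir / "FAILED").write_text(name + "\n")
            raise
    state.write_manifest(status="ok")
    return state.outdir
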