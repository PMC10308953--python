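"""Functional and compositional stability of propagated lineages.

A lineage's functional stability between consecutive generations is the
absolute change in its functional readout, ΔDOC = |DOC(Gn) − DOC(Gn−1)|
(smaller = more stable); its compositional change is the Bray–Curtis
dissimilarity between the same pair of samples.  Samples are stratified
into "most stable" (ΔDOC at or below the pooled 25th percentile),
"least stable" (at or above the 75th), and intermediate groups; cutoffs
are computed over all child generations pooled, with linear interpolation
between order statistics, and boundary values fall in the tail groups
(the stability intervals are closed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .tables import MetadataTable

logger = logging.getLogger(__name__)

MOST_STABLE = "most_stable"
INTERMEDIATE = "intermediate"
LEAST_STABLE = "least_stable"


@dataclass
class StabilityCutoffs:
    """Pooled ΔDOC percentile cutoffs (mg DOC per g litter).

    ``pooling`` describes the sample set the quantiles were computed over;
    ``quantile_method`` records the convention (linear interpolation
    between order statistics).
    """

    q25: float
    q75: float
    median: float
    pooling: str
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median <= self.q75):
            raise ValueError("cutoffs must satisfy q25 <= median <= q75")


def pair_lineages(metadata: MetadataTable) -> list[tuple[str, str]]:
    """(child, parent) sample-id pairs, one per non-G0 sample."""
    return [
        (r.sample_id, r.parent_sample_id)
        for r in metadata.records
        if r.generation > 0
    ]


def delta_function(
    pairs: list[tuple[str, str]],
    metadata: MetadataTable,
    variable: str = "DOC",
) -> pd.Series:
    """|value(child) − value(parent)| per child sample."""
    if variable not in ("DOC", "CO2"):
        raise ValueError(f"unsupported variable {variable!r}")
    out = {}
    for child, parent in pairs:
        for sid in (child, parent):
            if sid not in metadata:
                raise KeyError(f"sample {sid!r} missing from metadata")
        vc = getattr(metadata[child], variable)
        vp = getattr(metadata[parent], variable)
        if vc is None or vp is None or np.isnan(vc) or np.isnan(vp):
            raise ValueError(f"missing {variable} for pair ({child}, {parent})")
        out[child] = abs(vc - vp)
    return pd.Series(out, name=f"delta_{variable.lower()}", dtype=float)


def delta_composition(
    pairs: list[tuple[str, str]], dist: DistanceMatrix
) -> pd.Series:
    """Bray–Curtis dissimilarity between each child and its parent."""
    ids = set(dist.ids)
    out = {}
    for child, parent in pairs:
        missing = {child, parent} - ids
        if missing:
            raise KeyError(
                f"sample(s) absent from distance matrix: {sorted(missing)}"
            )
        out[child] = float(dist[child, parent])
    return pd.Series(out, name="delta_composition", dtype=float)


def generation_cv(metadata: MetadataTable, variable: str = "DOC") -> pd.Series:
    """Coefficient of variation (SD with n−1 denominator / mean) per generation."""
    if variable not in ("DOC", "CO2"):
        raise ValueError(f"unsupported variable {variable!r}")
    df = metadata.to_dataframe()
    out = {}
    for g, grp in df.groupby("generation"):
        vals = grp[variable].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"generation {g} has fewer than 2 samples")
        mean = vals.mean()
        if mean <= 0:
            raise ValueError(f"generation {g} has non-positive mean {variable}")
        out[int(g)] = float(vals.std(ddof=1) / mean)
    return pd.Series(out, name=f"cv_{variable.lower()}").sort_index()


def stratify_stability(
    deltas: pd.Series,
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> tuple[pd.Series, StabilityCutoffs]:
    """Label samples most/least stable by pooled ΔDOC percentiles.

    Quantiles use linear interpolation; values exactly at a cutoff are
    included in the tail group.  If the two cutoffs coincide (degenerate
    ΔDOC distribution) every sample is labelled intermediate and a warning
    is raised.
    """
    vals = np.asarray(deltas, dtype=float)
    if len(vals) < 4:
        raise ValueError("need at least 4 ΔDOC values to stratify")
    if not 0.0 <= q_low < q_high <= 1.0:
        raise ValueError("require 0 <= q_low < q_high <= 1")
    lo = float(np.quantile(vals, q_low))
    hi = float(np.quantile(vals, q_high))
    med = float(np.quantile(vals, 0.5))
    cutoffs = StabilityCutoffs(
        q25=lo, q75=hi, median=med,
        pooling=f"pooled over {len(vals)} child samples, all generations",
    )
    if lo == hi:
        warnings.warn(
            "degenerate ΔDOC distribution: percentile cutoffs coincide; "
            "all samples labelled intermediate",
            stacklevel=2,
        )
        labels = pd.Series(INTERMEDIATE, index=deltas.index, name="group")
        return labels, cutoffs
    labels = np.where(
        vals <= lo, MOST_STABLE, np.where(vals >= hi, LEAST_STABLE, INTERMEDIATE)
    )
    return pd.Series(labels, index=deltas.index, name="group"), cutoffs


def stability_assignments(
    metadata: MetadataTable,
    dist_bacterial: DistanceMatrix | None = None,
    dist_fungal: DistanceMatrix | None = None,
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> tuple[pd.DataFrame, StabilityCutoffs]:
    """Full per-sample stability table: ΔDOC, Δcomposition, group label.

    Convenience composition of :func:`pair_lineages`,
    :func:`delta_function`, :func:`delta_composition` and
    :func:`stratify_stability`; rows are non-G0 samples.
    """
    pairs = pair_lineages(metadata)
    ddoc = delta_function(pairs, metadata, "DOC")
    labels, cutoffs = stratify_stability(ddoc, q_low, q_high)
    df = pd.DataFrame({
        "sample_id": ddoc.index,
        "generation": [metadata[s].generation for s in ddoc.index],
        "delta_doc": ddoc.values,
    }).set_index("sample_id", drop=False)
    for name, dist in (("delta_comp_bact", dist_bacterial),
                       ("delta_comp_fungi", dist_fungal)):
        if dist is not None:
            usable = [(c, p) for c, p in pairs
                      if c in set(dist.ids) and p in set(dist.ids)]
            df[name] = delta_composition(usable, dist).reindex(df.index)
        else:
            df[name] = np.nan
    df["group"] = labels
    return df, cutoffs
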