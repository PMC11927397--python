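"""Sequencing-depth robustness: rarefaction and depth sweeps.

Rarefaction subsamples a sample's read-count profile WITHOUT replacement
(multivariate hypergeometric) to a fixed depth, emulating read-level
subsampling at the count-profile level.  A depth sweep rarefies deeply
sequenced samples to a grid of depths, rebuilds relative-abundance tables,
re-applies the standard detection filters, recomputes the features and
scores every method, then summarizes per-sample score stability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dysbio.errors import DysbioError
from dysbio.features import ReferenceAssets, build_feature_table
from dysbio.comparators import gmhi_score, richness, shannon_entropy
from dysbio.profile_io import (
    FilterThresholds,
    FunctionProfileTable,
    PathwayCoverageTable,
    TaxonProfileTable,
    apply_filters,
)

__all__ = ["ReadCountProfile", "rarefy_counts", "profiles_to_tables", "depth_sweep"]


@dataclass
class ReadCountProfile:
    """Integer read counts for one sample.

    ``species_counts`` is the taxonomic pool (one entry per species);
    ``strat_counts`` holds functional reads per (pathway, taxon) stratum and
    is rarefied proportionally alongside the taxonomic pool.
    """

    sample_id: str
    species_counts: pd.Series
    strat_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def __post_init__(self) -> None:
        for s in (self.species_counts, self.strat_counts):
            v = s.to_numpy()
            if len(v) and (v < 0).any():
                raise DysbioError("read counts must be non-negative")
            if len(v) and not np.issubdtype(v.dtype, np.integer):
                if not np.allclose(v, np.round(v)):
                    raise DysbioError("read counts must be integral")
        self.species_counts = self.species_counts.astype(np.int64)
        self.strat_counts = self.strat_counts.astype(np.int64)

    @property
    def total_reads(self) -> int:
        return int(self.species_counts.sum())


def rarefy_counts(profile: ReadCountProfile, depth: int, seed: int = 0) -> ReadCountProfile:
    """Subsample to exactly ``depth`` taxonomic reads without replacement.

    The functional stratified pool is rarefied to the equivalently scaled
    depth.  Deterministic given (seed, sample_id, depth).
    """
    total = profile.total_reads
    if depth <= 0:
        raise DysbioError("rarefaction depth must be positive")
    if depth > total:
        raise DysbioError(f"depth {depth} exceeds total reads {total}")
    rng = np.random.default_rng(
        (seed + zlib.crc32(f"{profile.sample_id}:{depth}".encode())) % (2**31)
    )
    sub = rng.multivariate_hypergeometric(profile.species_counts.to_numpy(), depth)
    species = pd.Series(sub, index=profile.species_counts.index)

    strat = profile.strat_counts
    if len(strat) and strat.sum() > 0:
        strat_depth = int(round(strat.sum() * depth / total))
        strat_depth = min(strat_depth, int(strat.sum()))
        if strat_depth > 0:
            sub_s = rng.multivariate_hypergeometric(strat.to_numpy(), strat_depth)
        else:
            sub_s = np.zeros(len(strat), dtype=int)
        strat = pd.Series(sub_s, index=strat.index)
    return ReadCountProfile(profile.sample_id, species, strat)


def profiles_to_tables(
    profiles: list[ReadCountProfile],
) -> tuple[TaxonProfileTable, FunctionProfileTable, PathwayCoverageTable]:
    """Convert count profiles to percent-scale relative-abundance tables.

    Community pathway abundance is the sum of its strata; coverage is set to
    1 for detected pathways (rarefaction carries no coverage information).
    """
    if not profiles:
        raise DysbioError("no profiles to convert")
    tax_rows, func_rows, ids = [], [], []
    for p in profiles:
        ids.append(p.sample_id)
        total = p.total_reads
        tax_rows.append(p.species_counts / total * 100 if total else p.species_counts * 0.0)
        st = p.strat_counts
        s_total = st.sum()
        func_rows.append(st / s_total * 100 if s_total else st * 0.0)
    tax = pd.DataFrame(tax_rows, index=ids).fillna(0.0)
    strat = pd.DataFrame(func_rows, index=ids).fillna(0.0).T
    if len(strat):
        strat.index = pd.MultiIndex.from_tuples(strat.index, names=["pathway", "taxon"])
        community = strat.groupby(level="pathway").sum().T
    else:
        community = pd.DataFrame(index=ids)
    cov = PathwayCoverageTable(coverage=(community > 0).astype(float))
    return (
        TaxonProfileTable(abundance=tax),
        FunctionProfileTable(abundance=community, stratified=strat),
        cov,
    )


def depth_sweep(
    profiles: list[ReadCountProfile],
    depths: list[int],
    refs: ReferenceAssets,
    results=None,
    thresholds: FilterThresholds = FilterThresholds(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every sample at every rarefaction depth with every method.

    Returns ``(scores, stability)``: a long frame (sample, depth, method,
    score) and a per-(sample, method) summary with the score range, standard
    deviation across depths, and whether the model score ever crosses the
    health threshold.  Depths exceeding a sample's total are marked missing.
    """
    depths = sorted(set(int(d) for d in depths), reverse=True)
    records = []
    # nested subsampling: each depth rarefies the previous (deeper) draw, so
    # per-sample detection is monotone along the depth axis
    current: dict[str, ReadCountProfile] = {p.sample_id: p for p in profiles}
    for depth in depths:
        usable = [p for p in profiles if p.total_reads >= depth]
        skipped = [p.sample_id for p in profiles if p.total_reads < depth]
        for sid in skipped:
            records.append({"sample": sid, "depth": depth, "method": "fhi",
                            "score": np.nan})
        if not usable:
            continue
        rare = [rarefy_counts(current[p.sample_id], depth, seed=seed)
                for p in usable]
        current.update({p.sample_id: p for p in rare})
        tax, func, cov = profiles_to_tables(rare)
        tax_f, func_f = apply_filters(tax, func, cov, thresholds)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            feats = build_feature_table(tax_f, func_f, refs)
            for p, rp in zip(usable, rare):
                sid = p.sample_id
                sp_raw = tax.abundance.loc[sid]
                sp_f = tax_f.abundance.loc[sid]
                records.append({"sample": sid, "depth": depth, "method": "richness",
                                "score": richness(sp_raw)})
                records.append({
                    "sample": sid, "depth": depth, "method": "shannon_taxa",
                    "score": shannon_entropy(sp_f) if (sp_f > 0).any() else 0.0,
                })
                records.append({
                    "sample": sid, "depth": depth, "method": "gmhi",
                    "score": gmhi_score(sp_f, refs.gmhi_good, refs.gmhi_bad),
                })
            if results is not None:
                fhi = results.predict_health_score(feats)
                for sid, score in fhi.items():
                    records.append({"sample": sid, "depth": depth, "method": "fhi",
                                    "score": float(score)})
    scores = pd.DataFrame.from_records(records)

    summaries = []
    for (sid, method), grp in scores.dropna().groupby(["sample", "method"]):
        vals = grp["score"].to_numpy()
        row = {
            "sample": sid,
            "method": method,
            "score_range": float(vals.max() - vals.min()),
            "score_std": float(vals.std()),
            "n_depths": len(vals),
        }
        if method == "fhi" and results is not None:
            row["crosses_threshold"] = bool(
                (vals >= results.threshold).any() and (vals < results.threshold).any()
            )
        summaries.append(row)
    stability = pd.DataFrame(summaries)
    return scores, stability
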