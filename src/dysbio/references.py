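"""Derivation of the reference assets that define a healthy microbiome.

Two assets are derived from healthy-only cohorts:

* the **core-function set** — pathways present (post-filter) in more than a
  prevalence threshold (default 80 %) of pooled healthy samples;
* the **healthy pair set** — unordered species pairs whose SparCC
  correlation exceeds 0.1 in at least one healthy cohort and is
  non-negative in every healthy cohort where both species occur.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

from dysbio.errors import DysbioError, EmptyTableError
from dysbio.profile_io import FunctionProfileTable, TaxonProfileTable
from dysbio.sparcc import CorrelationMatrix, sparcc_correlations

__all__ = [
    "PrevalenceProfile",
    "CoreFunctionSet",
    "HealthyPairSet",
    "prevalence_profile",
    "derive_core_functions",
    "derive_healthy_pairs",
    "derive_reference_assets",
]


@dataclass
class PrevalenceProfile:
    """Pooled and per-cohort prevalence (fraction of samples with signal)."""

    prevalence: pd.Series  # feature -> pooled fraction in [0, 1]
    per_cohort: pd.DataFrame  # feature x cohort fractions
    n_samples: dict[str, int]  # cohort -> sample count

    def cumulative_curve(self) -> pd.DataFrame:
        """Fraction of features present in at least x fraction of samples.

        Returns a two-column frame (threshold, fraction_of_features) suitable
        for prevalence-distribution plots.
        """
        thresholds = sorted(set(self.prevalence.round(10))) or [0.0]
        frac = [(self.prevalence >= t).mean() for t in thresholds]
        return pd.DataFrame({"threshold": thresholds, "fraction_of_features": frac})


@dataclass(frozen=True)
class CoreFunctionSet:
    """Pathways whose pooled healthy prevalence strictly exceeds the threshold."""

    pathway_ids: tuple[str, ...]
    prevalence_threshold: float = 0.8
    source: tuple[str, ...] = ()

    def __contains__(self, pathway: str) -> bool:
        return pathway in set(self.pathway_ids)

    def __len__(self) -> int:
        return len(self.pathway_ids)


@dataclass(frozen=True)
class HealthyPairSet:
    """Unordered, unique species pairs co-occurring in health."""

    pairs: frozenset[tuple[str, str]]
    min_corr: float = 0.1

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)


def _as_cohort_list(tables) -> list[tuple[object, str]]:
    out = []
    for i, item in enumerate(tables):
        if isinstance(item, tuple):
            out.append(item)
        else:
            out.append((item, f"cohort_{i}"))
    return out


def prevalence_profile(
    tables: list[tuple[TaxonProfileTable | FunctionProfileTable, str]],
) -> PrevalenceProfile:
    """Pooled + per-cohort prevalence of features over filtered tables.

    Presence is post-filter abundance > 0.  The pooled prevalence is the
    sample-weighted combination of the per-cohort values.
    """
    tables = _as_cohort_list(tables)
    if not tables:
        raise EmptyTableError("prevalence_profile needs at least one table")
    per_cohort = {}
    counts = {}
    present_total = None
    n_total = 0
    for table, cohort in tables:
        ab = table.abundance
        if ab.shape[0] == 0:
            raise EmptyTableError(f"cohort '{cohort}' has zero samples")
        pres = (ab > 0).sum(axis=0)
        per_cohort[cohort] = pres / ab.shape[0]
        counts[cohort] = ab.shape[0]
        present_total = pres if present_total is None else present_total.add(pres, fill_value=0)
        n_total += ab.shape[0]
    pooled = (present_total / n_total).fillna(0.0).sort_index()
    per = pd.DataFrame(per_cohort).reindex(pooled.index).fillna(0.0)
    return PrevalenceProfile(prevalence=pooled, per_cohort=per, n_samples=counts)


def derive_core_functions(
    healthy_tables: list[tuple[FunctionProfileTable, str]],
    threshold: float = 0.8,
    require_all_cohorts: bool = False,
) -> CoreFunctionSet:
    """Pathways with pooled healthy prevalence strictly above ``threshold``.

    ``require_all_cohorts`` additionally demands the per-cohort prevalence to
    exceed the threshold in every healthy cohort.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    healthy_tables = _as_cohort_list(healthy_tables)
    if not healthy_tables:
        raise EmptyTableError("derive_core_functions needs healthy tables")
    prof = prevalence_profile(healthy_tables)
    members = prof.prevalence.index[prof.prevalence > threshold]
    if require_all_cohorts:
        ok = (prof.per_cohort.loc[members] > threshold).all(axis=1)
        members = members[ok.to_numpy()]
    if len(members) == 0:
        warnings.warn("no pathway exceeds the core prevalence threshold", stacklevel=2)
    return CoreFunctionSet(
        pathway_ids=tuple(sorted(members)),
        prevalence_threshold=threshold,
        source=tuple(c for _, c in healthy_tables),
    )


def _qualify_pairs(
    corr_by_cohort: dict[str, CorrelationMatrix | pd.DataFrame],
    occurrence: dict[str, set[str]],
    min_corr: float,
) -> set[tuple[str, str]]:
    """Apply the two-clause pair rule to per-cohort correlation matrices.

    A pair qualifies iff rho > min_corr in >= 1 cohort AND rho >= 0 in every
    cohort in which both species occur.
    """
    mats = {
        c: (m.rho if isinstance(m, CorrelationMatrix) else m)
        for c, m in corr_by_cohort.items()
    }
    species = sorted(set().union(*(set(m.columns) for m in mats.values())))
    qualified = set()
    for a, b in itertools.combinations(species, 2):
        exceeds = False
        nonneg = True
        seen = False
        for cohort, m in mats.items():
            if a not in m.columns or b not in m.columns:
                continue
            if a not in occurrence.get(cohort, set()) or b not in occurrence.get(cohort, set()):
                continue
            seen = True
            rho = float(m.loc[a, b])
            if rho > min_corr:
                exceeds = True
            if rho < 0:
                nonneg = False
                break
        if seen and exceeds and nonneg:
            qualified.add((a, b))
    return qualified


def derive_healthy_pairs(
    healthy_cohort_tables: list[tuple[TaxonProfileTable, str]],
    min_corr: float = 0.1,
    species_subset: list[str] | None = None,
    seed: int = 0,
    **sparcc_params,
) -> HealthyPairSet:
    """Derive healthy co-occurring species pairs via per-cohort SparCC.

    ``species_subset`` optionally restricts candidates (a hook for an
    externally computed relevance selection).  When several cohorts are given
    and no subset is supplied, candidates default to species present in at
    least two cohorts.  Cohorts too small for SparCC are skipped with a
    warning; if every cohort is skipped an error is raised.
    """
    healthy_cohort_tables = _as_cohort_list(healthy_cohort_tables)
    if not healthy_cohort_tables:
        raise EmptyTableError("derive_healthy_pairs needs >= 1 healthy cohort")

    occurrence = {
        cohort: set(t.abundance.columns[(t.abundance > 0).any(axis=0)])
        for t, cohort in healthy_cohort_tables
    }
    if species_subset is None:
        if len(healthy_cohort_tables) >= 2:
            counts: dict[str, int] = {}
            for occ in occurrence.values():
                for s in occ:
                    counts[s] = counts.get(s, 0) + 1
            species_subset = sorted(s for s, k in counts.items() if k >= 2)
        else:
            species_subset = sorted(set().union(*occurrence.values()))
    subset = sorted(set(species_subset))

    corr_by_cohort: dict[str, pd.DataFrame] = {}
    for table, cohort in healthy_cohort_tables:
        cols = [s for s in subset if s in table.abundance.columns]
        sub = table.abundance[cols]
        try:
            cm = sparcc_correlations(sub, seed=seed, **sparcc_params)
        except DysbioError as exc:
            warnings.warn(f"cohort '{cohort}' skipped for SparCC: {exc}", stacklevel=2)
            continue
        corr_by_cohort[cohort] = cm.rho
    if not corr_by_cohort:
        raise DysbioError("every healthy cohort was too small for SparCC")

    occurrence = {c: occurrence[c] & set(subset) for c in corr_by_cohort}
    pairs = _qualify_pairs(corr_by_cohort, occurrence, min_corr)
    return HealthyPairSet(pairs=frozenset(pairs), min_corr=min_corr)


def derive_reference_assets(
    healthy_tax: list[tuple[TaxonProfileTable, str]],
    healthy_func: list[tuple[FunctionProfileTable, str]],
    core_threshold: float = 0.8,
    min_corr: float = 0.1,
    species_subset: list[str] | None = None,
    seed: int = 0,
    gmhi_good: tuple[str, ...] | None = None,
    gmhi_bad: tuple[str, ...] | None = None,
    **sparcc_params,
):
    """Convenience wrapper deriving both assets and bundling GMHI lists."""
    from dysbio.features import ReferenceAssets  # local import avoids a cycle

    core = derive_core_functions(healthy_func, threshold=core_threshold)
    pairs = derive_healthy_pairs(
        healthy_tax,
        min_corr=min_corr,
        species_subset=species_subset,
        seed=seed,
        **sparcc_params,
    )
    kwargs = {}
    if gmhi_good is not None:
        kwargs["gmhi_good"] = tuple(gmhi_good)
    if gmhi_bad is not None:
        kwargs["gmhi_bad"] = tuple(gmhi_bad)
    return ReferenceAssets(core_functions=core, healthy_pairs=pairs, **kwargs)
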