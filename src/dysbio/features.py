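"""The six per-sample health features.

All features are presence/absence summaries of *filtered* profiles — a cell
counts as present only if it survived the detection thresholds — so they are
invariant to abundance rescaling that crosses no threshold:

==============================  =============================================
Frac_of_core_functions_found    |sample ∩ core| / |core|
Frac_of_core_functions_among_all|sample ∩ core| / |functions in sample|
Species_found_together          fraction of reference pairs fully present
Func_contributions_per_species  distinct stratified (pathway, species)
                                entries / species present
GMHI_good, GMHI_bad             counts of GMHI list species present
==============================  =============================================

Degenerate samples (no species, no functions) score 0 on the affected
features, never NaN — shallow samples must remain scorable.
"""

from __future__ import annotations

import json
import hashlib
import warnings
from dataclasses import dataclass

import pandas as pd

from dysbio.errors import AlignmentError, ConfigurationError
from dysbio.gmhi_lists import GMHI_BAD_SPECIES, GMHI_GOOD_SPECIES
from dysbio.profile_io import FunctionProfileTable, TaxonProfileTable
from dysbio.references import CoreFunctionSet, HealthyPairSet

__all__ = [
    "FEATURE_COLUMNS",
    "ReferenceAssets",
    "frac_core_functions_found",
    "frac_core_among_all",
    "species_found_together",
    "func_contributions_per_species",
    "gmhi_species_counts",
    "build_feature_table",
]

FEATURE_COLUMNS: tuple[str, ...] = (
    "Frac_of_core_functions_found",
    "Frac_of_core_functions_among_all",
    "Species_found_together",
    "Func_contributions_per_species",
    "GMHI_good",
    "GMHI_bad",
)

_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ReferenceAssets:
    """Bundle of the assets needed to featurize a sample."""

    core_functions: CoreFunctionSet
    healthy_pairs: HealthyPairSet
    gmhi_good: tuple[str, ...] = GMHI_GOOD_SPECIES
    gmhi_bad: tuple[str, ...] = GMHI_BAD_SPECIES

    def __post_init__(self) -> None:
        if set(self.gmhi_good) & set(self.gmhi_bad):
            raise ConfigurationError("GMHI good and bad lists overlap")

    def sha256(self) -> str:
        """Stable content hash used to bind models to the assets they saw."""
        payload = json.dumps(
            {
                "core": sorted(self.core_functions.pathway_ids),
                "pairs": sorted(map(list, self.healthy_pairs.pairs)),
                "good": sorted(self.gmhi_good),
                "bad": sorted(self.gmhi_bad),
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "core_functions": sorted(self.core_functions.pathway_ids),
                    "core_prevalence_threshold": self.core_functions.prevalence_threshold,
                    "healthy_pairs": sorted(map(list, self.healthy_pairs.pairs)),
                    "pair_min_corr": self.healthy_pairs.min_corr,
                    "gmhi_good": list(self.gmhi_good),
                    "gmhi_bad": list(self.gmhi_bad),
                    "provenance": {"sha256": self.sha256()},
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ReferenceAssets":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            core_functions=CoreFunctionSet(
                pathway_ids=tuple(sorted(d["core_functions"])),
                prevalence_threshold=d.get("core_prevalence_threshold", 0.8),
            ),
            healthy_pairs=HealthyPairSet(
                pairs=frozenset(tuple(sorted(p)) for p in d["healthy_pairs"]),
                min_corr=d.get("pair_min_corr", 0.1),
            ),
            gmhi_good=tuple(d.get("gmhi_good", GMHI_GOOD_SPECIES)),
            gmhi_bad=tuple(d.get("gmhi_bad", GMHI_BAD_SPECIES)),
        )


def frac_core_functions_found(sample_functions: set[str], core: CoreFunctionSet) -> float:
    """|sample ∩ core| / |core|."""
    if len(core) == 0:
        raise ConfigurationError("core function set is empty")
    return len(sample_functions & set(core.pathway_ids)) / len(core)


def frac_core_among_all(sample_functions: set[str], core: CoreFunctionSet) -> float:
    """|sample ∩ core| / |sample|; 0 (with a warning) for empty samples."""
    if not sample_functions:
        warnings.warn("sample has no functions; Frac_of_core_functions_among_all = 0",
                      stacklevel=2)
        return 0.0
    return len(sample_functions & set(core.pathway_ids)) / len(sample_functions)


def species_found_together(sample_species: set[str], pairs: HealthyPairSet) -> float:
    """Fraction of reference pairs with both members present."""
    if len(pairs) == 0:
        raise ConfigurationError("healthy pair set is empty")
    hits = sum(1 for a, b in pairs.pairs if a in sample_species and b in sample_species)
    return hits / len(pairs)


def func_contributions_per_species(
    contributions: set[tuple[str, str]], n_species: int
) -> float:
    """Distinct nonzero (pathway, species) strata per species present.

    Unclassified strata are not species contributions and are ignored.
    """
    if n_species < 0:
        raise ValueError("species count must be >= 0")
    if n_species == 0:
        return 0.0
    n = sum(1 for _, taxon in contributions if taxon.lower() != _UNCLASSIFIED)
    return n / n_species


def gmhi_species_counts(
    sample_species: set[str],
    good: tuple[str, ...] = GMHI_GOOD_SPECIES,
    bad: tuple[str, ...] = GMHI_BAD_SPECIES,
) -> tuple[int, int]:
    """Counts of good- and bad-list species present in the sample."""
    if set(good) & set(bad):
        raise ConfigurationError("GMHI good and bad lists overlap")
    return len(sample_species & set(good)), len(sample_species & set(bad))


def build_feature_table(
    tax: TaxonProfileTable,
    func: FunctionProfileTable,
    refs: ReferenceAssets,
) -> pd.DataFrame:
    """One row per sample with the six features in fixed column order.

    Inputs must be filtered and sample-aligned; presence is abundance > 0.
    """
    if set(tax.sample_ids) != set(func.sample_ids):
        offenders = sorted(set(tax.sample_ids) ^ set(func.sample_ids))
        raise AlignmentError(
            f"samples present in only one of the profile tables: {offenders[:10]}"
        )
    rows = []
    core = refs.core_functions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate samples score 0 quietly here
        for sample in tax.sample_ids:
            sp_row = tax.abundance.loc[sample]
            species = set(sp_row.index[sp_row > 0])
            functions = func.nonzero_pathways(sample)
            contribs = func.nonzero_contributions(sample)
            good, bad = gmhi_species_counts(species, refs.gmhi_good, refs.gmhi_bad)
            rows.append(
                (
                    frac_core_functions_found(functions, core),
                    frac_core_among_all(functions, core),
                    species_found_together(species, refs.healthy_pairs),
                    func_contributions_per_species(contribs, len(species)),
                    good,
                    bad,
                )
            )
    return pd.DataFrame(rows, index=pd.Index(tax.sample_ids, name="sample"),
                        columns=list(FEATURE_COLUMNS))
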