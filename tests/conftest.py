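"""Shared fixtures: hand-built toy tables and small synthetic cohorts."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dysbio import (
    CoreFunctionSet,
    FunctionProfileTable,
    GeneratorConfig,
    HealthyPairSet,
    PathwayCoverageTable,
    ReferenceAssets,
    TaxonProfileTable,
    generate_cohort,
)


@pytest.fixture()
def toy_tax() -> TaxonProfileTable:
    """Three samples x four species (percent scale)."""
    return TaxonProfileTable(
        abundance=pd.DataFrame(
            {
                "Species_A": [5.0, 0.05, 0.1],
                "Species_B": [2.0, 1.0, 0.0],
                "Species_C": [0.05, 0.1, 2.0],
                "Species_D": [0.0, 3.0, 4.0],
            },
            index=["s1", "s2", "s3"],
        )
    )


@pytest.fixture()
def toy_func() -> FunctionProfileTable:
    strat = pd.DataFrame(
        {
            "s1": [10.0, 5.0, 2.0],
            "s2": [0.0, 3.0, 1.0],
            "s3": [4.0, 0.0, 0.5],
        },
        index=pd.MultiIndex.from_tuples(
            [("PWY-1", "Species_A"), ("PWY-1", "Species_B"), ("PWY-2", "Species_A")],
            names=["pathway", "taxon"],
        ),
    )
    return FunctionProfileTable(
        abundance=pd.DataFrame(
            {
                "PWY-1": [60.0, 30.0, 10.0],
                "PWY-2": [30.0, 0.005, 50.0],
                "PWY-3": [10.0, 69.995, 40.0],
            },
            index=["s1", "s2", "s3"],
        ),
        stratified=strat,
    )


@pytest.fixture()
def toy_cov(toy_func) -> PathwayCoverageTable:
    return PathwayCoverageTable(
        coverage=pd.DataFrame(
            {
                "PWY-1": [1.0, 1.0, 0.19],
                "PWY-2": [0.9, 0.9, 0.9],
                "PWY-3": [0.2, 1.0, 1.0],
            },
            index=["s1", "s2", "s3"],
        )
    )


@pytest.fixture()
def toy_refs() -> ReferenceAssets:
    return ReferenceAssets(
        core_functions=CoreFunctionSet(pathway_ids=("PWY-1", "PWY-2", "PWY-3", "PWY-4")),
        healthy_pairs=HealthyPairSet(
            pairs=frozenset({("Species_A", "Species_B"), ("Species_C", "Species_D")})
        ),
        gmhi_good=("Species_A",),
        gmhi_bad=("Species_C", "Species_D"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort reused across tests (deterministic)."""
    cfg = GeneratorConfig(n_healthy=30, n_dysbiotic=30, n_rare_species=40,
                          read_depth_mean=50_000, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


@pytest.fixture(scope="session")
def separable_features(small_cohort):
    """Feature table + labels computed against the cohort's ground truth."""
    from dysbio import apply_filters, build_feature_table

    refs = ReferenceAssets(
        core_functions=CoreFunctionSet(pathway_ids=small_cohort.truth.core_pathways),
        healthy_pairs=HealthyPairSet(pairs=small_cohort.truth.pairs),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tax_f, func_f = apply_filters(small_cohort.tax, small_cohort.func,
                                      small_cohort.coverage)
        feats = build_feature_table(tax_f, func_f, refs)
    return feats, small_cohort.labels, refs
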