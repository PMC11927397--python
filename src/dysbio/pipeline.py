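"""End-to-end pipelines: ingest -> filter -> derive -> featurize -> train -> score.

The training pipeline mirrors the published protocol shape: reference assets
are derived from the *healthy* samples of the training cohorts, features are
computed for every sample, a leave-one-cohort-out benchmark is run, the
final forest is retrained on all cohorts, and the operating threshold is the
mean of the per-iteration training thresholds from the benchmark.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import pandas as pd

from dysbio.classifier import (
    EvaluationReport,
    HealthIndexModel,
    HealthIndexResults,
    LabeledCohort,
    calibrate_final_threshold,
    leave_one_cohort_out,
)
from dysbio.errors import ConfigurationError, DysbioError
from dysbio.features import FEATURE_COLUMNS, ReferenceAssets, build_feature_table
from dysbio.profile_io import (
    FilterThresholds,
    FunctionProfileTable,
    PathwayCoverageTable,
    TaxonProfileTable,
    apply_filters,
)
from dysbio.references import derive_reference_assets

__all__ = ["CohortData", "PipelineResult", "derive_and_train", "score_samples",
           "save_model", "load_model"]

_MODEL_FORMAT_VERSION = 1


class _CohortLike(Protocol):
    tax: TaxonProfileTable
    func: FunctionProfileTable
    coverage: PathwayCoverageTable | None
    labels: pd.Series
    cohort_id: str


@dataclass
class CohortData:
    """Raw (unfiltered) profile tables plus labels for one cohort."""

    tax: TaxonProfileTable
    func: FunctionProfileTable
    coverage: PathwayCoverageTable | None
    labels: pd.Series
    cohort_id: str


@dataclass
class PipelineResult:
    """Everything the training pipeline produces, with provenance."""

    assets: ReferenceAssets
    results: HealthIndexResults
    report: EvaluationReport
    config_hash: str
    seed: int

    def summary(self) -> str:
        return "\n\n".join([
            self.results.summary(),
            self.report.summary(),
            f"config hash: {self.config_hash}  seed: {self.seed}",
        ])


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def derive_and_train(
    cohorts: Sequence[_CohortLike],
    thresholds: FilterThresholds = FilterThresholds(),
    core_threshold: float = 0.8,
    min_corr: float = 0.1,
    seed: int = 17,
    k_folds: int = 5,
    hyperparams: dict | None = None,
) -> PipelineResult:
    """Run the full training pipeline on labelled cohorts.

    References come from healthy samples only; the final threshold is the
    mean of the leave-one-cohort-out training thresholds.  Deterministic for
    a fixed seed and input.
    """
    if len(cohorts) < 2:
        raise DysbioError("derive_and_train needs >= 2 labelled cohorts")

    filtered: list[tuple[_CohortLike, TaxonProfileTable, FunctionProfileTable]] = []
    healthy_tax, healthy_func = [], []
    for c in cohorts:
        tax_f, func_f = apply_filters(c.tax, c.func, c.coverage, thresholds)
        filtered.append((c, tax_f, func_f))
        healthy = c.labels[c.labels == 1].index
        if len(healthy) == 0:
            raise DysbioError(
                f"cohort '{c.cohort_id}' has zero healthy samples; cannot "
                "derive healthy reference assets"
            )
        healthy_tax.append((TaxonProfileTable(tax_f.abundance.loc[healthy]),
                            c.cohort_id))
        strat = func_f.stratified
        healthy_func.append((
            FunctionProfileTable(
                abundance=func_f.abundance.loc[healthy],
                stratified=strat[healthy] if not strat.empty else strat,
            ),
            c.cohort_id,
        ))

    assets = derive_reference_assets(
        healthy_tax, healthy_func,
        core_threshold=core_threshold, min_corr=min_corr, seed=seed,
    )

    labeled = [
        LabeledCohort(build_feature_table(t, f, assets), c.labels, c.cohort_id)
        for c, t, f in filtered
    ]
    report = leave_one_cohort_out(labeled, seed=seed, k_folds=k_folds,
                                  hyperparams=hyperparams)
    final_threshold = calibrate_final_threshold(report.training_thresholds)

    model = HealthIndexModel.from_cohorts(labeled, hyperparams=hyperparams)
    results = model.fit(seed=seed, calibrate=False)
    results.threshold = float(final_threshold)
    results.refs_sha256 = assets.sha256()

    cfg_hash = _config_hash({
        "thresholds": vars(thresholds) if hasattr(thresholds, "__dict__")
        else {"species_min": thresholds.species_min,
              "pathway_coverage_min": thresholds.pathway_coverage_min,
              "function_min": thresholds.function_min},
        "core_threshold": core_threshold,
        "min_corr": min_corr,
        "seed": seed,
        "k_folds": k_folds,
        "cohorts": [c.cohort_id for c in cohorts],
        "refs": assets.sha256(),
    })
    return PipelineResult(assets=assets, results=results, report=report,
                          config_hash=cfg_hash, seed=seed)


def score_samples(
    results: HealthIndexResults,
    refs: ReferenceAssets,
    tax: TaxonProfileTable,
    func: FunctionProfileTable,
    coverage: PathwayCoverageTable | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    force: bool = False,
) -> pd.DataFrame:
    """Filter, featurize and score new samples with a fitted index.

    Refuses to score when the model was trained against different reference
    assets (hash mismatch) unless ``force`` is set.  The output carries the
    score, the healthy/dysbiotic call at the model threshold and the six
    feature values for interpretability.
    """
    if results.refs_sha256 is not None and results.refs_sha256 != refs.sha256():
        if not force:
            raise ConfigurationError(
                "reference-asset hash mismatch between model and refs "
                "(pass force=True to override)"
            )
        warnings.warn("scoring with mismatched reference assets (forced)",
                      stacklevel=2)
    tax_f, func_f = apply_filters(tax, func, coverage, thresholds)
    feats = build_feature_table(tax_f, func_f, refs)
    out = feats.copy()
    out.insert(0, "fhi", results.predict_health_score(feats))
    out.insert(1, "healthy_call", (out["fhi"] >= results.threshold).astype(int))
    return out


def save_model(results: HealthIndexResults, path) -> None:
    """Serialize a fitted index with feature order, threshold and asset hash."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "feature_order": list(results.feature_order),
        "threshold": results.threshold,
        "seed": results.seed,
        "refs_sha256": results.refs_sha256,
        "results": results,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> HealthIndexResults:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ConfigurationError("unsupported model file version")
    results: HealthIndexResults = payload["results"]
    if list(results.feature_order) != payload["feature_order"]:
        raise ConfigurationError("corrupt model file: feature order mismatch")
    return results
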