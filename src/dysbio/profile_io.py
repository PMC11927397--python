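"""Reading, validation and filtering of taxonomic / functional profile tables.

Two TSV dialects are understood for taxonomy:

* ``merged-metaphlan`` — rows are clade strings such as
  ``k__Bacteria|p__...|s__Escherichia_coli`` with one column per sample;
  only species-level rows (deepest clade ``s__``) are retained and the
  clade prefix is stripped to a canonical species name.
* ``plain-matrix`` — rows are species names, columns samples.

Functional tables follow the HUMAnN *pathabundance* dialect: community rows
``PWY-ID[: description]`` plus stratified rows
``PWY-ID[: description]|g__Genus.s__Genus_species`` attributing the pathway
to individual taxa.  ``UNMAPPED``/``UNINTEGRATED`` rows are bookkeeping, not
biology, and are dropped before any computation; community abundances are
then renormalized to percent of the retained total.

Filtering implements the detection thresholds applied before any feature is
computed: species abundance >= 0.1 %, pathway coverage >= 20 % and function
abundance >= 0.01 %, with cells below threshold set to zero (no
renormalization afterwards).  Cells exactly at a threshold are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dysbio.errors import AlignmentError, EmptyTableError, ProfileParseError

__all__ = [
    "TaxonProfileTable",
    "FunctionProfileTable",
    "PathwayCoverageTable",
    "FilterThresholds",
    "read_taxonomic_profile",
    "read_functional_profile",
    "read_coverage_table",
    "write_taxonomic_profile",
    "write_functional_profile",
    "apply_filters",
]

_SPECIAL_ROWS = {"UNMAPPED", "UNINTEGRATED"}
_SUM_TOL = 1e-6


def _check_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce to float, raising ProfileParseError naming the first bad cell."""
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.any().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise ProfileParseError(
            f"{path}: non-numeric cell at row '{row}', column '{col}': "
            f"{df.loc[row, col]!r}"
        )
    if coerced.isna().any().any():
        row = coerced.index[coerced.isna().any(axis=1)][0]
        col = coerced.columns[coerced.loc[row].isna()][0]
        raise ProfileParseError(f"{path}: missing value at row '{row}', column '{col}'")
    return coerced.astype(float)


@dataclass
class TaxonProfileTable:
    """Samples x species relative abundances in percent (0-100)."""

    abundance: pd.DataFrame  # index = sample_ids, columns = species_ids

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.columns.duplicated().any():
            dupes = ab.columns[ab.columns.duplicated()].tolist()
            raise ProfileParseError(f"duplicate species identifiers: {dupes}")
        if (ab.values < 0).any():
            raise ProfileParseError("negative abundance in taxonomic profile")
        sums = ab.sum(axis=1)
        if (sums > 100 + _SUM_TOL).any():
            offender = sums.idxmax()
            raise ProfileParseError(
                f"sample '{offender}' abundances sum to {sums.max():.6f} > 100"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean samples x species presence matrix (abundance > 0)."""
        return self.abundance > 0


@dataclass
class FunctionProfileTable:
    """Community-level pathway abundances plus stratified per-taxon rows.

    ``abundance``  : samples x pathways (percent).
    ``stratified`` : rows indexed by (pathway, taxon) MultiIndex, columns =
                     samples; values >= 0 on the same percent scale.
    """

    abundance: pd.DataFrame
    stratified: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.abundance.values < 0).any():
            raise ProfileParseError("negative abundance in functional profile")
        if self.stratified is None or self.stratified.empty:
            self.stratified = pd.DataFrame(
                index=pd.MultiIndex.from_arrays([[], []], names=["pathway", "taxon"]),
                columns=self.abundance.index,
                dtype=float,
            )
            return
        if (self.stratified.values < 0).any():
            raise ProfileParseError("negative stratified abundance")
        known = set(self.abundance.columns)
        orphans = [p for p in self.stratified.index.get_level_values(0) if p not in known]
        if orphans:
            raise ProfileParseError(
                f"stratified rows reference unknown pathways: {sorted(set(orphans))[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def nonzero_pathways(self, sample: str) -> set[str]:
        row = self.abundance.loc[sample]
        return set(row.index[row > 0])

    def nonzero_contributions(self, sample: str) -> set[tuple[str, str]]:
        """Distinct nonzero (pathway, taxon) stratified entries for a sample."""
        if self.stratified.empty:
            return set()
        col = self.stratified[sample]
        return set(col.index[col > 0])


@dataclass
class PathwayCoverageTable:
    """Samples x pathways coverage fractions in [0, 1]."""

    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.coverage.values
        if ((vals < 0) | (vals > 1)).any():
            raise ProfileParseError("coverage values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coverage.index)


@dataclass(frozen=True)
class FilterThresholds:
    """Detection thresholds (inclusive: cells exactly at a threshold survive)."""

    species_min: float = 0.1  # percent
    pathway_coverage_min: float = 0.2  # fraction
    function_min: float = 0.01  # percent

    def __post_init__(self) -> None:
        if min(self.species_min, self.pathway_coverage_min, self.function_min) < 0:
            raise ValueError("filter thresholds must be non-negative")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _species_from_clade(clade: str) -> str | None:
    """Return the species name if the clade string terminates at s__ level."""
    last = clade.split("|")[-1]
    if last.startswith("s__"):
        return last[len("s__"):]
    return None


def read_taxonomic_profile(path, dialect: str = "merged-metaphlan") -> TaxonProfileTable:
    """Read a taxonomic profile TSV in the given dialect.

    merged-metaphlan keeps only terminal species-level ("s__") clade rows and
    strips the clade prefix; plain-matrix passes the matrix through.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    if dialect == "merged-metaphlan":
        keep: dict[str, str] = {}
        for clade in df.index:
            sp = _species_from_clade(clade)
            if sp is not None:
                keep[clade] = sp
        if not keep:
            raise EmptyTableError(f"{path}: no species-level ('s__') rows found")
        df = df.loc[list(keep)].rename(index=keep)
    elif dialect != "plain-matrix":
        raise ValueError(f"unknown dialect: {dialect!r}")
    if df.shape[0] == 0:
        raise EmptyTableError(f"{path}: no species rows")
    df = _check_numeric(df, str(path))
    out = df.T
    out.index.name = None
    out.columns.name = None
    return TaxonProfileTable(abundance=out)


def _split_pathway_row(row: str) -> tuple[str, str | None]:
    """Parse 'PWY[: desc][|stratum]' into (pathway_id, taxon or None)."""
    if "|" in row:
        head, stratum = row.split("|", 1)
    else:
        head, stratum = row, None
    pwy = head.split(":", 1)[0].strip()
    if not pwy:
        raise ProfileParseError(f"malformed pathway row: {row!r}")
    taxon = None
    if stratum is not None:
        stratum = stratum.strip()
        if not stratum:
            raise ProfileParseError(f"malformed stratified row: {row!r}")
        # HUMAnN strata look like 'g__Genus.s__Genus_species' or 'unclassified'
        taxon = stratum
        for part in stratum.split("."):
            if part.startswith("s__"):
                taxon = part[len("s__"):]
                break
    return pwy, taxon


def read_functional_profile(path) -> FunctionProfileTable:
    """Read a HUMAnN-style pathabundance TSV.

    UNMAPPED / UNINTEGRATED rows (and their strata) are dropped, pathway
    descriptions stripped, stratified rows parsed into (pathway, taxon) keys
    and community abundances renormalized to percent of the retained total
    (stratified rows are rescaled by the same per-sample factor).  A
    stratified row without a parent community row synthesizes the parent as
    the sum of its strata, with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df = _check_numeric(df, str(path))
    samples = list(df.columns)

    community: dict[str, np.ndarray] = {}
    strat: dict[tuple[str, str], np.ndarray] = {}
    for row in df.index:
        pwy, taxon = _split_pathway_row(row)
        if pwy in _SPECIAL_ROWS:
            continue
        vals = df.loc[row].to_numpy(dtype=float)
        if taxon is None:
            community[pwy] = community.get(pwy, 0) + vals
        else:
            key = (pwy, taxon)
            strat[key] = strat.get(key, 0) + vals

    orphan_parents = sorted({p for p, _ in strat} - set(community))
    for pwy in orphan_parents:
        total = np.sum(
            [v for (p, _), v in strat.items() if p == pwy], axis=0
        )
        community[pwy] = total
    if orphan_parents:
        warnings.warn(
            "stratified rows without community parent; parents synthesized as "
            f"stratum sums: {orphan_parents[:5]}",
            stacklevel=2,
        )
    if not community:
        raise EmptyTableError(f"{path}: no pathway rows after dropping special rows")

    ab = pd.DataFrame(community, index=samples).sort_index(axis=1)
    totals = ab.sum(axis=1)
    factor = np.where(totals > 0, 100.0 / totals.replace(0, np.nan), 0.0)
    ab = ab.mul(factor, axis=0).fillna(0.0)

    if strat:
        sdf = pd.DataFrame(strat, index=samples).T
        sdf.index = pd.MultiIndex.from_tuples(sdf.index, names=["pathway", "taxon"])
        sdf = sdf.mul(factor, axis=1).sort_index()
    else:
        sdf = pd.DataFrame()
    return FunctionProfileTable(abundance=ab, stratified=sdf)


def read_coverage_table(path) -> PathwayCoverageTable:
    """Read a HUMAnN-style pathcoverage TSV (pathways x samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [_split_pathway_row(str(r))[0] for r in df.index]
    df = df.loc[[r for r in df.index if r not in _SPECIAL_ROWS]]
    df = _check_numeric(df, str(path))
    df = df.groupby(level=0).max()
    return PathwayCoverageTable(coverage=df.T)


def write_taxonomic_profile(table: TaxonProfileTable, path) -> None:
    """Write a plain species x samples matrix TSV."""
    table.abundance.T.to_csv(path, sep="\t", index_label="species")


def write_functional_profile(table: FunctionProfileTable, path) -> None:
    """Write community + stratified rows in the pathabundance dialect."""
    rows = table.abundance.T.copy()
    rows.index = rows.index.astype(str)
    out = [rows]
    if not table.stratified.empty:
        sdf = table.stratified.copy()
        sdf.index = [f"{p}|s__{t}" for p, t in sdf.index]
        out.append(sdf)
    pd.concat(out).to_csv(path, sep="\t", index_label="pathway")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def apply_filters(
    tax: TaxonProfileTable,
    func: FunctionProfileTable,
    cov: PathwayCoverageTable | None,
    thr: FilterThresholds = FilterThresholds(),
) -> tuple[TaxonProfileTable, FunctionProfileTable]:
    """Zero cells below the detection thresholds; no renormalization after.

    Species cells < species_min become 0.  Function cells — community and the
    pathway's stratified children alike — become 0 wherever the community
    abundance < function_min or the pathway's coverage < pathway_coverage_min.
    Missing coverage entries are treated as 1.0 with a warning.
    """
    tax_samples = list(tax.sample_ids)
    if list(func.sample_ids) != tax_samples:
        missing = sorted(set(tax_samples) ^ set(func.sample_ids))
        if missing:
            raise AlignmentError(f"sample mismatch between tables: {missing[:10]}")
        func = FunctionProfileTable(
            abundance=func.abundance.loc[tax_samples],
            stratified=(
                func.stratified[tax_samples] if not func.stratified.empty else func.stratified
            ),
        )

    tax_f = tax.abundance.where(tax.abundance >= thr.species_min, 0.0)

    ab = func.abundance
    if cov is None:
        cov_m = pd.DataFrame(1.0, index=ab.index, columns=ab.columns)
        warnings.warn("no coverage table supplied; coverage treated as 1.0", stacklevel=2)
    else:
        if set(cov.sample_ids) < set(tax_samples):
            missing = sorted(set(tax_samples) - set(cov.sample_ids))
            raise AlignmentError(f"coverage table missing samples: {missing[:10]}")
        cov_m = cov.coverage.reindex(index=ab.index, columns=ab.columns)
        if cov_m.isna().any().any():
            warnings.warn(
                "coverage missing for some (sample, pathway) cells; treated as 1.0",
                stacklevel=2,
            )
            cov_m = cov_m.fillna(1.0)

    keep = (ab >= thr.function_min) & (cov_m >= thr.pathway_coverage_min)
    ab_f = ab.where(keep, 0.0)

    strat = func.stratified
    if not strat.empty:
        # a stratified child survives only if its parent pathway survives
        parent_keep = keep.T  # pathways x samples
        mask = parent_keep.reindex(strat.index.get_level_values(0)).to_numpy()
        strat_f = pd.DataFrame(
            np.where(mask, strat.to_numpy(), 0.0),
            index=strat.index,
            columns=strat.columns,
        )
    else:
        strat_f = strat

    return (
        TaxonProfileTable(abundance=tax_f),
        FunctionProfileTable(abundance=ab_f, stratified=strat_f),
    )
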