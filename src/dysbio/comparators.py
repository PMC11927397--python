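"""Benchmark indices: Shannon entropy (taxa / functions) and the GMHI score.

These taxonomy- or richness-centred indices are the baselines the functional
health index is compared against.  The GMHI (Gupta et al. 2020) contrasts the
collective abundance of a fixed list of health-prevalent species against a
list of health-scarce species; a score above 0 calls the sample healthy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from dysbio.errors import ConfigurationError, DysbioError
from dysbio.features import ReferenceAssets
from dysbio.gmhi_lists import GMHI_BAD_SPECIES, GMHI_GOOD_SPECIES
from dysbio.profile_io import FunctionProfileTable, TaxonProfileTable

__all__ = ["shannon_entropy", "gmhi_score", "richness", "score_all_indices"]


def shannon_entropy(abundances, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero entries.

    The vector is renormalized to sum to 1 over its nonzero entries; the
    natural logarithm is the default base.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise DysbioError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise DysbioError("all-zero abundance vector has no entropy")
    p = x / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(abundances) -> int:
    """Number of nonzero features (the naive depth-sensitive comparator)."""
    return int((np.asarray(abundances) > 0).sum())


def gmhi_score(
    species_abundances: pd.Series,
    good: tuple[str, ...] = GMHI_GOOD_SPECIES,
    bad: tuple[str, ...] = GMHI_BAD_SPECIES,
    epsilon: float = 1e-5,
) -> float:
    """GMHI: log10 ratio of good-list to bad-list collective abundance.

    For each list M the collective abundance is the richness-weighted
    Shannon-like term

        psi_M = (R_M / |M|) * sum_{i in M present} n_i |ln n_i|

    with n_i the renormalized fractional abundances and R_M the number of
    list species present.  The score is log10((psi_good + eps)/(psi_bad + eps));
    eps is the pseudo-count of the reference implementation.  Score > 0
    classifies healthy.  A sample containing species from neither list
    scores 0 with a warning.
    """
    if set(good) & set(bad):
        raise ConfigurationError("GMHI good and bad lists overlap")
    x = species_abundances[species_abundances > 0]
    total = float(x.sum())
    if total <= 0:
        warnings.warn("empty sample; GMHI score 0", stacklevel=2)
        return 0.0
    n = x / total

    def psi(members: tuple[str, ...]) -> float:
        present = [s for s in members if s in n.index]
        if not present:
            return 0.0
        vals = n[present].to_numpy()
        return (len(present) / len(members)) * float(np.sum(vals * np.abs(np.log(vals))))

    psi_good, psi_bad = psi(good), psi(bad)
    if psi_good == 0.0 and psi_bad == 0.0:
        warnings.warn("sample contains no GMHI list species; score 0", stacklevel=2)
        return 0.0
    # difference of logs keeps the list-swap antisymmetry exact in floats
    return float(np.log10(psi_good + epsilon) - np.log10(psi_bad + epsilon))


def score_all_indices(
    tax: TaxonProfileTable,
    func: FunctionProfileTable,
    refs: ReferenceAssets,
    results=None,
) -> pd.DataFrame:
    """Score every index per sample: fhi, gmhi, shannon_taxa, shannon_functions.

    ``results`` is a fitted :class:`dysbio.classifier.HealthIndexResults`;
    when omitted the fhi column is left out with a warning.  Samples with no
    signal score 0 on the affected comparator.
    """
    from dysbio.features import build_feature_table

    rows = {}
    sh_t, sh_f, gm = [], [], []
    for sample in tax.sample_ids:
        sp = tax.abundance.loc[sample]
        fn = func.abundance.loc[sample]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sh_t.append(shannon_entropy(sp) if (sp > 0).any() else 0.0)
            sh_f.append(shannon_entropy(fn) if (fn > 0).any() else 0.0)
            gm.append(gmhi_score(sp, refs.gmhi_good, refs.gmhi_bad))
    rows["gmhi"] = gm
    rows["shannon_taxa"] = sh_t
    rows["shannon_functions"] = sh_f
    out = pd.DataFrame(rows, index=pd.Index(tax.sample_ids, name="sample"))
    if results is not None:
        feats = build_feature_table(tax, func, refs)
        out.insert(0, "fhi", results.predict_health_score(feats))
    else:
        warnings.warn("no fitted model supplied; fhi column omitted", stacklevel=2)
    return out
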