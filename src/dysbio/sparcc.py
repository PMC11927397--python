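"""SparCC compositional correlation estimator.

Relative-abundance data are compositional: the unit-sum constraint induces
spurious negative correlations between taxa.  SparCC (Friedman & Alm 2012)
estimates correlations between the *basis* (unobserved absolute) abundances
from the variances of pairwise log-ratios,

    t_ij = Var[ log(x_i / x_j) ] = w_i^2 + w_j^2 - 2 rho_ij w_i w_j,

under a sparsity assumption (most rho_ij ~ 0), which turns the row sums of
``t`` into a linear system for the basis variances w_i^2.  Strongly
correlated pairs violate sparsity, so the strongest pair above an exclusion
threshold is iteratively removed from the system and the variances re-solved.
Robustness to sampling noise comes from aggregating the estimate over
Dirichlet-resampled composition draws by the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dysbio.errors import DysbioError
from dysbio.profile_io import TaxonProfileTable

__all__ = ["CorrelationMatrix", "sparcc_correlations"]


@dataclass
class CorrelationMatrix:
    """Symmetric species x species correlation estimate in [-1, 1]."""

    species_ids: list[str]
    rho: pd.DataFrame
    n_iterations: int
    exclusion_corr: float

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        if not np.allclose(r, r.T, atol=1e-9):
            raise DysbioError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise DysbioError("correlation matrix diagonal must be 1")
        if (np.abs(r) > 1 + 1e-9).any():
            raise DysbioError("correlation entries must lie in [-1, 1]")


def _basis_variances(t: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    ``excluded`` is a boolean adjacency matrix of pairs removed from the
    system (strong correlations violating the sparsity assumption).
    """
    d = t.shape[0]
    mask = ~excluded
    np.fill_diagonal(mask, False)
    row_sums = np.where(mask, t, 0.0).sum(axis=1)
    n_partners = mask.sum(axis=1)
    # Sum_{j in partners(i)} t_ij ~= |partners(i)| w_i^2 + Sum_{j in partners(i)} w_j^2
    a = mask.astype(float)
    np.fill_diagonal(a, np.maximum(n_partners, 1))
    w2 = np.linalg.solve(a + np.eye(d) * 1e-12, row_sums)
    return np.clip(w2, 1e-12, None)


def _correlation_from_t(t: np.ndarray, w2: np.ndarray) -> np.ndarray:
    w = np.sqrt(w2)
    rho = (w2[:, None] + w2[None, :] - t) / (2.0 * np.outer(w, w))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_single(
    fractions: np.ndarray, exclusion_corr: float, exclusion_rounds: int
) -> np.ndarray:
    """One SparCC estimate from a samples x species fraction matrix."""
    logx = np.log(fractions)
    cov = np.cov(logx, rowvar=False)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    d = t.shape[0]

    excluded = np.zeros((d, d), dtype=bool)
    w2 = _basis_variances(t, excluded)
    rho = _correlation_from_t(t, w2)
    for _ in range(exclusion_rounds):
        cand = np.abs(np.where(excluded, 0.0, rho))
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_corr:
            break
        # never exclude a species from so many pairs the system degenerates
        if excluded[i].sum() >= d - 3 or excluded[j].sum() >= d - 3:
            break
        excluded[i, j] = excluded[j, i] = True
        w2 = _basis_variances(t, excluded)
        rho = _correlation_from_t(t, w2)
    return rho


def sparcc_correlations(
    table: TaxonProfileTable | pd.DataFrame,
    n_iterations: int = 20,
    exclusion_corr: float = 0.7,
    exclusion_rounds: int = 10,
    pseudo_count: float = 1e-6,
    resample_depth: float = 2000.0,
    seed: int = 0,
) -> CorrelationMatrix:
    """Estimate SparCC correlations between species.

    Parameters
    ----------
    table
        Samples x species relative abundances (percent or fractions); species
        with no nonzero value are dropped before estimation.
    n_iterations
        Number of Dirichlet-resampled composition draws aggregated by the
        median (the plain point estimate is always included as one draw).
    exclusion_corr, exclusion_rounds
        Threshold and maximum number of rounds for iterative exclusion of
        strongly correlated pairs from the basis-variance system.
    pseudo_count
        Added to zero fractions before taking log-ratios.
    resample_depth
        Effective count depth of the Dirichlet resampling; smaller values
        inject more resampling noise.
    seed
        Seed for the resampling; the estimate is deterministic given it.
    """
    if isinstance(table, TaxonProfileTable):
        df = table.abundance
    else:
        df = table
    df = df.loc[:, df.sum(axis=0) > 0]
    n, d = df.shape
    if d < 3:
        raise DysbioError(
            f"SparCC needs >= 3 species with signal, got {d} (basis system underdetermined)"
        )
    if n < 8:
        raise DysbioError(f"SparCC needs >= 8 samples, got {n}")

    x = df.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise DysbioError("sample with all-zero abundances")
    frac = x / totals
    frac = frac + pseudo_count
    frac = frac / frac.sum(axis=1, keepdims=True)
    if not np.isfinite(np.log(frac)).all():
        raise DysbioError("non-finite log-ratios after pseudo-count")

    rng = np.random.default_rng(seed)
    draws = [_sparcc_single(frac, exclusion_corr, exclusion_rounds)]
    alpha = frac * resample_depth
    for _ in range(max(n_iterations - 1, 0)):
        resampled = np.vstack([rng.dirichlet(alpha[k]) for k in range(n)])
        resampled = np.clip(resampled, 1e-12, None)
        resampled = resampled / resampled.sum(axis=1, keepdims=True)
        draws.append(_sparcc_single(resampled, exclusion_corr, exclusion_rounds))

    rho = np.median(np.stack(draws), axis=0)
    rho = (rho + rho.T) / 2.0
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    out = pd.DataFrame(rho, index=df.columns, columns=df.columns)
    return CorrelationMatrix(
        species_ids=list(df.columns),
        rho=out,
        n_iterations=n_iterations,
        exclusion_corr=exclusion_corr,
    )
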