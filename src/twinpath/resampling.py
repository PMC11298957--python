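"""Permutation significance for the AIC improvement and FDR correction.

The permutation null destroys both within-pair resemblance and zygosity
structure: all individuals are pooled, re-paired uniformly at random into
pseudo-pairs, and MZ/DZ labels reassigned preserving the original group
sizes.  The statistic is the AIC improvement of the best genetic model
over the E-only control, refitted on every permuted dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import TwinpathError
from .table import TwinPairTable
from .variance_models import (
    GENETIC_FACTORS,
    MODEL_COMPONENTS,
    fit_univariate,
    _as_pair_arrays,
)

__all__ = [
    "PermutationResult",
    "permute_twin_dataset",
    "permute_pair_arrays",
    "permutation_test_delta_aic",
    "bh_fdr",
]


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_values: np.ndarray
    n_perm: int
    p: float
    seed: int | None


def permute_pair_arrays(
    mz: np.ndarray, dz: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Re-pair all individuals at random, then reassign MZ/DZ group sizes."""
    pool = np.concatenate([np.asarray(mz, float).ravel(), np.asarray(dz, float).ravel()])
    if len(pool) % 2:
        raise TwinpathError("odd number of individuals cannot be re-paired")
    rng.shuffle(pool)
    pairs = pool.reshape(-1, 2)
    n_mz = len(mz)
    return pairs[:n_mz], pairs[n_mz:]


def permute_twin_dataset(
    data: TwinPairTable, seed: int | np.random.Generator | None = None,
    phenotype: str | None = None,
) -> TwinPairTable:
    """Permuted copy of a one-phenotype table (see module docstring).

    Group sizes and the multiset of phenotype values are conserved; the
    pairing and the zygosity structure are destroyed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mz = data.pairs(phenotype=phenotype, zygosity="MZ")
    dz = data.pairs(phenotype=phenotype, zygosity="DZ")
    pmz, pdz = permute_pair_arrays(mz, dz, rng)
    name = phenotype or (data.phenotypes[0] if len(data.phenotypes) == 1 else "phen")
    return TwinPairTable.from_arrays(pmz, pdz, phenotype=name)


def permutation_test_delta_aic(
    data,
    best_spec: str,
    n_perm: int = 10_000,
    seed: int | None = 0,
    phenotype: str | None = None,
    n_starts: int = 3,
) -> PermutationResult:
    """Permutation p for the AIC improvement of a genetic model over E.

    observed = AIC(E) - AIC(best_spec) on the real data; each null draw
    refits both models on a permuted dataset.  p uses the add-one formula
    (1 + #{null >= observed}) / (1 + n_perm), which can never be zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (GENETIC_FACTORS & set(MODEL_COMPONENTS[best_spec])):
        raise ValueError(f"best_spec {best_spec!r} contains no genetic factor")
    if isinstance(data, TwinPairTable):
        mz = data.pairs(phenotype=phenotype, zygosity="MZ")
        dz = data.pairs(phenotype=phenotype, zygosity="DZ")
    else:
        mz, dz = _as_pair_arrays(data)

    def delta(mzp, dzp) -> float:
        best = fit_univariate((mzp, dzp), best_spec, n_starts=n_starts)
        e = fit_univariate((mzp, dzp), "E")
        return e.aic - best.aic

    observed = delta(mz, dz)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        pmz, pdz = permute_pair_arrays(mz, dz, rng)
        null[b] = delta(pmz, pdz)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed=float(observed), null_values=null, n_perm=n_perm, p=float(p), seed=seed
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
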