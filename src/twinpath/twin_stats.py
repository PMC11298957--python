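"""Twin-pair correlation statistics.

Intraclass correlations (ICC) of a phenotype within monozygotic and
dizygotic pairs are the raw material of the classical twin design: a
markedly larger MZ than DZ correlation points at genetic variance.  This
module provides the per-group ICC with its one-tailed significance and
Fisher's Z comparison of two independent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError
from .table import TwinPairTable

__all__ = ["IccResult", "FisherZResult", "compute_icc", "fisher_z_compare"]


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation of one phenotype within one zygosity group."""

    r: float
    n_pairs: int
    p_one_tailed: float


@dataclass(frozen=True)
class FisherZResult:
    """Standard-normal deviate for the difference of two correlations."""

    z: float
    p_one_tailed: float


def compute_icc(
    pairs: np.ndarray | TwinPairTable,
    method: str = "anova",
    phenotype: str | None = None,
    zygosity: str | None = None,
) -> IccResult:
    """Intraclass correlation of twin pairs with a one-tailed p for r > 0.

    Parameters
    ----------
    pairs : (n, 2) array or TwinPairTable
        Twin-1 / twin-2 phenotype values of one zygosity group.  When a
        table is given, ``phenotype`` / ``zygosity`` select the column and
        group; missing pairs are dropped.
    method : {"anova", "double_entry"}
        ``"anova"`` is the one-way random-effects ICC(1,1), the canonical
        twin-pair estimator (admits negative estimates).  ``"double_entry"``
        is the Pearson correlation of the double-entered data.

    Notes
    -----
    With the one-way ANOVA decomposition into between-pair (MSB, n-1 df)
    and within-pair (MSW, n df) mean squares,

        ICC(1,1) = (MSB - MSW) / (MSB + MSW)

    and the one-tailed p comes from F = MSB/MSW on (n-1, n) df.  For the
    double-entry method the p is the one-tailed Pearson test on 2n pairs
    of double-entered values (conservative only as a rough guide; the
    ANOVA F-test is the default inferential route).
    """
    if isinstance(pairs, TwinPairTable):
        pairs = pairs.pairs(phenotype=phenotype, zygosity=zygosity)
    x = np.asarray(pairs, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, got {n}")
    grand = x.mean()
    pair_means = x.mean(axis=1)
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - pair_means[:, None]) ** 2) / n
    if msb + msw == 0.0:
        raise DegenerateDataError("zero between- and within-pair variance")

    if method == "anova":
        r = (msb - msw) / (msb + msw)
        if msw == 0.0:
            p = 0.0
        else:
            p = float(stats.f.sf(msb / msw, n - 1, n))
    elif method == "double_entry":
        a = np.concatenate([x[:, 0], x[:, 1]])
        b = np.concatenate([x[:, 1], x[:, 0]])
        if a.std() == 0.0:
            raise DegenerateDataError("constant phenotype")
        r = float(np.corrcoef(a, b)[0, 1])
        # one-tailed t-test treating the n distinct pairs as the unit
        t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
        p = float(stats.t.sf(t, n - 2))
    else:
        raise ValueError(f"unknown ICC method {method!r}")
    return IccResult(r=float(r), n_pairs=n, p_one_tailed=min(max(p, 0.0), 1.0))


def fisher_z_compare(
    r_mz: float, n_mz: int, r_dz: float, n_dz: int
) -> FisherZResult:
    """Fisher's Z test of rMZ > rDZ for two independent correlations.

    z = (atanh(r_mz) - atanh(r_dz)) / sqrt(1/(n_mz-3) + 1/(n_dz-3)),
    one-tailed p from the upper normal tail.
    """
    for r, n, lab in ((r_mz, n_mz, "MZ"), (r_dz, n_dz, "DZ")):
        if abs(r) >= 1.0:
            raise ValueError(f"|r_{lab}| must be < 1 for the z-transform")
        if n < 4:
            raise InsufficientDataError(f"n_{lab} must be >= 4")
    se = np.sqrt(1.0 / (n_mz - 3) + 1.0 / (n_dz - 3))
    z = (np.arctanh(r_mz) - np.arctanh(r_dz)) / se
    return FisherZResult(z=float(z), p_one_tailed=float(stats.norm.sf(z)))
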