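"""Synthetic twin phenotypes and expression matrices with known truth.

The generators emulate the statistical structure the analysis assumes:
twin pairs drawn from the model-implied bivariate (or 2p-variate) normal
per zygosity group, and region x gene expression with cluster-structured
mean shifts plus donor replicates of configurable consistency.  Dominance
is simulated at the pair level through the covariance structure — the
analysis only ever sees second moments, so this is exact.

Default pair counts mirror a typical twin-fMRI sample (113 MZ / 58 DZ);
recovery suites pass larger n explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .table import TwinPairTable
from .variance_models import VarianceComponents, twin_correlation_weights

__all__ = [
    "SimulationConfig",
    "simulate_univariate_twins",
    "simulate_cp_twins",
    "simulate_expression",
]

DEFAULT_N_MZ = 113
DEFAULT_N_DZ = 58


@dataclass
class SimulationConfig:
    """Bundle of generator settings (used by the CLI and pipeline driver)."""

    n_mz: int = DEFAULT_N_MZ
    n_dz: int = DEFAULT_N_DZ
    phenotypes: list[tuple[str, VarianceComponents]] = field(default_factory=list)
    factor_structure: dict | None = None
    expression: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_mz < 1 or self.n_dz < 1:
            raise ConfigError("pair counts must be >= 1")


def _pair_cov(components: VarianceComponents, zygosity: str) -> np.ndarray:
    wa, wd = twin_correlation_weights(zygosity)
    v = components.total
    c = wa * components.a2 + components.c2 + wd * components.d2
    return np.array([[v, c], [c, v]])


def simulate_univariate_twins(
    truth: VarianceComponents,
    n_mz: int = DEFAULT_N_MZ,
    n_dz: int = DEFAULT_N_DZ,
    mean: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    phenotype: str = "phen",
) -> TwinPairTable:
    """Draw twin pairs from the model-implied bivariate normal per group."""
    if truth.total <= 0:
        raise ConfigError("truth must have positive total variance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mz = rng.multivariate_normal([mean, mean], _pair_cov(truth, "MZ"), size=n_mz)
    dz = rng.multivariate_normal([mean, mean], _pair_cov(truth, "DZ"), size=n_dz)
    return TwinPairTable.from_arrays(mz, dz, phenotype=phenotype)


def simulate_cp_twins(
    loadings: np.ndarray,
    factor_components: Sequence[VarianceComponents],
    specific_components: Sequence[VarianceComponents],
    n_mz: int = DEFAULT_N_MZ,
    n_dz: int = DEFAULT_N_DZ,
    means: Sequence[float] | None = None,
    seed: int | np.random.Generator | None = 0,
    phenotypes: Sequence[str] | None = None,
) -> TwinPairTable:
    """Draw multivariate twin pairs from a common-pathway truth.

    Each latent factor has unit variance split into its own A/C/D/E
    shares (so cross-twin factor covariance is the zygosity-weighted
    genetic + shared-environment part); factors propagate through the
    loading matrix, and phenotype-specific components are added with the
    same zygosity weighting.
    """
    lam = np.atleast_2d(np.asarray(loadings, dtype=float))
    p, m = lam.shape
    if len(factor_components) != m:
        raise ConfigError("factor_components length must equal the factor count")
    if len(specific_components) != p:
        raise ConfigError("specific_components length must equal the phenotype count")
    for fc in factor_components:
        if abs(fc.total - 1.0) > 1e-8:
            raise ConfigError("factor components must sum to 1 (unit factor variance)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if means is None:
        means = np.zeros(p)
    means = np.asarray(means, dtype=float)
    if phenotypes is None:
        phenotypes = [f"phen{j+1}" for j in range(p)]

    def draw(zygosity: str, n: int) -> np.ndarray:
        wa, wd = twin_correlation_weights(zygosity)
        # factors: (n, m) per twin with cross-twin correlation r_f
        eta = np.empty((n, 2, m))
        for f, fc in enumerate(factor_components):
            r = wa * fc.a2 + fc.c2 + wd * fc.d2
            cov = np.array([[1.0, r], [r, 1.0]])
            eta[:, :, f] = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        y = np.empty((n, 2, p))
        for t in range(2):
            y[:, t, :] = eta[:, t, :] @ lam.T
        for j, sc in enumerate(specific_components):
            cov = _pair_cov(sc, zygosity)
            y[:, :, j] += rng.multivariate_normal([0.0, 0.0], cov, size=n)
        y += means[None, None, :]
        # wide layout: (phen1_t1..phenp_t1, phen1_t2..phenp_t2)
        return np.concatenate([y[:, 0, :], y[:, 1, :]], axis=1)

    return TwinPairTable.from_wide(draw("MZ", n_mz), draw("DZ", n_dz), phenotypes)


def simulate_expression(
    n_clusters: int = 6,
    n_regions_per_cluster: int = 4,
    n_genes: int = 200,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    informative_fraction: float = 0.2,
    n_donors: int = 2,
    inter_donor_corr: float = 0.5,
    seed: int | np.random.Generator | None = 0,
) -> tuple[list[pd.DataFrame], pd.Series, np.ndarray]:
    """Cluster-structured region x gene expression with donor replicates.

    A random ``informative_fraction`` of genes receives a per-cluster mean
    shift of ``effect_size`` (in units of ``noise_sd``); all genes get
    Gaussian noise of which a ``inter_donor_corr`` share of variance is
    common to donors, so uninformative genes have inter-donor expression
    correlation ~ ``inter_donor_corr`` and informative genes more.

    Returns (per-donor matrices as region x gene DataFrames, true cluster
    labels indexed by region, boolean informative-gene mask).
    """
    if effect_size < 0:
        raise ConfigError("effect size must be nonnegative")
    if n_clusters < 2 or n_regions_per_cluster < 2:
        raise ConfigError("need >=2 clusters and >=2 regions per cluster")
    if not 0.0 <= inter_donor_corr <= 1.0:
        raise ConfigError("inter_donor_corr must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_regions = n_clusters * n_regions_per_cluster
    regions = [f"region{i:03d}" for i in range(n_regions)]
    genes = [f"gene{g:05d}" for g in range(n_genes)]
    labels = pd.Series(
        np.repeat(np.arange(n_clusters), n_regions_per_cluster),
        index=regions, name="cluster",
    )
    n_info = int(round(informative_fraction * n_genes))
    informative = np.zeros(n_genes, dtype=bool)
    informative[rng.choice(n_genes, size=n_info, replace=False)] = True

    signal = np.zeros((n_regions, n_genes))
    shift = effect_size * noise_sd
    # informative genes partitioned into disjoint per-cluster signature
    # blocks, so every cluster pair differs by the full shift on the union
    # of their blocks (between-cluster contrast equals the effect size)
    info_idx = rng.permutation(np.flatnonzero(informative))
    blocks = np.array_split(info_idx, n_clusters)
    for c in range(n_clusters):
        signal[np.ix_(labels.to_numpy() == c, blocks[c])] += shift

    shared = rng.normal(scale=noise_sd, size=(n_regions, n_genes))
    donors = []
    for d in range(n_donors):
        own = rng.normal(scale=noise_sd, size=(n_regions, n_genes))
        noise = np.sqrt(inter_donor_corr) * shared + np.sqrt(1 - inter_donor_corr) * own
        donors.append(pd.DataFrame(signal + noise, index=regions, columns=genes))
    return donors, labels, informative
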