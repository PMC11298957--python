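"""Common-pathway (CP) multivariate twin models and loading-space clustering.

In the CP model, m latent common factors — each with unit variance split
into its own additive-genetic / dominance (or shared-environment) /
unique-environment shares — load onto p phenotypes through a loading
matrix, and each phenotype keeps its own specific A/D(/C)/E components.
The cross-twin cross-trait covariance therefore follows

    Cov_g(y_twin1, y_twin2) = L diag(r_gf) L' + diag(specific cross-twin)

with r_gf the zygosity-weighted genetic + shared-environment share of
factor f (weights 1/1 for MZ, 0.5/0.25 for DZ additive/dominance).

Identification: factor variances fixed at 1 (loadings carry scale), the
upper-right triangle of the loading matrix fixed at 0 for m > 1 (echelon
form), and each factor's first nonzero loading made nonnegative.

Clustering of phenotypes by their loading vectors uses k-means with the
gap statistic (uniform-box reference sets, first-SE-max rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .errors import ConfigError, ConvergenceError, DegenerateDataError
from .table import TwinPairTable
from .variance_models import VarianceComponents, twin_correlation_weights

__all__ = [
    "CPModelFit",
    "ClusterSolution",
    "CommonPathwayModel",
    "GapKMeans",
    "fit_cp",
    "select_n_factors",
    "shared_genetic_factor",
    "cluster_loadings",
]


@dataclass(frozen=True)
class CPModelFit:
    """A fitted common-pathway model."""

    loadings: np.ndarray  # (p, m)
    factor_components: tuple[VarianceComponents, ...]  # per factor, sum 1
    specific_components: tuple[VarianceComponents, ...]  # per phenotype
    means: np.ndarray  # (p,)
    minus2ll: float
    n_params: int
    variance_model: str
    phenotypes: tuple[str, ...]
    converged: bool = True

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.n_params

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def implied_covariance(self, zygosity: str) -> np.ndarray:
        """Model-implied 2p x 2p twin-pair covariance for one group."""
        return _implied_cov(
            self.loadings, self.factor_components, self.specific_components, zygosity
        )


@dataclass(frozen=True)
class ClusterSolution:
    """k-means partition of phenotypes in loading space."""

    assignments: pd.Series  # phenotype -> cluster id
    k: int
    gap_curve: pd.DataFrame  # columns k, gap, se, log_w


# ---------------------------------------------------------------------------
# likelihood machinery


def _implied_cov(lam, factor_comps, specific_comps, zygosity):
    wa, wd = twin_correlation_weights(zygosity)
    lam = np.atleast_2d(lam)
    r = np.array([wa * f.a2 + f.c2 + wd * f.d2 for f in factor_comps])
    spec_tot = np.array([s.total for s in specific_comps])
    spec_x = np.array([wa * s.a2 + s.c2 + wd * s.d2 for s in specific_comps])
    within = lam @ lam.T + np.diag(spec_tot)
    cross = lam @ (r[:, None] * lam.T) + np.diag(spec_x)
    return np.block([[within, cross], [cross.T, within]])


@dataclass(frozen=True)
class _WideStats:
    """Sufficient statistics of one group's (n, 2p) pair matrix."""

    n: int
    m1: np.ndarray  # column means
    m2: np.ndarray  # (1/n) Z'Z

    @classmethod
    def from_wide(cls, z: np.ndarray) -> "_WideStats":
        z = np.asarray(z, dtype=float)
        return cls(n=len(z), m1=z.mean(axis=0), m2=(z.T @ z) / len(z))

    def scatter(self, mu_wide: np.ndarray) -> np.ndarray:
        d = np.outer(self.m1, mu_wide)
        return self.m2 - d - d.T + np.outer(mu_wide, mu_wide)


_BIG = 1e12


def _group_m2ll(g: _WideStats, sigma: np.ndarray, mu_wide: np.ndarray) -> float:
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return _BIG
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    s = g.scatter(mu_wide)
    inv_s = np.linalg.solve(sigma, s)
    tr = np.trace(inv_s)
    d = sigma.shape[0]
    return g.n * (logdet + tr + d * np.log(2.0 * np.pi))


class _CPParam:
    """Packing/unpacking of the CP parameter vector.

    Layout: [means (p)] [free loadings (echelon)] [factor paths (3 per
    factor, squared then normalised to sum 1)] [specific paths (3 per
    phenotype, squared; e2 floored)].
    """

    def __init__(self, p, m, floor, factor_genetic_free=True):
        self.p, self.m, self.floor = p, m, floor
        self.factor_genetic_free = factor_genetic_free
        self.free_idx = [(j, f) for f in range(m) for j in range(p) if f <= j or m == 1]
        if m == 1:
            self.free_idx = [(j, 0) for j in range(p)]
        self.n_loadings = len(self.free_idx)
        self.n_factor_paths = (3 if factor_genetic_free else 1) * m
        self.size = p + self.n_loadings + self.n_factor_paths + 3 * p

    @property
    def n_params(self) -> int:
        # effective free parameters: sum-to-1 removes one df per factor
        per_factor = 2 if self.factor_genetic_free else 0
        return self.p + self.n_loadings + per_factor * self.m + 3 * self.p

    def unpack(self, theta):
        p, m = self.p, self.m
        mu = theta[:p]
        lam = np.zeros((p, m))
        off = p
        for (j, f), t in zip(self.free_idx, theta[off : off + self.n_loadings]):
            lam[j, f] = t
        off += self.n_loadings
        fcs = []
        for f in range(m):
            if self.factor_genetic_free:
                ta, tx, te = theta[off : off + 3]
                off += 3
                sq = np.array([ta * ta, tx * tx, te * te]) + 1e-12
                sq /= sq.sum()
                fcs.append(self._vc(sq[0], sq[1], sq[2]))
            else:
                off += 1
                fcs.append(VarianceComponents(e2=1.0))
        scs = []
        for j in range(p):
            ta, tx, te = theta[off : off + 3]
            off += 3
            scs.append(self._vc(ta * ta, tx * tx, te * te + self.floor[j]))
        return mu, lam, tuple(fcs), tuple(scs)

    def _vc(self, a2, x2, e2):
        raise NotImplementedError


class _ADEParam(_CPParam):
    def _vc(self, a2, x2, e2):
        return VarianceComponents(a2=a2, d2=x2, e2=e2)


class _ACEParam(_CPParam):
    def _vc(self, a2, x2, e2):
        return VarianceComponents(a2=a2, c2=x2, e2=e2)


# ---------------------------------------------------------------------------
# estimator


class CommonPathwayModel(BaseEstimator):
    """Maximum-likelihood common-pathway twin model.

    Parameters
    ----------
    n_factors : int
        Number of common latent factors m (1 <= m <= p).
    variance_model : {"ADE", "ACE"}
        Decomposition used for both factor and specific components.
    n_starts : int
        Optimiser multi-starts (moment-based start + seeded perturbations).
    random_state : int
    factor_genetic_free : bool
        When False the factors are forced pure-E (used for the
        shared-genetic-factor likelihood-ratio test).

    Attributes
    ----------
    loadings_, factor_components_, specific_components_, means_,
    minus2ll_, aic_, n_params_, result_
    """

    def __init__(
        self,
        n_factors: int = 1,
        variance_model: str = "ADE",
        n_starts: int = 5,
        random_state: int = 0,
        max_iter: int = 3000,
        factor_genetic_free: bool = True,
    ):
        self.n_factors = n_factors
        self.variance_model = variance_model
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_iter = max_iter
        self.factor_genetic_free = factor_genetic_free

    def fit(self, X, y=None):
        """Fit on a TwinPairTable or ((n_mz, 2p), (n_dz, 2p), phenotypes)."""
        if isinstance(X, TwinPairTable):
            phen = X.phenotypes
            mz = X.values_wide(zygosity="MZ")
            dz = X.values_wide(zygosity="DZ")
        else:
            mz, dz, phen = X
            phen = tuple(phen)
        p = len(phen)
        m = self.n_factors
        if not 1 <= m <= p:
            raise ConfigError(f"n_factors must lie in [1, {p}], got {m}")
        if len(mz) < 3 or len(dz) < 3:
            raise DegenerateDataError("need >=3 complete pairs per zygosity group")
        if self.variance_model == "ADE":
            param_cls = _ADEParam
        elif self.variance_model == "ACE":
            param_cls = _ACEParam
        else:
            raise ValueError(f"variance_model must be ADE or ACE")

        gmz = _WideStats.from_wide(mz)
        gdz = _WideStats.from_wide(dz)
        # per-phenotype pooled variances for scaling and the e2 floor
        all_ind = np.concatenate(
            [mz[:, :p], mz[:, p:], dz[:, :p], dz[:, p:]], axis=0
        )
        pooled_var = all_ind.var(axis=0)
        if np.any(pooled_var <= 0):
            raise DegenerateDataError("zero phenotype variance")
        floor = 1e-8 * pooled_var
        packer = param_cls(p, m, floor, self.factor_genetic_free)

        def objective(theta):
            mu, lam, fcs, scs = packer.unpack(theta)
            mu_wide = np.concatenate([mu, mu])
            total = 0.0
            for g, zyg in ((gmz, "MZ"), (gdz, "DZ")):
                sigma = _implied_cov(lam, fcs, scs, zyg)
                total += _group_m2ll(g, sigma, mu_wide)
            return total

        rng = np.random.default_rng(self.random_state)
        base = self._start(packer, gmz, gdz, pooled_var, p, m)
        best = None
        for s in range(max(1, self.n_starts)):
            x0 = base.copy()
            if s > 0:
                x0 += 0.3 * np.abs(base).mean() * rng.standard_normal(len(base))
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-8},
            )
            # polish with a simplex pass; helps on the ridge-shaped surface
            res2 = optimize.minimize(
                objective, res.x, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-8, "maxiter": 4000},
            )
            cand = res2 if res2.fun <= res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
        if best is None or not np.isfinite(best.fun) or best.fun >= _BIG / 2:
            raise ConvergenceError("CP fit did not converge", best=best)

        mu, lam, fcs, scs = packer.unpack(best.x)
        lam = _fix_signs(lam)
        self.means_ = np.asarray(mu, dtype=float)
        self.loadings_ = lam
        self.factor_components_ = fcs
        self.specific_components_ = scs
        self.minus2ll_ = float(best.fun)
        self.n_params_ = packer.n_params
        self.aic_ = self.minus2ll_ + 2.0 * self.n_params_
        self.result_ = CPModelFit(
            loadings=lam,
            factor_components=fcs,
            specific_components=scs,
            means=self.means_,
            minus2ll=self.minus2ll_,
            n_params=self.n_params_,
            variance_model=self.variance_model,
            phenotypes=phen,
            converged=True,
        )
        return self

    @staticmethod
    def _start(packer, gmz, gdz, pooled_var, p, m):
        """Moment start: principal axes of the pooled within-twin covariance."""
        mu0 = 0.5 * (gmz.m1[:p] + gmz.m1[p:])
        n_tot = gmz.n + gdz.n
        m2 = (gmz.n * gmz.m2 + gdz.n * gdz.m2) / n_tot
        m1 = (gmz.n * gmz.m1 + gdz.n * gdz.m1) / n_tot
        cov_full = m2 - np.outer(m1, m1)
        cov_w = 0.5 * (cov_full[:p, :p] + cov_full[p:, p:])
        w, v = np.linalg.eigh(cov_w)
        order = np.argsort(w)[::-1]
        lam0 = np.zeros((p, m))
        for f in range(m):
            lam0[:, f] = v[:, order[f]] * np.sqrt(max(w[order[f]], 1e-6) * 0.5)
        theta = list(mu0)
        for (j, f) in packer.free_idx:
            theta.append(lam0[j, f])
        for _ in range(packer.m):
            if packer.factor_genetic_free:
                theta += [0.6, 0.5, 0.6]
            else:
                theta += [0.0]
        for j in range(p):
            resid = max(pooled_var[j] - (lam0[j] ** 2).sum(), 0.1 * pooled_var[j])
            theta += [np.sqrt(resid / 3.0)] * 3
        return np.asarray(theta, dtype=float)


def _fix_signs(lam: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """First nonzero loading per factor made nonnegative (sign convention)."""
    lam = lam.copy()
    for f in range(lam.shape[1]):
        col = lam[:, f]
        nz = np.flatnonzero(np.abs(col) > tol)
        if len(nz) and col[nz[0]] < 0:
            lam[:, f] = -col
    return lam


# ---------------------------------------------------------------------------
# functional wrappers


def fit_cp(
    data,
    m: int = 1,
    variance_model: str = "ADE",
    n_starts: int = 5,
    random_state: int = 0,
) -> CPModelFit:
    """Fit an m-factor common-pathway model and return its CPModelFit."""
    est = CommonPathwayModel(
        n_factors=m, variance_model=variance_model,
        n_starts=n_starts, random_state=random_state,
    )
    est.fit(data)
    return est.result_


def select_n_factors(
    data,
    m_max: int,
    variance_model: str = "ADE",
    criterion: str = "aic",
    alpha: float = 0.05,
    n_starts: int = 5,
    random_state: int = 0,
) -> int:
    """Smallest m at which adding a factor stops improving the fit.

    ``criterion="aic"`` stops when AIC no longer decreases;
    ``criterion="lrt"`` when the nested chi-square test fails at ``alpha``.
    """
    prev = fit_cp(data, 1, variance_model, n_starts, random_state)
    for m in range(2, m_max + 1):
        cur = fit_cp(data, m, variance_model, n_starts, random_state)
        if criterion == "aic":
            improves = cur.aic < prev.aic
        elif criterion == "lrt":
            chi2 = max(0.0, prev.minus2ll - cur.minus2ll)
            df = cur.n_params - prev.n_params
            improves = stats.chi2.sf(chi2, df) < alpha
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if not improves:
            return m - 1
        prev = cur
    return m_max


def shared_genetic_factor(
    data,
    variance_model: str = "ADE",
    alpha: float = 0.05,
    n_starts: int = 5,
    random_state: int = 0,
) -> dict:
    """One-factor CP fit plus a test of the factor's genetic component.

    The likelihood-ratio test compares the m=1 CP model against the same
    model with the factor's genetic shares fixed at zero (pure-E factor).
    Returns a dict with the fit, the chi2/df/p of the test, the
    significance flag, and the loading signs (a negative loading flags an
    oppositely-directed phenotype).
    """
    full_est = CommonPathwayModel(
        n_factors=1, variance_model=variance_model,
        n_starts=n_starts, random_state=random_state,
    ).fit(data)
    null_est = CommonPathwayModel(
        n_factors=1, variance_model=variance_model,
        n_starts=n_starts, random_state=random_state,
        factor_genetic_free=False,
    ).fit(data)
    chi2 = max(0.0, null_est.minus2ll_ - full_est.minus2ll_)
    df = full_est.n_params_ - null_est.n_params_
    p = float(stats.chi2.sf(chi2, df))
    fit = full_est.result_
    return {
        "fit": fit,
        "chi2": chi2,
        "df": df,
        "p": p,
        "genetic": bool(p < alpha),
        "loading_signs": np.sign(fit.loadings[:, 0]),
    }


# ---------------------------------------------------------------------------
# gap-statistic clustering


class GapKMeans(BaseEstimator):
    """k-means over loading vectors with gap-statistic model selection.

    The gap statistic compares log within-cluster dispersion against
    uniform-box reference draws; the number of clusters is the smallest k
    whose gap is within one reference standard error of the next k
    (first-SE-max rule).

    Parameters
    ----------
    k_range : sequence of int
    b_refs : int
        Number of uniform reference sets (ignored when ``reference_sets``
        is given explicitly, e.g. for cross-implementation checks).
    n_init : int
        k-means restarts per k.
    random_state : int
    """

    def __init__(
        self,
        k_range=(1, 2, 3, 4, 5, 6),
        b_refs: int = 100,
        n_init: int = 100,
        random_state: int = 0,
        reference_sets=None,
    ):
        self.k_range = k_range
        self.b_refs = b_refs
        self.n_init = n_init
        self.random_state = random_state
        self.reference_sets = reference_sets

    @staticmethod
    def _inertia(x, k, n_init, seed) -> tuple[float, np.ndarray]:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        return float(km.inertia_), km.labels_

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        if isinstance(X, pd.DataFrame):
            index = X.index
        else:
            index = pd.RangeIndex(len(x))
        ks = sorted(self.k_range)
        if ks[-1] > len(x):
            raise ValueError("k_range exceeds the number of points")
        total_ss = float(((x - x.mean(axis=0)) ** 2).sum())
        if total_ss < 1e-12:  # all points identical
            self.k_ = 1
            self.labels_ = np.zeros(len(x), dtype=int)
            self.gap_curve_ = pd.DataFrame(
                {"k": ks, "gap": np.nan, "se": np.nan, "log_w": np.nan}
            )
            self.assignments_ = pd.Series(self.labels_, index=index)
            return self

        rng = np.random.default_rng(self.random_state)
        if self.reference_sets is not None:
            refs = [np.asarray(r, dtype=float) for r in self.reference_sets]
        else:
            lo, hi = x.min(axis=0), x.max(axis=0)
            refs = [
                rng.uniform(lo, hi, size=x.shape) for _ in range(self.b_refs)
            ]

        log_w = np.empty(len(ks))
        gap = np.empty(len(ks))
        se = np.empty(len(ks))
        labels_by_k = {}
        for i, k in enumerate(ks):
            w, labels = self._inertia(x, k, self.n_init, self.random_state)
            labels_by_k[k] = labels
            log_w[i] = np.log(max(w, 1e-300))
            ref_log_w = np.array(
                [
                    np.log(max(self._inertia(r, k, self.n_init, self.random_state)[0], 1e-300))
                    for r in refs
                ]
            )
            gap[i] = ref_log_w.mean() - log_w[i]
            b = len(refs)
            se[i] = ref_log_w.std(ddof=0) * np.sqrt(1.0 + 1.0 / b)

        k_opt = ks[-1]
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                k_opt = ks[i]
                break
        self.k_ = int(k_opt)
        self.labels_ = labels_by_k[k_opt]
        self.gap_curve_ = pd.DataFrame({"k": ks, "gap": gap, "se": se, "log_w": log_w})
        self.assignments_ = pd.Series(self.labels_, index=index)
        return self


def cluster_loadings(
    fit: CPModelFit | np.ndarray,
    k_range=(1, 2, 3, 4, 5, 6),
    b_refs: int = 100,
    seed: int = 0,
    n_init: int = 100,
    reference_sets=None,
) -> ClusterSolution:
    """Cluster phenotypes by their loading vectors (gap-statistic k-means)."""
    if isinstance(fit, CPModelFit):
        x = pd.DataFrame(fit.loadings, index=list(fit.phenotypes))
    else:
        x = pd.DataFrame(np.asarray(fit, dtype=float))
    est = GapKMeans(
        k_range=k_range, b_refs=b_refs, n_init=n_init,
        random_state=seed, reference_sets=reference_sets,
    ).fit(x)
    return ClusterSolution(assignments=est.assignments_, k=est.k_, gap_curve=est.gap_curve_)
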