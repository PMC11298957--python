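"""Maximum-likelihood fitting of classical twin variance-decomposition models.

The classical twin design decomposes phenotypic variance into additive
genetic (A), common-environment (C), dominance genetic (D) and unique
environment (E) components from the contrast between monozygotic twins
(sharing all segregating genes) and dizygotic twins (sharing half of the
additive and a quarter of the dominance variance).  C and D are confounded
and never estimated jointly, so the model family is {ACE, ADE, AE, CE, DE,
E}.

Each model is fitted by maximising the two-group bivariate-normal
likelihood of the raw pair vectors, with a single mean shared across twin
order and zygosity groups and the model-implied covariance structure.
Variance components are parameterised as squared free path coefficients,
so estimates respect nonnegativity without constrained optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, DegenerateDataError, NestingError
from .table import TwinPairTable

__all__ = [
    "MODEL_COMPONENTS",
    "VarianceComponents",
    "ModelFit",
    "FitComparison",
    "TwinVarianceModel",
    "expected_covariance",
    "fit_univariate",
    "fit_all_models",
    "compare_fits",
]

#: free variance components of each model label (E is always free)
MODEL_COMPONENTS: dict[str, tuple[str, ...]] = {
    "ACE": ("A", "C", "E"),
    "ADE": ("A", "D", "E"),
    "AE": ("A", "E"),
    "CE": ("C", "E"),
    "DE": ("D", "E"),
    "E": ("E",),
}

#: genetic factors; a model "contains a genetic factor" if it frees one
GENETIC_FACTORS = frozenset({"A", "D"})


@dataclass(frozen=True)
class VarianceComponents:
    """Variance shares (same units as the phenotype variance)."""

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0

    def __post_init__(self):
        for name in ("a2", "c2", "d2", "e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.a2 + self.c2 + self.d2 + self.e2

    def standardized(self) -> "VarianceComponents":
        t = self.total
        if t <= 0:
            raise DegenerateDataError("zero total variance")
        return VarianceComponents(self.a2 / t, self.c2 / t, self.d2 / t, self.e2 / t)


@dataclass(frozen=True)
class ModelFit:
    """One fitted variance-decomposition model on one phenotype."""

    model: str
    components: VarianceComponents
    mean: float
    minus2ll: float
    n_params: int
    phenotype: str | None = None
    converged: bool = True

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.n_params

    @property
    def free_components(self) -> tuple[str, ...]:
        return MODEL_COMPONENTS[self.model]

    @property
    def has_genetic_factor(self) -> bool:
        return bool(GENETIC_FACTORS & set(self.free_components))


@dataclass(frozen=True)
class FitComparison:
    """Likelihood-ratio / AIC comparison of a reduced against a full model."""

    chi2: float
    df: int
    p: float
    delta_aic: float


def twin_correlation_weights(zygosity: str) -> tuple[float, float]:
    """(additive, dominance) cross-twin weighting for a zygosity group."""
    if zygosity == "MZ":
        return 1.0, 1.0
    if zygosity == "DZ":
        return 0.5, 0.25
    raise ValueError(f"unknown zygosity {zygosity!r}")


def expected_covariance(components: VarianceComponents, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 covariance of a twin pair.

    Diagonal: a2 + c2 + d2 + e2.  Off-diagonal: a2 + c2 + d2 for MZ,
    0.5 a2 + c2 + 0.25 d2 for DZ.
    """
    wa, wd = twin_correlation_weights(zygosity)
    v = components.total
    c = wa * components.a2 + components.c2 + wd * components.d2
    return np.array([[v, c], [c, v]])


# ---------------------------------------------------------------------------
# sufficient statistics and likelihood


@dataclass(frozen=True)
class _GroupStats:
    """Per-zygosity sufficient statistics of paired data."""

    n: int
    s1: float  # sum of all 2n values
    ss: float  # sum of squared values
    sp: float  # sum of within-pair products

    @classmethod
    def from_pairs(cls, x: np.ndarray) -> "_GroupStats":
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x).any(axis=1)]
        return cls(
            n=len(x),
            s1=float(x.sum()),
            ss=float((x * x).sum()),
            sp=float((x[:, 0] * x[:, 1]).sum()),
        )


_LOG_2PI = float(np.log(2.0 * np.pi))


def _group_neg2ll(g: _GroupStats, mu: float, v: float, c: float) -> float:
    det = v * v - c * c
    if det <= 0.0 or v <= 0.0:
        return np.inf
    ssc = g.ss - 2.0 * mu * g.s1 + 2.0 * g.n * mu * mu
    spc = g.sp - mu * g.s1 + g.n * mu * mu
    quad = (v * ssc - 2.0 * c * spc) / det
    return g.n * (np.log(det) + 2.0 * _LOG_2PI) + quad


def _neg2ll(
    mz: _GroupStats, dz: _GroupStats, mu: float, comps: VarianceComponents
) -> float:
    v = comps.total
    c_mz = comps.a2 + comps.c2 + comps.d2
    c_dz = 0.5 * comps.a2 + comps.c2 + 0.25 * comps.d2
    return _group_neg2ll(mz, mu, v, c_mz) + _group_neg2ll(dz, mu, v, c_dz)


def _as_pair_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, TwinPairTable):
        return data.pairs(zygosity="MZ"), data.pairs(zygosity="DZ")
    mz, dz = data
    return np.asarray(mz, dtype=float), np.asarray(dz, dtype=float)


# ---------------------------------------------------------------------------
# estimator


class TwinVarianceModel(BaseEstimator):
    """Maximum-likelihood ACE/ADE-family twin model.

    Parameters
    ----------
    model : {"ACE", "ADE", "AE", "CE", "DE", "E"}
        Which variance components are freed (E is always free).
    n_starts : int
        Number of optimiser starts (moment-based start plus seeded random
        perturbations) used to dodge local optima.
    random_state : int
        Seed for the random starts.
    e2_floor_scale : float
        e2 is floored at ``e2_floor_scale`` times the pooled sample
        variance so the likelihood stays proper.
    phenotype : str or None
        Which phenotype column to fit when a multi-phenotype table is
        passed.

    Attributes
    ----------
    components_ : VarianceComponents
    mean_ : float
    minus2ll_ : float
    aic_ : float
    n_params_ : int
    result_ : ModelFit
    """

    def __init__(
        self,
        model: str = "ADE",
        n_starts: int = 10,
        random_state: int = 0,
        e2_floor_scale: float = 1e-8,
        phenotype: str | None = None,
    ):
        self.model = model
        self.n_starts = n_starts
        self.random_state = random_state
        self.e2_floor_scale = e2_floor_scale
        self.phenotype = phenotype

    # -- fitting -------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit the model.

        ``X`` is a TwinPairTable (use ``phenotype`` to pick a column) or a
        tuple of (n_mz, 2) and (n_dz, 2) pair arrays.
        """
        if self.model not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model {self.model!r}")
        if isinstance(X, TwinPairTable):
            mz = X.pairs(phenotype=self.phenotype, zygosity="MZ")
            dz = X.pairs(phenotype=self.phenotype, zygosity="DZ")
        else:
            mz, dz = _as_pair_arrays(X)
        if len(mz) < 3 or len(dz) < 3:
            raise DegenerateDataError(
                f"need >=3 pairs per zygosity group, got {len(mz)} MZ / {len(dz)} DZ"
            )
        gmz = _GroupStats.from_pairs(mz)
        gdz = _GroupStats.from_pairs(dz)
        n_ind = 2 * (gmz.n + gdz.n)
        grand = (gmz.s1 + gdz.s1) / n_ind
        pooled_var = (gmz.ss + gdz.ss) / n_ind - grand * grand
        if pooled_var <= 0.0:
            raise DegenerateDataError("zero phenotype variance")
        floor = self.e2_floor_scale * pooled_var
        free = MODEL_COMPONENTS[self.model]

        if self.model == "E":
            comps = VarianceComponents(e2=max(pooled_var, floor))
            m2ll = _neg2ll(gmz, gdz, grand, comps)
            self._set_result(comps, grand, m2ll, converged=True)
            return self

        comps, mu, m2ll, ok = _optimize(
            gmz, gdz, free, floor, grand, pooled_var,
            self.n_starts, self.random_state,
        )
        self._set_result(comps, mu, m2ll, converged=ok)
        if not ok:
            raise ConvergenceError(
                f"{self.model} fit did not converge", best=self.result_
            )
        return self

    def _set_result(self, comps, mean, minus2ll, converged):
        self.components_ = comps
        self.mean_ = float(mean)
        self.minus2ll_ = float(minus2ll)
        self.n_params_ = len(MODEL_COMPONENTS[self.model]) + 1
        self.aic_ = self.minus2ll_ + 2.0 * self.n_params_
        self.result_ = ModelFit(
            model=self.model,
            components=comps,
            mean=self.mean_,
            minus2ll=self.minus2ll_,
            n_params=self.n_params_,
            phenotype=self.phenotype,
            converged=converged,
        )


def _moment_start(gmz, gdz, free, pooled_var):
    """Falconer-style moment estimates mapped to the free components."""

    def cov(g):
        if g.n == 0:
            return 0.0
        mu = g.s1 / (2 * g.n)
        return g.sp / g.n - mu * mu

    cmz = cov(gmz)
    cdz = cov(gdz)
    lo, hi = 0.02 * pooled_var, 0.95 * pooled_var
    clip = lambda x: float(np.clip(x, lo, hi))
    est = {"A": lo, "C": lo, "D": lo}
    if "A" in free and "C" in free:
        est["A"] = clip(2.0 * (cmz - cdz))
        est["C"] = clip(2.0 * cdz - cmz)
    elif "A" in free and "D" in free:
        est["D"] = clip(2.0 * cmz - 4.0 * cdz)
        est["A"] = clip(4.0 * cdz - cmz)
    elif "A" in free:
        est["A"] = clip(cmz)
    elif "C" in free:
        est["C"] = clip(cdz)
    elif "D" in free:
        est["D"] = clip(cmz)
    gen_env = sum(est[k] for k in free if k != "E")
    e0 = clip(pooled_var - gen_env)
    return [np.sqrt(est[k]) for k in free if k != "E"] + [np.sqrt(e0)]


def _optimize(gmz, gdz, free, floor, grand, pooled_var, n_starts, random_state):
    non_e = [k for k in free if k != "E"]

    def unpack(theta):
        kw = {"a2": 0.0, "c2": 0.0, "d2": 0.0}
        for k, t in zip(non_e, theta[1:]):
            kw[{"A": "a2", "C": "c2", "D": "d2"}[k]] = t * t
        kw["e2"] = theta[-1] ** 2 + floor
        return theta[0], VarianceComponents(**kw)

    def objective(theta):
        mu, comps = unpack(theta)
        return _neg2ll(gmz, gdz, mu, comps)

    rng = np.random.default_rng(random_state)
    base = np.array([grand] + _moment_start(gmz, gdz, free, pooled_var))
    sd = np.sqrt(pooled_var)
    best = None
    for s in range(max(1, n_starts)):
        x0 = base.copy()
        if s > 0:
            x0[0] += 0.3 * sd * rng.standard_normal()
            x0[1:] *= np.exp(0.5 * rng.standard_normal(len(x0) - 1))
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    ok = bool(best is not None and np.isfinite(best.fun))
    mu, comps = unpack(best.x)
    return comps, mu, float(best.fun), ok


# ---------------------------------------------------------------------------
# functional wrappers


def fit_univariate(
    data,
    spec: str = "ADE",
    phenotype: str | None = None,
    n_starts: int = 10,
    random_state: int = 0,
) -> ModelFit:
    """Fit one model label to one phenotype and return its ModelFit."""
    est = TwinVarianceModel(
        model=spec, n_starts=n_starts, random_state=random_state, phenotype=phenotype
    )
    est.fit(data)
    return est.result_


def submodels_of(initial: str) -> tuple[str, ...]:
    """Nested submodels compared against an initial ACE or ADE model."""
    if initial == "ACE":
        return ("AE", "CE", "E")
    if initial == "ADE":
        return ("AE", "DE", "E")
    raise ValueError(f"initial model must be ACE or ADE, got {initial!r}")


def fit_all_models(
    data,
    initial: str,
    phenotype: str | None = None,
    n_starts: int = 10,
    random_state: int = 0,
) -> dict[str, ModelFit]:
    """Fit an initial model and all its submodels (including E)."""
    fits = {}
    for label in (initial,) + submodels_of(initial):
        fits[label] = fit_univariate(
            data, label, phenotype=phenotype, n_starts=n_starts,
            random_state=random_state,
        )
    return fits


def compare_fits(
    full: ModelFit, reduced: ModelFit, boundary: str = "chi2"
) -> FitComparison:
    """Likelihood-ratio and AIC comparison of nested fits on the same data.

    ``boundary="chi2"`` uses the plain chi-square reference (the common
    SEM-software default even though variance components sit on the
    boundary under the null); ``boundary="mixture"`` uses the 50:50
    chi-square mixture with df and df-1.
    """
    if not set(reduced.free_components) < set(full.free_components):
        raise NestingError(
            f"{reduced.model} is not nested in {full.model}"
        )
    chi2 = max(0.0, reduced.minus2ll - full.minus2ll)
    df = full.n_params - reduced.n_params
    if boundary == "chi2":
        p = float(stats.chi2.sf(chi2, df))
    elif boundary == "mixture":
        if df == 1:
            lower = 1.0 if chi2 <= 0.0 else 0.0  # chi2_0 point mass at zero
        else:
            lower = float(stats.chi2.sf(chi2, df - 1))
        p = 0.5 * float(stats.chi2.sf(chi2, df)) + 0.5 * lower
    else:
        raise ValueError(f"unknown boundary option {boundary!r}")
    return FitComparison(
        chi2=chi2, df=df, p=p, delta_aic=reduced.aic - full.aic
    )
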