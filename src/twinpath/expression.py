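"""Region x gene expression analyses.

Differential-stability filtering of genes, leave-one-region-out (LORO)
decoding of region groups from expression profiles with a linear
max-margin classifier, background-resampled binary decoding, permutation
chance estimation, top-weight gene extraction and per-cluster marker-gene
t tests.

Expression matrices are pandas DataFrames with region labels as the index
and gene labels as columns (normalized, z-like units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateDataError, InsufficientDataError, TwinpathError

__all__ = [
    "DecodingResult",
    "GeneScore",
    "LeaveRegionOutDecoder",
    "differential_stability",
    "differential_stability_filter",
    "loro_decode",
    "sampled_binary_decode",
    "permutation_chance",
    "top_weight_genes",
    "cluster_specific_genes",
]


@dataclass(frozen=True)
class DecodingResult:
    """Cross-validated decoding accuracy with optional chance/permutation p."""

    accuracy: float
    per_iteration: np.ndarray
    chance: float | None = None
    p: float | None = None
    seed: int | None = None
    mean_weights: pd.Series | None = None


@dataclass(frozen=True)
class GeneScore:
    gene_label: str
    score: float
    rank: int


# ---------------------------------------------------------------------------
# differential stability


def differential_stability(matrices: list[pd.DataFrame]) -> pd.Series:
    """Per-gene mean pairwise inter-donor Pearson correlation across regions."""
    if len(matrices) < 2:
        raise InsufficientDataError("differential stability needs >=2 donors")
    shared_regions = matrices[0].index
    shared_genes = matrices[0].columns
    for m in matrices[1:]:
        shared_regions = shared_regions.intersection(m.index)
        shared_genes = shared_genes.intersection(m.columns)
    if len(shared_regions) < 3:
        raise InsufficientDataError("need >=3 shared regions to correlate")
    mats = [m.loc[shared_regions, shared_genes].to_numpy(dtype=float) for m in matrices]

    def col_corr(a, b):
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        denom = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a * b).sum(axis=0) / denom
        return np.where(denom > 0, r, 0.0)

    pairs = [
        col_corr(mats[i], mats[j])
        for i in range(len(mats))
        for j in range(i + 1, len(mats))
    ]
    return pd.Series(np.mean(pairs, axis=0), index=shared_genes, name="DS")


def differential_stability_filter(
    matrices: list[pd.DataFrame], top_fraction: float = 0.05
) -> pd.Index:
    """Genes in the top ``top_fraction`` of differential stability.

    Retains floor(top_fraction * G) genes ranked by descending DS, ties
    broken by stable gene order (e.g. 501 of 10,020 genes at 5%).
    """
    ds = differential_stability(matrices)
    n_keep = int(np.floor(top_fraction * len(ds)))
    order = np.argsort(-ds.to_numpy(), kind="stable")
    return ds.index[order[:n_keep]]


# ---------------------------------------------------------------------------
# leave-one-region-out decoding


class LeaveRegionOutDecoder(BaseEstimator):
    """Leave-one-region-out linear max-margin decoding of region groups.

    Each region in turn is held out; a linear SVM (libsvm, C=1,
    one-vs-one for multiclass) is trained on the remaining regions and
    predicts the held-out one.  Features are z-scored on the training
    fold only.

    Attributes
    ----------
    accuracy_ : float
    fold_outcomes_ : (n_regions,) 0/1 array
    predictions_ : pd.Series
    weights_ : pd.Series or None
        Mean absolute linear weight per gene across folds (binary only).
    """

    def __init__(self, C: float = 1.0, standardize: bool = True):
        self.C = C
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y), index=X.index)
        classes = y.unique()
        if len(classes) < 2:
            raise TwinpathError("decoding needs >=2 classes")
        xv = X.to_numpy(dtype=float)
        yv = y.to_numpy()
        n = len(xv)
        outcomes = np.empty(n)
        preds = np.empty(n, dtype=object)
        weight_sum = np.zeros(xv.shape[1])
        binary = len(classes) == 2
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[:] = True
            mask[i] = False
            xtr, ytr = xv[mask], yv[mask]
            if len(np.unique(ytr)) < 2:
                raise TwinpathError("a training fold lost all but one class")
            if self.standardize:
                scaler = StandardScaler().fit(xtr)
                xtr = scaler.transform(xtr)
                xte = scaler.transform(xv[i : i + 1])
            else:
                xte = xv[i : i + 1]
            clf = SVC(kernel="linear", C=self.C).fit(xtr, ytr)
            pred = clf.predict(xte)[0]
            preds[i] = pred
            outcomes[i] = float(pred == yv[i])
            if binary:
                weight_sum += np.abs(clf.coef_[0])
        self.accuracy_ = float(outcomes.mean())
        self.fold_outcomes_ = outcomes
        self.predictions_ = pd.Series(preds, index=X.index)
        self.weights_ = (
            pd.Series(weight_sum / n, index=X.columns, name="weight") if binary else None
        )
        return self


def loro_decode(X: pd.DataFrame, y, C: float = 1.0, standardize: bool = True):
    """Leave-one-region-out decoding; returns (DecodingResult, decoder)."""
    dec = LeaveRegionOutDecoder(C=C, standardize=standardize).fit(X, y)
    return (
        DecodingResult(accuracy=dec.accuracy_, per_iteration=dec.fold_outcomes_),
        dec,
    )


def sampled_binary_decode(
    X: pd.DataFrame,
    target_regions,
    background_pool,
    n_iter: int = 100,
    seed: int | None = 0,
    C: float = 1.0,
) -> DecodingResult:
    """Binary target-vs-background decoding with resampled backgrounds.

    Each iteration samples ``len(target_regions)`` background regions
    without replacement from the pool, then runs leave-one-region-out
    decoding on the balanced set.  Mean weight traces across iterations
    are accumulated for top-gene extraction.
    """
    target_regions = list(target_regions)
    background_pool = list(background_pool)
    if len(background_pool) < len(target_regions):
        raise TwinpathError("background pool smaller than the target set")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    weight_sum = np.zeros(X.shape[1])
    for it in range(n_iter):
        bg = list(rng.choice(background_pool, size=len(target_regions), replace=False))
        rows = target_regions + bg
        y = np.array([1] * len(target_regions) + [0] * len(bg))
        res, dec = loro_decode(X.loc[rows], y, C=C)
        accs[it] = res.accuracy
        weight_sum += dec.weights_.to_numpy()
    return DecodingResult(
        accuracy=float(accs.mean()),
        per_iteration=accs,
        seed=seed,
        mean_weights=pd.Series(weight_sum / n_iter, index=X.columns),
    )


def permutation_chance(
    X: pd.DataFrame,
    y,
    n_perm: int = 1000,
    seed: int | None = 0,
    C: float = 1.0,
) -> DecodingResult:
    """Permuted-label chance level and add-one permutation p for LORO accuracy."""
    y = np.asarray(y)
    observed, _ = loro_decode(X, y, C=C)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        null[b] = loro_decode(X, yp, C=C)[0].accuracy
    p = (1.0 + np.count_nonzero(null >= observed.accuracy)) / (1.0 + n_perm)
    return DecodingResult(
        accuracy=observed.accuracy,
        per_iteration=null,
        chance=float(null.mean()),
        p=float(p),
        seed=seed,
    )


def top_weight_genes(weights: pd.Series, fraction: float = 0.01) -> list[GeneScore]:
    """Top ceil(fraction * G) genes ranked by mean absolute linear weight."""
    if weights is None:
        raise TwinpathError(
            "weights unavailable (multiclass decoding has no single weight vector)"
        )
    scores = np.abs(weights.to_numpy(dtype=float))
    order = np.argsort(-scores, kind="stable")
    n_top = int(np.ceil(fraction * len(scores)))
    return [
        GeneScore(gene_label=str(weights.index[j]), score=float(scores[j]), rank=r + 1)
        for r, j in enumerate(order[:n_top])
    ]


def cluster_specific_genes(
    X: pd.DataFrame,
    cluster_labels,
    t_threshold: float = 3.7,
    p_threshold: float = 0.001,
    equal_var: bool = True,
) -> dict:
    """Per-cluster marker genes by two-sample t test (cluster vs the rest).

    A gene is a marker of a cluster when its pooled-variance two-sample t
    exceeds ``t_threshold`` and the two-sided p is below ``p_threshold``;
    markers are ranked by t.  ``equal_var=False`` switches to the Welch
    variant.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=X.index)
    clusters = labels.unique()
    if len(clusters) < 2:
        raise TwinpathError("need >=2 clusters")
    out = {}
    xv = X.to_numpy(dtype=float)
    for c in clusters:
        in_c = (labels == c).to_numpy()
        if in_c.sum() < 2 or (~in_c).sum() < 2:
            raise DegenerateDataError(f"cluster {c!r} has <2 samples on one side")
        t, p = stats.ttest_ind(xv[in_c], xv[~in_c], axis=0, equal_var=equal_var)
        keep = np.flatnonzero((t > t_threshold) & (p < p_threshold))
        keep = keep[np.argsort(-t[keep], kind="stable")]
        out[c] = [
            GeneScore(gene_label=str(X.columns[j]), score=float(t[j]), rank=r + 1)
            for r, j in enumerate(keep)
        ]
    return out
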