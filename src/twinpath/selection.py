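"""Per-region model selection and classification.

Maps intraclass correlations and fitted variance models to a per-region
decision: which initial model (ACE or ADE) to entertain, which member of
the model family fits best by AIC, whether the best model improves
significantly on the E-only control, and whether the region counts as
genetically influenced, environmentally influenced, or other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import TwinpathError
from .variance_models import (
    GENETIC_FACTORS,
    MODEL_COMPONENTS,
    FitComparison,
    ModelFit,
    compare_fits,
)

__all__ = [
    "RegionDecision",
    "choose_initial_model",
    "select_best_model",
    "classify_regions",
    "categorize",
]

#: deterministic tie-break order (fewest parameters first)
_LABEL_ORDER = ("E", "AE", "CE", "DE", "ACE", "ADE")


@dataclass(frozen=True)
class RegionDecision:
    """One region's row of the selection summary."""

    region_id: str
    r_mz: float
    r_dz: float
    initial_model: str
    best_model: str
    delta_aic_vs_E: float | None
    p_vs_E: float | None
    category: str


def choose_initial_model(r_mz: float, r_dz: float) -> str:
    """ADE when the DZ correlation is less than half the MZ correlation.

    A DZ correlation below half the MZ correlation indicates dominance
    (D); otherwise shared environment (C) is entertained.  Correlations
    are clamped below at zero before the half-rule, so that negative
    estimates (which carry no heritable signal) behave like zero.
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    mz = max(r_mz, 0.0)
    dz = max(r_dz, 0.0)
    return "ADE" if dz < 0.5 * mz else "ACE"


def _is_genetic_label(label: str) -> bool:
    return bool(GENETIC_FACTORS & set(MODEL_COMPONENTS[label]))


def select_best_model(
    fits: Mapping[str, ModelFit] | Sequence[ModelFit],
    r_mz: float,
    r_dz: float,
    boundary: str = "chi2",
    p_vs_e: float | None = None,
    alpha: float = 0.05,
    region_id: str = "",
) -> RegionDecision:
    """Pick the lowest-AIC model and compare it against the E control.

    ``fits`` must contain the E model.  Ties in AIC are broken toward
    fewer parameters.  A winning model containing a genetic factor (A or
    D) additionally requires rMZ > rDZ; failing that it is demoted to the
    best-AIC model without genetic factors.  ``p_vs_e`` overrides the
    analytic likelihood-ratio p (e.g. with a permutation p).
    """
    if not isinstance(fits, Mapping):
        fits = {f.model: f for f in fits}
    phens = {f.phenotype for f in fits.values()}
    if len(phens) > 1:
        raise TwinpathError(f"fits come from different phenotypes: {phens}")
    if "E" not in fits:
        raise TwinpathError("fits must include the E control model")

    def aic_key(label: str):
        f = fits[label]
        return (f.aic, f.n_params, _LABEL_ORDER.index(label))

    best_label = min(fits, key=aic_key)
    if _is_genetic_label(best_label) and not (r_mz > r_dz):
        non_genetic = [l for l in fits if not _is_genetic_label(l)]
        best_label = min(non_genetic, key=aic_key)
    best = fits[best_label]

    if best_label == "E":
        delta_aic = None
        p = None
    else:
        cmp: FitComparison = compare_fits(best, fits["E"], boundary=boundary)
        delta_aic = cmp.delta_aic
        p = cmp.p if p_vs_e is None else p_vs_e

    category = categorize(best_label, p, r_mz, r_dz, alpha=alpha)
    return RegionDecision(
        region_id=region_id,
        r_mz=r_mz,
        r_dz=r_dz,
        initial_model=choose_initial_model(r_mz, r_dz),
        best_model=best_label,
        delta_aic_vs_E=delta_aic,
        p_vs_E=p,
        category=category,
    )


def categorize(
    best_model: str,
    p_vs_e: float | None,
    r_mz: float,
    r_dz: float,
    alpha: float = 0.05,
) -> str:
    """Category rule: genetic / environmental / other.

    genetic: best model frees A or D, improves on E at ``alpha`` and
    rMZ > rDZ.  environmental: best model is CE and improves on E at
    ``alpha``.  Everything else (including best model E) is other.
    """
    if best_model == "E" or p_vs_e is None:
        return "other"
    if _is_genetic_label(best_model) and p_vs_e < alpha and r_mz > r_dz:
        return "genetic"
    if best_model == "CE" and p_vs_e < alpha:
        return "environmental"
    return "other"


def classify_regions(decisions: Iterable[RegionDecision]) -> dict:
    """Summary counts by category and by best-model label.

    Returns ``{"by_category": {...}, "genetic_by_model": {...}, "n": N}``;
    genetic_by_model counts best-model labels among genetic regions only.
    """
    decisions = list(decisions)
    ids = [d.region_id for d in decisions]
    if len(set(ids)) != len(ids):
        dup = [i for i, c in Counter(ids).items() if c > 1]
        raise TwinpathError(f"duplicate region ids: {dup}")
    by_category = Counter(d.category for d in decisions)
    genetic_by_model = Counter(
        d.best_model for d in decisions if d.category == "genetic"
    )
    for cat in ("genetic", "environmental", "other"):
        by_category.setdefault(cat, 0)
    return {
        "n": len(decisions),
        "by_category": dict(by_category),
        "genetic_by_model": dict(genetic_by_model),
    }
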