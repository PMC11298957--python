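"""End-to-end pipeline driver.

Runs the full analysis sequence on a twin table: per-phenotype ICCs,
initial-model choice, model fits and best-model selection, optional
permutation significance, FDR correction, region categories, a
common-pathway fit on the genetic phenotypes, loading-space clustering
and (optionally) expression decoding.  Writes a summary table shaped
like the per-region reference table, cluster assignments and a JSON
provenance record sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .common_pathway import cluster_loadings, fit_cp
from .errors import TwinpathError
from .expression import loro_decode, permutation_chance
from .io import decisions_to_frame, read_expression_matrix, read_twin_table
from .resampling import bh_fdr, permutation_test_delta_aic
from .selection import categorize, choose_initial_model, classify_regions, select_best_model
from .table import TwinPairTable
from .twin_stats import compute_icc
from .variance_models import fit_all_models

log = logging.getLogger("twinpath")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; all stages are toggleable."""

    twin_table: str | None = None
    expression_matrix: str | None = None
    expression_labels: str | None = None
    out_dir: str = "twinpath_out"
    univariate: bool = True
    permutation: bool = False
    cp: bool = True
    clustering: bool = True
    expression: bool = False
    alpha: float = 0.05
    fdr: bool = True
    n_perm: int = 10_000
    n_perm_decoding: int = 1000
    cp_factors: int | None = None
    k_range: tuple = (1, 2, 3, 4, 5, 6)
    seed: int = 0
    n_starts: int = 10

    def validate(self):
        if not 0 < self.alpha < 1:
            raise TwinpathError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise TwinpathError("n_perm must be >= 1")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, table: TwinPairTable | None = None) -> dict:
    """Execute the configured stages; returns the result bundle as a dict.

    ``table`` may be passed directly (e.g. simulated data); otherwise
    ``config.twin_table`` is read from disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: list[str] = []
    stage = "setup"
    t0 = time.time()
    try:
        if table is None and config.twin_table is not None:
            table = read_twin_table(config.twin_table)

        decisions = []
        iccs = {}
        pvals = []
        if config.univariate:
            stage = "univariate"
            if table is None:
                raise TwinpathError("univariate stage needs a twin table")
            for phen in table.phenotypes:
                icc_mz = compute_icc(table, phenotype=phen, zygosity="MZ")
                icc_dz = compute_icc(table, phenotype=phen, zygosity="DZ")
                iccs[phen] = (icc_mz, icc_dz)
                initial = choose_initial_model(icc_mz.r, icc_dz.r)
                fits = fit_all_models(
                    table, initial, phenotype=phen,
                    n_starts=config.n_starts, random_state=config.seed,
                )
                p_override = None
                if config.permutation:
                    stage = "permutation"
                    best_probe = select_best_model(
                        fits, icc_mz.r, icc_dz.r, region_id=phen
                    )
                    if best_probe.best_model != "E":
                        spec = best_probe.best_model
                        if set("AD") & set(spec):
                            perm = permutation_test_delta_aic(
                                table, spec, n_perm=config.n_perm,
                                seed=config.seed, phenotype=phen,
                            )
                            p_override = perm.p
                    stage = "univariate"
                d = select_best_model(
                    fits, icc_mz.r, icc_dz.r, p_vs_e=p_override,
                    alpha=config.alpha, region_id=phen,
                )
                decisions.append(d)
                pvals.append(d.p_vs_E)

            if config.fdr:
                stage = "fdr"
                idx = [i for i, p in enumerate(pvals) if p is not None]
                if idx:
                    adj = bh_fdr([pvals[i] for i in idx])
                    for j, i in enumerate(idx):
                        d = decisions[i]
                        decisions[i] = type(d)(
                            region_id=d.region_id, r_mz=d.r_mz, r_dz=d.r_dz,
                            initial_model=d.initial_model, best_model=d.best_model,
                            delta_aic_vs_E=d.delta_aic_vs_E, p_vs_E=float(adj[j]),
                            category=categorize(
                                d.best_model, float(adj[j]), d.r_mz, d.r_dz,
                                alpha=config.alpha,
                            ),
                        )
            summary = decisions_to_frame(decisions, iccs)
            summary.to_csv(out / "summary.tsv", sep="\t", index=False)
            manifest.append("summary.tsv")
            bundle["decisions"] = decisions
            bundle["summary"] = summary
            bundle["counts"] = classify_regions(decisions)

        genetic_phens = [d.region_id for d in decisions if d.category == "genetic"]
        if config.cp and len(genetic_phens) >= 2:
            stage = "cp"
            sub = table.select(genetic_phens)
            m = config.cp_factors or 1
            cp_fit = fit_cp(
                sub, m=m, n_starts=max(3, config.n_starts // 2),
                random_state=config.seed,
            )
            bundle["cp_fit"] = cp_fit
            pd.DataFrame(
                cp_fit.loadings, index=genetic_phens,
                columns=[f"factor{f+1}" for f in range(cp_fit.n_factors)],
            ).to_csv(out / "cp_loadings.tsv", sep="\t")
            manifest.append("cp_loadings.tsv")
            if config.clustering:
                stage = "clustering"
                k_range = [k for k in config.k_range if k <= len(genetic_phens)]
                sol = cluster_loadings(cp_fit, k_range=k_range, seed=config.seed)
                bundle["clusters"] = sol
                sol.assignments.rename("cluster").to_csv(
                    out / "cluster_assignments.tsv", sep="\t",
                    index_label="region",
                )
                manifest.append("cluster_assignments.tsv")

        if config.expression and config.expression_matrix:
            stage = "expression"
            xmat = read_expression_matrix(config.expression_matrix)
            labels = pd.read_csv(
                config.expression_labels, sep="\t", index_col=0
            ).iloc[:, 0]
            res = permutation_chance(
                xmat, labels.loc[xmat.index].to_numpy(),
                n_perm=config.n_perm_decoding, seed=config.seed,
            )
            bundle["decoding"] = res
            with open(out / "decoding.json", "w") as fh:
                json.dump(
                    {"accuracy": res.accuracy, "chance": res.chance, "p": res.p},
                    fh, indent=2,
                )
            manifest.append("decoding.json")

        stage = "provenance"
        prov = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "outputs": manifest,
            "elapsed_s": round(time.time() - t0, 3),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, default=str)
        bundle["provenance"] = prov
        return bundle
    except TwinpathError:
        partial = {"failed_stage": stage, "outputs": manifest}
        with open(out / "partial_manifest.json", "w") as fh:
            json.dump(partial, fh, indent=2)
        log.error("pipeline aborted in stage %s", stage)
        raise
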