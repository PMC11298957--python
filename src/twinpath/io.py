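"""Reading and writing the package's TSV dialects.

Canonical dialect: tab-separated, UTF-8, '.' decimal, header row.  CSV is
accepted on input via delimiter sniffing.  Missing values are empty cells
or ``NA``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .table import TwinPairTable

log = logging.getLogger("twinpath")

__all__ = [
    "read_twin_table",
    "write_twin_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "decisions_to_frame",
]


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise ParseError(f"{path} is empty")
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_twin_table(path) -> TwinPairTable:
    """Parse a twin-pair phenotype table (TSV/CSV).

    Expected header: family_id, zygosity, then ``<phenotype>_t1`` /
    ``<phenotype>_t2`` column pairs.  Missing values (empty or NA) keep
    the pair but flag the phenotype as missing.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"family_id": str}, na_values=["NA", ""])
    table = TwinPairTable(df)
    n_missing = int(df.drop(columns=["family_id", "zygosity"]).isna().sum().sum())
    log.info(
        "read %d pairs (%d MZ / %d DZ), %d phenotype(s), %d missing values from %s",
        len(table), table.n_pairs("MZ"), table.n_pairs("DZ"),
        len(table.phenotypes), n_missing, path,
    )
    return table


def write_twin_table(table: TwinPairTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    """Region x gene matrix: header row of genes, first column region labels."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: expression matrix contains missing values")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate region or gene labels")
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def decisions_to_frame(decisions, iccs=None) -> pd.DataFrame:
    """Region decisions as a reference-table-shaped frame.

    ``iccs`` optionally maps region_id -> (IccResult MZ, IccResult DZ) to
    fill the per-group p columns.
    """
    rows = []
    for d in decisions:
        row = {
            "region": d.region_id,
            "r_mz": d.r_mz,
            "p_mz": np.nan,
            "r_dz": d.r_dz,
            "p_dz": np.nan,
            "rmz_minus_rdz": d.r_mz - d.r_dz,
            "two_rdz_minus_rmz": 2.0 * d.r_dz - d.r_mz,
            "initial_model": d.initial_model,
            "best_model": d.best_model,
            "delta_aic": d.delta_aic_vs_E,
            "p_vs_e": d.p_vs_E,
            "category": d.category,
        }
        if iccs and d.region_id in iccs:
            mz, dz = iccs[d.region_id]
            row["p_mz"] = mz.p_one_tailed
            row["p_dz"] = dz.p_one_tailed
        rows.append(row)
    return pd.DataFrame(rows)
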