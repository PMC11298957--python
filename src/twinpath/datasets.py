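"""Bundled reference tables.

The package ships one fixture: the published per-region twin-modelling
summary for 40 language-responsive brain regions (MZ/DZ intraclass
correlations with one-tailed p values, initial and best-fitting variance
models, the AIC improvement of the best model over the E-only control and
the resulting cluster membership).  It is used by the worked examples and
by the desk checks of the selection logic; '***' in the significance
column means p < 0.001 and '-' marks entries the source leaves blank.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = ["load_region_table"]

#: numeric stand-in for a significance entry printed as '***' (p < 0.001)
P_BELOW_PRINT = 5e-4


def _num(series: pd.Series) -> pd.Series:
    s = series.replace({"-": np.nan, "***": P_BELOW_PRINT})
    return pd.to_numeric(s)


def load_region_table(parsed: bool = True) -> pd.DataFrame:
    """Load the 40-region twin-modelling reference table.

    With ``parsed=True`` (default), adds numeric columns
    ``delta_aic_num``/``p_vs_e_num``/``cluster_num`` plus the printed
    derived columns as floats, keeping the verbatim printed tokens in the
    original columns.
    """
    ref = importlib.resources.files("twinpath.data").joinpath("table1.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("r_mz", "p_mz", "r_dz", "p_dz"):
        df[col] = pd.to_numeric(df[col])
    df["region_number"] = df["region_number"].astype(int)
    if parsed:
        df["rmz_minus_rdz_num"] = _num(df["rmz_minus_rdz"])
        df["two_rdz_minus_rmz_num"] = _num(df["two_rdz_minus_rmz"])
        df["delta_aic_num"] = _num(df["delta_aic"])
        df["p_vs_e_num"] = _num(df["p_vs_e"])
        df["cluster_num"] = _num(df["cluster"])
    return df
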