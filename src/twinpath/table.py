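"""Twin-pair phenotype tables.

The universal input of the package: one row per twin pair, with a family
identifier, a zygosity label (``MZ`` or ``DZ``) and one or more paired
phenotype columns named ``<phenotype>_t1`` / ``<phenotype>_t2`` (e.g. fMRI
activation t-values of twin 1 and twin 2 in one brain region).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

ZYGOSITIES = ("MZ", "DZ")


class TwinPairTable:
    """A validated pairs x phenotypes table with zygosity labels.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain columns ``family_id`` and ``zygosity`` plus, for each
        phenotype ``p``, a column pair ``p_t1`` / ``p_t2``.  Missing
        phenotype values are allowed (NaN) and are dropped pairwise per
        phenotype by consumers.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("family_id", "zygosity"):
            if col not in df.columns:
                raise ParseError(f"missing required column {col!r}")
        bad = set(df["zygosity"].unique()) - set(ZYGOSITIES)
        if bad:
            row = df.index[df["zygosity"].isin(bad)][0]
            raise ParseError(
                f"unknown zygosity token {sorted(bad)!r} (first at row {row}); "
                f"expected one of {ZYGOSITIES}"
            )
        if df["family_id"].duplicated().any():
            dup = df.loc[df["family_id"].duplicated(), "family_id"].iloc[0]
            raise ParseError(f"duplicate family_id {dup!r}")
        value_cols = [c for c in df.columns if c not in ("family_id", "zygosity")]
        names: list[str] = []
        for c in value_cols:
            if c.endswith("_t1"):
                base = c[:-3]
                if base + "_t2" not in df.columns:
                    raise ParseError(f"phenotype column {c!r} has no matching {base}_t2")
                names.append(base)
            elif not c.endswith("_t2"):
                raise ParseError(f"unpaired phenotype column {c!r}")
        for c in value_cols:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        self._df = df.reset_index(drop=True)
        self._phenotypes = tuple(names)

    # -- basic introspection -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return self._phenotypes

    def __len__(self) -> int:
        return len(self._df)

    def n_pairs(self, zygosity: str | None = None) -> int:
        if zygosity is None:
            return len(self._df)
        return int((self._df["zygosity"] == zygosity).sum())

    # -- data access ---------------------------------------------------------
    def pairs(
        self,
        phenotype: str | None = None,
        zygosity: str | None = None,
        dropna: bool = True,
    ) -> np.ndarray:
        """Return an (n, 2) array of twin-1/twin-2 values.

        NaN-containing pairs are dropped when ``dropna`` (the default),
        mirroring pairwise-complete handling of missing phenotype values.
        """
        phenotype = self._resolve(phenotype)
        sub = self._df
        if zygosity is not None:
            sub = sub[sub["zygosity"] == zygosity]
        x = sub[[phenotype + "_t1", phenotype + "_t2"]].to_numpy(dtype=float)
        if dropna:
            x = x[~np.isnan(x).any(axis=1)]
        return x

    def values_wide(
        self, phenotypes: Sequence[str] | None = None, zygosity: str | None = None
    ) -> np.ndarray:
        """Return an (n, 2p) array ordered (phen1_t1..phenp_t1, phen1_t2..phenp_t2).

        Pairs missing any requested phenotype value are dropped (complete-case
        across phenotypes, as required by multivariate fits).
        """
        if phenotypes is None:
            phenotypes = self._phenotypes
        sub = self._df
        if zygosity is not None:
            sub = sub[sub["zygosity"] == zygosity]
        cols = [p + "_t1" for p in phenotypes] + [p + "_t2" for p in phenotypes]
        x = sub[cols].to_numpy(dtype=float)
        return x[~np.isnan(x).any(axis=1)]

    def select(self, phenotypes: Iterable[str]) -> "TwinPairTable":
        phenotypes = list(phenotypes)
        cols = ["family_id", "zygosity"]
        for p in phenotypes:
            if p not in self._phenotypes:
                raise KeyError(f"unknown phenotype {p!r}")
            cols += [p + "_t1", p + "_t2"]
        return TwinPairTable(self._df[cols])

    def _resolve(self, phenotype: str | None) -> str:
        if phenotype is None:
            if len(self._phenotypes) != 1:
                raise ValueError(
                    "phenotype must be named when the table holds several: "
                    f"{self._phenotypes}"
                )
            return self._phenotypes[0]
        if phenotype not in self._phenotypes:
            raise KeyError(f"unknown phenotype {phenotype!r}")
        return phenotype

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        mz: np.ndarray,
        dz: np.ndarray,
        phenotype: str = "phen",
    ) -> "TwinPairTable":
        """Build a one-phenotype table from (n, 2) MZ and DZ pair arrays."""
        mz = np.asarray(mz, dtype=float)
        dz = np.asarray(dz, dtype=float)
        n_mz, n_dz = len(mz), len(dz)
        df = pd.DataFrame(
            {
                "family_id": [f"fam{i:05d}" for i in range(n_mz + n_dz)],
                "zygosity": ["MZ"] * n_mz + ["DZ"] * n_dz,
                phenotype + "_t1": np.concatenate([mz[:, 0], dz[:, 0]]),
                phenotype + "_t2": np.concatenate([mz[:, 1], dz[:, 1]]),
            }
        )
        return cls(df)

    @classmethod
    def from_wide(
        cls,
        mz: np.ndarray,
        dz: np.ndarray,
        phenotypes: Sequence[str],
    ) -> "TwinPairTable":
        """Build a multi-phenotype table from (n, 2p) MZ/DZ arrays."""
        p = len(phenotypes)
        mz = np.asarray(mz, dtype=float)
        dz = np.asarray(dz, dtype=float)
        if mz.shape[1] != 2 * p or dz.shape[1] != 2 * p:
            raise ValueError("wide arrays must have 2 * n_phenotypes columns")
        n_mz, n_dz = len(mz), len(dz)
        data = {
            "family_id": [f"fam{i:05d}" for i in range(n_mz + n_dz)],
            "zygosity": ["MZ"] * n_mz + ["DZ"] * n_dz,
        }
        for j, name in enumerate(phenotypes):
            data[name + "_t1"] = np.concatenate([mz[:, j], dz[:, j]])
            data[name + "_t2"] = np.concatenate([mz[:, p + j], dz[:, p + j]])
        return cls(pd.DataFrame(data))
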