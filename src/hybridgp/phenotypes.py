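"""Long-format phenotype container.

Phenotypes are adjusted genotype means (stage-1 BLUEs) in long format:
one record per (genotype, environment) cell.  Missing values (NaN) mark
cells whose value is to be predicted; absent rows mark cells that were
never observed (unbalanced trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable"]

COLUMNS = ("genotype", "environment", "value")


@dataclass
class PhenotypeTable:
    """Long-format phenotype records with columns genotype/environment/value.

    Records are kept sorted by (environment, genotype) — the canonical
    ordering used by all incidence matrices and Kronecker/Hadamard
    comparisons in this package.  Duplicate (genotype, environment) cells
    are rejected.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing_cols = [c for c in COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table missing columns {missing_cols}")
        df = df.loc[:, list(COLUMNS)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["environment"] = df["environment"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        dup = df.duplicated(subset=["genotype", "environment"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (genotype, environment) cell(s)"
            )
        self.df = df.sort_values(["environment", "genotype"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_arrays(cls, genotypes, environments, values) -> "PhenotypeTable":
        return cls(
            pd.DataFrame(
                {
                    "genotype": list(genotypes),
                    "environment": list(environments),
                    "value": np.asarray(values, dtype=float),
                }
            )
        )

    @classmethod
    def from_vector(cls, ids, values, environment: str = "env1") -> "PhenotypeTable":
        """Wrap a single-environment phenotype vector."""
        return cls.from_arrays(ids, [environment] * len(list(ids)), values)

    @property
    def genotype_ids(self) -> list[str]:
        return sorted(self.df["genotype"].unique().tolist())

    @property
    def environment_ids(self) -> list[str]:
        return sorted(self.df["environment"].unique().tolist())

    @property
    def n_environments(self) -> int:
        return self.df["environment"].nunique()

    def is_balanced(self) -> bool:
        """True iff every genotype has a record in every environment."""
        piv = self.df.pivot(index="genotype", columns="environment", values="value")
        # pivot inserts NaN for absent cells; compare against recorded NaNs
        counts = self.df.groupby("genotype")["environment"].nunique()
        return bool((counts == self.n_environments).all())

    def restrict_genotypes(self, ids) -> "PhenotypeTable":
        keep = self.df["genotype"].isin(set(map(str, ids)))
        return PhenotypeTable(self.df.loc[keep])

    def single_env_vector(self, ids) -> np.ndarray:
        """Phenotype vector aligned to ``ids`` for single-environment data.

        Genotypes without a record get NaN (treated as masked).
        """
        if self.n_environments != 1:
            raise ValueError("single_env_vector requires exactly one environment")
        lookup = dict(zip(self.df["genotype"], self.df["value"]))
        return np.array([lookup.get(str(g), np.nan) for g in ids], dtype=float)

    def mask_cells(self, cells) -> "PhenotypeTable":
        """Return a copy with the given (genotype, environment) cells set to NaN."""
        df = self.df.copy()
        cellset = {(str(g), str(e)) for g, e in cells}
        sel = [
            (g, e) in cellset
            for g, e in zip(df["genotype"], df["environment"])
        ]
        df.loc[sel, "value"] = np.nan
        return PhenotypeTable(df)

    def __len__(self) -> int:
        return len(self.df)
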