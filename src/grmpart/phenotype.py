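"""Phenotype tables: one or two continuous traits per individual.

Values are de-regressed-proof-like continuous phenotypes. The on-disk
format is the PLINK/GCTA phenotype dialect: whitespace-delimited
``FID IID y1 [y2]`` with ``NA`` marking a missing trait value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PhenotypeTable:
    individual_ids: np.ndarray  # (n,), str
    values: np.ndarray  # (n, n_traits) float, NaN = missing
    trait_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.individual_ids):
            raise ValueError("phenotype rows do not match individual ids")
        if not self.trait_names:
            self.trait_names = tuple(f"trait{i + 1}" for i in range(self.values.shape[1]))
        if len(self.trait_names) != self.values.shape[1]:
            raise ValueError("trait_names length mismatch")
        if np.isnan(self.values).all(axis=1).any():
            raise ValueError("some individuals have no observed trait value")

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def n_observed(self, trait: int) -> int:
        return int(np.isfinite(self.values[:, trait]).sum())

    def select_traits(self, traits) -> "PhenotypeTable":
        idx = list(traits)
        vals = self.values[:, idx]
        keep = ~np.isnan(vals).all(axis=1)
        return PhenotypeTable(
            self.individual_ids[keep], vals[keep], tuple(self.trait_names[i] for i in idx)
        )


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    with open(path, "w") as fh:
        for iid, row in zip(pheno.individual_ids, pheno.values):
            vals = " ".join("NA" if np.isnan(v) else f"{v:.10g}" for v in row)
            fh.write(f"{iid} {iid} {vals}\n")


def read_phenotypes(path, trait_names=()) -> PhenotypeTable:
    df = pd.read_csv(Path(path), sep=r"\s+", header=None, na_values=["NA"])
    if df.shape[1] < 3:
        raise ValueError("phenotype file needs FID IID and at least one trait column")
    return PhenotypeTable(
        df[1].astype(str).to_numpy(dtype=object),
        df.iloc[:, 2:].to_numpy(dtype=float),
        trait_names=tuple(trait_names),
    )
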