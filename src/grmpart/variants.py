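"""Variant map handling: the per-variant table and subset definitions.

The variant table is a :class:`pandas.DataFrame` with one row per variant,
ordered by (chromosome, position). Required columns:

``variant_id``
    unique string identifier,
``chromosome``
    chromosome label as a string; autosomes are numeric strings,
``position``
    1-based base-pair position, strictly increasing within chromosome,
``allele1`` / ``allele2``
    the counted allele and the other allele,
``maf``
    sample minor allele frequency in [0, 0.5],
``dr2``
    imputation quality (squared correlation of imputed and true dosage)
    in [0, 1]; genotyped variants carry 1.0.

Two more columns are filled in by the LD-score stage (NaN before that):
``ld_score`` (1 plus the sum of windowed r2, so always >= 1) and
``snp_num`` (variant count inside the window including the index variant,
the "variant density"). An optional ``category`` column carries a
functional-annotation label per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "allele1",
    "allele2",
    "maf",
    "dr2",
)

SEX_CHROMOSOMES = {"X", "Y", "MT", "XY", "M"}


def make_variant_table(
    variant_id: Sequence[str],
    chromosome: Sequence,
    position: Sequence[int],
    allele1: Sequence[str] | None = None,
    allele2: Sequence[str] | None = None,
    maf: Sequence[float] | None = None,
    dr2: Sequence[float] | None = None,
    category: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble and validate a variant table."""
    n = len(variant_id)
    table = pd.DataFrame(
        {
            "variant_id": np.asarray(variant_id, dtype=object),
            "chromosome": np.asarray(chromosome, dtype=object).astype(str),
            "position": np.asarray(position, dtype=np.int64),
            "allele1": np.asarray(allele1, dtype=object) if allele1 is not None else np.full(n, "A", dtype=object),
            "allele2": np.asarray(allele2, dtype=object) if allele2 is not None else np.full(n, "B", dtype=object),
            "maf": np.asarray(maf, dtype=float) if maf is not None else np.full(n, np.nan),
            "dr2": np.asarray(dr2, dtype=float) if dr2 is not None else np.ones(n),
            "ld_score": np.full(n, np.nan),
            "snp_num": np.full(n, np.nan),
        }
    )
    if category is not None:
        table["category"] = np.asarray(category, dtype=object)
    validate_variant_table(table)
    return table


def validate_variant_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if table["variant_id"].duplicated().any():
        dups = table.loc[table["variant_id"].duplicated(), "variant_id"].tolist()[:5]
        raise ValueError(f"duplicate variant ids: {dups}")
    maf = table["maf"].to_numpy(dtype=float)
    ok = np.isnan(maf) | ((maf >= 0) & (maf <= 0.5))
    if not ok.all():
        raise ValueError("maf outside [0, 0.5]")
    dr2 = table["dr2"].to_numpy(dtype=float)
    if not (((dr2 >= 0) & (dr2 <= 1)) | np.isnan(dr2)).all():
        raise ValueError("dr2 outside [0, 1]")
    for chrom, sub in table.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")


def is_autosome(label: str) -> bool:
    return str(label).upper() not in SEX_CHROMOSOMES and str(label).isdigit()


@dataclass
class SubsetDefinition:
    """A named set of variants used as one genome-partitioning category."""

    name: str
    variant_ids: list[str] = field(default_factory=list)
    provenance: str = "annotation"  # quartile | annotation | external-list

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        if not self.variant_ids:
            raise ValueError(f"subset {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        """Boolean membership over the rows of ``table``."""
        members = set(self.variant_ids)
        return table["variant_id"].isin(members).to_numpy()


def write_subsets_tsv(subsets: Iterable[SubsetDefinition], path) -> None:
    rows = [
        {"subset": s.name, "variant_id": vid, "provenance": s.provenance}
        for s in subsets
        for vid in s.variant_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_subsets_tsv(path) -> list[SubsetDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for name, sub in df.groupby("subset", sort=False):
        prov = sub["provenance"].iloc[0] if "provenance" in sub else "external-list"
        out.append(SubsetDefinition(name=name, variant_ids=sub["variant_id"].tolist(), provenance=prov))
    return out
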