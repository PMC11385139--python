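"""Genotype matrices and PLINK text/binary input-output.

Dosages are stored as the count of ``allele1`` per variant, so every entry
is 0, 1 or 2 after loading (missing genotypes are mean-imputed per variant
at load time and the imputation count is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import make_variant_table

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # variant-major .bed

# two-bit PLINK codes, LSB first within each byte:
# 00 -> homozygous allele1 (dosage 2), 10 -> heterozygous (1),
# 11 -> homozygous allele2 (0), 01 -> missing
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
_BED_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}


@dataclass
class GenotypeMatrix:
    """Individuals-by-variants dosage matrix linked to a variant table."""

    individual_ids: np.ndarray  # shape (n,), str
    dosages: np.ndarray  # shape (n, m), float64 values in {0,1,2}
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if self.dosages.shape[0] != len(self.individual_ids):
            raise ValueError("row count does not match individual ids")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("column count does not match variant table")
        # hard calls are 0/1/2; mean-imputed entries may be fractional but
        # must stay inside the dosage range
        if np.isnan(self.dosages).any():
            raise ValueError("dosages must have no missing values after load")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of allele1 per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def sample_maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset(self, variant_ids) -> "GenotypeMatrix":
        """Restrict to the given variants, preserving map order."""
        members = set(variant_ids)
        keep = self.variants["variant_id"].isin(members).to_numpy()
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            dosages=self.dosages[:, keep],
            variants=self.variants.loc[keep].reset_index(drop=True),
        )

    def standardized(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Columns centred at 2p and scaled by sqrt(2p(1-p))."""
        x = self.dosages if columns is None else self.dosages[:, columns]
        p = x.mean(axis=0) / 2.0
        denom = np.sqrt(2.0 * p * (1.0 - p))
        if np.any(denom == 0):
            bad = np.flatnonzero(denom == 0)
            ids = self.variants["variant_id"].to_numpy()
            if columns is not None:
                ids = ids[columns]
            raise ValueError(f"monomorphic variants cannot be standardized: {list(ids[bad][:5])}")
        return (x - 2.0 * p) / denom

    def unit_norm_columns(self) -> np.ndarray:
        """Columns centred and scaled to unit Euclidean norm, so that the
        dot product of two columns is exactly their Pearson correlation."""
        xc = self.dosages - self.dosages.mean(axis=0)
        norms = np.linalg.norm(xc, axis=0)
        if np.any(norms == 0):
            bad = self.variants["variant_id"].to_numpy()[norms == 0]
            raise ValueError(f"zero-variance dosage columns: {list(bad[:5])}")
        return xc / norms


# ---------------------------------------------------------------------------
# text PLINK (.ped/.map)
# ---------------------------------------------------------------------------

def write_ped_map(geno: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    tab = geno.variants
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in tab.iterrows():
            fh.write(f"{row.chromosome}\t{row.variant_id}\t0\t{row.position}\n")
    a1 = tab["allele1"].to_numpy()
    a2 = tab["allele2"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(geno.individual_ids):
            fields = [str(iid), str(iid), "0", "0", "0", "-9"]
            d = geno.dosages[i]
            for j in range(geno.n_variants):
                k = int(d[j])
                pair = (a1[j], a1[j]) if k == 2 else (a1[j], a2[j]) if k == 1 else (a2[j], a2[j])
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "variant_id", "cm", "position"],
        dtype={"chromosome": str, "variant_id": str},
    )
    iids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            iids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(mp):
                raise ValueError(
                    f".ped row for {parts[1]} has {len(alleles)} alleles, expected {2 * len(mp)}"
                )
            rows.append(alleles)
    alleles = np.array(rows, dtype=object)
    m = len(mp)
    dosages = np.zeros((len(iids), m))
    a1_list, a2_list = [], []
    for j in range(m):
        pair = alleles[:, 2 * j : 2 * j + 2]
        seen = sorted(a for a in pd.unique(pair.ravel()) if a != "0")
        if not seen:
            raise ValueError(f"variant {mp.variant_id[j]} entirely missing")
        # counted allele: alphabetically first, so write->read roundtrips
        a1 = seen[0]
        a2 = seen[1] if len(seen) > 1 else ("B" if a1 != "B" else "A")
        a1_list.append(a1)
        a2_list.append(a2)
        dosages[:, j] = (pair == a1).sum(axis=1)
        miss = (pair == "0").any(axis=1)
        if miss.any():
            mean_d = dosages[~miss, j].mean()
            dosages[miss, j] = mean_d
            logger.info("mean-imputed %d genotypes at %s", int(miss.sum()), mp.variant_id[j])
    maf = np.minimum(dosages.mean(axis=0) / 2, 1 - dosages.mean(axis=0) / 2)
    table = make_variant_table(
        mp["variant_id"], mp["chromosome"], mp["position"], a1_list, a2_list, maf=maf
    )
    return GenotypeMatrix(np.array(iids, dtype=object), np.round(dosages, 0), table)


# ---------------------------------------------------------------------------
# binary PLINK (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

def write_bed(geno: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    tab = geno.variants
    with open(str(prefix) + ".bim", "w") as fh:
        for _, row in tab.iterrows():
            fh.write(f"{row.chromosome}\t{row.variant_id}\t0\t{row.position}\t{row.allele1}\t{row.allele2}\n")
    with open(str(prefix) + ".fam", "w") as fh:
        for iid in geno.individual_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    n = geno.n_individuals
    n_bytes = (n + 3) // 4
    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.empty(n, dtype=np.uint8)
        for j in range(geno.n_variants):
            col = geno.dosages[:, j].astype(int)
            for k, c in _BED_ENCODE.items():
                codes[col == k] = c
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for off in range(4):
                chunk = codes[off::4]
                packed[: len(chunk)] |= chunk << (2 * off)
            fh.write(packed.tobytes())


def read_bed(prefix) -> GenotypeMatrix:
    """Decode a variant-major .bed triplet; missing genotypes are
    mean-imputed (dosage 2p from the observed individuals)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        str(prefix) + ".bim",
        sep=r"\s+",
        header=None,
        names=["chromosome", "variant_id", "cm", "position", "allele1", "allele2"],
        dtype=str,
    )
    bim["position"] = bim["position"].astype(np.int64)
    if bim["variant_id"].duplicated().any():
        raise ValueError("duplicate variant IDs in .bim")
    fam = pd.read_csv(str(prefix) + ".fam", sep=r"\s+", header=None, dtype=str)
    iids = fam[1].to_numpy(dtype=object)
    n, m = len(iids), len(bim)
    n_bytes = (n + 3) // 4
    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(".bed magic bytes do not match variant-major PLINK format")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != n_bytes * m:
        raise ValueError(
            f".bed payload is {len(body)} bytes, expected {n_bytes * m} for {n} individuals x {m} variants"
        )
    body = body.reshape(m, n_bytes)
    # unpack 2-bit codes, LSB first
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for off in range(4):
        codes[:, off::4] = (body >> (2 * off)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T.copy()  # (n, m)
    n_imputed = 0
    for j in range(m):
        col = dosages[:, j]
        miss = np.isnan(col)
        if miss.any():
            if miss.all():
                raise ValueError(f"variant {bim.variant_id[j]} entirely missing")
            col[miss] = col[~miss].mean()
            n_imputed += int(miss.sum())
    if n_imputed:
        logger.info("mean-imputed %d missing genotypes", n_imputed)
    maf = np.minimum(dosages.mean(axis=0) / 2, 1 - dosages.mean(axis=0) / 2)
    table = make_variant_table(
        bim["variant_id"], bim["chromosome"], bim["position"],
        bim["allele1"], bim["allele2"], maf=maf,
    )
    return GenotypeMatrix(iids, dosages, table)


def load_plink(prefix) -> GenotypeMatrix:
    """Load genotypes from ``prefix`` (.bed/.bim/.fam preferred, else .ped/.map)."""
    prefix = Path(prefix)
    if Path(str(prefix) + ".bed").exists():
        return read_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return read_ped_map(prefix)
    raise FileNotFoundError(f"no PLINK fileset at {prefix}")
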