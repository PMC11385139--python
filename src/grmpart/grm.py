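"""Additive genomic relationship matrices (GRMs).

The estimator is the per-variant-standardized form

    G_jk = (1/M) sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m)),

with p_m the sample frequency of the counted allele and M the number of
variants used. Allele frequencies always come from the analysed sample
itself. On disk the GCTA binary dialect is used: ``.grm.bin`` holds the
lower triangle (row-major, float32), ``.grm.N.bin`` the per-pair variant
counts (float32) and ``.grm.id`` two whitespace-separated id columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype import GenotypeMatrix


@dataclass
class Grm:
    matrix: np.ndarray  # (n, n) float64
    individual_ids: np.ndarray
    n_variants_used: int
    name: str = "grm"

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.float64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n = len(self.individual_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape does not match individual ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def align(self, ids) -> np.ndarray:
        """Submatrix for ``ids`` in that order; errors on unknown ids."""
        pos = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            idx = np.array([pos[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in GRM {self.name!r}") from None
        return self.matrix[np.ix_(idx, idx)]


def compute_grm(
    genotypes: GenotypeMatrix,
    variant_ids=None,
    name: str = "grm",
) -> Grm:
    """GRM over ``variant_ids`` (default: all variants in the matrix)."""
    if variant_ids is None:
        cols = np.arange(genotypes.n_variants)
    else:
        members = set(variant_ids)
        cols = np.flatnonzero(genotypes.variants["variant_id"].isin(members).to_numpy())
        if len(cols) != len(members):
            present = set(genotypes.variants["variant_id"].iloc[cols])
            missing = sorted(members - present)[:5]
            raise KeyError(f"subset variants absent from genotype matrix: {missing}")
    x = genotypes.dosages[:, cols]
    p = x.mean(axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        ids = genotypes.variants["variant_id"].to_numpy()[cols[mono]]
        raise ValueError(f"monomorphic variants in GRM subset: {list(ids[:10])}")
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    g = (w @ w.T) / len(cols)
    return Grm(g, genotypes.individual_ids, n_variants_used=len(cols), name=name)


def write_grm_gcta(grm: Grm, prefix) -> None:
    prefix = Path(prefix)
    n = grm.n
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype("<f4").tofile(str(prefix) + ".grm.bin")
    np.full(tri.shape, grm.n_variants_used, dtype="<f4").tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in grm.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_gcta(prefix, name: str | None = None) -> Grm:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(str(prefix) + ".grm.id") if line.strip()]
    n = len(ids)
    expect = n * (n + 1) // 2
    tri = np.fromfile(str(prefix) + ".grm.bin", dtype="<f4")
    if len(tri) != expect:
        raise ValueError(
            f".grm.bin holds {len(tri)} values but .grm.id lists {n} individuals "
            f"(need n(n+1)/2 = {expect})"
        )
    counts = np.fromfile(str(prefix) + ".grm.N.bin", dtype="<f4")
    if len(counts) != expect:
        raise ValueError(".grm.N.bin length does not match n(n+1)/2")
    mat = np.zeros((n, n))
    il = np.tril_indices(n)
    mat[il] = tri.astype(np.float64)
    mat = mat + mat.T - np.diag(np.diag(mat))
    return Grm(
        mat,
        np.array(ids, dtype=object),
        n_variants_used=int(round(float(counts.max()))) if len(counts) else 0,
        name=name or prefix.name,
    )
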