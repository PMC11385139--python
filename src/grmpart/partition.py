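"""Variant filtering and genome-partitioning subsets.

Filters mirror routine imputed-sequence quality control: drop sex
chromosomes, a minor-allele-frequency floor and a DR2 imputation-quality
floor. Partitioning produces rank-based quartile subsets of the windowed
LD score, the variant density (count of variants in the window) and the
MAF, plus annotation-category subsets and externally supplied membership
lists.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .variants import SubsetDefinition, is_autosome, validate_variant_table

logger = logging.getLogger(__name__)

_QUARTILE_PREFIX = {"ld_score": "LD", "snp_num": "VD", "maf": "MAF"}


def filter_variants(
    table: pd.DataFrame,
    maf_min: float = 0.05,
    dr2_min: float = 0.75,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Keep variants with maf >= maf_min, dr2 >= dr2_min and (optionally)
    autosomal location; order preserved, removal counts logged."""
    validate_variant_table(table)
    keep = np.ones(len(table), dtype=bool)
    maf = table["maf"].to_numpy(dtype=float)
    dr2 = table["dr2"].to_numpy(dtype=float)
    drop_maf = maf < maf_min
    drop_dr2 = dr2 < dr2_min
    keep &= ~drop_maf
    keep &= ~drop_dr2
    if autosomes_only:
        drop_sex = ~table["chromosome"].map(is_autosome).to_numpy()
        keep &= ~drop_sex
    else:
        drop_sex = np.zeros(len(table), dtype=bool)
    logger.info(
        "filter_variants: %d below MAF %.3g, %d below DR2 %.3g, %d on sex chromosomes, %d retained",
        int(drop_maf.sum()), maf_min, int(drop_dr2.sum()), dr2_min,
        int(drop_sex.sum()), int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("no variants survive the filters")
    return table.loc[keep].reset_index(drop=True)


def compute_ld_scores(
    genotypes: GenotypeMatrix,
    window_bp: int = 50_000,
    chunk: int = 2_000,
) -> pd.DataFrame:
    """Windowed LD score and variant density for every variant.

    For variant i: ld_score_i = 1 + sum of r2(i, j) over all other
    variants j on the same chromosome with |pos_i - pos_j| <= window_bp;
    snp_num_i counts the variants in that window including i itself.
    r2 is the squared Pearson correlation of the dosage vectors.
    Returns a copy of the variant table with both columns filled.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    table = genotypes.variants.copy()
    z = genotypes.unit_norm_columns()  # corr = z'z
    ld = np.ones(len(table))
    num = np.ones(len(table), dtype=np.int64)
    for _, idx in table.groupby("chromosome", sort=False).indices.items():
        idx = np.sort(idx)
        pos = table["position"].to_numpy()[idx]
        zc = z[:, idx]
        mc = len(idx)
        for start in range(0, mc, chunk):
            stop = min(start + chunk, mc)
            lo = np.searchsorted(pos, pos[start:stop] - window_bp, side="left")
            hi = np.searchsorted(pos, pos[start:stop] + window_bp, side="right")
            r = zc[:, lo.min() : hi.max()].T @ zc[:, start:stop]  # (win, block)
            r2 = r**2
            for k in range(stop - start):
                a, b = lo[k] - lo.min(), hi[k] - lo.min()
                j = start + k
                # self term contributes exactly 1
                ld[idx[j]] = 1.0 + r2[a:b, k].sum() - r2[j - lo.min(), k]
                num[idx[j]] = b - a
    table["ld_score"] = ld
    table["snp_num"] = num
    return table


def quartile_subsets(
    table: pd.DataFrame,
    field: str,
    drop_lowest: bool = False,
) -> list[SubsetDefinition]:
    """Rank-based quartiles of ``field`` (ld_score, snp_num or maf).

    Variants are ranked ascending, ties broken by genome order
    (chromosome, position); the four groups have sizes differing by at
    most one, named e.g. LD1..LD4 with 1 the lowest. ``drop_lowest``
    omits quartile 1 (used for the MAF field).
    """
    if field not in _QUARTILE_PREFIX:
        raise ValueError(f"field must be one of {sorted(_QUARTILE_PREFIX)}")
    if len(table) < 4:
        raise ValueError("need at least 4 variants to form quartiles")
    values = table[field].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{field} not populated for all variants")
    chrom_rank = pd.factorize(table["chromosome"], sort=False)[0]
    order = np.lexsort((table["position"].to_numpy(), chrom_rank, values))
    groups = np.array_split(order, 4)
    prefix = _QUARTILE_PREFIX[field]
    ids = table["variant_id"].to_numpy()
    out = []
    for q, grp in enumerate(groups, start=1):
        if drop_lowest and q == 1:
            continue
        out.append(
            SubsetDefinition(f"{prefix}{q}", ids[np.sort(grp)].tolist(), provenance="quartile")
        )
    return out


def annotation_subsets(
    table: pd.DataFrame,
    category_map: Mapping[str, str] | None = None,
    external_lists: Mapping[str, Sequence[str] | str | Path] | None = None,
) -> list[SubsetDefinition]:
    """Annotation-category subsets plus external membership lists.

    ``category_map`` maps raw annotation labels onto subset names (several
    labels may merge into one subset). ``external_lists`` maps a subset
    name onto either a sequence of variant ids or a path to a
    one-id-per-line file; each list is intersected with the table and the
    overlap logged. A variant may belong to several subsets.
    """
    out: list[SubsetDefinition] = []
    ids = table["variant_id"].to_numpy()
    if category_map:
        if "category" not in table.columns:
            raise ValueError("table has no 'category' column for annotation subsets")
        cats = table["category"].to_numpy()
        subset_names = list(dict.fromkeys(category_map.values()))
        for name in subset_names:
            labels = {lab for lab, s in category_map.items() if s == name}
            member = np.isin(cats, sorted(labels))
            if member.any():
                out.append(SubsetDefinition(name, ids[member].tolist(), provenance="annotation"))
            else:
                logger.warning("annotation subset %r matched no variants; skipped", name)
    if external_lists:
        known = set(ids)
        for name, src in external_lists.items():
            if isinstance(src, (str, Path)):
                wanted = [ln.strip() for ln in open(src) if ln.strip()]
            else:
                wanted = list(src)
            present = [v for v in wanted if v in known]
            if not present:
                raise ValueError(f"external list {name!r} has zero overlap with the variant table")
            if len(present) < len(wanted):
                logger.warning(
                    "external list %r: %d of %d ids present in the variant table",
                    name, len(present), len(wanted),
                )
            out.append(SubsetDefinition(name, present, provenance="external-list"))
    return out
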