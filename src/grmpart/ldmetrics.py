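"""Subset-level linkage-disequilibrium characterization.

For a variant subset, every subset variant is paired with every other
variant within a physical window (default 500 kbp) on the same
chromosome. A pair is *intern* when both members belong to the subset
and *extern* when exactly one does. Six parameters summarize a subset:

* ``mean_ld_extern`` / ``mean_ld_intern`` — mean r2 over extern/intern
  pairs,
* ``decay_extern`` / ``decay_intern`` — mean r2 of pairs at long range
  (120-500 kbp) over mean r2 at short range (<= 25 kbp); values above 1
  are legal and mean LD increases with distance,
* ``distribution`` — intern pairs as a share of all pairs; 1 means no
  non-subset variant falls inside any subset variant's window, low
  values mean the subset is clustered among other variants,
* ``mean_maf`` — mean minor allele frequency of the subset variants.

Empty strata yield :class:`~grmpart._util.Undefined` carrying the
reason, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import Undefined, is_defined
from .genotype import GenotypeMatrix
from .variants import SubsetDefinition

PAIR_COLUMNS = ["chrom", "pos_a", "variant_a", "pos_b", "variant_b", "distance", "r2", "class"]


@dataclass
class LdMetrics:
    mean_ld_extern: float | Undefined
    mean_ld_intern: float | Undefined
    decay_extern: float | Undefined
    decay_intern: float | Undefined
    distribution: float | Undefined
    mean_maf: float

    def as_dict(self) -> dict:
        return {
            "mean_ld_extern": self.mean_ld_extern,
            "mean_ld_intern": self.mean_ld_intern,
            "decay_extern": self.decay_extern,
            "decay_intern": self.decay_intern,
            "distribution": self.distribution,
            "mean_maf": self.mean_maf,
        }


def enumerate_pairs(
    genotypes: GenotypeMatrix,
    subset: SubsetDefinition,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """All (subset variant, other variant) pairs within the window.

    Pairs between two subset variants appear once (class ``intern``);
    pairs with exactly one subset member once with class ``extern``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    table = genotypes.variants
    member = subset.mask(table)
    if not member.any():
        raise ValueError(f"subset {subset.name!r} has no variants in the genotype matrix")
    z = genotypes.unit_norm_columns()
    rows = []
    for chrom, idx in table.groupby("chromosome", sort=False).indices.items():
        idx = np.sort(idx)
        pos = table["position"].to_numpy()[idx]
        ids = table["variant_id"].to_numpy()[idx]
        mem = member[idx]
        sub_local = np.flatnonzero(mem)
        if len(sub_local) == 0:
            continue
        zc = z[:, idx]
        for a in sub_local:
            lo = np.searchsorted(pos, pos[a] - window_bp, side="left")
            hi = np.searchsorted(pos, pos[a] + window_bp, side="right")
            nb = np.arange(lo, hi)
            nb = nb[nb != a]
            if len(nb) == 0:
                continue
            # intern pairs only once: keep b > a among subset members
            keep = ~mem[nb] | (nb > a)
            nb = nb[keep]
            if len(nb) == 0:
                continue
            r2 = (zc[:, nb].T @ zc[:, a]) ** 2
            for b, val in zip(nb, r2):
                rows.append(
                    (
                        chrom,
                        int(pos[a]),
                        ids[a],
                        int(pos[b]),
                        ids[b],
                        int(abs(pos[b] - pos[a])),
                        float(val),
                        "intern" if mem[b] else "extern",
                    )
                )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _stratum_mean(r2: np.ndarray, dist: np.ndarray, mask, label: str) -> float | Undefined:
    sel = r2[mask]
    if len(sel) == 0:
        return Undefined(f"no pairs in the {label} stratum")
    return float(sel.mean())


def _decay(r2: np.ndarray, dist: np.ndarray, near_bp: int, far_lo_bp: int, far_hi_bp: int, klass: str):
    near = _stratum_mean(r2, dist, dist <= near_bp, f"{klass} near (<= {near_bp} bp)")
    far = _stratum_mean(
        r2, dist, (dist > far_lo_bp) & (dist <= far_hi_bp), f"{klass} far ({far_lo_bp}-{far_hi_bp} bp)"
    )
    if not is_defined(near):
        return near
    if not is_defined(far):
        return far
    if near == 0:
        return Undefined(f"zero mean r2 in the {klass} near stratum")
    return float(far / near)


def subset_metrics(
    pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    subset: SubsetDefinition,
    near_bp: int = 25_000,
    far_lo_bp: int = 120_000,
    far_hi_bp: int = 500_000,
) -> LdMetrics:
    """The six LD/MAF/distribution parameters from an enumerated pair list."""
    member = subset.mask(genotypes.variants)
    mean_maf = float(genotypes.sample_maf()[member].mean())
    if len(pairs) == 0:
        why = Undefined("no variant pairs within the window")
        return LdMetrics(why, why, why, why, why, mean_maf)
    r2 = pairs["r2"].to_numpy()
    dist = pairs["distance"].to_numpy()
    ext = (pairs["class"] == "extern").to_numpy()
    intern = ~ext
    n_int, n_ext = int(intern.sum()), int(ext.sum())
    return LdMetrics(
        mean_ld_extern=(
            _stratum_mean(r2[ext], dist[ext], np.ones(n_ext, bool), "extern")
            if n_ext
            else Undefined("no extern pairs")
        ),
        mean_ld_intern=(
            _stratum_mean(r2[intern], dist[intern], np.ones(n_int, bool), "intern")
            if n_int
            else Undefined("no intern pairs")
        ),
        decay_extern=(
            _decay(r2[ext], dist[ext], near_bp, far_lo_bp, far_hi_bp, "extern")
            if n_ext
            else Undefined("no extern pairs")
        ),
        decay_intern=(
            _decay(r2[intern], dist[intern], near_bp, far_lo_bp, far_hi_bp, "intern")
            if n_int
            else Undefined("no intern pairs")
        ),
        distribution=float(n_int / (n_int + n_ext)),
        mean_maf=mean_maf,
    )


def correlate_metrics(
    metrics_by_subset: dict[str, LdMetrics],
    per_variant_h2_by_subset: dict[str, float],
) -> pd.DataFrame:
    """Pearson correlation of each LD parameter with the across-trait
    per-variant h2, over subsets where both are defined."""
    params = ["mean_ld_extern", "mean_ld_intern", "decay_extern", "decay_intern", "distribution", "mean_maf"]
    rows = []
    for p in params:
        xs, ys = [], []
        for name, m in metrics_by_subset.items():
            v = m.as_dict()[p]
            h = per_variant_h2_by_subset.get(name)
            if is_defined(v) and h is not None and np.isfinite(h):
                xs.append(float(v))
                ys.append(float(h))
        if len(xs) < 3:
            rows.append({"parameter": p, "r": np.nan, "n": len(xs), "reason": "fewer than 3 complete subsets"})
            continue
        x, y = np.array(xs), np.array(ys)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"parameter": p, "r": np.nan, "n": len(xs), "reason": "zero variance"})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"parameter": p, "r": r, "n": len(xs), "reason": ""})
    return pd.DataFrame(rows)
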