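"""Synthetic genotypes, annotations and phenotypes with known truth.

Genotypes follow a block-mosaic haplotype model: the genome is tiled into
blocks of fixed physical length, each block carries a small finite pool of
haplotypes, and every individual draws two pool haplotypes per block.
Variants inside one block therefore share haplotype identity and show
strong LD, while variants in different blocks are drawn independently and
are essentially uncorrelated. This is deliberately simpler than a
coalescent model; it is fully seeded and produces the within/between
subset LD contrasts the LD metrics need to detect.

Phenotypes follow the two-component additive model used throughout the
package: for each trait t,

    y_t = g_chip,t + g_set,t + e_t,

where each genetic component is a sum of standardized-dosage effects over
its causal set, effect pairs across the two traits are bivariate normal,
and the per-component effect variance is scaled so the expected component
(co)variances equal the configured targets on the standardized scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype import GenotypeMatrix
from .phenotype import PhenotypeTable
from .variants import SubsetDefinition, make_variant_table

_ANNOTATION_LABELS = (
    ("intergenic", 0.45),
    ("intron", 0.30),
    ("gene_end", 0.10),
    ("5_prime_UTR", 0.04),
    ("3_prime_UTR", 0.05),
    ("splice_site", 0.02),
    ("noncoding_transcript_exon_variant", 0.02),
    ("missense", 0.02),
)


@dataclass(frozen=True)
class SubsetSpec:
    """One requested variant subset: absolute count or proportion, placed
    either in one consecutive map run ("clustered") or spread at random
    ("uniform")."""

    name: str
    size: float  # int count, or proportion if < 1
    placement: str = "uniform"

    def count(self, n_variants: int) -> int:
        if 0 < self.size < 1:
            return max(1, int(round(self.size * n_variants)))
        return int(self.size)


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 1000
    n_variants: int = 5000
    n_chromosomes: int = 5
    block_length_bp: int = 25_000
    haplotypes_per_block: int = 8
    variant_spacing_bp: int = 1_000
    maf_floor: float = 0.05
    subset_specs: tuple[SubsetSpec, ...] = (SubsetSpec("subset", 0.10, "uniform"),)
    n_traits: int = 2
    var_g_chip: float = 0.30
    var_g_subset: float = 0.10
    var_e: float = 0.60
    cov_g_chip: float = -0.06
    cov_g_subset: float = -0.05
    cov_e: float = -0.06
    n_causal_chip: int = 500
    n_causal_subset: int = 100
    missing_rate_trait2: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_variants < 1:
            raise ValueError("need at least 2 individuals and 1 variant")
        for name in ("var_g_chip", "var_g_subset", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        pairs = [
            ("cov_g_chip", self.var_g_chip, self.var_g_chip),
            ("cov_g_subset", self.var_g_subset, self.var_g_subset),
            ("cov_e", self.var_e, self.var_e),
        ]
        for name, v1, v2 in pairs:
            if abs(getattr(self, name)) > np.sqrt(v1 * v2) + 1e-12:
                raise ValueError(f"|{name}| exceeds sqrt of its variance product")
        if not 0 <= self.missing_rate_trait2 < 1:
            raise ValueError("missing_rate_trait2 must be in [0, 1)")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        total = sum(s.count(self.n_variants) for s in self.subset_specs)
        if total > self.n_variants:
            raise ValueError("subset sizes sum to more than n_variants")
        if self.n_traits not in (1, 2):
            raise ValueError("n_traits must be 1 or 2")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "subset_specs" in data:
            data["subset_specs"] = tuple(
                s if isinstance(s, SubsetSpec) else SubsetSpec(**s) for s in data["subset_specs"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["subset_specs"] = [dataclasses.asdict(s) for s in self.subset_specs]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthRecord:
    """Realized per-component genetic values and the statistics implied by
    the drawn effects; reproduces exactly under the same seed."""

    g_chip: np.ndarray  # (n, n_traits)
    g_subset: np.ndarray
    residual: np.ndarray
    causal_chip_ids: list[str]
    causal_subset_ids: list[str]
    realized: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"statistic": k, "value": v} for k, v in sorted(self.realized.items())]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _chromosome_sizes(n_variants: int, n_chromosomes: int) -> list[int]:
    base = n_variants // n_chromosomes
    sizes = [base] * n_chromosomes
    for i in range(n_variants - base * n_chromosomes):
        sizes[i] += 1
    return [s for s in sizes if s > 0]


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, list[SubsetDefinition]]:
    """Draw a block-mosaic genotype matrix and the configured subsets."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    max_tries = 200

    chrom_labels, positions, columns = [], [], []
    vars_per_block = max(1, config.block_length_bp // config.variant_spacing_bp)
    for ci, size in enumerate(_chromosome_sizes(config.n_variants, config.n_chromosomes)):
        chrom = str(ci + 1)
        pos = (np.arange(size) + 1) * config.variant_spacing_bp
        chrom_labels.extend([chrom] * size)
        positions.extend(pos.tolist())
        for start in range(0, size, vars_per_block):
            v = min(vars_per_block, size - start)
            k = config.haplotypes_per_block
            assign = rng.integers(0, k, size=(n, 2))
            q = rng.uniform(config.maf_floor, 0.5, size=v)
            pool = (rng.random((k, v)) < q).astype(np.int8)
            dos = pool[assign[:, 0]] + pool[assign[:, 1]].astype(np.float64)
            freq = dos.mean(axis=0) / 2.0
            bad = np.minimum(freq, 1 - freq) < config.maf_floor
            tries = 0
            while bad.any():
                tries += 1
                if tries > max_tries:
                    raise ValueError(
                        f"cannot satisfy MAF floor {config.maf_floor} on chromosome "
                        f"{chrom}, block starting at variant {start} "
                        f"(haplotype pool of {k} too small)"
                    )
                nb = int(bad.sum())
                q_new = rng.uniform(config.maf_floor, 0.5, size=nb)
                pool[:, bad] = rng.random((k, nb)) < q_new
                dos[:, bad] = pool[assign[:, 0]][:, bad] + pool[assign[:, 1]][:, bad]
                freq = dos.mean(axis=0) / 2.0
                bad = np.minimum(freq, 1 - freq) < config.maf_floor
            columns.append(dos)

    dosages = np.concatenate(columns, axis=1)
    m = dosages.shape[1]
    labels, probs = zip(*_ANNOTATION_LABELS)
    categories = rng.choice(labels, size=m, p=np.array(probs) / sum(probs))
    freq = dosages.mean(axis=0) / 2.0
    table = make_variant_table(
        [f"var{i + 1}" for i in range(m)],
        chrom_labels,
        positions,
        maf=np.minimum(freq, 1 - freq),
        category=categories,
    )
    iids = np.array([f"ind{i + 1}" for i in range(n)], dtype=object)
    geno = GenotypeMatrix(iids, dosages, table)
    subsets = _place_subsets(config, table, rng)
    return geno, subsets


def _place_subsets(config: SimConfig, table: pd.DataFrame, rng) -> list[SubsetDefinition]:
    m = len(table)
    ids = table["variant_id"].to_numpy()
    taken = np.zeros(m, dtype=bool)
    out: list[SubsetDefinition] = []
    # clustered subsets claim consecutive runs first, then uniform ones
    # draw from whatever remains, so subsets stay disjoint
    for spec in sorted(config.subset_specs, key=lambda s: s.placement != "clustered"):
        size = spec.count(m)
        if spec.placement == "clustered":
            for _ in range(200):
                start = int(rng.integers(0, m - size + 1))
                if not taken[start : start + size].any():
                    idx = np.arange(start, start + size)
                    break
            else:
                raise ValueError(f"cannot place clustered subset {spec.name!r}")
        elif spec.placement == "uniform":
            free = np.flatnonzero(~taken)
            if len(free) < size:
                raise ValueError(f"not enough free variants for subset {spec.name!r}")
            idx = rng.choice(free, size=size, replace=False)
            idx.sort()
        else:
            raise ValueError(f"unknown placement policy {spec.placement!r}")
        taken[idx] = True
        out.append(SubsetDefinition(spec.name, ids[idx].tolist(), provenance="external-list"))
    # restore the caller's ordering
    order = {s.name: i for i, s in enumerate(config.subset_specs)}
    out.sort(key=lambda s: order[s.name])
    return out


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _component_sigma(var: float, cov: float, n_traits: int) -> np.ndarray:
    if n_traits == 1:
        return np.array([[var]])
    sig = np.array([[var, cov], [cov, var]])
    if np.linalg.eigvalsh(sig)[0] < -1e-12:
        raise ValueError("component covariance matrix is not positive semidefinite")
    return sig


def _draw_effects(rng, sigma: np.ndarray, n_causal: int) -> np.ndarray:
    # exact Cholesky draw; PSD-but-singular matrices get an eigen fallback
    try:
        chol = np.linalg.cholesky(sigma + 1e-14 * np.eye(len(sigma)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("effect covariance not positive semidefinite") from exc
    z = rng.standard_normal((n_causal, len(sigma)))
    return z @ chol.T / np.sqrt(n_causal)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    subsets: list[SubsetDefinition],
    config: SimConfig,
) -> tuple[PhenotypeTable, TruthRecord]:
    """Draw phenotypes under the two-component model; the first subset in
    ``subsets`` is the focal genetic subset, the chip component draws its
    causal variants from the complement."""
    rng = np.random.default_rng([config.seed, 104729])
    t = config.n_traits
    ids = genotypes.variants["variant_id"].to_numpy()
    focal = subsets[0].mask(genotypes.variants) if subsets else np.zeros(len(ids), bool)
    chip_pool = np.flatnonzero(~focal)
    set_pool = np.flatnonzero(focal)
    if config.n_causal_chip > len(chip_pool):
        raise ValueError("n_causal_chip exceeds the non-subset variant pool")
    if config.n_causal_subset > len(set_pool):
        raise ValueError("n_causal_subset exceeds the subset variant pool")

    n = genotypes.n_individuals
    g = {}
    causal = {}
    for comp, pool, n_causal, var, cov in (
        ("chip", chip_pool, config.n_causal_chip, config.var_g_chip, config.cov_g_chip),
        ("subset", set_pool, config.n_causal_subset, config.var_g_subset, config.cov_g_subset),
    ):
        if n_causal > 0 and var > 0:
            cols = np.sort(rng.choice(pool, size=n_causal, replace=False))
            beta = _draw_effects(rng, _component_sigma(var, cov, t), n_causal)
            z = genotypes.standardized(cols)
            g[comp] = z @ beta
            causal[comp] = ids[cols].tolist()
        else:
            g[comp] = np.zeros((n, t))
            causal[comp] = []

    sig_e = _component_sigma(config.var_e, config.cov_e, t)
    e = rng.standard_normal((n, t)) @ np.linalg.cholesky(sig_e + 1e-14 * np.eye(t)).T
    y = g["chip"] + g["subset"] + e

    if t == 2 and config.missing_rate_trait2 > 0:
        mask = rng.random(n) < config.missing_rate_trait2
        y = y.copy()
        y[mask, 1] = np.nan

    realized = {}
    for comp, vals in (("chip", g["chip"]), ("subset", g["subset"]), ("e", e)):
        for j in range(t):
            realized[f"var_{comp}_t{j + 1}"] = float(np.var(vals[:, j], ddof=1))
        if t == 2:
            c = float(np.cov(vals[:, 0], vals[:, 1], ddof=1)[0, 1])
            realized[f"cov_{comp}_12"] = c
            denom = np.sqrt(realized[f"var_{comp}_t1"] * realized[f"var_{comp}_t2"])
            if denom > 0:
                realized[f"r_g_{comp}_12" if comp != "e" else "r_e_12"] = c / denom
    for j in range(t):
        tot = sum(realized[f"var_{c}_t{j + 1}"] for c in ("chip", "subset", "e"))
        realized[f"h2_50K_t{j + 1}"] = realized[f"var_chip_t{j + 1}"] / tot
        realized[f"h2_set_t{j + 1}"] = realized[f"var_subset_t{j + 1}"] / tot

    pheno = PhenotypeTable(genotypes.individual_ids, y)
    truth = TruthRecord(
        g_chip=g["chip"],
        g_subset=g["subset"],
        residual=e,
        causal_chip_ids=causal["chip"],
        causal_subset_ids=causal["subset"],
        realized=realized,
    )
    return pheno, truth
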