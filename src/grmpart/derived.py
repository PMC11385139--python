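"""Statistics derived from fitted variance components.

From a two-GRM univariate fit the phenotypic variance splits as

    h2_set = s2_set / (s2_set + s2_chip + s2_e),
    h2_chip = s2_chip / (s2_set + s2_chip + s2_e),

and from a bivariate fit each random term yields a correlation

    r = cov_12 / sqrt(var_1 * var_2)

plus the three relative covariances, each covariance divided by the sum
of the absolute values of all three covariance terms (so the relative
covariances keep their signs and their absolute values add to one).

Standard errors for all ratio statistics use the first-order delta method
on the sampling covariance of the components from the AI matrix.

Per-variant summaries divide subset-level estimates by the subset's
variant count (and, for the across-trait value, by the number of traits)
to make small causal-variant-rich subsets comparable with huge ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import Undefined, is_defined
from .reml import BiFit, UniFit


@dataclass
class Estimate:
    value: float
    se: float
    clamped: bool = False

    @property
    def significant(self) -> bool:
        flag = significance_flag(self.value, self.se)
        return bool(flag) if is_defined(flag) else False


def _delta_se(grad: np.ndarray, cov: np.ndarray) -> float:
    with np.errstate(over="ignore"):
        return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def heritabilities(fit: UniFit) -> dict[str, Estimate]:
    """Fraction of phenotypic variance per genetic term.

    For a two-GRM fit the keys are ``h2_<term>`` for each genetic term
    (both share the denominator s2_1 + s2_2 + s2_e); a single-GRM fit
    returns the ordinary h2 = s2_g / (s2_g + s2_e).
    """
    names = fit.term_names
    theta = np.array([fit.sigma2[nm] for nm in names])
    total = float(theta.sum())
    if total == 0:
        raise ValueError("zero phenotypic variance: heritability undefined")
    out = {}
    for k, nm in enumerate(names[:-1]):  # genetic terms only
        h = theta[k] / total
        grad = np.full(len(theta), -theta[k] / total**2)
        grad[k] += 1.0 / total
        out[f"h2_{nm}"] = Estimate(h, _delta_se(grad, fit.sampling_cov))
    return out


def genetic_correlations(fit: BiFit) -> dict[str, Estimate | Undefined]:
    """Correlation cov12 / sqrt(var1 var2) per random term.

    Values outside [-1, 1] are clamped and flagged; a nonpositive
    variance makes the correlation undefined (reported, not raised).
    """
    out: dict[str, Estimate | Undefined] = {}
    for k, nm in enumerate(fit.term_names):
        blk = fit.blocks[nm]
        v1, v2, c = blk[0, 0], blk[1, 1], blk[0, 1]
        key = f"r_{nm}"
        if v1 <= 0 or v2 <= 0:
            out[key] = Undefined(f"nonpositive variance for term {nm!r}")
            continue
        r = c / np.sqrt(v1 * v2)
        # parameter order: (var1, var2, cov12) within the term's triple
        grad = np.zeros(fit.sampling_cov.shape[0])
        grad[3 * k] = -r / (2 * v1)
        grad[3 * k + 1] = -r / (2 * v2)
        grad[3 * k + 2] = 1.0 / np.sqrt(v1 * v2)
        se = _delta_se(grad, fit.sampling_cov)
        clamped = abs(r) > 1
        out[key] = Estimate(float(np.clip(r, -1.0, 1.0)), se, clamped=clamped)
    return out


def relative_covariances(fit: BiFit) -> dict[str, Estimate] | Undefined:
    """Signed share of each covariance term in the total absolute covariance."""
    covs = np.array([fit.blocks[nm][0, 1] for nm in fit.term_names])
    if not np.isfinite(covs).all():
        raise ValueError("covariance estimates are not finite")
    total = float(np.abs(covs).sum())
    if total == 0:
        return Undefined("all covariance terms are exactly zero")
    p = fit.sampling_cov.shape[0]
    out = {}
    for k, nm in enumerate(fit.term_names):
        val = covs[k] / total
        grad = np.zeros(p)
        # total^2 can underflow to 0 for subnormal covariances; the ratio
        # itself is still well defined, only its SE degenerates
        with np.errstate(divide="ignore", invalid="ignore"):
            for j in range(len(fit.term_names)):
                grad[3 * j + 2] = (
                    (1.0 if j == k else 0.0) / total - covs[k] * np.sign(covs[j]) / total**2
                )
            se = _delta_se(grad, fit.sampling_cov) if np.isfinite(grad).all() else float("nan")
        out[f"relcov_{nm}"] = Estimate(float(val), se)
    return out


def significance_flag(estimate: float, se: float) -> bool | Undefined:
    """Inclusive two-standard-error rule: |estimate| >= 2 se."""
    if se is None or not np.isfinite(se) or se <= 0:
        return Undefined("standard error not positive")
    return bool(abs(estimate) >= 2.0 * se)


def across_trait_per_variant_h2(
    h2_by_trait, n_variants: int, n_traits: int | None = None
) -> float | Undefined:
    """Sum of per-trait subset heritabilities over (n_traits * n_variants)."""
    if n_variants <= 0:
        raise ValueError("subset size must be positive")
    values = list(h2_by_trait)
    n_traits = n_traits if n_traits is not None else len(values)
    if len(values) != n_traits or any(v is None or not np.isfinite(v) for v in values):
        return Undefined("missing trait estimate")
    return float(sum(values) / (n_traits * n_variants))


def per_variant(value: float, n_variants: int) -> float:
    """A subset-level estimate divided by the subset's variant count."""
    if n_variants <= 0:
        raise ValueError("subset size must be positive")
    return float(value) / n_variants


def per_variant_summary_table(
    estimates: pd.DataFrame,
    subset_sizes: dict[str, int],
    n_traits: int | None = None,
) -> pd.DataFrame:
    """Long-format per-variant summary over subsets.

    ``estimates`` needs columns (subset, trait, statistic, estimate) with
    statistic "h2_set" per trait and optionally "r_g_set" per trait pair
    (the pair label goes in the trait column). Emits one row per
    (subset, statistic): the across-trait per-variant h2, the
    trait-specific per-variant h2 per trait, and the signed
    trait-specific per-variant r_g with its absolute value alongside.
    """
    rows = []
    for subset, sub in estimates.groupby("subset", sort=False):
        if subset not in subset_sizes:
            raise KeyError(f"no variant count for subset {subset!r}")
        m = subset_sizes[subset]
        h2 = sub[sub["statistic"] == "h2_set"]
        if len(h2):
            val = across_trait_per_variant_h2(h2["estimate"], m, n_traits)
            rows.append(
                {
                    "subset": subset,
                    "trait": "all",
                    "statistic": "across_trait_per_variant_h2",
                    "value": float(val) if is_defined(val) else np.nan,
                    "reason": "" if is_defined(val) else val.reason,
                }
            )
        for _, row in h2.iterrows():
            rows.append(
                {
                    "subset": subset,
                    "trait": row["trait"],
                    "statistic": "trait_specific_per_variant_h2",
                    "value": per_variant(row["estimate"], m),
                    "reason": "",
                }
            )
        for _, row in sub[sub["statistic"] == "r_g_set"].iterrows():
            pv = per_variant(row["estimate"], m)
            rows.append(
                {
                    "subset": subset,
                    "trait": row["trait"],
                    "statistic": "trait_specific_per_variant_rg",
                    "value": pv,
                    "abs_value": abs(pv),
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)
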