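"""Restricted maximum likelihood for one- and two-GRM mixed models.

Four model shapes are supported, all with intercept-only fixed effects:

* univariate, one GRM:   y = mu 1 + g + e
* univariate, two GRMs:  y = mu 1 + g_set + g_chip + e
* bivariate, one GRM:    stacked traits with a 2x2 genetic block and a
  2x2 residual block,
* bivariate, two GRMs:   as above with two genetic blocks.

Estimation is average-information (AI) REML preceded by a few EM-REML
warm-up iterations, the strategy used by standard GREML software. The
bivariate models stack one record per observed trait value, so an
individual missing one trait still contributes its other record; the
residual covariance only acts between the two records of an individual
observed for both traits.

Nonconvergence within the iteration budget is reported via the
``converged`` flag, never raised, so batch runs over many variant subsets
always complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, lapack

from .grm import Grm
from .phenotype import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """REML model settings: the GRM list plus iteration controls."""

    grms: Sequence[Grm]
    max_iterations: int = 100
    tolerance: float = 1e-8  # relative log-likelihood change
    em_iterations: int = 3
    variance_floor_frac: float = 1e-6  # fraction of phenotypic variance

    def __post_init__(self) -> None:
        if not 1 <= len(self.grms) <= 2:
            raise ValueError("ModelSpec supports 1 or 2 GRMs")

    @property
    def term_names(self) -> list[str]:
        names = [g.name for g in self.grms]
        if len(set(names)) != len(names):
            names = [f"{nm}{i + 1}" for i, nm in enumerate(names)]
        return names + ["e"]


@dataclass
class UniFit:
    """Univariate variance components with SEs and diagnostics."""

    term_names: list[str]  # genetic terms then "e"
    sigma2: dict[str, float]
    se: dict[str, float]
    sampling_cov: np.ndarray  # order = term_names
    loglik_trace: list[float]
    converged: bool
    pinned: dict[str, bool]
    n_records: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


@dataclass
class BiFit:
    """Bivariate (co)variance blocks per random term, with SEs.

    Each term (genetic terms and the residual) carries a symmetric 2x2
    trait block [[var1, cov12], [cov12, var2]]. ``param_names`` orders the
    flattened parameters as (var1, var2, cov12) per term, matching the
    rows of ``sampling_cov``.
    """

    term_names: list[str]
    blocks: dict[str, np.ndarray]
    se_blocks: dict[str, np.ndarray]
    param_names: list[str]
    sampling_cov: np.ndarray
    loglik_trace: list[float]
    converged: bool
    pinned: dict[str, bool]
    n_records: tuple[int, int]

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


class _StackedREML:
    """AI-REML on trait-stacked records with block-structured kernels."""

    def __init__(self, y, ind_idx, trait_idx, kernels, n_traits, n_individuals):
        order = np.lexsort((ind_idx, trait_idx))
        self.y = np.asarray(y, dtype=float)[order]
        self.ind = np.asarray(ind_idx)[order]
        self.trait = np.asarray(trait_idx)[order]
        self.n_traits = n_traits
        self.N = len(self.y)
        self.slices = [np.flatnonzero(self.trait == t) for t in range(n_traits)]
        self.slices = [slice(s[0], s[-1] + 1) if len(s) else slice(0, 0) for s in self.slices]
        # kernels: list of (name, K or None); None = residual identity
        self.term_names = [nm for nm, _ in kernels]
        self.blocks: list[dict[tuple[int, int], np.ndarray]] = []
        for _, K in kernels:
            blk = {}
            for i in range(n_traits):
                for j in range(i, n_traits):
                    ai = self.ind[self.slices[i]]
                    aj = self.ind[self.slices[j]]
                    if K is None:
                        blk[(i, j)] = (ai[:, None] == aj[None, :]).astype(float)
                    else:
                        blk[(i, j)] = K[np.ix_(ai, aj)]
            self.blocks.append(blk)
        # parameter list: per term, variances then the covariance
        self.params: list[tuple[int, int, int]] = []
        for k in range(len(kernels)):
            for i in range(n_traits):
                self.params.append((k, i, i))
            if n_traits == 2:
                self.params.append((k, 0, 1))
        # intercept per trait
        self.X = np.zeros((self.N, n_traits))
        for t in range(n_traits):
            self.X[self.slices[t], t] = 1.0

    @property
    def param_labels(self) -> list[str]:
        out = []
        for k, i, j in self.params:
            nm = self.term_names[k]
            out.append(f"{nm}:{i + 1}{j + 1}" if self.n_traits == 2 else nm)
        return out

    def build_v(self, theta) -> np.ndarray:
        V = np.zeros((self.N, self.N))
        for th, (k, i, j) in zip(theta, self.params):
            blk = self.blocks[k][(i, j)]
            if i == j:
                V[self.slices[i], self.slices[i]] += th * blk
            else:
                V[self.slices[i], self.slices[j]] += th * blk
                V[self.slices[j], self.slices[i]] += th * blk.T
        return V

    def loglik(self, theta) -> float | None:
        """Restricted log-likelihood, or None if V is not positive definite."""
        V = self.build_v(theta)
        try:
            c = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        d = np.diag(c[0])
        # V technically PD but so ill-conditioned that downstream solves
        # would be garbage: treat as infeasible
        if d.min() <= 0 or d.min() / d.max() < 1e-6:
            return None
        logdet_v = 2.0 * np.log(d).sum()
        Viy = cho_solve(c, self.y, check_finite=False)
        ViX = cho_solve(c, self.X, check_finite=False)
        XtViX = self.X.T @ ViX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        XtViy = self.X.T @ Viy
        beta = np.linalg.solve(XtViX, XtViy)
        yPy = self.y @ Viy - XtViy @ beta
        return -0.5 * (logdet_v + logdet_x + yPy)

    def _mul(self, k, i, j, vec_blocks):
        """D_{k,i,j} @ v given v split into trait blocks."""
        out = np.zeros(self.N)
        blk = self.blocks[k][(i, j)]
        if i == j:
            out[self.slices[i]] = blk @ vec_blocks[i]
        else:
            out[self.slices[i]] = blk @ vec_blocks[j]
            out[self.slices[j]] = blk.T @ vec_blocks[i]
        return out

    def derivatives(self, theta):
        """Log-likelihood, score vector and AI matrix at theta."""
        V = self.build_v(theta)
        c = cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.log(np.diag(c[0])).sum()
        # dpotri inverts from the Cholesky factor in N^3/3 flops
        inv_tri, info = lapack.dpotri(c[0], lower=True)
        if info != 0:
            Vinv = cho_solve(c, np.eye(self.N), check_finite=False)
        else:
            Vinv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
        W = Vinv @ self.X
        XtViX = self.X.T @ W
        B = np.linalg.pinv(XtViX)
        Viy = Vinv @ self.y
        XtViy = self.X.T @ Viy
        Py = Viy - W @ (B @ XtViy)
        yPy = float(self.y @ Py)
        sign, logdet_x = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdet_v + logdet_x + yPy)

        p = len(self.params)
        Py_blocks = [Py[self.slices[t]] for t in range(self.n_traits)]
        u = [self._mul(k, i, j, Py_blocks) for (k, i, j) in self.params]
        tr_pd = np.empty(p)
        for a, (k, i, j) in enumerate(self.params):
            blk = self.blocks[k][(i, j)]
            if i == j:
                tr_vi = float((Vinv[self.slices[i], self.slices[i]] * blk).sum())
                Wi = W[self.slices[i]]
                corr = Wi.T @ blk @ Wi
            else:
                tr_vi = 2.0 * float((Vinv[self.slices[i], self.slices[j]] * blk).sum())
                Wi, Wj = W[self.slices[i]], W[self.slices[j]]
                m = Wi.T @ (blk @ Wj)
                corr = m + m.T
            tr_pd[a] = tr_vi - float(np.trace(B @ corr))
        score = np.array([-0.5 * (tr_pd[a] - u[a] @ Py) for a in range(p)])
        Pu = [Vinv @ ua - W @ (B @ (W.T @ ua)) for ua in u]
        ai = 0.5 * np.array([[u[a] @ Pu[b] for b in range(p)] for a in range(p)])
        ai = 0.5 * (ai + ai.T)
        return ll, score, ai, tr_pd, u, Py

    def fit(self, max_iterations, tolerance, em_iterations, variance_floor_frac):
        var_p = [float(np.var(self.y[self.slices[t]], ddof=1)) for t in range(self.n_traits)]
        cov_p = 0.0
        if self.n_traits == 2:
            # phenotypic covariance over individuals observed for both traits
            i1, i2 = self.ind[self.slices[0]], self.ind[self.slices[1]]
            shared, a1, a2 = np.intersect1d(i1, i2, return_indices=True)
            if len(shared) >= 2:
                y1 = self.y[self.slices[0]][a1]
                y2 = self.y[self.slices[1]][a2]
                cov_p = float(np.cov(y1, y2, ddof=1)[0, 1])
        theta = np.zeros(len(self.params))
        n_terms = len(self.blocks)
        floors = np.full(len(self.params), -np.inf)
        for a, (k, i, j) in enumerate(self.params):
            if i == j:
                theta[a] = var_p[i] / n_terms
                floors[a] = variance_floor_frac * var_p[i]
            else:
                theta[a] = 0.5 * cov_p / n_terms
        if self.loglik(theta) is None:
            raise ValueError("singular V at the starting values")

        pinned = np.zeros(len(self.params), dtype=bool)
        trace: list[float] = []
        converged = False
        ai_mat = None
        for it in range(max_iterations):
            ll, score, ai_mat, tr_pd, u, Py = self.derivatives(theta)
            trace.append(ll)
            # release floored components whose score points back uphill
            release = pinned & (score > 0)
            if release.any():
                pinned &= ~release
            # converge once AI iterations have started, the likelihood has
            # stopped moving AND the quasi-Newton step predicts no further
            # gain (AI is not the exact Hessian, so the likelihood change
            # alone can look converged while the score is still large)
            if it > em_iterations and abs(trace[-1] - trace[-2]) < tolerance * max(1.0, abs(trace[-1])):
                free_ = ~pinned
                ai_f_ = ai_mat[np.ix_(free_, free_)]
                try:
                    d_ = np.linalg.solve(
                        ai_f_ + 1e-10 * np.eye(ai_f_.shape[0]), score[free_]
                    )
                    gain = 0.5 * abs(float(score[free_] @ d_))
                except np.linalg.LinAlgError:
                    gain = 0.0
                if gain < 100.0 * tolerance * max(1.0, abs(ll)):
                    converged = True
                    break
            if it < em_iterations:
                new = theta.copy()
                for a in range(len(theta)):
                    if pinned[a]:
                        continue
                    new[a] = theta[a] + theta[a] ** 2 * (u[a] @ Py - tr_pd[a]) / self.N
                cand = np.where(new < floors, floors, new)
                if self.loglik(cand) is None:
                    # EM overshoot into a non-PD region: fall back to AI logic
                    cand = theta
                theta = cand
            else:
                free = ~pinned
                ai_f = ai_mat[np.ix_(free, free)]
                diag_scale = max(float(np.trace(ai_f)) / max(1, ai_f.shape[0]), 1e-12)
                scale = max(var_p)
                # Levenberg-Marquardt-style search: escalate the ridge on
                # the AI matrix (ending at pure gradient ascent) until a
                # direction with an accepted uphill step is found
                directions = []
                for rf in (1e-10, 1e-6, 1e-3, 1e-1, 10.0):
                    try:
                        directions.append(
                            np.linalg.solve(ai_f + rf * diag_scale * np.eye(ai_f.shape[0]), score[free])
                        )
                    except np.linalg.LinAlgError:
                        continue
                directions.append(score[free])
                # last resort: coordinate ascent — on narrow likelihood
                # ridges (e.g. a correlation pressed against +/-1) joint
                # directions leave the feasible cone almost immediately,
                # while a single coordinate can still move far
                nf = int(free.sum())
                for ci in np.argsort(-np.abs(score[free])):
                    e_i = np.zeros(nf)
                    e_i[ci] = np.sign(score[free][ci])
                    directions.append(e_i)
                # escalate past the first direction only while the score
                # still predicts substantial gain (a stalled likelihood
                # ridge); in the ordinary convergence tail the first
                # direction is used as-is, keeping one loglik evaluation
                # per iteration
                gain_pred = float(abs(score[free] @ directions[0])) if directions else 0.0
                stalled_bar = tolerance * max(1.0, abs(ll))
                escalate = gain_pred >= 100.0 * stalled_bar
                best = None  # (ll_new, cand)
                for direction in directions:
                    mx = float(np.max(np.abs(direction))) if len(direction) else 0.0
                    if mx == 0 or not np.isfinite(mx):
                        continue
                    # cap the first trial step at the phenotypic-variance scale
                    if mx > scale:
                        direction = direction * (scale / mx)
                    step = 1.0
                    for _ in range(40):
                        cand = theta.copy()
                        cand[free] = theta[free] + step * direction
                        cand = np.where(cand < floors, floors, cand)
                        ll_new = self.loglik(cand)
                        if ll_new is not None and ll_new >= ll - 1e-10:
                            if best is None or ll_new > best[0]:
                                best = (ll_new, cand)
                            break
                        step *= 0.5
                    if best is not None and best[0] > ll + stalled_bar:
                        break  # the lowest-ridge uphill direction wins:
                        # larger ridges can give a bigger one-step gain but
                        # step off the likelihood ridge into flat corners
                    if not escalate:
                        break
                if best is None:
                    converged = True  # no uphill direction left
                    break
                theta = best[1]
            newly = (theta <= floors) & ~pinned
            if newly.any():
                pinned |= newly
                for a in np.flatnonzero(newly):
                    logger.info("component %s pinned at the variance floor", self.param_labels[a])
        else:
            logger.warning("REML did not converge in %d iterations", max_iterations)

        if ai_mat is None:  # pragma: no cover - max_iterations >= 1 always
            raise RuntimeError("no iterations performed")
        # SEs from the AI matrix at the optimum
        ll, score, ai_mat, *_ = self.derivatives(theta)
        trace.append(ll)
        cov = np.linalg.pinv(ai_mat)
        return theta, cov, trace, converged, pinned


def _prepare_records(pheno: PhenotypeTable, traits: Sequence[int]):
    ids = pheno.individual_ids
    y_parts, ind_parts, trait_parts = [], [], []
    for t_out, t in enumerate(traits):
        obs = np.flatnonzero(np.isfinite(pheno.values[:, t]))
        y_parts.append(pheno.values[obs, t])
        ind_parts.append(obs)
        trait_parts.append(np.full(len(obs), t_out))
    return (
        np.concatenate(y_parts),
        np.concatenate(ind_parts),
        np.concatenate(trait_parts),
        ids,
    )


def _aligned_kernels(spec: ModelSpec, ids) -> list[tuple[str, np.ndarray | None]]:
    names = spec.term_names
    kernels: list[tuple[str, np.ndarray | None]] = []
    for nm, g in zip(names[:-1], spec.grms):
        kernels.append((nm, g.align(ids)))
    kernels.append(("e", None))
    return kernels


def fit_univariate(pheno: PhenotypeTable, spec: ModelSpec, trait: int = 0) -> UniFit:
    """Fit the single-trait model with 1 or 2 GRMs by AI-REML."""
    y, ind, tr, ids = _prepare_records(pheno, [trait])
    if len(y) < 3:
        raise ValueError("fewer than 3 phenotype records")
    kernels = _aligned_kernels(spec, ids)
    prob = _StackedREML(y, ind, tr, kernels, n_traits=1, n_individuals=len(ids))
    theta, cov, trace, converged, pinned = prob.fit(
        spec.max_iterations, spec.tolerance, spec.em_iterations, spec.variance_floor_frac
    )
    names = spec.term_names
    return UniFit(
        term_names=names,
        sigma2={nm: float(th) for nm, th in zip(names, theta)},
        se={nm: float(np.sqrt(max(cov[a, a], 0.0))) for a, nm in enumerate(names)},
        sampling_cov=cov,
        loglik_trace=trace,
        converged=converged,
        pinned={nm: bool(p) for nm, p in zip(names, pinned)},
        n_records=len(y),
    )


def fit_bivariate(pheno: PhenotypeTable, spec: ModelSpec, traits: Sequence[int] = (0, 1)) -> BiFit:
    """Fit the two-trait model with 1 or 2 GRMs by stacked-record AI-REML.

    Individuals missing one trait contribute their observed record only;
    at least one individual must be observed for both traits, otherwise
    the covariances are unidentifiable.
    """
    if pheno.n_traits < 2:
        raise ValueError("bivariate fit needs a two-trait phenotype table")
    y, ind, tr, ids = _prepare_records(pheno, list(traits))
    n1 = int((tr == 0).sum())
    n2 = int((tr == 1).sum())
    if n1 < 3 or n2 < 3:
        raise ValueError("fewer than 3 records for one of the traits")
    both = np.intersect1d(ind[tr == 0], ind[tr == 1])
    if len(both) == 0:
        raise ValueError("no individual observed for both traits; covariances unidentifiable")
    kernels = _aligned_kernels(spec, ids)
    prob = _StackedREML(y, ind, tr, kernels, n_traits=2, n_individuals=len(ids))
    theta, cov, trace, converged, pinned = prob.fit(
        spec.max_iterations, spec.tolerance, spec.em_iterations, spec.variance_floor_frac
    )
    names = spec.term_names
    blocks, se_blocks, pin = {}, {}, {}
    for k, nm in enumerate(names):
        v1, v2, c12 = theta[3 * k : 3 * k + 3]
        s1, s2, sc = (np.sqrt(max(cov[a, a], 0.0)) for a in range(3 * k, 3 * k + 3))
        blocks[nm] = np.array([[v1, c12], [c12, v2]])
        se_blocks[nm] = np.array([[s1, sc], [sc, s2]])
        pin[nm] = bool(pinned[3 * k : 3 * k + 3].any())
    return BiFit(
        term_names=names,
        blocks=blocks,
        se_blocks=se_blocks,
        param_names=prob.param_labels,
        sampling_cov=cov,
        loglik_trace=trace,
        converged=converged,
        pinned=pin,
        n_records=(n1, n2),
    )
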