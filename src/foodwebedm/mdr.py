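"""Multiview distance regularised S-map: time-varying Jacobian estimation.

For each network node the method proceeds in two steps.

1. *Multiview distances.*  Many low-dimensional state-space reconstructions
   (SSRs) are drawn from the node's causal variables (lags 0–2, the node
   itself at lag 0 always included).  Each SSR is scored by leave-one-out
   simplex forecast skill ρ on the node's next value; the top 100 are kept
   and their pairwise state distances averaged with weights w_c ∝ ρ
   (Σ w_c = 1), giving a multiview distance d^E between every pair of time
   points.  State weights follow the S-map kernel
   W_t = exp(−θ · d^E(t, ·) / mean d^E(t, ·)).

2. *Locally weighted elastic net.*  At every time t a weighted elastic-net
   regression of x_i(t+1) on the causal variables at time t is solved,

       argmin_B ||√W_t (y − X B)||² + λ[α|B|₂² + (1−α)|B|₁],

   whose coefficients approximate the discrete-time Jacobian row
   ∂x_i(t+1)/∂x_j(t).  NOTE the penalty convention: α weights the ridge
   term and (1−α) the lasso term.  θ, λ, α are chosen per node by
   leave-one-out cross-validation on the one-step forecast rMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .edm import simplex_loo

__all__ = [
    "MultiviewWeights",
    "JacobianSeries",
    "build_multiview_weights",
    "weighted_elastic_net",
    "estimate_jacobians",
    "THETA_GRID",
    "LAMBDA_GRID",
    "ALPHA_GRID",
]

THETA_GRID = (0.0, 0.1, 0.5, 1.0, 2.0, 4.0, 8.0)
LAMBDA_GRID = tuple(np.logspace(-4, 1, 6))
ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
MAX_LAG = 2  # mirrors the CCM lag window


@dataclass
class MultiviewWeights:
    """Kept SSR ensemble and the multiview distance matrix for one node."""

    target: str
    ssrs: list          # each SSR: tuple of (variable, lag) coordinates
    skills: np.ndarray  # leave-one-out simplex rho per kept SSR
    weights: np.ndarray  # w_c >= 0, sum to 1
    distances: np.ndarray  # d^E, (n_states, n_states), symmetric, 0 diagonal
    times: np.ndarray      # original series index of each state row

    def state_weights(self, theta: float) -> np.ndarray:
        """W[t, k] = exp(−θ d(t,k)/mean_k d(t,k)), mean over k ≠ t."""
        d = self.distances
        n = d.shape[0]
        if theta == 0:
            return np.ones_like(d)
        off = d.sum(axis=1) / max(n - 1, 1)
        off = np.where(off > 0, off, 1.0)
        return np.exp(-theta * d / off[:, None])


@dataclass
class JacobianSeries:
    """Per-time-step s×s interaction matrices B_t.

    B_t[i, j] approximates ∂x_i(t+1)/∂x_j(t); entries without an accepted
    causal link j→i are structural zeros.  ``times`` are original panel
    indices; the matrix size is fixed over time.
    """

    species: list
    times: np.ndarray
    matrices: np.ndarray  # (n_times, s, s)
    hyperparams: dict = field(default_factory=dict)  # per node
    flagged: list = field(default_factory=list)  # nodes with no causes

    def trace(self) -> np.ndarray:
        return np.trace(self.matrices, axis1=1, axis2=2)

    def to_frame(self) -> pd.DataFrame:
        t_idx, i_idx, j_idx = np.meshgrid(
            self.times, range(len(self.species)), range(len(self.species)),
            indexing="ij")
        return pd.DataFrame({
            "t": t_idx.ravel(),
            "target": np.asarray(self.species)[i_idx.ravel()],
            "source": np.asarray(self.species)[j_idx.ravel()],
            "value": self.matrices.ravel(),
        })


def _candidate_ssrs(target, causes, E, n_candidates, rng,
                    lagged_target=True):
    """E-sized coordinate sets; (target, 0) always included."""
    pool = [(v, lag) for v in list(causes) + [target]
            for lag in range(MAX_LAG + 1) if (v, lag) != (target, 0)
            and (lagged_target or v != target)]
    k = E - 1
    total = comb(len(pool), k)
    if total <= n_candidates:
        return [((target, 0),) + c for c in combinations(pool, k)]
    seen = set()
    out = []
    while len(out) < n_candidates:
        pick = tuple(sorted(rng.choice(len(pool), size=k, replace=False)))
        if pick in seen:
            continue
        seen.add(pick)
        out.append(((target, 0),) + tuple(pool[i] for i in pick))
    return out


def _ssr_states(panel: pd.DataFrame, ssr, times: np.ndarray) -> np.ndarray:
    cols = [panel[v].to_numpy(dtype=float)[times - lag] for v, lag in ssr]
    return np.column_stack(cols)


def build_multiview_weights(target: str, causes, panel: pd.DataFrame,
                            E: int, n_candidates: int = 1000,
                            n_keep: int = 100, seed: int = 0,
                            lagged_target: bool = True
                            ) -> MultiviewWeights:
    """Score candidate SSRs and assemble the multiview distance matrix.

    ``panel`` is one site's standardised wide panel.  Candidate SSRs are
    random E-sized coordinate draws from the target and its causes at lags
    0–2 (target at lag 0 always present; set ``lagged_target=False`` to
    exclude lagged copies of the target from the pool).  Skill is the
    leave-one-out simplex ρ forecasting the target one step ahead.  The
    top ``n_keep`` positive-skill SSRs are kept; w_c ∝ max(ρ_c, 0),
    Σ w_c = 1.
    """
    rng = np.random.default_rng(seed)
    y_all = panel[target].to_numpy(dtype=float)
    n = y_all.size
    times = np.arange(MAX_LAG, n)  # common valid times across all SSRs
    has_next = times + 1 <= n - 1
    targets = np.where(has_next, y_all[np.minimum(times + 1, n - 1)], np.nan)

    candidates = _candidate_ssrs(target, causes, E, n_candidates, rng,
                                 lagged_target=lagged_target)
    skills = np.full(len(candidates), -np.inf)
    states = []
    for c, ssr in enumerate(candidates):
        X = _ssr_states(panel, ssr, times)
        states.append(X)
        pred, obs = simplex_loo(X, times, targets, has_next,
                                n_neighbors=min(E + 1, len(times) - 1),
                                exclusion_radius=E)
        if pred.size >= 3 and np.std(pred) > 0:
            skills[c] = pearsonr(pred, obs)[0]

    positive = np.flatnonzero(skills > 0)
    if positive.size == 0:
        raise ValueError(
            f"no SSR with positive forecast skill for node {target!r}")
    if positive.size < n_keep:
        warnings.warn(
            f"only {positive.size} positive-skill SSRs for {target!r} "
            f"(requested {n_keep}); keeping all of them")
        kept = positive[np.argsort(skills[positive])[::-1]]
    else:
        kept = positive[np.argsort(skills[positive])[::-1][:n_keep]]

    w = skills[kept]
    w = w / w.sum()
    d = np.zeros((times.size, times.size))
    for w_c, idx in zip(w, kept):
        d += w_c * cdist(states[idx], states[idx])
    return MultiviewWeights(target=target,
                            ssrs=[candidates[i] for i in kept],
                            skills=skills[kept], weights=w,
                            distances=d, times=times)


def _cd_solve(G, c, lam_l1, lam_l2, b0=None, tol=1e-7, max_iter=1000):
    """Coordinate descent on ½-free quadratic form.

    Minimises  bᵀGb − 2cᵀb + lam_l2·Σb² + lam_l1·Σ|b|  (the weighted RSS up
    to a constant, with centred Gram G = XᵀWX and c = XᵀWy).
    """
    k = G.shape[0]
    b = np.zeros(k) if b0 is None else b0.copy()
    denom = np.diag(G) + lam_l2
    denom = np.where(denom > 0, denom, 1.0)
    for _ in range(max_iter):
        b_old = b.copy()
        for j in range(k):
            r = c[j] - G[j] @ b + G[j, j] * b[j]
            b[j] = np.sign(r) * max(abs(r) - lam_l1 / 2.0, 0.0) / denom[j]
        if np.max(np.abs(b - b_old)) < tol:
            break
    return b


def _cd_solve_batch(G_all, c_all, lam_l1, lam_l2, tol=1e-7, max_iter=1000):
    """Coordinate descent run in lockstep over a stack of local problems.

    Each slice t minimises  bᵀG_t b − 2c_tᵀb + lam_l2·Σb² + lam_l1·Σ|b|;
    sweeps are vectorised over t so the Python loop is only over the (few)
    coordinates.
    """
    n, k = c_all.shape
    b = np.zeros((n, k))
    diag = np.einsum("njj->nj", G_all)
    denom = diag + lam_l2
    denom = np.where(denom > 0, denom, 1.0)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(k):
            r = (c_all[:, j]
                 - np.einsum("nl,nl->n", G_all[:, j, :], b)
                 + diag[:, j] * b[:, j])
            new = np.sign(r) * np.maximum(np.abs(r) - lam_l1 / 2.0, 0.0) \
                / denom[:, j]
            delta = max(delta, float(np.max(np.abs(new - b[:, j]))))
            b[:, j] = new
        if delta < tol:
            break
    return b


def weighted_elastic_net(X, y, W, lam: float, alpha: float,
                         fit_intercept: bool = True, tol: float = 1e-7):
    """Solve  argmin_b ||√W(y − Xb − b0)||² + λ[α|b|₂² + (1−α)|b|₁].

    α weights the ridge term and (1−α) the lasso term.  The intercept b0 is
    unpenalised.  Returns (coefficients, intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(W, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(w))):
        raise ValueError("non-finite values in inputs")
    if lam < 0 or not (0.0 <= alpha <= 1.0):
        raise ValueError("need lambda >= 0 and alpha in [0, 1]")
    sw = w.sum()
    if fit_intercept:
        x_mean = (w @ X) / sw
        y_mean = (w @ y) / sw
        Xc = X - x_mean
        yc = y - y_mean
    else:
        x_mean = np.zeros(X.shape[1])
        y_mean = 0.0
        Xc, yc = X, y
    G = (Xc * w[:, None]).T @ Xc
    c = (Xc * w[:, None]).T @ yc
    lam_l2 = lam * alpha
    lam_l1 = lam * (1.0 - alpha)
    if lam_l1 == 0.0:
        b = np.linalg.solve(G + lam_l2 * np.eye(G.shape[0]), c)
    else:
        b = _cd_solve(G, c, lam_l1, lam_l2, tol=tol)
    intercept = float(y_mean - x_mean @ b) if fit_intercept else 0.0
    return b, intercept


def _local_fits(X, y, W, lam, alpha, loo=True):
    """One local weighted elastic net per prediction time.

    Returns (coefs (n,k), intercepts (n,), preds (n,)).  With ``loo`` the
    row's own observation gets weight 0 before fitting (for honest CV).
    """
    n, k = X.shape
    Wm = W.copy()
    if loo:
        np.fill_diagonal(Wm, 0.0)
    sw = Wm.sum(axis=1)
    Sx = Wm @ X
    Sy = Wm @ y
    Sxx = np.einsum("tn,ni,nj->tij", Wm, X, X, optimize=True)
    Sxy = np.einsum("tn,ni,n->ti", Wm, X, y, optimize=True)
    x_mean = Sx / sw[:, None]
    y_mean = Sy / sw
    G_all = Sxx - x_mean[:, :, None] * Sx[:, None, :]
    c_all = Sxy - x_mean * Sy[:, None]
    lam_l2 = lam * alpha
    lam_l1 = lam * (1.0 - alpha)
    if lam_l1 == 0.0:
        coefs = np.linalg.solve(
            G_all + lam_l2 * np.eye(k)[None, :, :], c_all[:, :, None]
        )[:, :, 0]
    else:
        coefs = _cd_solve_batch(G_all, c_all, lam_l1, lam_l2)
    intercepts = y_mean - np.einsum("tk,tk->t", x_mean, coefs)
    preds = np.einsum("tk,tk->t", X, coefs) + intercepts
    return coefs, intercepts, preds


def estimate_jacobians(network, panel: pd.DataFrame,
                       theta_grid=THETA_GRID, lambda_grid=LAMBDA_GRID,
                       alpha_grid=ALPHA_GRID, seed: int = 0,
                       E_by_species: dict | None = None,
                       n_candidates: int = 1000, n_keep: int = 100
                       ) -> JacobianSeries:
    """Estimate the time-varying Jacobian for every node of the network.

    ``panel`` is one site's standardised wide panel; ``network`` supplies
    the accepted causes of each node (entries without a link are structural
    zeros).  Hyperparameters (θ, λ, α) are selected per node by
    leave-one-out rMSE of the one-step forecast; the returned matrices are
    refit with the full weight matrix at the chosen triple.
    """
    from .edm import select_E

    species = list(network.species)
    s = len(species)
    col_of = {sp: i for i, sp in enumerate(species)}
    n = panel.shape[0]
    times = np.arange(MAX_LAG, n - 1)  # prediction times common to nodes
    n_t = times.size
    matrices = np.zeros((n_t, s, s))
    hyperparams = {}
    flagged = []

    for i, target in enumerate(species):
        causes = [sp for sp in network.causes_of(target) if sp != target]
        if not causes:
            flagged.append(target)
        predictors = causes + [target]
        if E_by_species and target in E_by_species:
            E = E_by_species[target]
        else:
            E, _ = select_E(panel[target].to_numpy())
        E = max(2, min(E, len(predictors) * (MAX_LAG + 1) - MAX_LAG))
        mv = build_multiview_weights(
            target, causes, panel, E, n_candidates=n_candidates,
            n_keep=n_keep, seed=seed + 7 * i)

        y_all = panel[target].to_numpy(dtype=float)
        X = panel[predictors].to_numpy(dtype=float)[times]
        y = y_all[times + 1]
        # restrict the multiview distance matrix to the prediction times
        pos = np.searchsorted(mv.times, times)
        d_sub = mv.distances[np.ix_(pos, pos)]
        mv_sub = MultiviewWeights(
            target=target, ssrs=mv.ssrs, skills=mv.skills,
            weights=mv.weights, distances=d_sub, times=times)

        best = None
        for theta in theta_grid:
            W = mv_sub.state_weights(theta)
            for lam in lambda_grid:
                for alpha in alpha_grid:
                    _, _, preds = _local_fits(X, y, W, lam, alpha, loo=True)
                    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
                    if best is None or rmse < best[0]:
                        best = (rmse, theta, lam, alpha)
        rmse, theta, lam, alpha = best
        hyperparams[target] = {"theta": theta, "lambda": lam,
                               "alpha": alpha, "cv_rmse": rmse, "E": E}
        W = mv_sub.state_weights(theta)
        coefs, _, _ = _local_fits(X, y, W, lam, alpha, loo=False)
        for j, sp in enumerate(predictors):
            matrices[:, i, col_of[sp]] = coefs[:, j]

    return JacobianSeries(species=species, times=times, matrices=matrices,
                          hyperparams=hyperparams, flagged=flagged)
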