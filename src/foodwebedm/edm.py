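"""Empirical dynamic modelling primitives.

Delay embedding (Takens reconstruction), leave-one-out simplex projection
for embedding-dimension selection, and cross-map prediction — the building
blocks for causal-network reconstruction and the multiview S-map.

Conventions (standard simplex projection): E+1 nearest neighbours,
exponential distance weights exp(−d/d_min), leave-one-out with a temporal
exclusion radius of E points around the prediction target so short seasonal
series cannot self-match.  Nearest-neighbour ties break toward the earlier
time index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


__all__ = ["Embedding", "RhoCurve", "delay_embed", "select_E", "cross_map",
           "simplex_loo"]

DEFAULT_E_RANGE = range(2, 10)


@dataclass
class Embedding:
    """Delay-coordinate matrix: row k = (x(t), x(t−1), …, x(t−E+1))."""

    vectors: np.ndarray
    E: int
    times: np.ndarray  # original series index t of each row

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class RhoCurve:
    """Cross-map skill as a function of library length."""

    lengths: np.ndarray
    rhos: np.ndarray
    n_pred: int  # prediction points contributing to each rho

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths)
        self.rhos = np.asarray(self.rhos, dtype=float)
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("library lengths must be strictly increasing")

    @property
    def rho_min(self) -> float:
        return float(self.rhos[0])

    @property
    def rho_full(self) -> float:
        return float(self.rhos[-1])


def delay_embed(series, E: int) -> Embedding:
    series = np.asarray(series, dtype=float)
    if E < 1:
        raise ValueError("E must be >= 1")
    n = series.size
    if n < E + 2:
        raise ValueError(f"series of length {n} too short for E={E}")
    if np.isnan(series).any():
        raise ValueError("series contains missing values; fill or truncate")
    idx = np.arange(E - 1, n)
    vectors = np.column_stack([series[idx - k] for k in range(E)])
    return Embedding(vectors=vectors, E=E, times=idx)


def _knn_predict(dist: np.ndarray, lib_values: np.ndarray, k: int):
    """Simplex prediction for each row of a (pred × library) distance matrix.

    Entries of `dist` set to +inf are unavailable (excluded) neighbours.
    Returns (predictions, valid) where valid marks rows with >= k usable
    neighbours.
    """
    n_pred, n_lib = dist.shape
    if n_lib < k:
        return np.full(n_pred, np.nan), np.zeros(n_pred, dtype=bool)
    # argpartition then stable sort of the k candidates: ties -> earlier index
    part = np.argpartition(dist, k - 1, axis=1)[:, :k]
    rows = np.arange(n_pred)[:, None]
    d = dist[rows, part]
    order = np.lexsort((part, d), axis=1)
    nn = part[rows, order]
    d = dist[rows, nn]
    valid = np.isfinite(d[:, -1])
    d_min = d[:, 0].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.exp(-d / np.where(d_min > 0, d_min, 1.0)[:, None])
        w[d_min == 0] = (d[d_min == 0] == 0).astype(float)  # exact matches
    w_sum = w.sum(axis=1)
    pred = (w * lib_values[nn]).sum(axis=1) / np.where(w_sum > 0, w_sum, 1.0)
    pred[~valid] = np.nan
    return pred, valid


def simplex_loo(vectors: np.ndarray, times: np.ndarray, targets: np.ndarray,
                target_valid: np.ndarray, n_neighbors: int,
                exclusion_radius: int):
    """Leave-one-out simplex forecast over all rows of an embedding.

    ``targets[k]`` is the value to predict for row k; ``target_valid[k]``
    marks rows whose target exists.  Rows within ``exclusion_radius`` time
    points of the prediction row (including itself) are excluded from its
    neighbour pool.  Returns (pred, obs) over predictable rows.
    """
    dist = cdist(vectors, vectors)
    excl = np.abs(times[:, None] - times[None, :]) <= exclusion_radius
    dist[excl] = np.inf
    dist[:, ~target_valid] = np.inf
    pred, valid = _knn_predict(dist, np.where(target_valid, targets, np.nan),
                               n_neighbors)
    use = valid & target_valid
    return pred[use], targets[use]


def _loo_mae(series: np.ndarray, E: int) -> float:
    emb = delay_embed(series, E)
    n = series.size
    has_next = emb.times + 1 <= n - 1
    targets = np.full(len(emb), np.nan)
    targets[has_next] = series[np.minimum(emb.times + 1, n - 1)][has_next]
    pred, obs = simplex_loo(emb.vectors, emb.times, targets, has_next,
                            n_neighbors=E + 1, exclusion_radius=E)
    if pred.size == 0:
        return np.nan
    return float(np.mean(np.abs(pred - obs)))


def select_E(series, E_range=DEFAULT_E_RANGE):
    """Pick the embedding dimension minimising one-step simplex MAE.

    Ties break toward the smallest E.  Returns (E_best, {E: MAE}).
    """
    series = np.asarray(series, dtype=float)
    maes = {}
    for E in E_range:
        try:
            maes[E] = _loo_mae(series, E)
        except ValueError:
            maes[E] = np.nan
    finite = {E: m for E, m in maes.items() if np.isfinite(m)}
    if not finite:
        raise ValueError("no embedding dimension yields valid forecasts")
    E_best = min(finite, key=lambda E: (finite[E], E))
    return E_best, maes


def library_grid(n_rows: int, start: int = 10, step: int = 5) -> np.ndarray:
    """Library lengths {start, start+step, …} ∪ {n_rows}."""
    if n_rows <= start:
        return np.array([n_rows])
    grid = np.arange(start, n_rows, step)
    return np.append(grid, n_rows)


def _batch_rho(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of (n_batch, n_points) predictions
    against one observation vector, NaN-aware per row (vectorised)."""
    valid = np.isfinite(pred) & np.isfinite(obs)[None, :]
    n = valid.sum(axis=1).astype(float)
    p = np.where(valid, pred, 0.0)
    o = np.where(valid, obs[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mp = p.sum(axis=1) / n
        mo = o.sum(axis=1) / n
        cov = (p * o).sum(axis=1) / n - mp * mo
        vp = (p * p).sum(axis=1) / n - mp ** 2
        vo = (o * o).sum(axis=1) / n - mo ** 2
        rho = cov / np.sqrt(vp * vo)
    rho[(n < 3) | (vp <= 0) | (vo <= 0)] = np.nan
    return rho


class CrossMapWorkspace:
    """Precomputed geometry for cross-mapping from one effect embedding.

    Holds the pairwise distances of the effect's delay embedding with the
    leave-one-out exclusion (radius E) applied, so that skill can be
    recomputed cheaply for many lags, library lengths, subsamples, and
    surrogate versions of the cause series.
    """

    def __init__(self, effect: np.ndarray, E: int, lag: int | None = None):
        self.E = E
        self.lag = lag  # optional default; methods accept a per-call lag
        self.emb = delay_embed(np.asarray(effect, dtype=float), E)
        times = self.emb.times
        dist = cdist(self.emb.vectors, self.emb.vectors).astype(np.float32)
        dist[np.abs(times[:, None] - times[None, :]) <= E] = np.inf
        self._dist = dist

    def _lag(self, lag: int | None) -> int:
        lag = self.lag if lag is None else lag
        if lag is None or lag > 0:
            raise ValueError("lag must be <= 0 (cause precedes effect)")
        return lag

    def cause_targets(self, cause: np.ndarray,
                      lag: int | None = None) -> np.ndarray:
        lag = self._lag(lag)
        t = self.emb.times + lag
        ok = t >= 0
        targets = np.asarray(cause, dtype=float)[np.where(ok, t, 0)]
        return np.where(ok, targets, np.nan)

    def full_library(self, cause: np.ndarray,
                     lag: int | None = None) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.cause_targets(cause, lag)))

    def n_predictions(self, cause: np.ndarray,
                      lag: int | None = None) -> int:
        return int((~np.isnan(self.cause_targets(cause, lag))).sum())

    def rho_batch(self, cause: np.ndarray, libs: np.ndarray,
                  lag: int | None = None) -> np.ndarray:
        """Cross-map skill for a batch of library subsets.

        ``libs`` is (n_batch, L): each row indexes library rows of the
        embedding.  Returns one ρ per batch row.
        """
        lag = self._lag(lag)
        targets = self.cause_targets(cause, lag)
        k = min(self.E + 1, libs.shape[1])
        # (n_pred, n_batch, L) distance gather; k successive argmin passes
        # along the last axis beat argpartition for the small k used here
        dist3 = self._dist[:, libs].copy()
        n_pred, n_batch = dist3.shape[:2]
        d = np.empty((n_pred, n_batch, k), dtype=np.float32)
        nn = np.empty((n_pred, n_batch, k), dtype=np.int64)
        for j in range(k):
            am = dist3.argmin(axis=2)
            nn[:, :, j] = am
            d[:, :, j] = np.take_along_axis(
                dist3, am[:, :, None], axis=2)[:, :, 0]
            np.put_along_axis(dist3, am[:, :, None], np.inf, axis=2)
        lib_t = targets[libs]  # (n_batch, L)
        vals = np.take_along_axis(
            lib_t[None, :, :], nn, axis=2)  # (n_pred, n_batch, k)
        d0 = d[:, :, :1]
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            w = np.exp(-d / np.where(d0 > 0, d0, 1.0))
        w[(d0 == 0).repeat(k, axis=2)] = (d[(d0 == 0).repeat(k, axis=2)]
                                          == 0).astype(np.float32)
        invalid = ~np.isfinite(d[:, :, -1])
        wsum = w.sum(axis=2)
        pred = (w * vals).sum(axis=2) / np.where(wsum > 0, wsum, 1.0)
        pred[invalid] = np.nan
        return _batch_rho(pred.T, targets)

    def rho(self, cause: np.ndarray, lib_rows: np.ndarray,
            lag: int | None = None) -> float:
        """Cross-map skill using the given library rows only."""
        lag = self._lag(lag)
        targets = self.cause_targets(cause, lag)
        # library rows must have their own target values to lend them out
        lib_ok = lib_rows[~np.isnan(targets[lib_rows])]
        if lib_ok.size < self.E + 2:
            return np.nan
        return float(self.rho_batch(cause, lib_ok[None, :], lag)[0])

    def rho_curve(self, cause: np.ndarray, lag: int,
                  library_lengths=None, n_subsamples: int = 100,
                  seed: int = 0) -> RhoCurve:
        cause = np.asarray(cause, dtype=float)
        full_lib = self.full_library(cause, lag)
        n_lib = full_lib.size
        if library_lengths is None:
            library_lengths = library_grid(n_lib)
        rng = np.random.default_rng(seed)
        lengths, rhos = [], []
        for L in np.asarray(library_lengths):
            L = int(min(L, n_lib))
            if L < self.E + 2 or (lengths and lengths[-1] >= L):
                continue
            if L >= n_lib:
                vals = self.rho_batch(cause, full_lib[None, :], lag)
            else:
                libs = np.stack([rng.choice(full_lib, size=L, replace=False)
                                 for _ in range(n_subsamples)])
                vals = self.rho_batch(cause, libs, lag)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                lengths.append(L)
                rhos.append(float(np.mean(vals)))
        if not lengths:
            raise ValueError("no usable library length (series too short)")
        return RhoCurve(lengths=np.array(lengths), rhos=np.array(rhos),
                        n_pred=self.n_predictions(cause, lag))


def cross_map(target_cause, map_from_effect, E: int, lag: int = 0,
              library_lengths=None, n_subsamples: int = 100,
              seed: int = 0, workspace: CrossMapWorkspace | None = None
              ) -> RhoCurve:
    """Cross-map the cause from the effect's delay embedding.

    The effect series' shadow attractor is used to predict the cause at
    ``t + lag`` (lag ∈ {0, −1, −2}) via simplex projection.  For each
    library length L, ``n_subsamples`` random subsets of L library rows are
    drawn (seeded) and the mean Pearson ρ between predictions and
    observations is reported; at the full library a single evaluation is
    made.  Library lengths below E+2 are skipped.  Passing a prebuilt
    ``workspace`` (same effect series and E) avoids recomputing distances.
    """
    cause = np.asarray(target_cause, dtype=float)
    effect = np.asarray(map_from_effect, dtype=float)
    if cause.size != effect.size:
        raise ValueError("series must have equal length")
    ws = workspace if workspace is not None \
        else CrossMapWorkspace(effect, E)
    return ws.rho_curve(cause, lag, library_lengths=library_lengths,
                        n_subsamples=n_subsamples, seed=seed)
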