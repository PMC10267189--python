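"""Causal-network reconstruction by convergent cross mapping.

For every ordered species pair the putative effect's delay embedding is
used to cross-predict the putative cause at lags 0, −1, −2 sampling steps.
A link is accepted when three criteria all hold:

1. the real cross-map skill ρ at full library exceeds the 95th percentile
   of ρ over seasonal surrogates of the cause (seasonal climatology
   preserved, anomalies shuffled — controls for shared seasonality);
2. ρ increases monotonically with library length (one-sided Kendall τ,
   p < 0.05);
3. ρ at the largest library exceeds ρ at the smallest (one-sided Fisher
   z-test, p < 0.05).

Accepted links suspected to be indirect (two-step transitive chains with a
more negative lag and lower skill than the first hop) are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .edm import CrossMapWorkspace, RhoCurve, select_E
from .preprocess import LEVELS, TrophicAssignment

__all__ = [
    "LinkResult",
    "InteractionNetwork",
    "make_seasonal_surrogates",
    "test_convergence",
    "assess_link",
    "infer_network",
    "prune_indirect",
    "network_metrics",
]

DEFAULT_LAGS = (0, -1, -2)
ALPHA = 0.05


@dataclass
class LinkResult:
    """Outcome of the causal test for one ordered pair (source → target)."""

    source: str
    target: str
    best_lag: int
    rho_full: float
    rho_min: float
    surrogate_pass: bool
    kendall_p: float
    fisher_p: float
    accepted: bool
    pruned_as_indirect: bool = False
    curve: RhoCurve | None = None
    surrogate_rhos: np.ndarray | None = None


@dataclass
class InteractionNetwork:
    """Directed causal edge list over a fixed node set."""

    species: list
    links: list = field(default_factory=list)

    @property
    def edges(self) -> list[LinkResult]:
        """Accepted, unpruned links."""
        return [l for l in self.links
                if l.accepted and not l.pruned_as_indirect]

    def causes_of(self, target: str) -> list[str]:
        return [l.source for l in self.edges if l.target == target]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": l.source, "target": l.target, "lag": l.best_lag,
              "rho_full": l.rho_full, "rho_min": l.rho_min,
              "surrogate_pass": l.surrogate_pass,
              "kendall_p": l.kendall_p, "fisher_p": l.fisher_p,
              "accepted": l.accepted, "pruned": l.pruned_as_indirect}
             for l in self.links])

    def adjacency(self) -> pd.DataFrame:
        """Boolean matrix A[target, source] over accepted unpruned edges."""
        mat = pd.DataFrame(False, index=self.species, columns=self.species)
        for l in self.edges:
            mat.loc[l.target, l.source] = True
        return mat


def make_seasonal_surrogates(series: pd.Series, n: int = 100,
                             seed: int = 0) -> np.ndarray:
    """Seasonality-preserving null series.

    The seasonal climatology (the across-year mean of each season) is kept
    fixed; anomalies (observation minus its season's climatological mean)
    are permuted uniformly across all time points and added back.  Every
    surrogate therefore has the same seasonal cycle as the original — so a
    cross-map skill that merely reflects shared seasonality cannot beat the
    surrogate distribution — while any anomaly structure is destroyed.
    Returns an (n, len(series)) array.
    """
    names = series.index.names or []
    if "year" not in names or "season" not in names:
        raise ValueError("series must be indexed by (year, season)")
    years = series.index.get_level_values("year").to_numpy()
    if np.unique(years).size < 3:
        raise ValueError("seasonal surrogates need at least 3 years of data")
    seasons = series.index.get_level_values("season").to_numpy()
    values = series.to_numpy(dtype=float)
    season_means = (pd.Series(values).groupby(seasons)
                    .transform("mean").to_numpy())
    anomalies = values - season_means
    rng = np.random.default_rng(seed)
    out = np.empty((n, values.size))
    for k in range(n):
        out[k] = season_means + rng.permutation(anomalies)
    return out


def _clamp(rho: float) -> float:
    return float(np.clip(rho, -1 + 1e-10, 1 - 1e-10))


def test_convergence(curve: RhoCurve, n_min: int | None = None,
                     n_full: int | None = None):
    """One-sided convergence tests on a ρ(L) curve.

    Returns (kendall_p, fisher_p): p-value for a positive Kendall τ between
    library length and ρ, and for Fisher's z comparing ρ at the largest
    library against ρ at the smallest.  Effective n for the z-test is the
    number of prediction points behind each correlation.
    """
    if len(curve.lengths) < 4:
        raise ValueError("need at least 4 library lengths")
    tau = stats.kendalltau(curve.lengths, curve.rhos)
    if np.isnan(tau.statistic):
        kendall_p = 1.0
    else:
        kendall_p = tau.pvalue / 2 if tau.statistic > 0 \
            else 1 - tau.pvalue / 2
    n1 = n_full if n_full is not None else curve.n_pred
    n0 = n_min if n_min is not None else curve.n_pred
    if min(n0, n1) <= 3:
        fisher_p = 1.0
    else:
        z = (np.arctanh(_clamp(curve.rho_full))
             - np.arctanh(_clamp(curve.rho_min)))
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n0 - 3))
        fisher_p = float(stats.norm.sf(z / se))
    return float(kendall_p), fisher_p


def assess_link(cause: pd.Series, effect: pd.Series, E_effect: int,
                seed: int = 0, lags=DEFAULT_LAGS, n_surrogates: int = 100,
                n_subsamples: int = 100, library_lengths=None,
                keep_audit: bool = False) -> LinkResult:
    """Full causal test for one ordered pair (cause → effect).

    Both series must be standardised and share a (year, season) index.
    Cross-maps at each lag, keeps the lag with the highest full-library ρ,
    compares that ρ against 100 seasonal surrogates of the cause (same lag),
    and applies both convergence tests.
    """
    cause_v = cause.to_numpy(dtype=float)
    effect_v = effect.to_numpy(dtype=float)
    ws = CrossMapWorkspace(effect_v, E_effect)
    curves = {}
    for lag in lags:
        try:
            curves[lag] = ws.rho_curve(cause_v, lag,
                                       library_lengths=library_lengths,
                                       n_subsamples=n_subsamples, seed=seed)
        except ValueError:
            continue
    if not curves:
        raise ValueError("no lag produced a usable cross-map curve")
    best_lag = max(curves, key=lambda lag: curves[lag].rho_full)
    curve = curves[best_lag]

    # surrogate criterion: recompute full-library rho with the cause series
    # replaced by each surrogate; the effect embedding is unchanged.  Each
    # surrogate gets the same best-lag selection as the real series (max
    # over lags), otherwise the real maximum rides a multiplicity advantage
    # and the test is anti-conservative.
    surr = make_seasonal_surrogates(cause, n=n_surrogates, seed=seed + 1)
    surr_by_lag = []
    for lag in curves:
        full_lib = ws.full_library(cause_v, lag)
        surr_by_lag.append([ws.rho(s, full_lib, lag) for s in surr])
    surr_rhos = np.nanmax(np.array(surr_by_lag), axis=0)
    threshold = np.nanpercentile(surr_rhos, 95)
    surrogate_pass = bool(curve.rho_full > threshold)

    kendall_p, fisher_p = test_convergence(curve)
    accepted = surrogate_pass and kendall_p < ALPHA and fisher_p < ALPHA
    return LinkResult(
        source=cause.name if cause.name is not None else "cause",
        target=effect.name if effect.name is not None else "effect",
        best_lag=int(best_lag), rho_full=curve.rho_full,
        rho_min=curve.rho_min, surrogate_pass=surrogate_pass,
        kendall_p=kendall_p, fisher_p=fisher_p, accepted=accepted,
        curve=curve if keep_audit else None,
        surrogate_rhos=surr_rhos if keep_audit else None,
    )


def infer_network(std_panel: pd.DataFrame, seed: int = 0,
                  E_range=range(2, 10), lags=DEFAULT_LAGS,
                  n_surrogates: int = 100, n_subsamples: int = 100,
                  prune: bool = True, keep_audit: bool = False):
    """Run the pairwise causal screen over one site's standardised panel.

    Returns the (optionally pruned) InteractionNetwork and the per-species
    embedding dimensions chosen by simplex projection.
    """
    species = list(std_panel.columns)
    E_by_species = {}
    for sp in species:
        E_by_species[sp], _ = select_E(std_panel[sp].to_numpy(), E_range)
    links = []
    for k, (cause, effect) in enumerate(permutations(species, 2)):
        links.append(assess_link(
            std_panel[cause], std_panel[effect], E_by_species[effect],
            seed=seed + k, lags=lags, n_surrogates=n_surrogates,
            n_subsamples=n_subsamples, keep_audit=keep_audit))
    net = InteractionNetwork(species=species, links=links)
    if prune:
        net = prune_indirect(net)
    return net, E_by_species


def prune_indirect(network: InteractionNetwork) -> InteractionNetwork:
    """Flag accepted links that look like two-step transitive shortcuts.

    An accepted edge X→Z is pruned when accepted unpruned edges X→Y and
    Y→Z exist and X→Z has BOTH a strictly more negative lag and a strictly
    lower ρ than the first hop X→Y.  The pass iterates to a fixed point so
    longer chains collapse too.  Pruned edges stay in the record, flagged.
    """
    changed = True
    while changed:
        changed = False
        edges = network.edges
        by_source = {}
        for e in edges:
            by_source.setdefault(e.source, []).append(e)
        for xz in edges:
            for xy in by_source.get(xz.source, []):
                if xy.target in (xz.source, xz.target):
                    continue
                closes = any(yz.target == xz.target
                             for yz in by_source.get(xy.target, []))
                if closes and xz.best_lag < xy.best_lag \
                        and xz.rho_full < xy.rho_full:
                    xz.pruned_as_indirect = True
                    changed = True
                    break
    return network


_RANK = {lev: i for i, lev in enumerate(LEVELS)}


def _food_chain_length(network: InteractionNetwork,
                       trophic: TrophicAssignment) -> int:
    """Node count of the longest directed path ascending trophic ranks."""
    edges = [(e.source, e.target) for e in network.edges
             if _RANK[trophic.level(e.source)] < _RANK[trophic.level(e.target)]]
    if not edges:
        return 1 if network.species else 0
    # strictly ascending ranks -> acyclic; longest path by rank-ordered DP
    longest = {sp: 1 for sp in network.species}
    for sp in sorted(network.species, key=lambda s: _RANK[trophic.level(s)]):
        for src, tgt in edges:
            if src == sp:
                longest[tgt] = max(longest[tgt], longest[sp] + 1)
    return max(longest.values())


def network_metrics(network: InteractionNetwork,
                    trophic: TrophicAssignment | None = None) -> dict:
    """L, link density L/S, connectance L/S², and food chain length."""
    S = len(network.species)
    L = len(network.edges)
    if S == 0:
        return {"L": 0, "link_density": 0.0, "connectance": 0.0,
                "food_chain_length": 0}
    out = {"L": L, "link_density": L / S, "connectance": L / S ** 2}
    out["food_chain_length"] = (_food_chain_length(network, trophic)
                                if trophic is not None else np.nan)
    return out
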