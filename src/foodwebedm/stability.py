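"""Stability, synchrony and diversity metrics of a food web.

Structural stability is the volume contraction rate: the divergence of the
vector field, i.e. the trace of the time-varying Jacobian.  A smaller trace
means dynamics that are more robust to parameter perturbation.  The trace
decomposes exactly into the diagonal contributions of the three trophic
groups (producers; consumers = herbivores; predators = omnivores and
secondary-or-higher consumers).

Temporal stability is the inverse of the coefficient of variation (sd/mean)
of total community abundance over a trailing moving window (6 seasonal
points = 1.5 years by default; 12 points in the sensitivity variant), on
raw — never standardised — abundances, because the mean and variance are
part of the statistic.  Synchrony uses the variance-ratio statistic
φ = σ²/(Σ σ_i)², which runs from 0 (perfectly compensatory fluctuations)
to 1 (perfectly synchronous).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mdr import JacobianSeries
from .preprocess import TrophicAssignment, transform_temperature

__all__ = [
    "structural_stability",
    "trophic_contributions",
    "temporal_stability",
    "synchrony",
    "diversity_indices",
    "stability_table",
]

GROUPS = ("producer", "consumer", "predator")


def structural_stability(jac: JacobianSeries) -> pd.Series:
    """Tr(J) per time step — the volume contraction rate."""
    return pd.Series(jac.trace(), index=pd.Index(jac.times, name="t"),
                     name="TrJ")


def trophic_contributions(jac: JacobianSeries,
                          groups: TrophicAssignment) -> pd.DataFrame:
    """Partial diagonal sums of B_t by trophic group.

    The three columns add up to Tr(J) exactly at every time step.
    """
    group_of = {sp: groups.group(sp) for sp in jac.species}
    diag = np.diagonal(jac.matrices, axis1=1, axis2=2)
    out = {}
    for g in GROUPS:
        cols = [k for k, sp in enumerate(jac.species) if group_of[sp] == g]
        out[f"contribution_{g}"] = diag[:, cols].sum(axis=1) if cols \
            else np.zeros(len(jac.times))
    return pd.DataFrame(out, index=pd.Index(jac.times, name="t"))


def _window_starts(n: int, window: int, stride: int) -> range:
    return range(0, n - window + 1, stride)


def _cv(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return np.nan
    return float(values.std(ddof=1) / m)


def _group_totals(raw: pd.DataFrame, groups: TrophicAssignment):
    """Community total plus per-group summed abundance, per time point."""
    totals = {"community": raw.sum(axis=1)}
    for g in GROUPS:
        cols = [sp for sp in raw.columns if groups.group(sp) == g]
        if cols:
            totals[g] = raw[cols].sum(axis=1)
    return totals


def temporal_stability(raw: pd.DataFrame, groups: TrophicAssignment,
                       window: int = 6, stride: int = 1) -> pd.DataFrame:
    """Moving-window CV of community and per-group total abundance.

    Windows are trailing and labelled by their last time point (positional
    index into ``raw``).  A window whose mean total is 0 yields a missing
    CV.  ``ln_cv_*`` columns carry the natural-log CV used downstream.
    """
    totals = _group_totals(raw, groups)
    rows = []
    for start in _window_starts(len(raw), window, stride):
        end = start + window - 1
        row = {"t": end}
        for name, series in totals.items():
            row[f"cv_{name}"] = _cv(series.to_numpy()[start:start + window])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("t")
    for col in list(out.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            out["ln_" + col] = np.where(out[col] > 0, np.log(out[col]),
                                        np.nan)
    return out


def _phi(block: pd.DataFrame) -> float:
    """Variance-ratio synchrony of one window of species abundances."""
    sds = block.std(ddof=1).to_numpy()
    denom = sds.sum() ** 2
    if denom == 0:
        return np.nan
    if block.shape[1] == 1:
        return 1.0  # a lone species is trivially synchronous with itself
    total_var = block.sum(axis=1).to_numpy().var(ddof=1)
    return float(total_var / denom)


def synchrony(raw: pd.DataFrame, groups: TrophicAssignment,
              window: int = 6, stride: int = 1) -> pd.DataFrame:
    """Moving-window synchrony φ = σ²/(Σσ_i)², community and per group."""
    group_cols = {"community": list(raw.columns)}
    for g in GROUPS:
        cols = [sp for sp in raw.columns if groups.group(sp) == g]
        if cols:
            group_cols[g] = cols
    rows = []
    for start in _window_starts(len(raw), window, stride):
        row = {"t": start + window - 1}
        block = raw.iloc[start:start + window]
        for name, cols in group_cols.items():
            row[f"phi_{name}"] = _phi(block[cols])
        rows.append(row)
    return pd.DataFrame(rows).set_index("t")


def diversity_indices(raw: pd.DataFrame) -> pd.DataFrame:
    """Richness, Simpson (1 − Σp²) and Shannon (−Σp ln p) per time point.

    Richness counts species with strictly positive abundance; proportions
    are over the species present.  A time point with zero total abundance
    yields missing diversity values.
    """
    values = raw.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    richness = (values > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = values / totals[:, None]
        simpson = 1.0 - np.nansum(p ** 2, axis=1)
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        shannon = -np.sum(p * logp, axis=1)
    bad = totals <= 0
    simpson[bad] = np.nan
    shannon[bad] = np.nan
    return pd.DataFrame(
        {"richness": richness, "simpson": simpson, "shannon": shannon},
        index=pd.RangeIndex(len(raw), name="t"))


def stability_table(raw: pd.DataFrame, temperature: pd.Series,
                    jac: JacobianSeries | None, groups: TrophicAssignment,
                    window: int = 6, site: str = "site") -> pd.DataFrame:
    """Assemble the per-site stability panel used by the statistics stage.

    Point-wise quantities (Tr(J), contributions, diversity, transformed
    temperature) sit on the time-point index; window quantities (CV, φ)
    are labelled by their window's last point.  ``raw`` must be positional
    (one row per seasonal time step).
    """
    n = len(raw)
    out = diversity_indices(raw)
    out["ln_richness"] = np.where(out["richness"] > 0,
                                  np.log(out["richness"]), np.nan)
    temp = np.asarray(temperature, dtype=float)[:n]
    out["temperature_C"] = temp
    out["ln_temperature_F"] = transform_temperature(temp)
    if jac is not None:
        out = out.join(structural_stability(jac))
        out = out.join(trophic_contributions(jac, groups))
    out = out.join(temporal_stability(raw, groups, window=window))
    out = out.join(synchrony(raw, groups, window=window))
    out.insert(0, "site", site)
    return out
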