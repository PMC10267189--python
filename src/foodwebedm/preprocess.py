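"""Turn raw observation tables into the analysis-ready seasonal panel.

The analysis operates on a seasonal (trimonthly) panel: one row per
(site, year, season), species abundances in individuals per litre and a
water-temperature column.  Sub-seasonal sampling is averaged within season,
interior gaps are linearly interpolated, species with too many zeros are
dropped (at least one nonzero observation per 1.5 years, i.e. per block of
6 seasonal points, by default), and series are z-scored before any
state-space reconstruction.  Raw (unstandardised) abundances are kept for
the temporal-stability statistics, whose definition involves the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEASON_ORDER = ("winter", "spring", "summer", "autumn")
LEVELS = ("producer", "herbivore", "omnivore", "predator")

#: derived trophic grouping: herbivores are the primary consumers;
#: omnivores and secondary-or-higher consumers count as predators.
LEVEL_TO_GROUP = {
    "producer": "producer",
    "herbivore": "consumer",
    "omnivore": "predator",
    "predator": "predator",
}

__all__ = [
    "AbundanceTable",
    "TrophicAssignment",
    "seasonalize",
    "fill_missing",
    "filter_rare",
    "zscore",
    "transform_temperature",
]


@dataclass
class AbundanceTable:
    """Seasonal abundance panel.

    ``data``: wide DataFrame, MultiIndex (site, year, season) in
    chronological order within site, one column per species, individuals
    per litre (NaN = missing).  ``temperature``: aligned series in °C.
    """

    data: pd.DataFrame
    temperature: pd.Series
    standardised: bool = False  # z-scored tables may hold negative values

    def __post_init__(self) -> None:
        if list(self.data.index.names) != ["site", "year", "season"]:
            raise ValueError(
                "index must be a (site, year, season) MultiIndex")
        if not self.data.index.equals(self.temperature.index):
            raise ValueError("temperature index must match abundance index")
        dup = self.data.index.duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate (site, year, season) rows: "
                f"{self.data.index[dup].tolist()[:5]}")
        if not self.standardised:
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("abundances must be >= 0 where present")

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.data.index.get_level_values("site").unique())

    def site_panel(self, site) -> pd.DataFrame:
        return self.data.xs(site, level="site")

    def site_temperature(self, site) -> pd.Series:
        return self.temperature.xs(site, level="site")

    def replace_data(self, data: pd.DataFrame) -> "AbundanceTable":
        return AbundanceTable(data=data, temperature=self.temperature,
                              standardised=self.standardised)

    # ---- tidy CSV round-trip -------------------------------------------
    def to_tidy(self) -> pd.DataFrame:
        long = (self.data.stack(future_stack=True)
                .rename("abundance").reset_index()
                .rename(columns={"level_3": "species"}))
        temp = self.temperature.rename("temperature_C").reset_index()
        return long.merge(temp, on=["site", "year", "season"], how="left")

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame,
                  standardised: bool = False) -> "AbundanceTable":
        required = {"site", "year", "season", "species", "abundance"}
        missing = required - set(tidy.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if not standardised:
            neg = tidy["abundance"] < 0
            if neg.any():
                row = tidy.index[neg][0]
                raise ValueError(f"negative abundance at input row {row}")
        dup = tidy.duplicated(["site", "year", "season", "species"])
        if dup.any():
            raise ValueError(
                "duplicate (site, year, season, species) rows in input")
        wide = tidy.pivot(index=["site", "year", "season"],
                          columns="species", values="abundance")
        wide = wide[list(dict.fromkeys(tidy["species"]))]  # keep input order
        wide = _sort_seasonal(wide)
        if "temperature_C" in tidy.columns:
            temp = (tidy.groupby(["site", "year", "season"], sort=False)
                    ["temperature_C"].first().reindex(wide.index))
        else:
            temp = pd.Series(np.nan, index=wide.index)
        return cls(data=wide, temperature=temp.rename("temperature_C"),
                   standardised=standardised)

    @classmethod
    def read_csv(cls, path, standardised: bool = False) -> "AbundanceTable":
        return cls.from_tidy(pd.read_csv(path), standardised=standardised)


def _sort_seasonal(frame: pd.DataFrame) -> pd.DataFrame:
    """Chronological ordering of a (site, year, season) indexed frame."""
    order = {s: i for i, s in enumerate(SEASON_ORDER)}
    idx = frame.index.to_frame(index=False)
    key = idx["season"].map(order)
    if key.isna().any():
        # non-calendar labels like s1..s6: fall back to lexicographic
        key = idx["season"].str.lstrip("s").astype(int)
    pos = np.lexsort((key.to_numpy(), idx["year"].to_numpy(),
                      idx["site"].to_numpy()))
    return frame.iloc[pos]


@dataclass
class TrophicAssignment:
    """Species → trophic level, and the derived three-group mapping."""

    levels: dict

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.levels.items() if l not in LEVELS}
        if bad:
            raise ValueError(f"unknown trophic levels: {bad}")

    def level(self, species: str) -> str:
        try:
            return self.levels[species]
        except KeyError:
            raise KeyError(f"species {species!r} has no trophic assignment")

    def group(self, species: str) -> str:
        return LEVEL_TO_GROUP[self.level(species)]

    def groups(self, species_list) -> list[str]:
        return [self.group(s) for s in species_list]

    def validate_against(self, table: AbundanceTable) -> None:
        missing = [s for s in table.species if s not in self.levels]
        if missing:
            raise ValueError(
                f"species without trophic assignment: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.levels),
             "level": [self.levels[s] for s in self.levels],
             "group": [LEVEL_TO_GROUP[self.levels[s]] for s in self.levels]})

    @classmethod
    def read_csv(cls, path) -> "TrophicAssignment":
        frame = pd.read_csv(path)
        return cls(dict(zip(frame["species"], frame["level"])))


# meteorological seasons; December belongs to the following year's winter
_MONTH_TO_SEASON = {12: "winter", 1: "winter", 2: "winter",
                    3: "spring", 4: "spring", 5: "spring",
                    6: "summer", 7: "summer", 8: "summer",
                    9: "autumn", 10: "autumn", 11: "autumn"}


def seasonalize(raw: pd.DataFrame) -> AbundanceTable:
    """Average sub-seasonal observations to one row per (site, year, season).

    ``raw`` is tidy with columns site, date, species, abundance and
    optionally temperature_C.  Dates map to meteorological seasons (DJF,
    MAM, JJA, SON); December counts toward the next year's winter.  Seasons
    with no sample stay absent (missing), never 0.
    """
    raw = raw.copy()
    dates = pd.to_datetime(raw["date"], errors="coerce")
    if dates.isna().any():
        bad = raw.loc[dates.isna(), "date"].iloc[0]
        raise ValueError(f"unmappable date: {bad!r}")
    month = dates.dt.month
    raw["season"] = month.map(_MONTH_TO_SEASON)
    raw["year"] = dates.dt.year + (month == 12).astype(int)
    keys = ["site", "year", "season"]
    wide = (raw.groupby(keys + ["species"], sort=False)["abundance"]
            .mean().unstack("species"))
    wide = _sort_seasonal(wide)
    if "temperature_C" in raw.columns:
        temp = (raw.groupby(keys, sort=False)["temperature_C"].mean()
                .reindex(wide.index))
    else:
        temp = pd.Series(np.nan, index=wide.index)
    return AbundanceTable(data=wide, temperature=temp.rename("temperature_C"))


def fill_missing(table: AbundanceTable):
    """Linearly interpolate interior missing values, per species per site.

    Returns ``(filled_table, n_filled)``.  Leading or trailing gaps cannot
    be interpolated and raise, with the advice to truncate the series.
    """
    data = table.data.copy()
    n_filled = 0
    for site in table.sites:
        mask = data.index.get_level_values("site") == site
        block = data.loc[mask]
        for sp in block.columns:
            col = block[sp].to_numpy(dtype=float)
            isna = np.isnan(col)
            if not isna.any():
                continue
            if isna[0] or isna[-1]:
                raise ValueError(
                    f"species {sp!r} at site {site!r} has leading/trailing "
                    f"missing values; truncate the series instead of "
                    f"extrapolating")
            t = np.arange(col.size)
            col[isna] = np.interp(t[isna], t[~isna], col[~isna])
            n_filled += int(isna.sum())
            data.loc[mask, sp] = col
    filled = AbundanceTable(data=data, temperature=table.temperature)
    return filled, n_filled


def _blocks_ok(nonzero: np.ndarray, window: int, min_nonzero: int) -> bool:
    """Every non-overlapping `window`-block (incl. remainder) has enough hits."""
    n = nonzero.size
    for start in range(0, n, window):
        if nonzero[start:start + window].sum() < min_nonzero:
            return False
    return True


def _sliding_ok(nonzero: np.ndarray, window: int, min_nonzero: int) -> bool:
    n = nonzero.size
    if n <= window:
        return nonzero.sum() >= min_nonzero
    counts = np.convolve(nonzero.astype(int), np.ones(window, int), "valid")
    return bool((counts >= min_nonzero).all())


def filter_rare(table: AbundanceTable, min_nonzero_per_window: int = 1,
                window: int = 6, mode: str = "blocks"):
    """Drop low-frequency species.

    A species is retained iff every consecutive block of ``window`` time
    points (non-overlapping tiling from the series start, remainder block
    included) holds at least ``min_nonzero_per_window`` nonzero values, at
    every site where it occurs.  ``window=6`` encodes "at least once per
    1.5 years" at trimonthly sampling; the sensitivity variant uses 8
    ("once per 2 years").  ``mode="sliding"`` applies the rule to every
    window position instead of the tiling.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    check = _blocks_ok if mode == "blocks" else _sliding_ok
    keep = []
    for sp in table.species:
        ok = True
        for site in table.sites:
            col = table.site_panel(site)[sp].to_numpy(dtype=float)
            nonzero = np.nan_to_num(col) > 0
            if not check(nonzero, window, min_nonzero_per_window):
                ok = False
                break
        if ok:
            keep.append(sp)
    return table.replace_data(table.data[keep])


def zscore(table: AbundanceTable):
    """Standardise each species series (and temperature) per site.

    Returns ``(standardised, raw)`` — the raw table is passed through
    untouched because the temporal-stability statistics need original means
    and variances.  Uses the n−1 standard deviation.  A zero-variance
    series cannot be standardised and raises, naming the species.
    """
    data = table.data.copy().astype(float)
    temp = table.temperature.copy().astype(float)
    for site in table.sites:
        mask = data.index.get_level_values("site") == site
        block = data.loc[mask]
        sd = block.std(ddof=1)
        flat = sd[(sd == 0) | sd.isna()]
        if len(flat):
            raise ValueError(
                f"zero-variance series at site {site!r}: "
                f"{list(flat.index)}")
        data.loc[mask] = (block - block.mean()) / sd
        tblock = temp.loc[mask]
        tsd = tblock.std(ddof=1)
        if tsd > 0:
            temp.loc[mask] = (tblock - tblock.mean()) / tsd
    return AbundanceTable(data=data, temperature=temp,
                          standardised=True), table


def transform_temperature(celsius):
    """ln of the Fahrenheit temperature: ln(°C · 9/5 + 32).

    The log keeps the predictor positive-domain and compresses the range;
    Fahrenheit avoids negative winter values that the log could not take.
    """
    celsius = np.asarray(celsius, dtype=float)
    fahrenheit = celsius * 9.0 / 5.0 + 32.0
    if np.any(fahrenheit[np.isfinite(fahrenheit)] <= 0):
        raise ValueError(
            "temperature at or below -17.78 °C gives non-positive °F; "
            "cannot log-transform")
    return np.log(fahrenheit)
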