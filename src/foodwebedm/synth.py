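"""Synthetic multitrophic food-web time series with known ground truth.

Generates Ricker-type (discrete-time Lotka-Volterra) food webs with
seasonally forced temperature, trophic-structured interaction signs, and
field-like sampling artifacts (zero inflation of rare observations, missing
points).  The map has a closed-form Jacobian, so the simulator returns the
exact interaction strengths ``dx_i(t+1)/dx_j(t)`` along the realized
trajectory — the same quantity the MDR S-map estimates — making recovery
tests possible.

Dynamics
--------
    x_i(t+1) = x_i(t) * exp( r_i + sum_j a_ij(T_t) * x_j(t) + eps_it )

with ``a_ij(T) = a_ij * exp(temp_sensitivity * (T - temp_mean))`` for i != j
(an Arrhenius-like amplification of interaction rates with temperature) and
process noise ``eps ~ N(0, noise_sd)`` on the log scale.  Producers have
positive intrinsic growth and negative self-limitation; consumers have
negative intrinsic growth, gain from their resources and depress them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("winter", "spring", "summer", "autumn")

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_foodweb",
    "simulate_coupled_pair",
    "degrade_sampling",
]


class DivergenceError(RuntimeError):
    """Raised when a simulated trajectory blows up or leaves its domain."""


@dataclass
class SimConfig:
    """Configuration of a synthetic food-web run.

    Counts per trophic level may be 0 except producers (at least one basal
    species is required); the web must contain at least one species overall.
    """

    n_producers: int = 2
    n_herbivores: int = 2
    n_omnivores: int = 0
    n_predators: int = 1
    years: int = 20
    steps_per_year: int = 4
    temp_mean: float = 12.0
    temp_amplitude: float = 8.0
    temp_sensitivity: float = 0.1
    noise_sd: float = 0.02
    obs_noise_sd: float = 0.0
    zero_inflation: float = 0.0
    missing_rate: float = 0.0
    detection_quantile: float = 0.1
    seed: int = 0
    burn_in: int = 50
    site: str = "sim"

    def __post_init__(self) -> None:
        counts = (self.n_producers, self.n_herbivores, self.n_omnivores,
                  self.n_predators)
        if any(c < 0 for c in counts):
            raise ValueError("trophic group counts must be >= 0")
        if self.n_producers < 1:
            raise ValueError("at least one producer is required")
        if sum(counts) < 1:
            raise ValueError("at least one species is required")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.steps_per_year < 2:
            raise ValueError("steps_per_year must be >= 2")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_species(self) -> int:
        return (self.n_producers + self.n_herbivores + self.n_omnivores +
                self.n_predators)

    @property
    def levels(self) -> list[str]:
        """Trophic level of each species, in species order."""
        return (["producer"] * self.n_producers
                + ["herbivore"] * self.n_herbivores
                + ["omnivore"] * self.n_omnivores
                + ["predator"] * self.n_predators)

    @property
    def species(self) -> list[str]:
        prefix = {"producer": "P", "herbivore": "H", "omnivore": "O",
                  "predator": "C"}
        names, counter = [], {}
        for lev in self.levels:
            counter[lev] = counter.get(lev, 0) + 1
            names.append(f"{prefix[lev]}{counter[lev]}")
        return names


@dataclass
class SimTruth:
    """Ground truth of a simulated web.

    true_adjacency[i, j] is True iff a_ij != 0, i.e. species j enters the
    update of species i.  true_jacobians[t] holds dx_i(t+1)/dx_j(t)
    evaluated analytically at the realized state (process noise held fixed).
    """

    true_adjacency: np.ndarray
    true_jacobians: np.ndarray
    latent_abundances: np.ndarray
    species: list[str] = field(default_factory=list)
    levels: list[str] = field(default_factory=list)
    coefficients: np.ndarray | None = None
    growth_rates: np.ndarray | None = None


def _interaction_matrix(cfg: SimConfig, rng: np.random.Generator):
    """Draw trophic-structured coefficients a_ij and growth rates r_i.

    Producers sit near the overcompensation region of the Ricker map
    (r ≈ 1.6–2.1) so the web fluctuates persistently — the cyclic/chaotic
    regime typical of plankton — instead of settling on a fixed point;
    consumption losses exceed conversion gains so energy dissipates up the
    chain and no species crashes or explodes.
    """
    s = cfg.n_species
    levels = cfg.levels
    rank = {"producer": 0, "herbivore": 1, "omnivore": 2, "predator": 3}
    a = np.zeros((s, s))
    r = np.zeros(s)
    for i, lev in enumerate(levels):
        if lev == "producer":
            r[i] = rng.uniform(1.6, 2.1)
            a[i, i] = -r[i] * rng.uniform(0.9, 1.1)
        else:
            r[i] = -rng.uniform(0.1, 0.2)
            a[i, i] = -rng.uniform(0.3, 0.5)
    # feeding links: each consumer eats every species one rank below
    # (omnivores additionally eat producers), attack/conversion pairs
    conversion, loss = 0.4, 1.2
    for i, lev_i in enumerate(levels):
        if lev_i == "producer":
            continue
        prey_ranks = {rank[lev_i] - 1}
        if lev_i == "omnivore":
            prey_ranks.add(0)
        if lev_i == "predator":
            # predators take herbivores and omnivores alike
            prey_ranks = {1, 2} if cfg.n_omnivores else {1}
        for j, lev_j in enumerate(levels):
            if rank[lev_j] in prey_ranks:
                attack = rng.uniform(0.6, 0.9)
                a[i, j] = attack * conversion  # consumer gains from resource
                a[j, i] = -attack * loss       # resource loses
    return a, r


def _temperature(cfg: SimConfig, n_steps: int, offset: int = 0) -> np.ndarray:
    """Seasonal sinusoid peaking mid-year (summer).

    ``offset`` aligns the phase so season 0 of the *kept* series (after
    burn-in) is the coldest.
    """
    t = np.arange(n_steps) - offset
    phase = 2.0 * np.pi * (t % cfg.steps_per_year) / cfg.steps_per_year
    # minimum on season 0 (winter), maximum on the mid-year season (summer)
    return cfg.temp_mean + cfg.temp_amplitude * np.sin(phase - np.pi / 2.0)


def _step(x, a_t, r, eps):
    g = r + a_t @ x + eps
    return x * np.exp(g), g


def _jacobian(x, g, a_t):
    """d x_i(t+1) / d x_j(t) of the Ricker map at state x with exponent g."""
    growth = np.exp(g)
    return np.diag(growth) + (x * growth)[:, None] * a_t


def simulate_foodweb(config: SimConfig,
                     coefficients: np.ndarray | None = None,
                     growth_rates: np.ndarray | None = None,
                     initial: np.ndarray | None = None):
    """Simulate a seasonal food web; return (AbundanceTable, SimTruth).

    ``coefficients``/``growth_rates``/``initial`` override the randomly
    drawn parameterisation (used by tests with hand-picked dynamics).
    """
    from .preprocess import AbundanceTable

    rng = np.random.default_rng(config.seed)
    s = config.n_species
    a, r = _interaction_matrix(config, rng)
    if coefficients is not None:
        a = np.asarray(coefficients, dtype=float)
    if growth_rates is not None:
        r = np.asarray(growth_rates, dtype=float)

    n_keep = config.years * config.steps_per_year
    n_total = n_keep + config.burn_in
    temp = _temperature(config, n_total, offset=config.burn_in)
    scale = np.exp(config.temp_sensitivity * (temp - config.temp_mean))

    x = np.full(s, 0.5) if initial is None else np.asarray(initial, float)
    eps_all = rng.normal(0.0, config.noise_sd, size=(n_total, s)) \
        if config.noise_sd > 0 else np.zeros((n_total, s))

    states = np.empty((n_keep, s))
    jacobians = np.empty((n_keep, s, s))
    off = ~np.eye(s, dtype=bool)
    for t in range(n_total):
        a_t = a.copy()
        a_t[off] = a[off] * scale[t]
        x_next, g = _step(x, a_t, r, eps_all[t])
        if not np.all(np.isfinite(x_next)) or np.any(x_next > 1e9):
            raise DivergenceError(
                f"trajectory diverged at step {t} (seed={config.seed}, "
                f"temp_sensitivity={config.temp_sensitivity}, "
                f"noise_sd={config.noise_sd})")
        if t >= config.burn_in:
            k = t - config.burn_in
            states[k] = x
            jacobians[k] = _jacobian(x, g, a_t)
        x = x_next

    species = config.species
    years = np.repeat(np.arange(1, config.years + 1), config.steps_per_year)
    if config.steps_per_year == 4:
        seasons = np.tile(SEASONS, config.years)
    else:
        seasons = np.tile(
            [f"s{i + 1}" for i in range(config.steps_per_year)], config.years)
    index = pd.MultiIndex.from_arrays(
        [[config.site] * n_keep, years, seasons],
        names=["site", "year", "season"])
    data = pd.DataFrame(states, index=index, columns=species)
    temperature = pd.Series(temp[config.burn_in:], index=index,
                            name="temperature_C")
    table = AbundanceTable(data=data, temperature=temperature)

    truth = SimTruth(
        true_adjacency=a != 0,
        true_jacobians=jacobians,
        latent_abundances=states,
        species=species,
        levels=config.levels,
        coefficients=a,
        growth_rates=r,
    )
    return table, truth


def simulate_coupled_pair(rx: float, ry: float, bxy: float, byx: float,
                          n: int, seed: int = 0, burn_in: int = 100):
    """Two coupled logistic maps, the classic cross-mapping benchmark.

        x(t+1) = x(t) * (rx - rx*x(t) - bxy*y(t))
        y(t+1) = y(t) * (ry - ry*y(t) - byx*x(t))

    With bxy=0 and byx>0, x drives y and not vice versa.  The first
    ``burn_in`` steps are discarded so the shared initial transient does
    not masquerade as coupling.  Returns an AbundanceTable with species
    columns ``x`` and ``y`` (n rows).
    """
    from .preprocess import AbundanceTable

    if n < 50:
        raise ValueError("n must be >= 50")
    rng = np.random.default_rng(seed)
    x = 0.2 + 0.2 * rng.random()
    y = 0.3 + 0.2 * rng.random()
    xs = np.empty(n)
    ys = np.empty(n)
    for t in range(n + burn_in):
        if t >= burn_in:
            xs[t - burn_in], ys[t - burn_in] = x, y
        x, y = x * (rx - rx * x - bxy * y), y * (ry - ry * y - byx * x)
        if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
            raise DivergenceError(
                f"coupled-pair trajectory left (0,1) at step {t}")
    years = np.repeat(np.arange(1, n // 4 + 2), 4)[:n]
    seasons = np.tile(SEASONS, n // 4 + 1)[:n]
    index = pd.MultiIndex.from_arrays(
        [["pair"] * n, years, seasons], names=["site", "year", "season"])
    data = pd.DataFrame({"x": xs, "y": ys}, index=index)
    temperature = pd.Series(np.zeros(n), index=index, name="temperature_C")
    return AbundanceTable(data=data, temperature=temperature)


def degrade_sampling(table, config: SimConfig):
    """Apply field-like observation artifacts to a clean table.

    In order: multiplicative lognormal observation noise (sd
    ``config.obs_noise_sd`` on the log scale), zero inflation — values below
    the per-species ``detection_quantile`` are recorded as 0 with probability
    ``zero_inflation`` — and missingness (cells set to NaN with probability
    ``missing_rate``).  All draws come from one stream seeded by
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    data = table.data.copy()
    values = data.to_numpy(dtype=float)
    if config.obs_noise_sd > 0:
        values = values * np.exp(
            rng.normal(0.0, config.obs_noise_sd, size=values.shape))
    if config.zero_inflation > 0:
        thresh = np.nanquantile(values, config.detection_quantile, axis=0)
        low = values <= thresh
        hit = rng.random(values.shape) < config.zero_inflation
        values[low & hit] = 0.0
    if config.missing_rate > 0:
        gone = rng.random(values.shape) < config.missing_rate
        values[gone] = np.nan
    data.loc[:, :] = values
    return table.replace_data(data)
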