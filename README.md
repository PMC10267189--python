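# foodwebedm

Stability analysis of food webs from multispecies abundance time series,
using empirical dynamic modelling (EDM).

Long-term plankton monitoring programmes record seasonal abundances of
dozens of interacting species together with water temperature. This package
turns such records into statements about food-web stability. It is aimed at
community ecologists and theoreticians working with seasonal (trimonthly)
abundance panels spanning a decade or more — the kind of data produced by
LTER lake programmes or coastal monitoring stations — and at anyone who
wants a tested, reproducible implementation of the full inference chain:

1. **Preprocessing** — seasonal averaging, linear interpolation of interior
   gaps, removal of low-frequency species (at least one nonzero value per
   6-point block by default), z-scoring for state-space work while raw
   abundances are kept for variability statistics.
2. **Network reconstruction by convergent cross mapping (CCM).** For a
   candidate link X→Y, the delay embedding of the *affected* variable Y is
   used to cross-predict the *causal* variable X at lags 0 to −2; the link
   is accepted only if (i) the cross-map skill ρ beats the 95th percentile
   of 100 seasonality-preserving surrogates of X, and (ii) ρ increases with
   library length L (one-sided Kendall τ and Fisher z tests, both
   p < 0.05). Suspected transitive shortcuts X⇢Z are pruned when they carry
   a more negative lag and lower ρ than the direct first hop.
3. **Time-varying interaction strengths** via the multiview distance
   regularised S-map (MDR S-map). Per node, an ensemble of low-dimensional
   state-space reconstructions over its causal variables yields a multiview
   distance d^E; local weighted elastic-net regressions

       B̂_t = argmin_B ‖√W_t (X_{t+1} − X_t B)‖² + λ[α‖B‖₂² + (1−α)‖B‖₁],
       W_t = exp(−θ d^E(t,·)/mean d^E(t,·)),

   estimate the discrete-time Jacobian B_t[i,j] ≈ ∂x_i(t+1)/∂x_j(t), with
   (θ, λ, α) chosen per node by leave-one-out forecast rMSE.
4. **Stability metrics.** Structural stability as the volume contraction
   rate Tr(J(t)) (smaller = more stable) and its exact decomposition into
   producer/consumer/predator diagonal contributions; temporal stability as
   the moving-window (6 points = 1.5 years) coefficient of variation of
   community abundance; synchrony φ = σ²/(Σᵢσᵢ)² ∈ [0, 1]; richness,
   Simpson and Shannon diversity.
5. **Effect estimation** with linear mixed models: point-wise responses get
   crossed random intercepts for site, year and season; window-based
   responses a site intercept; per-web OLS trends alongside. Temperature is
   analysed as ln(°F), richness as ln(richness), CV on the log scale.

Because real monitoring data cannot ship with the package, a first-class
synthetic generator (`simulate_foodweb`) produces multitrophic Ricker
webs with seasonally forced, temperature-amplified interaction rates,
field-like sampling artifacts, and — crucially — the *analytic* Jacobian of
the simulated map along the trajectory, so every stage of the chain can be
validated against ground truth.

## Worked example

```python
import foodwebedm as fw

# a 5-species web (2 producers, 2 herbivores, 1 predator), 20 years of
# trimonthly sampling, temperature-sensitive interaction rates
cfg = fw.SimConfig(seed=7)
table, truth = fw.simulate_foodweb(cfg)

std, raw = fw.zscore(fw.filter_rare(table))
panel = std.site_panel("sim")

net, E_map = fw.infer_network(panel, seed=7, n_subsamples=20,
                              n_surrogates=50)
trophic = fw.TrophicAssignment(dict(zip(truth.species, truth.levels)))
print(fw.network_metrics(net, trophic))

jac = fw.estimate_jacobians(net, panel, seed=7, E_by_species=E_map)
trj = fw.structural_stability(jac)
print(float(trj.mean()))
```

prints:

```
{'L': 10, 'link_density': 2.0, 'connectance': 0.4, 'food_chain_length': 3}
1.5983227409367002
```

Ten directed links were accepted among the 20 ordered pairs (link density
L/S = 2.0, connectance L/S² = 0.4, a three-level chain), and the mean
volume contraction rate Tr(J) ≈ 1.60 summarises how fast local phase-space
volume contracts along the trajectory — the number whose temperature
response the mixed-model stage then quantifies.

The same chain runs from the shell:

```bash
foodwebedm run-all --seed 7 --out run/
```

writing `abundance.csv`, `edges.csv`, `jacobians.csv`, `stability.csv`,
`effects.csv` and a JSON manifest under `run/`. A `--sensitivity` flag
switches to the 12-point CV window and the looser rare-species rule.

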