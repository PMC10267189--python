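# Methods

This note documents the models, estimators, numerical choices and known
limitations of `foodwebedm`, in the order the pipeline runs.

## Scope and data model

The unit of analysis is a seasonal abundance panel: one row per
(site, year, season), one column per species (individuals per litre),
plus a water-temperature column (°C). Sampling is trimonthly — the shared
resolution of long-term plankton monitoring — and series span 10–30 years.
Species carry a trophic level (producer / herbivore / omnivore / predator);
for group-wise statistics herbivores are the "consumers" and omnivores
together with secondary-and-higher consumers form the "predators".

## Synthetic webs and ground truth

`simulate_foodweb` generates the study conditions. The map is a
discrete-time Ricker / Lotka–Volterra exponential model

    x_i(t+1) = x_i(t) · exp( r_i + Σ_j a_ij(T_t) x_j(t) + ε_it ),

with ε ~ N(0, noise_sd) on the log scale and off-diagonal rates scaled by
an Arrhenius-like factor `exp(temp_sensitivity · (T_t − temp_mean))`;
temperature is a seasonal sinusoid (mean 12 °C, amplitude 8 °C by default,
coldest in winter). This family was chosen because its Jacobian is closed
form,

    ∂x_i(t+1)/∂x_j(t) = δ_ij e^{g_i} + x_i e^{g_i} a_ij,
    g_i = r_i + Σ_j a_ij x_j + ε_i,

which is exactly the quantity the MDR S-map estimates, so recovery can be
scored against analytic truth (the realized noise draw is held fixed, so
the analytic Jacobian also matches a finite-difference derivative of the
realized transition).

Parameterisation: producers are placed near the overcompensating region of
the Ricker map (r ∈ [1.6, 2.1], self-limitation ≈ −r) so the web
fluctuates persistently — the cyclic/chaotic regime typical of plankton —
rather than settling on a fixed point, which would leave the Jacobian
constant and the whole EDM chain without a signal. Consumers have negative
intrinsic growth (−0.2 to −0.1), moderate self-limitation, and feeding
links with conversion efficiency 0.4 and loss factor 1.2 (losses exceed
gains, so energy dissipates up the chain); attack rates are drawn from
[0.6, 0.9]. Under these defaults no species crashes below ~10⁻² or
diverges across seeds. Default `temp_sensitivity` is 0.1 per °C, i.e. a
≈ 2.2-fold amplification of interaction rates between winter (4 °C) and
summer (20 °C). A 50-step burn-in is discarded.

The generator's defaults (2 producers, 2 herbivores, 1 predator, 20 years,
4 samples/year, process noise 0.02) emulate the structure of the real
monitoring panels; they do **not** emulate observation error, taxonomic
aggregation, unobserved compartments (fish, bacteria), or non-stationary
long-term trends. `degrade_sampling` adds the observational artifacts
(lognormal observation noise, zero-inflation of sub-detection values,
missingness) for robustness exercises. Passing tests on these webs shows
the chain is *internally* consistent — it recovers what the generator
encodes — not that any particular field system satisfies the embedding
assumptions.

The two-species benchmark `simulate_coupled_pair` implements the classic
unidirectionally coupled logistic maps; it discards a 100-step transient so
the shared approach to the attractor is not mistaken for coupling.

## Preprocessing

Sub-seasonal samples are averaged within meteorological seasons (DJF, MAM,
JJA, SON; December belongs to the next year's winter). Interior gaps are
linearly interpolated; leading/trailing gaps raise an error advising
truncation rather than extrapolating. The rare-species rule retains a
species iff every non-overlapping 6-point block (remainder block included)
of its series contains at least one nonzero value — the literal "at least
once per 1.5 years" at trimonthly sampling — with the window widened to 8
in sensitivity mode; a sliding-window variant is available via
`mode="sliding"`. Standardisation is per species per site with the n−1
standard deviation; raw abundances are carried alongside because CV and
synchrony are defined on the original scale. Temperature used as a
predictor is transformed as ln(°C·9/5 + 32): Fahrenheit keeps winter values
positive so the log exists.

## Embedding and cross mapping

Embedding dimension E is selected per series by leave-one-out simplex
projection over E ∈ {2,…,9}, minimising the one-step mean absolute error
(ties to the smaller E). Simplex uses the standard E+1 nearest neighbours
with weights exp(−d/d_min) and a temporal exclusion radius of E points so
neighbouring rows of short seasonal series cannot self-match; neighbour
ties break toward the earlier time index.

Cross mapping predicts the cause at lag 0, −1 or −2 from the effect's
embedding. Library lengths run from 10 to the full length in steps of 5 by
default; at each length the mean ρ over 100 random library subsamples is
reported (a single evaluation at the full library). The implementation
precomputes the embedding's distance matrix once and evaluates all
subsamples of a length in one vectorised pass, which is what makes the
Monte-Carlo acceptance studies tractable on one CPU; the benchmark studies
in the test suite use a step-20 grid and 50 subsamples per length, which
changes only the Monte-Carlo smoothness of ρ(L), not the statistic.

A link is accepted when all three hold: (1) full-library ρ exceeds the
95th percentile of ρ over 100 seasonal surrogates of the cause; (2)
one-sided Kendall τ on ρ(L) gives p < 0.05; (3) one-sided Fisher z
comparing ρ at the largest vs smallest library gives p < 0.05, with the
effective n being the number of prediction points (ρ clamped at
1 − 10⁻¹⁰ before the z-transform).

**Seasonal surrogates.** Surrogates preserve the seasonal climatology —
the across-year mean of each season — and permute the anomalies around it
uniformly across all time points. This is the construction that actually
factors seasonality out of the causal test: a skill that only reflects the
shared seasonal cycle cannot beat surrogates that contain the same cycle.
(Preserving *yearly* means instead destroys the cycle and lets shared
seasonality masquerade as causality; we verified the false-positive rate
on independent seasonal series roughly quadruples under that variant.)
Each surrogate is scored with the same best-lag selection (max ρ over the
lag set) as the real series; comparing a maximum against single-lag
surrogates would be anti-conservative.

**Pruning.** For accepted chains X→Y and Y→Z, an accepted X→Z is flagged
as indirect and removed iff it has BOTH a strictly more negative lag and a
strictly lower ρ than the first hop X→Y; the pass iterates to a fixed
point. Pruned links stay in the record for audit.

Network metrics: L accepted unpruned links, link density L/S, connectance
L/S², and food chain length defined (the literature leaves it open) as the
node count of the longest directed path with strictly ascending trophic
ranks.

## MDR S-map

For each node, candidate state-space reconstructions (SSRs) are E-sized
coordinate sets drawn from {node and its accepted causes} × {lags 0,1,2},
always containing the node at lag 0; 1000 candidates are sampled (or the
space enumerated when smaller) and the 100 with the highest leave-one-out
simplex skill ρ are kept. Weights w_c ∝ max(ρ_c, 0) normalised to sum 1
(negative-skill SSRs get weight 0); the multiview distance between two
time points is the w-weighted mean of the per-SSR Euclidean distances.
State weights follow the S-map kernel W_t(k) = exp(−θ d(t,k)/mean_k d(t,k))
with the mean taken over the row (the standard S-map normalisation; the
source description does not specify which mean).

At every prediction time t a weighted elastic net

    argmin_b Σ_k W_t(k) (y_k − b₀ − x_k·b)² + λ[α‖b‖₂² + (1−α)‖b‖₁]

is solved for the node's next value on its causes (plus itself) at time t.
Note the convention: α multiplies the *ridge* term — the reverse of the
glmnet convention — implemented exactly as the method defines it. The
intercept is unpenalised and discarded. The solver is coordinate descent
on the weighted Gram system (tolerance 10⁻⁷ on the max coefficient change),
run in lockstep across all prediction times; the pure-ridge path (α = 1)
uses the batched closed form. Hyperparameters are selected per node over
θ ∈ {0, 0.1, 0.5, 1, 2, 4, 8}, λ ∈ 10^{−4…1} (6 log steps),
α ∈ {0, 0.25, 0.5, 0.75, 1} by leave-one-out rMSE of the one-step forecast
(the row's own weight set to 0); the reported Jacobians are refit with the
full weight matrix at the chosen triple. Entries without an accepted
causal link are structural zeros; a node with no accepted causes is
estimated from its own lag and flagged.

## Stability, synchrony, diversity

Structural stability is Tr(B_t) per time step; group contributions are the
partial diagonal sums over producers / consumers / predators and add to the
trace exactly. Temporal variability is CV = sd/mean (n−1 sd) of the summed
abundance over trailing windows of 6 points (12 in sensitivity mode),
stride 1, labelled by the window's last point; a zero-mean window yields a
missing value, and ln CV is carried for the statistics stage. Synchrony is
φ = var(total)/(Σᵢ sdᵢ)² per window, community-wide and per group; a
single-species group is reported as φ = 1 (trivially synchronous), and a
window with all-constant species is missing rather than 0/0. Richness
counts strictly positive abundances; Simpson is 1 − Σp², Shannon −Σp ln p
over the species present.

## Mixed models

Point-wise responses (Tr(J), group contributions) are modelled with
crossed random intercepts for site, year and season, fitted as variance
components in a single-group mixed model (the standard statsmodels
encoding of crossed effects); window-based responses (ln CV, φ) use a site
intercept only, since the moving window already absorbs year and season.
Inference is Wald z (95% CI, two-sided p); REML, L-BFGS. A variance
component estimated at zero triggers a refit without it, down to OLS when
all vanish, recorded in the estimate's metadata. Per-web trends are OLS
within site (skipping webs with fewer than 10 complete observations), and
`mediation_chain` reports the x→m and m→y slopes as a pair without
product-of-coefficients inference.

## Problem sizes used in validation

The acceptance studies run at sizes chosen to give stable Monte-Carlo
verdicts on a single CPU: 20 replicate coupled pairs (n = 400, coupling
0.1) for directional detection; 40 independent seasonal pairs (n = 120)
for false-positive control; Jacobian recovery on 5-species webs with 200
time points at process noise 0.02/0.1/0.25 × 3 seeds; mixed-model coverage
over 50 replicates of 19 sites × 80 points and type-I error over 200
replicates; temperature-trend checks over 8 seeded webs at sensitivity 0
vs 0.1.

## Known limitations

- Simplex/CCM assume a deterministic skeleton observed with modest noise;
  heavily zero-inflated or very short series violate this, which is exactly
  why the rare-species filter runs first.
- The reverse direction of a strongly coupled pair can still pass the
  causality criteria through entrainment (generalised synchrony); the
  false-direction error rate reported in the tests applies to weak-to-
  moderate coupling.
- Surrogate calibration assumes exchangeable anomalies; strongly
  phase-locked periodic dynamics beyond the seasonal climatology (e.g. a
  deterministic 2-year cycle) can defeat it.
- The Jacobian is estimated on standardised variables; element (i, j) is
  the raw-scale derivative times sd_j/sd_i. Trace-based comparisons across
  webs therefore compare standardised contraction rates.
- Mixed-model p-values are Wald; with few sites (< ~8) they are
  anti-conservative and the per-web OLS view should be preferred.
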