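# Methods

`forestnep` simulates the daily carbon budget of a forested grid cell
with an individual-based stand on a representative patch and a
ten-pool soil column underneath. This note records the model as
implemented: its equations, the parameters that matter, the design
choices made where the problem was genuinely open, and what the
synthetic forcing does and does not emulate.

## Model structure

Each grid cell (nominally 10 km × 10 km, fractional forest `coverage`)
carries one representative patch (default 900 m², 36 trees) of a single
forest type out of eight: ECF, DCF, CBF, DBF, EBF, EDBF, SRF, RF
(evergreen/deciduous conifer, mixed, deciduous/evergreen broadleaf,
evergreen–deciduous mixed, seasonal rain forest, rain forest). The
daily loop runs top-down:

1. **Soil physics.** Soil temperature T_s is air temperature smoothed
   by a first-order filter (time constant 15 d). The water bucket
   updates as `W_s' = clamp(W_s + P/10 − AET, 0, W_f)` (cm) with
   `AET = PET · W_s/W_f`; potential evapotranspiration is the Hamon
   daylength-weighted saturation-vapour formula — a deliberately simple
   temperature-based demand term, configurable.
2. **Canopy photosynthesis** (big leaf). The daily light-saturated
   maximum integrates a rectangular-hyperbola leaf light response over
   canopy depth and daylight hours:

   `GPP_m = (2 A_m D / K) · ln[(1 + √(1 + K·S·PAR/A_m)) / (1 + √(1 + K·S·PAR·e^(−K·LAI)/A_m))]`

   with `A_m` the leaf photosynthetic capacity (kgC·m⁻²·h⁻¹), `K` the
   Beer–Lambert extinction coefficient, `S` the light-response initial
   slope, `PAR` the noon canopy photosynthetically active radiation
   (W·m⁻²), `D` sunshine hours. Actual GPP is
   `GPP_d = min(GPP_m · F_c · F_w · F_t, α · N_s)` with α = 150 the
   assimilation C:N parameter and N_s plant-available soil nitrogen:
   - `F_c = 1 + (C_t − C_0)/(C_t + 2 C_0)` (CO₂ fertilization, unity at
     the reference concentration, asymptote 2);
   - `F_w = min[1, W_s/W_f + max(Rh − 0.5, 0.1)]^(W/2)` with `W` the
     species drought tolerance. The exponent placement keeps F_w in
     (0, 1] and monotone in both soil water and humidity;
   - `F_t`: a beta-type response on the cardinal temperatures
     (T_min, T_opt, T_max) with exponents `(T_max−T_opt)/(T_max−T_min)`
     and `(T_opt−T_min)/(T_max−T_min)` — the unique exponent pair that
     peaks at exactly 1 at T_opt and stays within [0, 1]; clamped to 0
     outside the cardinal range where the expression is undefined.
3. **Autotrophic respiration per tree.** Maintenance respiration uses a
   modified-Q10 law referenced to 15 °C, weighted by day/night hours:

   `R_m = Σ_k (1/24)[D·f(T_d) + (24−D)·f(T_n)] · R_k · C_k`,
   `f(T) = e^(0.069315(T−15) − 0.009(T−15)²)`

   where C_k is the leaf and fine-root pool for those components and
   live sapwood for branches/stems/coarse roots. 0.069315 = ln2/10
   doubles respiration per 10 °C near the reference; the quadratic term
   caps the response ~18.9 °C above it. Growth respiration is
   `R_g = r_g · max(GPP_d − R_m, 0)`, r_g = 0.25; the deficit branch is
   clamped because negative construction cost is unphysical. The daily
   net assimilate enters each tree's nonstructural buffer, which pays
   maintenance on dark days and may go transiently negative (trees are
   flagged carbon-starved beyond a 0.5 kgC deficit; no mortality rule
   is applied by default).
4. **Phenology and litter.** Deciduous canopies (DCF, DBF, EDBF) are
   active while the 10-day smoothed air temperature stays above the
   leaf-on threshold (5 °C, with 2 °C hysteresis on leaf-off so one
   cold snap does not thrash the canopy). The whole canopy sheds at
   the autumn off-transition; at the spring on-transition leaves flush
   back from the buffer up to the allometric and stand LAI caps
   (reserves may be borrowed — a chronically failing stand surfaces as
   carbon-starved). While off, the leaf pool is dormant bud/storage
   tissue: no leaf maintenance respiration and no background leaf
   litter. Active leaf and fine-root pools shed at constant daily
   turnover rates. Litter routes to the soil pools:
   leaf (and reproductive) litter splits 60/40 metabolic/structural
   above ground, fine roots the same below ground, branch/stem/coarse
   root litter feed the three woody pools whole.
5. **Soil decomposition.** Ten pools (surface and buried
   metabolic/structural litter, fine/coarse/below-ground woody litter,
   active/slow/resistant organic matter) with reference rates per day
   S = (0.021, 0.1, 0.027, 0.13, 0.01, 0.002, 0.002, 0.042, 0.001,
   3.5×10⁻⁵). Pool u loses `S_u · G_t · G_w · shield_u · C_u` daily
   (capped at the pool), where
   `G_t = e^(3.36 (T_s−40)/(T_s+31.79))`,
   `G_w = 1 − (W_s/(0.6 W_f) − 1)²` clamped to [0, 1] (optimum at 60 %
   of field capacity, zero when dry), and lignin shielding
   `shield = e^(−5 L_s)` applies to the structural pools (all pools via
   config). A fraction P_u of the flux is respired (heterotrophic
   respiration R_s) and the rest routes downstream by a fixed transfer
   matrix whose rows sum to exactly 1 − P_u, so carbon conservation per
   step is exact. Respired carbon mineralizes nitrogen at per-pool C:N
   ratios into N_s; plant uptake is GPP_d/α.
6. **Annual growth** (December 31). Each buffer spends 5 % on
   flower/fruit litter, refills leaf mass up to its allometric cap
   `0.18·DBH^1.5` kgC — subject to a stand-level budget
   `LAI_v · patch_area / SLA` so the canopy never overshoots the
   species' maximum LAI — then fine roots toward a 0.8 root:leaf ratio,
   then wood (60/25/15 stem/branch/coarse root; 10 % of the surplus
   retained as reserve). Stem allometry `C_stem = 0.06·DBH^2.5` (kgC,
   DBH cm) inverts in closed form to the new DBH;
   `height = 1.5·DBH^0.6`. These allometric coefficients and the
   allocation priority are package defaults, not published values.
   There is no establishment, mortality or succession: stand
   composition is fixed over a run.

Annual accounting: `NPP = Σ_d (GPP_d − R_m − R_g)`,
`R_s = Σ_d R_s,daily`, `NEP = NPP − R_s`. Internally fluxes are
kgC·m⁻²·d⁻¹ on a ground-area basis (per-tree quantities divided by
patch area); reporting converts explicitly (gC·m⁻², TgC, PgC).

## Regional accounting

Per-type totals are `Σ_cells NEP · area · coverage` (TgC·a⁻¹, annual
means over the reporting window); the national total is their sum in
PgC·a⁻¹. Relative contributions divide by the **net** total including
negative (carbon-source) types, so contributions sum to exactly 100 %
with source types negative. Percentages are rounded half-up to 2
decimals only at the reporting layer. Model-vs-tower evaluation sums
daily NEP to months and scores bias (sim − obs), RMSE and Pearson r
against NEE with its sign flipped to the NEP convention (positive =
sink).

## Spin-up

Soil carbon is equilibrated by recycling a single designated forcing
year until the relative change in total soil carbon between
consecutive cycles falls below 10⁻⁴. The resistant pool turns over on
a multi-decade timescale, so the spin-up is semi-analytically
accelerated by default: every 40 cycles the pools jump to the steady
state of the linear balance `x = litter + Tᵀx`, `C*_u = x_u / k_u`
(k_u the pool's summed daily rate over the cycle), after which cycling
continues until the convergence criterion is met on its own terms.
A `freeze_vegetation` mode (static stand, constant litter, no annual
allocation) provides the classical fixed-vegetation soil spin-up; note
the NEP/ecosystem-carbon identity intentionally does not hold in that
mode.

## Synthetic forcing

Four climate archetypes (cold-temperate, warm-temperate, subtropical,
tropical) stand in for station meteorology, chosen per forest type.
Daily mean temperature is a sinusoid (trough late January) plus an
AR(1) anomaly (lag-1 ρ = 0.8, marginal σ = 3 °C); the diurnal range is
~N(10, 2) °C, narrowed on wet days. Rain occurrence is a two-state
Markov chain whose stationary wet fraction equals the archetype's
wet-day probability (wet persistence +0.35), amounts exponential;
sunshine is a wet/dry-conditioned fraction of the astronomical day
length; noon PAR applies Angström–Prescott transmittance
(a = 0.25, b = 0.50) and a 0.48 PAR fraction to top-of-atmosphere noon
irradiance. Day/night temperatures split as
`T_d = T_avg + 0.5(T_max − T_avg)` with T_n closing the
daylength-weighted mean. Initial soils draw lognormal total carbon
(per-type means 10–15 kgC·m⁻², log-sd 0.3) split by fixed fractions
dominated by slow+resistant SOM; NDVI draws in the upper (forested)
part of the scene range [0.033, 0.687] and inverts linearly to initial
LAI via the per-type maximum (ECF/DCF 8.0, DBF 7.0, CBF 7.5; the other
four types use field-typical package values: EBF 7.0, EDBF 7.5,
SRF 6.0, RF 6.5). All draws descend from one seed via seed-sequence
spawning, so grids of any size are bit-reproducible and each cell's
stream is independent of grid size.

What the generator does **not** emulate: real geography and station
interpolation, snow-cover radiation effects, inter-annual climate
modes, disturbance, and the observed covariance of soil, climate and
vegetation. Passing tests therefore demonstrate internal correctness
(conservation, limits, convergence, determinism, directional
sensitivities) — not skill against real observations.

## Numerical choices and degenerate inputs

- Daily decomposition flux is capped at the pool size; float dust below
  zero is clipped. Conservation then closes to ~10⁻¹³ relative.
- F_t and G_w are clamped to 0 outside their physical domains rather
  than evaluating complex powers.
- The nitrogen cap uses the current day's N_s before uptake;
  mineralized N returns the same day after decomposition.
- The stem-allometry inverse is closed-form (power law), verified in
  tests against an independent bisection root-finder.
- Rounding of reported percentages is decimal half-up, never applied
  internally.
- Leap years are simulated as 366-day sums (real calendar); annual
  operations reject partial years.
- P_u (respired fractions), the transfer topology and per-pool C:N are
  not published for this model family; the defaults here are
  CENTURY-style (metabolic pools respire more than SOM; structural
  flux splits 70/30 active/slow; slow feeds active and resistant) and
  are config-overridable.

## Parameters at a glance

| Parameter | Default | Units | Note |
|---|---|---|---|
| α (assimilation C:N) | 150 | – | caps GPP_d at α·N_s |
| r_g | 0.25 | – | growth respiration coefficient |
| b (lignin shielding) | 5.0 | – | structural pools only (config) |
| e_w (moisture optimum) | 0.6 | – | G_w peaks at 0.6·W_f |
| S_u | see above | d⁻¹ | reference decomposition rates |
| A_m | 0.9–1.3 ×10⁻³ | kgC·m⁻²·h⁻¹ | per type, package default |
| K, S | 0.5–0.6, ~10⁻⁵ | –, per W·m⁻² | per type, package default |
| leaf/fine-root turnover | 0.0010 / 0.0015 | d⁻¹ | background litter |
| soil/phenology smoothing | 15 / 10 | d | first-order constants |
| spin-up tol / max cycles | 10⁻⁴ / 200 | – | per-cycle relative ΔC |

## Known limitations

Single species per patch; no competition beyond the shared canopy and
leaf budget; no mortality, recruitment or succession; one-layer soil,
no freeze–thaw or methane; phenology is a temperature mask only; the
water bucket has no runoff routing or snow; evaluation against real
towers requires the user to supply observed NEE. The default problem
sizes in tests and the reproduction script (≤ 8 cells, 12–36 trees,
1–3 simulated years after spin-up) are the package's chosen study
conditions for a desk-scale demonstration of the method.
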